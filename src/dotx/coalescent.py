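"""Neutral X/autosome diversity null via a discrete Wright-Fisher coalescent.

In an XO system a population of ``n_m`` males and ``n_f`` females carries
``2(n_m + n_f)`` copies of each autosome but only ``2 n_f + n_m`` X copies.
With equal sex numbers the X therefore has 3/4 the copies of an autosome, and
the classical neutral expectation for the ratio of X to autosomal pairwise
diversity is 0.75.

Rather than plugging in the closed-form effective sizes, this module samples
pairwise coalescence times by explicit generation-by-generation parent
sampling, so the 0.75 ratio (and its sex-ratio dependence) is an output of the
process, not an input.  Per locus, pi = 2 * mu * T where T is the coalescence
time of two sampled copies in generations: each lineage accumulates mutations
independently for T generations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CoalescentConfig

__all__ = ["simulate_diversity_coalescent", "pairwise_times_autosome", "pairwise_times_x"]


def pairwise_times_autosome(rng: np.random.Generator, n_males: int, n_females: int, n_loci: int) -> np.ndarray:
    """Coalescence times (generations) for pairs of autosomal gene copies.

    Each generation a lineage's copy descends from a uniformly chosen parent of
    either sex (probability 1/2 each, diploid autosomal inheritance) and one of
    that parent's two copies; two lineages coalesce when they pick the same
    parental copy.
    """
    times = np.zeros(n_loci, dtype=np.int64)
    active = np.arange(n_loci)
    gen = 0
    while active.size:
        gen += 1
        k = active.size
        parent_is_male = rng.integers(0, 2, size=(2, k)).astype(bool)
        pool = np.where(parent_is_male, n_males, n_females)
        parent_id = np.floor(rng.random((2, k)) * pool).astype(np.int64)
        copy = rng.integers(0, 2, size=(2, k))
        coal = (
            (parent_is_male[0] == parent_is_male[1])
            & (parent_id[0] == parent_id[1])
            & (copy[0] == copy[1])
        )
        times[active[coal]] = gen
        active = active[~coal]
    return times


def pairwise_times_x(rng: np.random.Generator, n_males: int, n_females: int, n_loci: int) -> np.ndarray:
    """Coalescence times for pairs of X-linked copies in an XO population.

    A female's two X copies are one maternal and one paternal; a male's single
    X is always maternal.  So a lineage carried by a male moves to its mother
    (a random female, either of her copies), while a lineage carried by a
    female moves to its mother or father with probability 1/2 each (a father
    contributes his single copy).
    """
    # initial sample: two distinct copies from the standing pool of
    # 2*n_females + n_males X copies; copy index >= 2*n_females => male carrier
    total = 2 * n_females + n_males
    if total < 2:
        raise ValueError("need at least two X copies in the population")
    c0 = rng.integers(0, total, size=n_loci)
    c1 = (c0 + 1 + rng.integers(0, total - 1, size=n_loci)) % total
    carrier_is_male = np.stack([c0 >= 2 * n_females, c1 >= 2 * n_females])

    times = np.zeros(n_loci, dtype=np.int64)
    active = np.arange(n_loci)
    gen = 0
    while active.size:
        gen += 1
        k = active.size
        is_male = carrier_is_male[:, active]
        # male carrier -> mother; female carrier -> father with prob 1/2
        to_father = (~is_male) & (rng.random((2, k)) < 0.5)
        parent_id = np.where(
            to_father,
            np.floor(rng.random((2, k)) * n_males).astype(np.int64),
            np.floor(rng.random((2, k)) * n_females).astype(np.int64),
        )
        copy = np.where(to_father, 0, rng.integers(0, 2, size=(2, k)))
        coal = (to_father[0] == to_father[1]) & (parent_id[0] == parent_id[1]) & (copy[0] == copy[1])
        carrier_is_male[:, active] = to_father
        times[active[coal]] = gen
        active = active[~coal]
    return times


def simulate_diversity_coalescent(cc: CoalescentConfig) -> pd.DataFrame:
    """Per-locus pairwise diversity for the X and autosomal compartments.

    Returns a long table with columns ``compartment`` ("X"/"autosome"),
    ``locus``, ``t_coal`` (generations) and ``pi`` (= 2 * mu * t_coal).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cc.seed, spawn_key=(11,)))
    t_a = pairwise_times_autosome(rng, cc.n_males, cc.n_females, cc.n_loci)
    t_x = pairwise_times_x(rng, cc.n_males, cc.n_females, cc.n_loci)
    frames = []
    for compartment, t in (("autosome", t_a), ("X", t_x)):
        frames.append(
            pd.DataFrame(
                {
                    "compartment": compartment,
                    "locus": np.arange(cc.n_loci),
                    "t_coal": t,
                    "pi": 2.0 * cc.mu * t,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def x_over_a_ratio(loci: pd.DataFrame) -> float:
    """Ratio of mean X-linked to mean autosomal per-locus pi."""
    mean_x = loci.loc[loci["compartment"] == "X", "pi"].mean()
    mean_a = loci.loc[loci["compartment"] == "autosome", "pi"].mean()
    return float(mean_x / mean_a)
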