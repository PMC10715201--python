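import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dotx.config import SimulationConfig
from dotx.simulate import generate_genome

settings.register_profile(
    "dotx",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dotx")


@pytest.fixture(scope="session")
def small_genome():
    """A compact simulated genome + truth shared by read-only tests."""
    cfg = SimulationConfig(
        seed=7,
        n_scaffolds=8,
        scaffold_length_range=(60_000, 120_000),
        n_genes=400,
    )
    genome, truth = generate_genome(cfg, with_sequences=False)
    return cfg, genome, truth


def make_window_table(medians: dict[str, float], n_windows: int = 6) -> pd.DataFrame:
    """Constant-ratio window table for classifier unit tests."""
    rows = []
    for scaffold, ratio in medians.items():
        for i in range(n_windows):
            rows.append((scaffold, i * 10_000, (i + 1) * 10_000, ratio))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "log2_ratio"])


def brute_force_pi(genotypes: np.ndarray) -> float:
    """Independent oracle: mean pairwise difference per genotyped site.

    ``genotypes`` is a (sites x haplotypes) array of 0/1 with -1 for missing.
    For each site with >= 2 called haplotypes, averages |a_i - a_j| over all
    haplotype pairs; returns the mean over genotyped sites (NaN if none).
    """
    per_site = []
    for site in genotypes:
        alleles = site[site >= 0]
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            abs(int(alleles[i]) - int(alleles[j]))
            for i in range(n)
            for j in range(i + 1, n)
        )
        per_site.append(diffs / (n * (n - 1) / 2))
    return float(np.mean(per_site)) if per_site else float("nan")


def genotypes_to_sites(genotypes: np.ndarray, scaffold: str = "s1") -> pd.DataFrame:
    """Convert a (sites x haplotypes) 0/1/-1 array to the per-site count table."""
    rows = []
    for pos, site in enumerate(genotypes, start=1):
        called = site[site >= 0]
        rows.append((scaffold, pos, len(called), int((called == 1).sum())))
    return pd.DataFrame(rows, columns=["scaffold", "pos", "n", "k"])
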