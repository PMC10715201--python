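"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a law the downstream stages are tested against: an XO
genome where male X coverage is half the female's, an 18-library expression
design with configurable sex-bias / tissue-specificity / dosage effects,
ortholog tables with per-element X-linkage proportions, and window tables with
configured X-vs-autosome shifts in GC, repeat density and diversity.  Each
simulated object is paired with a truth table so recovery can be asserted
exactly.

Determinism: all draws come from ``numpy`` Generators seeded from
``SimulationConfig.seed`` through fixed spawn keys, so the same config yields
byte-identical outputs, and generating one data type never perturbs another.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, SEXES, SimulationConfig, TISSUE_CONTEXTS

__all__ = [
    "Genome",
    "TruthTable",
    "generate_genome",
    "simulate_coverage",
    "simulate_ortholog_table",
    "simulate_expression",
    "simulate_landscape_windows",
    "simulate_partition_tables",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# spawn keys: one fixed stream per generator
_K_STRUCTURE, _K_SEQUENCE, _K_GENES, _K_COVERAGE, _K_EXPRESSION, _K_LANDSCAPE, _K_ORTHOLOG = range(1, 8)


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class Genome:
    """Simulated assembly: scaffold metadata plus (optionally) sequences."""

    scaffolds: pd.DataFrame  # scaffold, length, chrom_class, noisy, gc_target
    sequences: Optional[Mapping[str, str]]

    def lengths(self) -> dict[str, int]:
        return dict(zip(self.scaffolds["scaffold"], self.scaffolds["length"]))


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for every simulated scaffold and gene (each appears once)."""

    scaffolds: pd.DataFrame  # scaffold, chrom_class, noisy
    genes: pd.DataFrame  # gene, scaffold, chrom_class, sex_bias, tissue_specific

    def scaffold_classes(self) -> pd.Series:
        return self.scaffolds.set_index("scaffold")["chrom_class"]


def generate_genome(config: SimulationConfig, with_sequences: bool = True) -> tuple[Genome, TruthTable]:
    """Simulate scaffold structure, class labels, gene placement and sequences.

    Scaffolds are named ``scaffold_1`` (longest) downwards, mirroring assembly
    convention.  ``round(n_scaffolds * x_scaffold_fraction)`` scaffolds are
    X-linked; ``n_male_specific`` are Y-like (male coverage only); one optional
    confounder scaffold gets coverage that is noisy in both sexes.  X scaffolds
    receive a GC target shifted by ``gc_shift``.  Genes are placed on X and
    autosomal scaffolds with probability proportional to length, and a
    configured fraction receives sex-bias or tissue-specificity truth labels
    (disjoint sets).
    """
    config.validate()
    rng = _rng(config.seed, _K_STRUCTURE)
    n = config.n_scaffolds
    lo, hi = config.scaffold_length_range
    lengths = np.sort(rng.integers(lo, hi + 1, size=n))[::-1]
    names = [f"scaffold_{i + 1}" for i in range(n)]

    classes = np.array(["autosome"] * n, dtype=object)
    noisy = np.zeros(n, dtype=bool)
    perm = rng.permutation(n)
    n_x = config.n_x_scaffolds
    x_idx = perm[:n_x]
    ms_idx = perm[n_x : n_x + config.n_male_specific]
    classes[x_idx] = "X"
    classes[ms_idx] = "male_specific"
    if config.include_noisy_confounder:
        noisy[perm[n_x + config.n_male_specific]] = True

    gc_target = np.where(classes == "X", config.gc_base + config.gc_shift, config.gc_base)
    scaffolds = pd.DataFrame(
        {
            "scaffold": names,
            "length": lengths.astype(np.int64),
            "chrom_class": classes,
            "noisy": noisy,
            "gc_target": gc_target,
        }
    )

    sequences: Optional[dict[str, str]] = None
    if with_sequences:
        seq_rng = _rng(config.seed, _K_SEQUENCE)
        sequences = {}
        for row in scaffolds.itertuples():
            gc = row.gc_target
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            draw = seq_rng.choice(4, size=row.length, p=p)
            sequences[row.scaffold] = _BASES[draw].tobytes().decode("ascii")

    genes = _assign_genes(config, scaffolds)
    truth = TruthTable(scaffolds=scaffolds[["scaffold", "chrom_class", "noisy"]].copy(), genes=genes)
    return Genome(scaffolds=scaffolds, sequences=sequences), truth


def _assign_genes(config: SimulationConfig, scaffolds: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config.seed, _K_GENES)
    # genes live on X and autosomal scaffolds only (a Y-like scaffold in an XO
    # species is an artifact we detect, not a gene source)
    eligible = scaffolds[scaffolds["chrom_class"].isin(["X", "autosome"])]
    weights = eligible["length"].to_numpy(float)
    weights /= weights.sum()
    n_genes = config.n_genes
    pick = rng.choice(len(eligible), size=n_genes, p=weights)
    gene_scaffold = eligible["scaffold"].to_numpy(object)[pick]
    gene_class = eligible["chrom_class"].to_numpy(object)[pick]

    sex_bias = np.array(["none"] * n_genes, dtype=object)
    tissue_specific = np.array(["none"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    n_sb = round(config.fraction_sex_biased * n_genes)
    n_ts = round(config.fraction_tissue_specific * n_genes)
    sb_idx = order[:n_sb]
    ts_idx = order[n_sb : n_sb + n_ts]
    sex_bias[sb_idx] = np.where(np.arange(n_sb) % 2 == 0, "male", "female")
    tissue_specific[ts_idx] = [TISSUE_CONTEXTS[i % len(TISSUE_CONTEXTS)] for i in range(n_ts)]

    width = max(4, len(str(n_genes)))
    return pd.DataFrame(
        {
            "gene": [f"g{i:0{width}d}" for i in range(n_genes)],
            "scaffold": gene_scaffold,
            "chrom_class": gene_class,
            "sex_bias": sex_bias,
            "tissue_specific": tissue_specific,
        }
    )


def _window_grid(length: int, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, length)
    return starts, ends


def _draw_depth(rng: np.random.Generator, config: SimulationConfig, lam: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """Mean per-base depth per window given per-base rate ``lam``."""
    mean_reads = lam * spans
    if config.depth_noise_model == "poisson":
        reads = rng.poisson(mean_reads)
    else:  # negbinom: var = m + disp * m^2
        r = 1.0 / config.negbinom_dispersion
        reads = np.where(
            mean_reads > 0,
            rng.negative_binomial(r, r / (r + np.maximum(mean_reads, 1e-12))),
            0,
        )
    return reads / spans


def simulate_coverage(genome: Genome, truth: TruthTable, config: SimulationConfig) -> pd.DataFrame:
    """Windowed male/female depth table implementing the XO coverage law.

    Autosomal windows have per-base rate D in both sexes; X windows D in the
    female and D/2 in the hemizygous male; male-specific scaffolds D in the
    male and a small residual rate in the female; the confounder scaffold gets
    a shared log-normal per-window factor in *both* sexes, so its M:F ratio
    stays centred on zero while its depth is highly variable.
    """
    rng = _rng(config.seed, _K_COVERAGE)
    d = config.mean_depth
    rows = []
    for row in genome.scaffolds.itertuples():
        if row.length < config.window_size:
            warnings.warn(
                f"scaffold {row.scaffold} shorter than window size; emitting one truncated window",
                stacklevel=2,
            )
        starts, ends = _window_grid(row.length, config.window_size)
        spans = (ends - starts).astype(float)
        k = len(starts)
        if row.chrom_class == "X":
            lam_m, lam_f = np.full(k, d / 2), np.full(k, d)
        elif row.chrom_class == "male_specific":
            lam_m, lam_f = np.full(k, d), np.full(k, config.male_specific_female_rate * d)
        else:
            lam_m, lam_f = np.full(k, d), np.full(k, d)
        if row.noisy:
            factor = rng.lognormal(mean=0.0, sigma=config.noisy_sigma, size=k)
            lam_m, lam_f = lam_m * factor, lam_f * factor
        rows.append(
            pd.DataFrame(
                {
                    "scaffold": row.scaffold,
                    "start": starts,
                    "end": ends,
                    "male_depth": _draw_depth(rng, config, lam_m, spans),
                    "female_depth": _draw_depth(rng, config, lam_f, spans),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_ortholog_table(
    seed: int,
    element_proportions: Mapping[str, float],
    n_per_element: int | Mapping[str, int] = 100,
    truth: Optional[TruthTable] = None,
) -> pd.DataFrame:
    """Ortholog pairs whose per-element X-linkage follows binomial sampling.

    ``element_proportions`` maps outgroup Muller-element labels to the
    probability that an ortholog on that element is X-linked in the focal
    species.  Elements with zero requested orthologs are absent from the
    output.  When a :class:`TruthTable` is supplied, focal gene ids are drawn
    from truth genes of the matching class so labels stay consistent with it.
    """
    for element, p in element_proportions.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"element_proportions[{element!r}]: must be in [0, 1]")
    rng = _rng(seed, _K_ORTHOLOG)
    counts = (
        {e: int(n_per_element) for e in element_proportions}
        if isinstance(n_per_element, int)
        else {e: int(n_per_element.get(e, 0)) for e in element_proportions}
    )
    pools: dict[str, list[str]] = {}
    if truth is not None:
        for cls in ("X", "autosome"):
            ids = truth.genes.loc[truth.genes["chrom_class"] == cls, "gene"].tolist()
            pools[cls] = list(rng.permutation(ids))
    records = []
    for element in sorted(element_proportions):
        n = counts.get(element, 0)
        if n == 0:
            continue
        is_x = rng.random(n) < element_proportions[element]
        for i, x in enumerate(is_x):
            cls = "X" if x else "autosome"
            if pools.get(cls):
                gene = pools[cls].pop()
            else:
                gene = f"og_{element}_{i:04d}"
            records.append((gene, cls, element))
    return pd.DataFrame(records, columns=["focal_gene", "focal_class", "outgroup_location"])


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (f"{sex}_{tissue}_{rep}", sex, tissue, rep)
        for sex in SEXES
        for tissue in config.tissues
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample", "sex", "tissue", "replicate"]).set_index("sample")


def simulate_expression(config: SimulationConfig, truth: TruthTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM-scale expression matrix (genes x samples) plus its sample sheet.

    Per-gene baselines are log-uniform on ``baseline_tpm_range`` (heavy-tailed,
    as TPM distributions are); multiplicative log-normal noise with natural-log
    sd ``expression_sigma`` is applied per measurement.  Effects, applied to
    the mean before noise:

    - sex-biased genes (gonad only): male/female means shifted symmetrically to
      the configured fold-change, half the genes in each direction;
    - tissue-specific genes: ``tissue_specific_tpm`` in the focal context and
      ``tissue_specific_off_tpm`` elsewhere (ovary/testis = the sex-matched
      gonad);
    - dosage: in tissues configured ``uncompensated_half_X``, male means of all
      X-linked genes are halved -- the XO expression signature without
      compensation.
    """
    genes = truth.genes
    if len(genes) != config.n_genes:
        raise ConfigError("n_genes: truth table does not match config")
    rng = _rng(config.seed, _K_EXPRESSION)
    sheet = _sample_sheet(config)
    lo, hi = config.baseline_tpm_range
    u = rng.uniform(np.log10(lo), np.log10(hi), size=len(genes))
    # remap truth-biased genes' baselines into [sex_biased_min_tpm, hi]:
    # labels must be detectable above the expression floor to be meaningful
    sb_mask = (genes["sex_bias"] != "none").to_numpy()
    lo_sb = np.log10(max(config.sex_biased_min_tpm, lo))
    if np.log10(hi) > np.log10(lo):
        u[sb_mask] = lo_sb + (u[sb_mask] - np.log10(lo)) * (np.log10(hi) - lo_sb) / (
            np.log10(hi) - np.log10(lo)
        )
    base = 10.0 ** u

    sqrt_fold = np.sqrt(config.sex_bias_fold)
    is_x = (genes["chrom_class"] == "X").to_numpy()
    sb = genes["sex_bias"].to_numpy()
    ts = genes["tissue_specific"].to_numpy()

    values = {}
    for sample, meta in sheet.iterrows():
        mean = base.copy()
        # tissue-specific overrides
        if meta["tissue"] == "gonad":
            context = "testis" if meta["sex"] == "M" else "ovary"
        else:
            context = meta["tissue"]
        specific = ts != "none"
        mean[specific] = np.where(
            ts[specific] == context, config.tissue_specific_tpm, config.tissue_specific_off_tpm
        )
        # gonad sex bias (applied to non-specific genes by construction)
        if meta["tissue"] == "gonad":
            up = sb == ("male" if meta["sex"] == "M" else "female")
            down = (sb != "none") & ~up
            mean[up] *= sqrt_fold
            mean[down] /= sqrt_fold
        # dosage
        if config.dosage_mode.get(meta["tissue"]) == "uncompensated_half_X" and meta["sex"] == "M":
            mean[is_x] *= 0.5
        noise = (
            np.exp(rng.normal(0.0, config.expression_sigma, size=len(genes)))
            if config.expression_sigma > 0
            else 1.0
        )
        values[sample] = mean * noise
    matrix = pd.DataFrame(values, index=genes["gene"].to_numpy())
    matrix.index.name = "gene"
    return matrix, sheet


def simulate_landscape_windows(config: SimulationConfig, truth: TruthTable) -> dict[str, pd.DataFrame]:
    """Window tables for GC fraction, repeat fraction, and pi.

    X windows are shifted relative to autosomal ones by ``gc_shift`` (negative
    in the default, lower GC on the X), ``repeat_shift`` (positive, more
    repeats) and the ``pi_x_over_a_target`` mean ratio.  Pi is gamma-distributed
    (shape 2) around the compartment mean, mimicking the long right tail of
    windowed diversity.  Scaffold lengths are derived from the config's
    structure stream, so tables align with :func:`generate_genome` output.
    """
    rng = _rng(config.seed, _K_LANDSCAPE)
    s_rng = _rng(config.seed, _K_STRUCTURE)
    lo, hi = config.scaffold_length_range
    lengths = np.sort(s_rng.integers(lo, hi + 1, size=config.n_scaffolds))[::-1]
    scaffolds = truth.scaffolds
    tables: dict[str, list[pd.DataFrame]] = {"gc_fraction": [], "repeat_fraction": [], "pi": []}
    for i, row in enumerate(scaffolds.itertuples()):
        starts, ends = _window_grid(int(lengths[i]), config.window_size)
        k = len(starts)
        on_x = row.chrom_class == "X"
        gc = np.clip(
            rng.normal(config.gc_base + (config.gc_shift if on_x else 0.0), config.gc_sd, size=k), 0, 1
        )
        rep = np.clip(
            rng.normal(config.repeat_base + (config.repeat_shift if on_x else 0.0), config.repeat_sd, size=k),
            0,
            1,
        )
        pi_mean = config.pi_autosomal_mean * (config.pi_x_over_a_target if on_x else 1.0)
        pi = rng.gamma(shape=2.0, scale=pi_mean / 2.0, size=k) if pi_mean > 0 else np.zeros(k)
        for metric, vals in (("gc_fraction", gc), ("repeat_fraction", rep), ("pi", pi)):
            tables[metric].append(
                pd.DataFrame(
                    {
                        "scaffold": row.scaffold,
                        "start": starts,
                        "end": ends,
                        "value": vals,
                        "chrom_class": row.chrom_class,
                    }
                )
            )
    return {metric: pd.concat(parts, ignore_index=True) for metric, parts in tables.items()}


def simulate_partition_tables(
    seed: int,
    n_genes: int = 1500,
    x_fraction: float = 0.115,
    f_given_x: float = 0.55,
    f_given_a: float = 0.02,
    p_out2_x: Optional[Mapping[str, float]] = None,
    elements: Sequence[str] = ("A", "B", "C", "D", "E", "F"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint ortholog tables for the two-outgroup X-partition analysis.

    Each focal gene is X-linked with probability ``x_fraction``; its location
    in outgroup 1 is element F with probability ``f_given_x`` (X genes) or
    ``f_given_a`` (autosomal genes), otherwise a uniform draw from A-E.  Its
    X-linkage in outgroup 2 depends on the partition group with probabilities
    ``p_out2_x`` (defaults: X_in_F 0.50, X_not_F 0.45, autosomal 0.08 -- the
    effect directions the enrichment stage is built to detect).
    """
    probs = {"X_in_F": 0.50, "X_not_F": 0.45, "autosomal": 0.08}
    if p_out2_x:
        probs.update(p_out2_x)
    for group, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"p_out2_x[{group!r}]: must be in [0, 1]")
    rng = _rng(seed, _K_ORTHOLOG)
    non_f = [e for e in elements if e != "F"]
    records1, records2 = [], []
    for i in range(n_genes):
        gene = f"pg{i:05d}"
        focal = "X" if rng.random() < x_fraction else "autosome"
        p_f = f_given_x if focal == "X" else f_given_a
        loc1 = "F" if rng.random() < p_f else non_f[rng.integers(0, len(non_f))]
        if focal == "X":
            group = "X_in_F" if loc1 == "F" else "X_not_F"
        else:
            group = "autosomal"
        loc2 = "X" if rng.random() < probs[group] else "2"
        records1.append((gene, focal, loc1))
        records2.append((gene, focal, loc2))
    cols = ["focal_gene", "focal_class", "outgroup_location"]
    return pd.DataFrame(records1, columns=cols), pd.DataFrame(records2, columns=cols)
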