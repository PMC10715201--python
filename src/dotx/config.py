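"""Configuration objects: simulation design constants and pipeline run settings.

The simulation defaults encode the study design the analysis assumes: an XO
(male X-hemizygous, no Y) genome assembled into a few dozen scaffolds, male and
female whole-genome coverage binned in 10-kb windows, and an 18-library
RNA-seq design of 3 replicates x 2 sexes x 3 tissues (head, gonad, carcass).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Tuple

import yaml

TISSUES: Tuple[str, ...] = ("head", "gonad", "carcass")
SEXES: Tuple[str, str] = ("M", "F")
#: tissue contexts used for tissue-specificity calls: gonads are split by sex
TISSUE_CONTEXTS: Tuple[str, ...] = ("head", "carcass", "ovary", "testis")
DOSAGE_MODES: Tuple[str, ...] = ("compensated", "uncompensated_half_X")
DEPTH_NOISE_MODELS: Tuple[str, ...] = ("poisson", "negbinom")


class ConfigError(ValueError):
    """Raised when a configuration field fails validation; names the field."""


def _require(ok: bool, field_name: str, message: str) -> None:
    if not ok:
        raise ConfigError(f"{field_name}: {message}")


def _default_dosage_mode() -> Mapping[str, str]:
    # somatic tissues compensated, gonad with halved male X expression --
    # the effect-direction pattern the expression stage is built to detect
    return {"head": "compensated", "gonad": "uncompensated_half_X", "carcass": "compensated"}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generator settings for every synthetic input.

    All stochastic outputs are bit-reproducible for a fixed ``seed``; each
    generator draws from an independent, seed-derived stream so that e.g.
    requesting sequences does not perturb the coverage simulation.
    """

    seed: int = 0
    # genome structure
    n_scaffolds: int = 25
    x_scaffold_fraction: float = 0.08
    n_male_specific: int = 0
    include_noisy_confounder: bool = True
    scaffold_length_range: Tuple[int, int] = (100_000, 250_000)
    window_size: int = 10_000
    # coverage
    mean_depth: float = 30.0
    depth_noise_model: str = "poisson"
    negbinom_dispersion: float = 0.05
    male_specific_female_rate: float = 0.02  # residual cross-mapping, x mean_depth
    noisy_sigma: float = 0.6  # log-normal sigma of the shared per-window factor
    # expression design
    n_genes: int = 2_000
    n_replicates: int = 3
    tissues: Tuple[str, ...] = TISSUES
    baseline_tpm_range: Tuple[float, float] = (0.1, 1000.0)
    expression_sigma: float = 0.1  # natural-log sd of the log-normal noise
    sex_bias_fold: float = 4.0
    fraction_sex_biased: float = 0.10
    fraction_tissue_specific: float = 0.10
    tissue_specific_tpm: float = 20.0
    tissue_specific_off_tpm: float = 0.05
    # truth-labelled sex-biased genes draw baselines above this floor so every
    # truth label is detectable in principle (a bias below the quantification
    # floor is not a meaningful label)
    sex_biased_min_tpm: float = 2.0
    dosage_mode: Mapping[str, str] = field(default_factory=_default_dosage_mode)
    # landscape
    gc_base: float = 0.40
    gc_sd: float = 0.02
    gc_shift: float = -0.05
    repeat_base: float = 0.30
    repeat_sd: float = 0.05
    repeat_shift: float = 0.05
    pi_autosomal_mean: float = 0.01
    pi_x_over_a_target: float = 0.23

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require(self.n_scaffolds >= 1, "n_scaffolds", "must be >= 1")
        _require(0.0 <= self.x_scaffold_fraction <= 1.0, "x_scaffold_fraction", "must be in [0, 1]")
        _require(self.n_male_specific >= 0, "n_male_specific", "must be >= 0")
        n_special = (
            round(self.n_scaffolds * self.x_scaffold_fraction)
            + self.n_male_specific
            + int(self.include_noisy_confounder)
        )
        _require(
            n_special <= self.n_scaffolds,
            "n_scaffolds",
            "too few scaffolds for the requested X / male-specific / confounder counts",
        )
        lo, hi = self.scaffold_length_range
        _require(0 < lo <= hi, "scaffold_length_range", "must satisfy 0 < low <= high")
        _require(self.window_size > 0, "window_size", "must be > 0")
        _require(self.mean_depth >= 0, "mean_depth", "must be >= 0")
        _require(
            self.depth_noise_model in DEPTH_NOISE_MODELS,
            "depth_noise_model",
            f"must be one of {DEPTH_NOISE_MODELS}",
        )
        _require(self.negbinom_dispersion > 0, "negbinom_dispersion", "must be > 0")
        _require(
            0.0 <= self.male_specific_female_rate <= 1.0,
            "male_specific_female_rate",
            "must be in [0, 1]",
        )
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        blo, bhi = self.baseline_tpm_range
        _require(0 < blo <= bhi, "baseline_tpm_range", "must satisfy 0 < low <= high")
        _require(self.expression_sigma >= 0, "expression_sigma", "must be >= 0")
        _require(self.sex_bias_fold >= 1, "sex_bias_fold", "must be >= 1")
        _require(0.0 <= self.fraction_sex_biased <= 1.0, "fraction_sex_biased", "must be in [0, 1]")
        _require(
            0.0 <= self.fraction_tissue_specific <= 1.0,
            "fraction_tissue_specific",
            "must be in [0, 1]",
        )
        _require(
            self.fraction_sex_biased + self.fraction_tissue_specific <= 1.0,
            "fraction_sex_biased",
            "fraction_sex_biased + fraction_tissue_specific must be <= 1",
        )
        for tissue, mode in self.dosage_mode.items():
            _require(tissue in self.tissues, "dosage_mode", f"unknown tissue {tissue!r}")
            _require(mode in DOSAGE_MODES, "dosage_mode", f"unknown mode {mode!r}")
        _require(0.0 <= self.gc_base <= 1.0, "gc_base", "must be in [0, 1]")
        _require(0.0 <= self.gc_base + self.gc_shift <= 1.0, "gc_shift", "shifted GC must stay in [0, 1]")
        _require(self.pi_autosomal_mean >= 0, "pi_autosomal_mean", "must be >= 0")
        _require(self.pi_x_over_a_target >= 0, "pi_x_over_a_target", "must be >= 0")

    @property
    def n_x_scaffolds(self) -> int:
        return round(self.n_scaffolds * self.x_scaffold_fraction)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dosage_mode"] = dict(d["dosage_mode"])
        return d


@dataclass(frozen=True)
class CoalescentConfig:
    """Discrete Wright-Fisher population for pairwise coalescent sampling.

    ``n_males``/``n_females`` are breeding individuals per generation; autosomal
    loci have 2 gene copies per individual, X-linked loci 2 per female and 1 per
    male (XO males). ``mu`` is the per-base per-generation mutation rate.
    """

    n_males: int
    n_females: int
    mu: float = 1e-8
    n_loci: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_males >= 1, "n_males", "must be >= 1 (an all-female population has no X/A copy-number contrast)")
        _require(self.n_females >= 1, "n_females", "must be >= 1")
        _require(self.mu > 0, "mu", "must be > 0")
        _require(self.n_loci >= 1, "n_loci", "must be >= 1")


@dataclass
class RunConfig:
    """End-to-end pipeline settings: input paths plus every analysis threshold.

    Inputs left as ``None`` cause the corresponding stage to be skipped.
    """

    out_dir: str
    seed: int = 0
    # sex-linkage inputs: either a pre-binned joint window table, or per-sex
    # samtools-depth-style text files
    coverage_windows: Optional[str] = None
    male_depth: Optional[str] = None
    female_depth: Optional[str] = None
    scaffold_lengths: Optional[str] = None
    # homology inputs
    orthologs: Optional[str] = None
    orthologs2: Optional[str] = None
    f_element: str = "F"
    outgroup2_x_label: str = "X"
    # expression inputs
    abundance_dir: Optional[str] = None
    sample_sheet: Optional[str] = None
    gene_map: Optional[str] = None
    # landscape inputs (window metric tables, or raw fasta/RepeatMasker out)
    gc_table: Optional[str] = None
    repeat_table: Optional[str] = None
    pi_table: Optional[str] = None
    fasta: Optional[str] = None
    rm_out: Optional[str] = None
    # thresholds (analysis defaults)
    window_size: int = 10_000
    delta: float = 0.5
    pseudocount: float = 0.1
    min_raw_depth: float = 3.0
    min_windows: int = 5
    female_max: float = 1.0
    male_min: float = 5.0
    min_hit_score: float = 50.0
    max_overlap: int = 20
    tpm_floor: float = 0.5
    tissue_high: float = 1.0
    fold: float = 2.0
    q_threshold: float = 0.05
    pi_window: int = 28_000

    def validate(self) -> None:
        _require(bool(self.out_dir), "out_dir", "must be set")
        for name in (
            "window_size",
            "delta",
            "min_windows",
            "min_hit_score",
            "max_overlap",
            "tpm_floor",
            "tissue_high",
            "fold",
            "q_threshold",
            "pi_window",
        ):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.pseudocount >= 0, "pseudocount", "must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
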