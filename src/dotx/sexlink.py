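"""Sex-linked scaffold classification from male/female coverage.

In an XO male the X is present in one copy against two autosomal copies, so
X-linked scaffolds show male:female depth ratios near 1/2 (log2 ratio near
-1).  The classifier bins depth into fixed windows, median-normalizes each
sex's library, computes per-window log2(M/F), and assigns a scaffold to the X
when its per-scaffold median ratio falls below a genome-wide cutoff of
``median(all window ratios) - delta`` (delta = 0.5 by default).  A separate
screen reports scaffolds with appreciable male but near-zero female coverage,
the genomic signature of a Y chromosome.

Coordinates are 0-based half-open (BED convention) throughout.
"""
from __future__ import annotations

import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "bin_depth",
    "normalize_sex_depth",
    "window_log2_ratio",
    "classify_scaffolds",
    "detect_male_specific",
]

_WINDOW_KEY = ["scaffold", "start", "end"]


def bin_depth(
    depth: pd.DataFrame,
    window_size: int,
    scaffold_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Bin a per-base depth table (samtools-depth style) into window means.

    ``depth`` has columns ``scaffold``, ``pos`` (1-based) and ``depth``;
    positions must be strictly increasing within each scaffold.  Positions
    absent from the table count as depth 0, i.e. each window's value is the sum
    of reported depths divided by the full window span.  The last window of a
    scaffold may be shorter than ``window_size``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    cols = ["scaffold", "start", "end", "depth"]
    if depth.empty:
        return pd.DataFrame(columns=cols)
    out = []
    for scaffold, grp in depth.groupby("scaffold", sort=True):
        pos = grp["pos"].to_numpy(np.int64)
        if pos.size > 1 and not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing within scaffold {scaffold}")
        if (pos < 1).any():
            raise ValueError(f"positions must be 1-based (scaffold {scaffold})")
        length = int(pos.max())
        if scaffold_lengths is not None and scaffold in scaffold_lengths:
            length = max(int(scaffold_lengths[scaffold]), length)
        n_windows = math.ceil(length / window_size)
        sums = np.bincount((pos - 1) // window_size, weights=grp["depth"].to_numpy(float), minlength=n_windows)
        starts = np.arange(n_windows, dtype=np.int64) * window_size
        ends = np.minimum(starts + window_size, length)
        out.append(
            pd.DataFrame(
                {"scaffold": scaffold, "start": starts, "end": ends, "depth": sums / (ends - starts)}
            )
        )
    return pd.concat(out, ignore_index=True)


def normalize_sex_depth(male_windows: pd.DataFrame, female_windows: pd.DataFrame) -> pd.DataFrame:
    """Join per-sex window tables and normalize by each sex's median depth.

    Depths are divided by the sex's genome-wide median window depth so an
    autosomal window has expected normalized depth 1 in both sexes regardless
    of library size; the raw depths are retained for masking and for the
    male-specific screen.
    """
    m = male_windows.rename(columns={"depth": "male_depth"})
    f = female_windows.rename(columns={"depth": "female_depth"})
    joined = m.merge(f, on=_WINDOW_KEY, how="inner")
    if len(joined) != len(m) or len(joined) != len(f):
        raise ValueError("male and female tables must share an identical windowing")
    med_m = float(joined["male_depth"].median())
    med_f = float(joined["female_depth"].median())
    if med_m == 0 or med_f == 0:
        raise ValueError(
            "zero median window depth in one sex; median normalization undefined "
            "(compute ratios on raw depths instead)"
        )
    joined["male_norm"] = joined["male_depth"] / med_m
    joined["female_norm"] = joined["female_depth"] / med_f
    return joined


def window_log2_ratio(
    windows: pd.DataFrame, pseudocount: float = 0.1, min_raw_depth: float = 3.0
) -> pd.DataFrame:
    """Add per-window ``log2_ratio`` = log2((M + pc) / (F + pc)) on normalized depths.

    Windows where *both* raw depths fall below ``min_raw_depth`` are masked
    (ratio set to NaN): a ratio between two noise-level depths carries no
    linkage signal and would otherwise dominate scaffold medians.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = windows.copy()
    num = out["male_norm"] + pseudocount
    den = out["female_norm"] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(num / den)
    masked = (out["male_depth"] < min_raw_depth) & (out["female_depth"] < min_raw_depth)
    ratio = np.where(masked | ~np.isfinite(ratio), np.nan, ratio)
    out["log2_ratio"] = ratio
    return out


def classify_scaffolds(
    windows: pd.DataFrame, delta: float = 0.5, min_windows: int = 5
) -> pd.DataFrame:
    """Per-scaffold X/autosome calls against the median-relative cutoff.

    The global cutoff is ``median(all unmasked window log2 ratios) - delta``;
    a scaffold is X-linked iff its per-scaffold median ratio is strictly below
    the cutoff.  Scaffolds with fewer than ``min_windows`` usable windows are
    left ``unassigned`` rather than forced into a class.
    """
    ratios = windows["log2_ratio"]
    usable = ratios.dropna()
    if usable.empty:
        raise ValueError("all windows are masked; no usable log2 ratios")
    cutoff = float(usable.median()) - delta
    rows = []
    for scaffold, grp in windows.groupby("scaffold", sort=True):
        used = grp["log2_ratio"].dropna()
        med = float(used.median()) if len(used) else float("nan")
        if len(used) < min_windows:
            cls = "unassigned"
        elif med < cutoff:
            cls = "X"
        else:
            cls = "autosome"
        rows.append((scaffold, len(grp), len(used), med, cutoff, cls))
    return pd.DataFrame(
        rows,
        columns=["scaffold", "n_windows", "n_used_windows", "median_log2_ratio", "global_cutoff", "chrom_class"],
    )


def detect_male_specific(
    windows: pd.DataFrame, female_max: float = 1.0, male_min: float = 5.0
) -> list[str]:
    """Scaffolds with Y-like coverage: median female depth <= ``female_max``
    and median male depth >= ``male_min``, on raw (pre-normalization) depths.
    """
    out = []
    for scaffold, grp in windows.groupby("scaffold", sort=True):
        if grp["female_depth"].median() <= female_max and grp["male_depth"].median() >= male_min:
            out.append(scaffold)
    return out


def sexlink_pipeline(
    male_windows: pd.DataFrame,
    female_windows: pd.DataFrame,
    delta: float = 0.5,
    pseudocount: float = 0.1,
    min_raw_depth: float = 3.0,
    min_windows: int = 5,
    female_max: float = 1.0,
    male_min: float = 5.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Convenience chain: normalize -> ratio -> classify + male-specific screen."""
    joined = normalize_sex_depth(male_windows, female_windows)
    joined = window_log2_ratio(joined, pseudocount=pseudocount, min_raw_depth=min_raw_depth)
    calls = classify_scaffolds(joined, delta=delta, min_windows=min_windows)
    candidates = detect_male_specific(joined, female_max=female_max, male_min=male_min)
    calls["male_specific_candidate"] = calls["scaffold"].isin(candidates)
    return calls, candidates
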