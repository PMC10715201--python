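"""Windowed genome landscape metrics: GC, repeat density, nucleotide diversity.

All coordinates are 0-based half-open.  GC is computed per fixed window with N
bases excluded from the denominator; repeat density is the fraction of window
bases covered by the *union* of repeat annotations (so stacked annotations
never push a window above 1); pi follows the pixy convention -- missing
genotypes reduce the per-site allele count rather than dropping the site, and
only genotyped sites enter the denominator, so missing data cannot deflate
diversity.  An X-vs-autosome summary reports medians, the X/A ratio of means,
and Wilcoxon rank-sum p-values BH-adjusted across metrics.
"""
from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._stats import bh_adjust, rank_sum_test

__all__ = [
    "gc_windows",
    "repeat_windows",
    "classify_repeat_family",
    "repeat_class_summary",
    "parse_repeatmasker_out",
    "nucleotide_diversity",
    "sites_from_vcf",
    "xa_summary",
]

DNA_TRANSPOSON = "dna_transposon"
RETROTRANSPOSON = "retrotransposon"
OTHER_REPEAT = "other"


def _load_sequences(source) -> Mapping[str, str]:
    if isinstance(source, (str, Path)):
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}
    return source


def gc_windows(fasta, window_size: int = 10_000) -> pd.DataFrame:
    """Per-window GC fraction: (G+C) / (A+C+G+T), Ns excluded; all-N masked (NaN)."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    sequences = _load_sequences(fasta)
    frames = []
    for scaffold in sequences:
        seq = sequences[scaffold].upper().encode("ascii")
        arr = np.frombuffer(seq, dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        starts = np.arange(0, len(arr), window_size, dtype=np.int64)
        gc = np.add.reduceat(is_gc.astype(np.int64), starts)
        acgt = np.add.reduceat(is_acgt.astype(np.int64), starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(acgt > 0, gc / np.maximum(acgt, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "start": starts,
                    "end": np.minimum(starts + window_size, len(arr)),
                    "value": value,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    order = np.argsort(starts, kind="mergesort")
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def repeat_windows(
    annotations: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Fraction of each window covered by the union of repeat annotations."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    frames = []
    grouped = dict(tuple(annotations.groupby("scaffold"))) if len(annotations) else {}
    for scaffold, length in scaffold_lengths.items():
        n_windows = math.ceil(length / window_size)
        covered = np.zeros(n_windows)
        if scaffold in grouped:
            grp = grouped[scaffold]
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            if (ends > length).any() or (starts < 0).any():
                warnings.warn(
                    f"annotations beyond scaffold {scaffold} bounds clipped", stacklevel=2
                )
                starts = np.clip(starts, 0, length)
                ends = np.clip(ends, 0, length)
            for s, e in _merge_intervals(starts, ends):
                first, last = s // window_size, (max(e, s + 1) - 1) // window_size
                for w in range(first, min(last, n_windows - 1) + 1):
                    w_start, w_end = w * window_size, min((w + 1) * window_size, length)
                    covered[w] += max(0, min(e, w_end) - max(s, w_start))
        w_starts = np.arange(n_windows, dtype=np.int64) * window_size
        w_ends = np.minimum(w_starts + window_size, length)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "start": w_starts,
                    "end": w_ends,
                    "value": covered / (w_ends - w_starts),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def classify_repeat_family(family: str) -> str:
    """Map a RepeatMasker class/family string onto a coarse repeat class."""
    fam = family.upper()
    if "DNA" in fam:
        return DNA_TRANSPOSON
    if any(tag in fam for tag in ("LINE", "SINE", "LTR")):
        return RETROTRANSPOSON
    return OTHER_REPEAT


def repeat_class_summary(
    annotations: pd.DataFrame, classes: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Masked-base totals and proportions per (chromosome class x repeat class)."""
    ann = annotations.copy()
    if "repeat_class" not in ann.columns:
        ann["repeat_class"] = ann["family"].map(classify_repeat_family)
        unknown = sorted(ann.loc[ann["repeat_class"] == OTHER_REPEAT, "family"].unique())
        if unknown:
            warnings.warn(f"families counted as 'other': {unknown}", stacklevel=2)
    cls = pd.Series(classes)
    ann["chrom_class"] = ann["scaffold"].map(cls)
    ann = ann[ann["chrom_class"].isin(["X", "autosome"])]
    ann["bases"] = ann["end"] - ann["start"]
    totals = ann.groupby(["chrom_class", "repeat_class"], sort=True)["bases"].sum().reset_index()
    totals["proportion"] = totals["bases"] / totals.groupby("chrom_class")["bases"].transform("sum")
    return totals


def parse_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse RepeatMasker ``.out`` (fixed-width dialect with 3 header lines).

    Returns 0-based half-open intervals with the raw class/family string and
    its coarse repeat class.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 11:
                continue
            try:
                int(fields[0])  # SW score; header lines fail here
            except ValueError:
                continue
            rows.append(
                {
                    "scaffold": fields[4],
                    "start": int(fields[5]) - 1,
                    "end": int(fields[6]),
                    "strand": fields[8],
                    "name": fields[9],
                    "family": fields[10],
                }
            )
    out = pd.DataFrame(rows, columns=["scaffold", "start", "end", "strand", "name", "family"])
    if len(out):
        out["repeat_class"] = out["family"].map(classify_repeat_family)
    return out


def nucleotide_diversity(
    sites: pd.DataFrame,
    window_size: int = 28_000,
    scaffold_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Windowed pi from per-site allele counts.

    ``sites`` has columns ``scaffold``, ``pos`` (1-based), ``n`` (genotyped
    allele count) and ``k`` (alternate-allele count).  Sites with n < 2 are not
    genotyped and are excluded from numerator and denominator.  Per window,
    pi = mean over genotyped sites of k(n-k)/C(n,2); windows with zero
    genotyped sites are masked (NaN).
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    s = sites[sites["n"] >= 2].copy()
    n = s["n"].to_numpy(float)
    k = s["k"].to_numpy(float)
    if ((k < 0) | (k > n)).any():
        raise ValueError("alternate-allele count k must satisfy 0 <= k <= n")
    s["contrib"] = k * (n - k) / (n * (n - 1) / 2.0)
    s["window"] = (s["pos"] - 1) // window_size

    per_scaffold: dict[str, pd.DataFrame] = {
        scaffold: grp for scaffold, grp in s.groupby("scaffold")
    }
    if scaffold_lengths is None:
        # tile from every input site (genotyped or not) so fully missing
        # regions still yield masked windows
        scaffold_lengths = {
            scaffold: int(grp["pos"].max()) for scaffold, grp in sites.groupby("scaffold")
        }
    if not scaffold_lengths:
        return pd.DataFrame(columns=["scaffold", "start", "end", "n_sites", "value"])
    frames = []
    for scaffold, length in scaffold_lengths.items():
        n_windows = math.ceil(length / window_size)
        total = np.zeros(n_windows)
        count = np.zeros(n_windows, dtype=np.int64)
        if scaffold in per_scaffold:
            grp = per_scaffold[scaffold]
            idx = grp["window"].to_numpy(np.int64)
            total = np.bincount(idx, weights=grp["contrib"].to_numpy(), minlength=n_windows)
            count = np.bincount(idx, minlength=n_windows)
        starts = np.arange(n_windows, dtype=np.int64) * window_size
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "start": starts,
                    "end": np.minimum(starts + window_size, length),
                    "n_sites": count,
                    "value": value,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sites_from_vcf(path: str | Path) -> pd.DataFrame:
    """Per-site genotyped/alternate allele counts from a VCF (all-sites style).

    Invariant records (no ALT) contribute k = 0; missing genotypes reduce the
    genotyped allele count n.  Multiallelic records are skipped with a warning.
    """
    from cyvcf2 import VCF

    rows = []
    skipped = 0
    for variant in VCF(str(path)):
        if len(variant.ALT) > 1:
            skipped += 1
            continue
        n = 0
        k = 0
        for genotype in variant.genotypes:
            for allele in genotype[:-1]:  # last element is the phasing flag
                if allele is not None and allele >= 0:
                    n += 1
                    if allele > 0:
                        k += 1
        rows.append({"scaffold": variant.CHROM, "pos": variant.POS, "n": n, "k": k})
    if skipped:
        warnings.warn(f"{skipped} multiallelic records skipped", stacklevel=2)
    return pd.DataFrame(rows, columns=["scaffold", "pos", "n", "k"])


def xa_summary(
    metric_tables: Mapping[str, pd.DataFrame],
    classes: Optional[Mapping[str, str] | pd.Series] = None,
) -> pd.DataFrame:
    """X-vs-autosome comparison per metric.

    Each table needs ``value`` plus either a ``chrom_class`` column or a
    ``scaffold`` column resolvable through ``classes``.  Reports medians, the
    X/A ratio of means, and a Wilcoxon rank-sum p-value (skipped when a class
    has fewer than 2 unmasked windows), BH-adjusted across metrics.
    """
    rows = []
    for metric, table in metric_tables.items():
        t = table.copy()
        if "chrom_class" not in t.columns:
            if classes is None:
                raise ValueError(f"metric {metric!r}: no chrom_class column and no classes map")
            t["chrom_class"] = t["scaffold"].map(pd.Series(classes))
        x = t.loc[t["chrom_class"] == "X", "value"].dropna()
        a = t.loc[t["chrom_class"] == "autosome", "value"].dropna()
        if len(x) == 0 or len(a) == 0:
            raise ValueError(f"metric {metric!r}: both X and autosome windows required")
        tested = len(x) >= 2 and len(a) >= 2
        if not tested:
            warnings.warn(f"metric {metric!r}: too few windows, test skipped", stacklevel=2)
        rows.append(
            (
                metric,
                len(x),
                len(a),
                float(x.median()),
                float(a.median()),
                float(x.mean() / a.mean()) if a.mean() != 0 else float("nan"),
                rank_sum_test(x, a) if tested else float("nan"),
                tested,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["metric", "n_x", "n_autosome", "median_x", "median_autosome", "xa_ratio_of_means", "p_value", "tested"],
    )
    out["q_value"] = bh_adjust(out["p_value"])
    return out
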