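"""X gene-content homology: best-hit resolution and Muller-element enrichment.

Transcripts placed on an outgroup genome (BLAT-style hits) are reduced to a
nonredundant set, linked to outgroup chromosomes / Muller elements, and tested
for overrepresentation of focal-X genes per element against the global
"X-linkage threshold" (the overall proportion of orthologs that are X-linked
in the focal species).  A partition analysis splits focal X genes by whether
their outgroup-1 homolog sits on element F and compares each set's X-linkage
in a second, more distant outgroup against the autosomal background.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import bh_adjust, chi2_2x2

__all__ = [
    "resolve_best_hits",
    "x_linkage_threshold",
    "element_enrichment",
    "partition_x_by_outgroup",
    "PartitionResult",
    "read_psl",
]

_HIT_COLS = ["query", "target", "target_start", "target_end", "score"]


def resolve_best_hits(
    hits: pd.DataFrame, min_score: float = 50.0, max_overlap: int = 20
) -> pd.DataFrame:
    """Reduce raw transcript placements to a nonredundant set.

    Three rules, applied in order: (1) drop hits with score <= ``min_score``
    (strictly "above" the threshold survives); (2) keep one best-scoring hit
    per query (ties broken by (target, target_start) order, with a warning);
    (3) among the retained placements on a common target, when two intervals
    overlap by more than ``max_overlap`` bases, drop the lower-scoring
    transcript -- overlaps of at most ``max_overlap`` keep both.  Placements
    are processed in descending score order with lexicographic query-id
    tie-breaks, which makes the retained set independent of input row order.
    """
    missing = [c for c in _HIT_COLS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    h = hits[hits["score"] > min_score].copy()
    if h.empty:
        return h.reset_index(drop=True)

    top = h.groupby("query")["score"].transform("max")
    ties = h[h["score"] == top].groupby("query").size()
    tied = ties[ties > 1]
    if len(tied):
        warnings.warn(
            f"{len(tied)} queries have tied best scores; keeping first by (target, start)",
            stacklevel=2,
        )
    h = h.sort_values(
        ["query", "score", "target", "target_start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("query", keep="first")

    h = h.sort_values(["score", "query"], ascending=[False, True], kind="mergesort")
    kept_index: list = []
    kept_intervals: dict[str, list[tuple[int, int]]] = {}
    for row in h.itertuples():
        intervals = kept_intervals.setdefault(row.target, [])
        if all(
            min(e, row.target_end) - max(s, row.target_start) <= max_overlap for s, e in intervals
        ):
            intervals.append((row.target_start, row.target_end))
            kept_index.append(row.Index)
    return (
        h.loc[kept_index]
        .sort_values(["target", "target_start", "query"], kind="mergesort")
        .reset_index(drop=True)
    )


def x_linkage_threshold(pairs: pd.DataFrame) -> float:
    """Global proportion of orthologs X-linked in the focal species."""
    if pairs.empty:
        raise ValueError("ortholog table is empty")
    return float((pairs["focal_class"] == "X").mean())


def element_enrichment(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-element X-linkage enrichment against all other elements.

    For each outgroup element the 2x2 table {this element vs. the rest} x
    {X-linked vs. not} is tested with a Yates-corrected chi-squared.  An
    element is flagged overrepresented when its raw p-value is below ``alpha``
    *and* its X-linked proportion exceeds the global X-linkage threshold;
    BH-adjusted p-values are reported alongside.
    """
    elements = sorted(pairs["outgroup_location"].dropna().unique())
    if len(elements) < 2:
        raise ValueError("need at least 2 outgroup elements for enrichment testing")
    threshold = x_linkage_threshold(pairs)
    is_x = (pairs["focal_class"] == "X").to_numpy()
    loc = pairs["outgroup_location"].to_numpy()
    rows = []
    for element in elements:
        on = loc == element
        n = int(on.sum())
        if n == 0:
            warnings.warn(f"element {element}: no orthologs, skipped", stacklevel=2)
            continue
        a = int((on & is_x).sum())
        c = int((~on & is_x).sum())
        stat, p = chi2_2x2([[a, n - a], [c, int((~on).sum()) - c]])
        rows.append((element, n, a, a / n, threshold, stat, p))
    out = pd.DataFrame(
        rows, columns=["element", "n", "n_x", "prop_x", "threshold", "chi2_stat", "p_value"]
    )
    out["q_value"] = bh_adjust(out["p_value"])
    out["overrepresented"] = (out["p_value"] < alpha) & (out["prop_x"] > out["threshold"])
    return out


@dataclass(frozen=True)
class PartitionResult:
    """X-gene partition by outgroup-1 location, scored in outgroup 2.

    ``groups`` has one row per group (X_in_F, X_not_F, autosomal) with its size
    and proportion X-linked in outgroup 2; ``comparisons`` holds the chi-squared
    tests of each X group against the autosomal background (BH-adjusted).
    """

    groups: pd.DataFrame
    comparisons: pd.DataFrame


def partition_x_by_outgroup(
    pairs_out1: pd.DataFrame,
    pairs_out2: pd.DataFrame,
    f_label: str = "F",
    x_label: str = "X",
    alpha: float = 0.05,
) -> PartitionResult:
    """Split focal X genes by element-F ancestry and score X-linkage in outgroup 2.

    ``pairs_out1`` assigns each focal gene an outgroup-1 element; focal X genes
    whose homolog is on ``f_label`` form "X_in_F", the remainder "X_not_F",
    and focal autosomal genes the background.  ``pairs_out2`` supplies each
    gene's outgroup-2 location; a gene counts as X-linked there when that
    location equals ``x_label``.  Groups of fewer than 2 genes report their
    proportion but skip the test (with a warning).
    """
    joined = pairs_out1[["focal_gene", "focal_class", "outgroup_location"]].merge(
        pairs_out2[["focal_gene", "outgroup_location"]],
        on="focal_gene",
        suffixes=("_1", "_2"),
    )
    if joined.empty:
        raise ValueError("no shared genes between the two ortholog tables")
    group = np.where(
        joined["focal_class"] == "X",
        np.where(joined["outgroup_location_1"] == f_label, "X_in_F", "X_not_F"),
        "autosomal",
    )
    joined = joined.assign(group=group, x_out2=joined["outgroup_location_2"] == x_label)

    rows = []
    for name in ("X_in_F", "X_not_F", "autosomal"):
        sub = joined[joined["group"] == name]
        n = len(sub)
        k = int(sub["x_out2"].sum())
        rows.append((name, n, k, k / n if n else float("nan")))
    groups = pd.DataFrame(rows, columns=["group", "n", "n_x_outgroup2", "prop_x_outgroup2"])

    bg = groups.set_index("group").loc["autosomal"]
    comps = []
    for name in ("X_in_F", "X_not_F"):
        g = groups.set_index("group").loc[name]
        if g["n"] < 2 or bg["n"] < 2:
            warnings.warn(f"group {name}: fewer than 2 genes, test skipped", stacklevel=2)
            comps.append((name, "autosomal", float("nan"), float("nan"), False))
            continue
        table = [
            [g["n_x_outgroup2"], g["n"] - g["n_x_outgroup2"]],
            [bg["n_x_outgroup2"], bg["n"] - bg["n_x_outgroup2"]],
        ]
        stat, p = chi2_2x2(table)
        comps.append((name, "autosomal", stat, p, True))
    comparisons = pd.DataFrame(
        comps, columns=["group", "versus", "chi2_stat", "p_value", "tested"]
    )
    comparisons["q_value"] = bh_adjust(comparisons["p_value"])
    return PartitionResult(groups=groups, comparisons=comparisons)


def read_psl(path: str | Path) -> pd.DataFrame:
    """Read a BLAT PSL file into a hit table.

    Handles the optional 5-line ``psLayout`` header.  The score is the
    classic BLAT web score: matches + repMatches - misMatches - qNumInsert -
    tNumInsert.  Target coordinates in PSL are already 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 17:
                continue
            try:
                matches = int(fields[0])
            except ValueError:
                continue  # header lines
            mis = int(fields[1])
            rep = int(fields[2])
            q_ins = int(fields[4])
            t_ins = int(fields[6])
            rows.append(
                {
                    "query": fields[9],
                    "target": fields[13],
                    "target_start": int(fields[15]),
                    "target_end": int(fields[16]),
                    "score": matches + rep - mis - q_ins - t_ins,
                    "strand": fields[8],
                }
            )
    return pd.DataFrame(rows, columns=_HIT_COLS + ["strand"])
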