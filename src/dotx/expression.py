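"""Expression normalization, dosage compensation, and gene classification.

The dosage-compensation question is whether X-linked expression in the
single-X male matches the two-X female (and the autosomal background).  The
procedure: quantile-normalize TPM within a tissue, average within sex,
quantile-normalize the two sex averages, keep genes expressed above a floor in
both sexes, then compare the four (sex x chromosome-class) distributions and
the per-gene log2(M/F) ratios with Wilcoxon rank-sum tests.

Sex-biased genes are called per tissue with a Welch t-test on log2(TPM + 0.5)
across replicates, BH-corrected, gated on a minimum expression floor in both
sexes and a minimum fold-change.  Tissue-specific genes are those above a high
floor in exactly one tissue context (head, carcass, ovary, testis) and below a
low floor in all others.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, chi2_2x2, expected_counts_2x2, rank_sum_test
from .config import TISSUE_CONTEXTS

__all__ = [
    "quantile_normalize",
    "sex_average_per_tissue",
    "filter_expressed",
    "dosage_statistics",
    "DosageResult",
    "call_sex_bias",
    "call_tissue_specific",
    "compare_class_proportions",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean of sorted values.

    After normalization each column holds the same multiset of values (the
    rank-wise means of the input columns); only the within-column ordering
    differs.  Tied values within a column receive the mean of the reference
    values spanned by their ranks, so the transform is invariant to row order.
    """
    if matrix.shape[1] == 0:
        raise ValueError("matrix has no columns")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the assigned reference values over each tie span
        assigned = pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean").to_numpy()
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _tissue_samples(sheet: pd.DataFrame, tissue: str) -> pd.DataFrame:
    sub = sheet[sheet["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    return sub


def sex_average_per_tissue(matrix: pd.DataFrame, sheet: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Two-column (M, F) matrix for one tissue.

    Quantile-normalize the tissue's samples, take the arithmetic mean within
    each sex, then quantile-normalize the two sex-average columns so a global
    expression shift between sexes cannot masquerade as dosage.
    """
    sub = _tissue_samples(sheet, tissue)
    for sex in ("M", "F"):
        if not (sub["sex"] == sex).any():
            raise ValueError(f"tissue {tissue!r} has no {sex} samples")
    norm = quantile_normalize(matrix[sub.index])
    means = pd.DataFrame(
        {
            "M": norm[sub.index[sub["sex"] == "M"]].mean(axis=1),
            "F": norm[sub.index[sub["sex"] == "F"]].mean(axis=1),
        }
    )
    return quantile_normalize(means)


def filter_expressed(two_col: pd.DataFrame, floor: float = 0.5) -> pd.DataFrame:
    """Genes strictly above ``floor`` in both sexes (boundary values excluded)."""
    keep = (two_col["M"] > floor) & (two_col["F"] > floor)
    return two_col[keep]


@dataclass(frozen=True)
class DosageResult:
    """Dosage-compensation summary for one tissue.

    ``summary``: n and median per (sex x chromosome class); ``ratios``:
    per-gene log2(M/F) with class labels; ``tests``: the three contrasts
    (X-male vs X-female, X-male vs A-male, ratio-X vs ratio-A) with raw and
    BH-adjusted Wilcoxon p-values.
    """

    tissue: str
    summary: pd.DataFrame
    ratios: pd.DataFrame
    tests: pd.DataFrame


def dosage_statistics(
    two_col: pd.DataFrame, classes: Mapping[str, str] | pd.Series, tissue: str = ""
) -> DosageResult:
    """Compare X and autosomal expression between sexes on a filtered gene set."""
    cls = pd.Series(classes).reindex(two_col.index)
    unmapped = cls.isna() | ~cls.isin(["X", "autosome"])
    if unmapped.any():
        warnings.warn(f"{int(unmapped.sum())} genes without X/autosome class dropped", stacklevel=2)
    data = two_col[~unmapped]
    cls = cls[~unmapped]

    groups = {
        ("M", "X"): data.loc[cls == "X", "M"],
        ("F", "X"): data.loc[cls == "X", "F"],
        ("M", "autosome"): data.loc[cls == "autosome", "M"],
        ("F", "autosome"): data.loc[cls == "autosome", "F"],
    }
    summary = pd.DataFrame(
        [
            (sex, chrom, len(v), float(v.median()) if len(v) else float("nan"))
            for (sex, chrom), v in groups.items()
        ],
        columns=["sex", "chrom_class", "n", "median"],
    )
    ratios = pd.DataFrame(
        {"log2_mf": np.log2(data["M"] / data["F"]), "chrom_class": cls}
    )
    contrasts = [
        ("X_male_vs_X_female", groups[("M", "X")], groups[("F", "X")]),
        ("X_male_vs_A_male", groups[("M", "X")], groups[("M", "autosome")]),
        (
            "ratio_X_vs_ratio_A",
            ratios.loc[ratios["chrom_class"] == "X", "log2_mf"],
            ratios.loc[ratios["chrom_class"] == "autosome", "log2_mf"],
        ),
    ]
    rows = []
    for name, a, b in contrasts:
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"contrast {name}: fewer than 2 genes in a group, skipped", stacklevel=2)
            rows.append((name, len(a), len(b), float("nan"), False))
        else:
            rows.append((name, len(a), len(b), rank_sum_test(a, b), True))
    tests = pd.DataFrame(rows, columns=["contrast", "n1", "n2", "p_value", "tested"])
    tests["q_value"] = bh_adjust(tests["p_value"])
    return DosageResult(tissue=tissue, summary=summary, ratios=ratios, tests=tests)


def call_sex_bias(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    tissue: str,
    q_threshold: float = 0.05,
    tpm_floor: float = 0.5,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene sex-bias calls for one tissue.

    Welch t-test on log2(TPM + 0.5) across replicates of the
    quantile-normalized tissue samples, BH q-values across genes, then the
    decision rule: biased iff q < ``q_threshold``, both sex-mean TPM >
    ``tpm_floor``, and the sex-mean fold-change reaches ``fold`` in the called
    direction.  Genes with zero variance and equal means are unbiased.
    """
    sub = _tissue_samples(sheet, tissue)
    m_cols = sub.index[sub["sex"] == "M"]
    f_cols = sub.index[sub["sex"] == "F"]
    if len(m_cols) < 2 or len(f_cols) < 2:
        raise ValueError(f"tissue {tissue!r} needs >= 2 replicates per sex for the differential test")
    norm = quantile_normalize(matrix[sub.index])
    logged = np.log2(norm + 0.5)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; their
        # p-values are treated as 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            logged[m_cols].to_numpy(), logged[f_cols].to_numpy(), axis=1, equal_var=False
        )
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    mean_m = norm[m_cols].mean(axis=1)
    mean_f = norm[f_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (mean_m / mean_f).to_numpy()
    expressed = (mean_m > tpm_floor) & (mean_f > tpm_floor)
    significant = (q < q_threshold) & expressed.to_numpy()
    cls = np.full(len(matrix), "unbiased", dtype=object)
    cls[significant & (fc >= fold)] = "male_biased"
    cls[significant & (fc <= 1.0 / fold)] = "female_biased"
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "tissue": tissue,
            "p_value": p,
            "q_value": q,
            "mean_male": mean_m.to_numpy(),
            "mean_female": mean_f.to_numpy(),
            "fold_change": fc,
            "bias_class": cls,
        }
    ).set_index("gene")


def call_tissue_specific(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    high: float = 1.0,
    low: float = 0.5,
) -> pd.DataFrame:
    """Classify genes as specific to head, carcass, ovary or testis.

    Expression is averaged across both sexes for head and carcass but
    separately per sex for gonads (female gonad = ovary context, male gonad =
    testis).  A gene is specific to the single context where it exceeds
    ``high`` TPM while staying below ``low`` TPM in all others; since
    ``high`` > ``low`` at most one context can qualify.
    """
    if high <= low:
        raise ValueError("high threshold must exceed low threshold")
    masks = {
        "head": sheet["tissue"] == "head",
        "carcass": sheet["tissue"] == "carcass",
        "ovary": (sheet["tissue"] == "gonad") & (sheet["sex"] == "F"),
        "testis": (sheet["tissue"] == "gonad") & (sheet["sex"] == "M"),
    }
    context_means = {}
    for context in TISSUE_CONTEXTS:
        cols = sheet.index[masks[context]]
        if len(cols) == 0:
            raise ValueError(f"tissue context {context!r} has no samples")
        context_means[context] = matrix[cols].mean(axis=1)
    ctx = pd.DataFrame(context_means)
    cls = pd.Series("none", index=matrix.index, dtype=object)
    for context in TISSUE_CONTEXTS:
        others = ctx.drop(columns=context)
        hit = (ctx[context] > high) & (others < low).all(axis=1)
        cls[hit] = context
    out = ctx.copy()
    out["specific_class"] = cls
    return out


def compare_class_proportions(
    categories: pd.Series,
    classes: Mapping[str, str] | pd.Series,
    skip_labels: Iterable[str] = ("none", "unbiased"),
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Chi-squared X-vs-autosome comparison of call-category proportions.

    For each category the 2x2 table (X vs autosome) x (in category vs not) is
    tested with Yates correction and BH-adjusted across categories.  Tables
    with any expected cell count below ``min_expected`` are reported
    descriptively but not tested -- too few calls to support a chi-squared.
    """
    cls = pd.Series(classes).reindex(categories.index)
    keep = cls.isin(["X", "autosome"])
    categories = categories[keep]
    cls = cls[keep]
    n_x = int((cls == "X").sum())
    n_a = int((cls == "autosome").sum())
    if n_x == 0 or n_a == 0:
        raise ValueError("both X and autosome gene sets must be nonempty")
    rows = []
    for cat in sorted(set(categories) - set(skip_labels)):
        in_cat = categories == cat
        x_in = int((in_cat & (cls == "X")).sum())
        a_in = int((in_cat & (cls == "autosome")).sum())
        table = [[x_in, n_x - x_in], [a_in, n_a - a_in]]
        tested = bool(expected_counts_2x2(table).min() >= min_expected)
        if tested:
            stat, p = chi2_2x2(table)
        else:
            warnings.warn(
                f"category {cat!r}: expected counts < {min_expected}, reported descriptively",
                stacklevel=2,
            )
            stat, p = float("nan"), float("nan")
        rows.append((cat, n_x, x_in, x_in / n_x, n_a, a_in, a_in / n_a, stat, p, tested))
    out = pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_x",
            "x_in_category",
            "prop_x",
            "n_autosome",
            "a_in_category",
            "prop_autosome",
            "chi2_stat",
            "p_value",
            "tested",
        ],
    )
    out["q_value"] = bh_adjust(out["p_value"])
    out["significant"] = out["q_value"] < alpha
    return out
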