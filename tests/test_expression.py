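"""Expression normalization, dosage statistics, and gene classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dotx import expression as expr
from dotx.config import SimulationConfig
from dotx.simulate import generate_genome, simulate_expression


def sheet_for(samples):
    rows = []
    for sample in samples:
        sex, tissue, rep = sample.split("_")
        rows.append((sample, sex, tissue, int(rep)))
    return pd.DataFrame(rows, columns=["sample", "sex", "tissue", "replicate"]).set_index("sample")


class TestQuantileNormalize:
    def test_two_column_worked_example(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = expr.quantile_normalize(m)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(expr.quantile_normalize(m), m)

    def test_tie_span_receives_mean_of_reference_values(self):
        # reference = mean of sorted columns = [1.5, 2.0, 4.5]; the tied pair
        # in column a spans ranks 1-2 -> both get (1.5 + 2.0) / 2 = 1.75
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = expr.quantile_normalize(m)
        assert out["a"].tolist() == [1.75, 1.75, 4.5]
        assert out["b"].tolist() == [1.5, 2.0, 4.5]

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((30, 4)), index=[f"g{i}" for i in range(30)])
        out = expr.quantile_normalize(m)
        perm = rng.permutation(30)
        out_perm = expr.quantile_normalize(m.iloc[perm])
        pd.testing.assert_frame_equal(out.iloc[perm], out_perm)

    @given(st.integers(0, 10_000))
    def test_columns_share_value_multiset(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.lognormal(size=(20, 5)))
        out = expr.quantile_normalize(m).to_numpy()
        reference = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), reference, atol=1e-12)

    def test_no_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            expr.quantile_normalize(pd.DataFrame(index=[1, 2]))


class TestSexAverage:
    def test_global_scale_shift_removed(self):
        """Males at exactly 2x female expression collapse to identical columns:
        a library-wide shift is not dosage."""
        rng = np.random.default_rng(1)
        f_vals = rng.lognormal(mean=2, size=(10, 3))
        samples = ["M_head_1", "M_head_2", "M_head_3", "F_head_1", "F_head_2", "F_head_3"]
        matrix = pd.DataFrame(
            np.hstack([2 * f_vals, f_vals]), columns=samples, index=[f"g{i}" for i in range(10)]
        )
        out = expr.sex_average_per_tissue(matrix, sheet_for(samples), "head")
        assert np.allclose(out["M"], out["F"])

    def test_missing_sex_rejected(self):
        samples = ["F_head_1", "F_head_2"]
        matrix = pd.DataFrame(np.ones((4, 2)), columns=samples)
        with pytest.raises(ValueError, match="no M samples"):
            expr.sex_average_per_tissue(matrix, sheet_for(samples), "head")


class TestFilterExpressed:
    def test_boundary_is_strict(self):
        table = pd.DataFrame({"M": [0.5, 0.6, 10.0], "F": [10.0, 0.6, 0.5]}, index=["a", "b", "c"])
        kept = expr.filter_expressed(table, floor=0.5)
        assert kept.index.tolist() == ["b"]


class TestDosageStatistics:
    def run_sim(self, seed, dosage):
        cfg = SimulationConfig(
            seed=seed,
            n_scaffolds=10,
            x_scaffold_fraction=0.2,
            scaffold_length_range=(50_000, 80_000),
            n_genes=800,
            dosage_mode={"head": "compensated", "gonad": dosage, "carcass": "compensated"},
        )
        _, truth = generate_genome(cfg, with_sequences=False)
        tpm, sheet = simulate_expression(cfg, truth)
        averaged = expr.sex_average_per_tissue(tpm, sheet, "gonad")
        kept = expr.filter_expressed(averaged)
        classes = truth.genes.set_index("gene")["chrom_class"]
        return expr.dosage_statistics(kept, classes, tissue="gonad")

    def test_uncompensated_gonad_detected(self):
        res = self.run_sim(0, "uncompensated_half_X")
        medians = res.ratios.groupby("chrom_class")["log2_mf"].median()
        assert medians["X"] == pytest.approx(-1.0, abs=0.25)
        tests = res.tests.set_index("contrast")
        assert tests.loc["ratio_X_vs_ratio_A", "p_value"] < 1e-3

    def test_compensated_null_is_calibrated(self):
        """Under full compensation the three contrasts are null: over 12 seeds
        at most a third may show any BH-adjusted p < 0.05."""
        n_hits = 0
        for seed in range(12):
            res = self.run_sim(100 + seed, "compensated")
            adjusted = res.tests["q_value"].dropna()
            n_hits += int((adjusted < 0.05).any())
        assert n_hits <= 4

    def test_missing_x_class_skips_contrasts(self):
        table = pd.DataFrame({"M": [1.0, 2.0, 3.0], "F": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        classes = pd.Series({"a": "autosome", "b": "autosome", "c": "autosome"})
        with pytest.warns(UserWarning, match="skipped"):
            res = expr.dosage_statistics(table, classes)
        assert not res.tests["tested"].any()
        summary = res.summary.set_index(["sex", "chrom_class"])
        assert summary.loc[("M", "autosome"), "n"] == 3


class TestCallSexBias:
    def spiked_matrix(self):
        """Deterministic 6-sample matrix: identical null genes in every column
        plus one 1.9-fold and one 4-fold male-biased gene (tiny replicate
        jitter so the t-test has degrees of freedom)."""
        rng = np.random.default_rng(3)
        null_vals = np.sort(rng.uniform(1, 100, size=200))
        samples = [f"{sex}_gonad_{r}" for sex in ("M", "F") for r in (1, 2, 3)]
        data = np.tile(null_vals[:, None], (1, 6))
        jitter = np.array([0.0, 1e-4, -1e-4])
        rows = {}
        for name, fold in (("fc19", 1.9), ("fc40", 4.0)):
            f_vals = 10.0 + jitter
            rows[name] = np.concatenate([fold * f_vals, f_vals])
        matrix = pd.DataFrame(data, columns=samples, index=[f"n{i}" for i in range(200)])
        for name, vals in rows.items():
            matrix.loc[name] = vals
        return matrix, sheet_for(samples)

    def test_fold_change_gate(self):
        """A gene at 1.9-fold is not called even with q < 0.05; 4-fold is."""
        matrix, sheet = self.spiked_matrix()
        calls = expr.call_sex_bias(matrix, sheet, "gonad")
        assert calls.loc["fc19", "q_value"] < 0.05
        assert 1.5 < calls.loc["fc19", "fold_change"] < 2.0
        assert calls.loc["fc19", "bias_class"] == "unbiased"
        assert calls.loc["fc40", "bias_class"] == "male_biased"

    def test_equal_sexes_yield_no_calls(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(mean=1, size=(50, 3))
        samples = [f"{sex}_head_{r}" for sex in ("M", "F") for r in (1, 2, 3)]
        matrix = pd.DataFrame(np.hstack([vals, vals]), columns=samples)
        calls = expr.call_sex_bias(matrix, sheet_for(samples), "head")
        assert (calls["bias_class"] == "unbiased").all()

    def test_recovery_on_simulated_truth(self):
        """>= 95% of 100 truth-biased genes (4-fold, sigma = 0.1, 3+3) are
        recovered with the correct direction, with empirical FDR <= 0.1."""
        cfg = SimulationConfig(
            seed=2,
            n_genes=1000,
            fraction_sex_biased=0.1,
            fraction_tissue_specific=0.0,
            dosage_mode={"head": "compensated", "gonad": "compensated", "carcass": "compensated"},
        )
        _, truth = generate_genome(cfg, with_sequences=False)
        tpm, sheet = simulate_expression(cfg, truth)
        calls = expr.call_sex_bias(tpm, sheet, "gonad")
        truth_bias = truth.genes.set_index("gene")["sex_bias"]
        called = calls["bias_class"] != "unbiased"
        true_pos = (called & (truth_bias != "none")).sum()
        false_pos = (called & (truth_bias == "none")).sum()
        assert true_pos >= 95
        assert false_pos / max(called.sum(), 1) <= 0.1
        directions = calls.loc[called & (truth_bias != "none"), "bias_class"]
        expected = truth_bias[directions.index].map({"male": "male_biased", "female": "female_biased"})
        assert (directions == expected).all()

    def test_single_replicate_rejected(self):
        samples = ["M_head_1", "F_head_1", "F_head_2"]
        matrix = pd.DataFrame(np.ones((5, 3)), columns=samples)
        with pytest.raises(ValueError, match="replicates"):
            expr.call_sex_bias(matrix, sheet_for(samples), "head")


class TestCallTissueSpecific:
    def full_sheet(self):
        samples = [
            f"{sex}_{tissue}_{r}" for sex in ("M", "F") for tissue in ("head", "gonad", "carcass") for r in (1,)
        ]
        return sheet_for(samples)

    def matrix_from_contexts(self, head, carcass, ovary, testis):
        sheet = self.full_sheet()
        values = {
            "M_head_1": head, "F_head_1": head,
            "M_carcass_1": carcass, "F_carcass_1": carcass,
            "F_gonad_1": ovary, "M_gonad_1": testis,
        }
        return pd.DataFrame({k: [v] for k, v in values.items()}), sheet

    def test_testis_specific(self):
        matrix, sheet = self.matrix_from_contexts(0.0, 0.0, 0.0, 2.0)
        assert expr.call_tissue_specific(matrix, sheet)["specific_class"].iloc[0] == "testis"

    def test_broadly_expressed_is_none(self):
        matrix, sheet = self.matrix_from_contexts(2.0, 2.0, 2.0, 2.0)
        assert expr.call_tissue_specific(matrix, sheet)["specific_class"].iloc[0] == "none"

    @pytest.mark.parametrize(
        "focal,other,expected",
        [(1.0, 0.0, "none"), (1.1, 0.5, "none"), (1.1, 0.49, "testis")],
    )
    def test_threshold_boundaries_are_strict(self, focal, other, expected):
        matrix, sheet = self.matrix_from_contexts(other, other, other, focal)
        assert expr.call_tissue_specific(matrix, sheet)["specific_class"].iloc[0] == expected

    @given(st.lists(st.floats(min_value=0, max_value=5, allow_nan=False), min_size=4, max_size=4))
    def test_at_most_one_context_per_gene(self, vals):
        matrix, sheet = self.matrix_from_contexts(*vals)
        out = expr.call_tissue_specific(matrix, sheet)
        assert out["specific_class"].iloc[0] in {"head", "carcass", "ovary", "testis", "none"}

    def test_recovery_on_simulated_truth(self):
        cfg = SimulationConfig(seed=4, n_genes=1000, fraction_tissue_specific=0.2, fraction_sex_biased=0.0)
        _, truth = generate_genome(cfg, with_sequences=False)
        tpm, sheet = simulate_expression(cfg, truth)
        out = expr.call_tissue_specific(expr.quantile_normalize(tpm), sheet)
        truth_labels = truth.genes.set_index("gene")["tissue_specific"]
        agree = (out["specific_class"] == truth_labels).mean()
        assert agree > 0.98


class TestCompareClassProportions:
    def test_against_closed_form_oracle(self):
        """X: 40/1000 in category vs A: 20/10000 -> Yates chi2 by hand."""
        categories = pd.Series(
            ["hit"] * 40 + ["none"] * 960 + ["hit"] * 20 + ["none"] * 9980,
            index=[f"g{i}" for i in range(11_000)],
        )
        classes = pd.Series(
            ["X"] * 1000 + ["autosome"] * 10_000, index=[f"g{i}" for i in range(11_000)]
        )
        res = expr.compare_class_proportions(categories, classes).set_index("category")
        a, b, c, d = 40, 960, 20, 9980
        n = a + b + c + d
        oracle = n * (abs(a * d - b * c) - n / 2) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.loc["hit", "chi2_stat"] == pytest.approx(oracle)
        assert res.loc["hit", "p_value"] < 1e-3

    def test_identical_proportions_not_significant(self):
        categories = pd.Series(["hit"] * 50 + ["none"] * 450 + ["hit"] * 100 + ["none"] * 900)
        classes = pd.Series(["X"] * 500 + ["autosome"] * 1000)
        res = expr.compare_class_proportions(categories, classes)
        assert (res["p_value"] > 0.9).all()

    def test_sparse_category_reported_descriptively(self):
        categories = pd.Series(["hit"] * 1 + ["none"] * 99 + ["none"] * 400)
        classes = pd.Series(["X"] * 100 + ["autosome"] * 400)
        with pytest.warns(UserWarning, match="descriptively"):
            res = expr.compare_class_proportions(categories, classes).set_index("category")
        assert not bool(res.loc["hit", "tested"])
        assert res.loc["hit", "x_in_category"] == 1
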