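import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from conftest import make_design
from degradome.differential import (
    filter_background,
    replicate_correlation,
    ttest_volcano,
)
from degradome.imputation import ImputedMatrix
from degradome.io import ExperimentDesign, SampleInfo


def pooled_t_oracle(vehicle, bafa1):
    """Textbook pooled-variance t and two-tailed p via incomplete beta."""
    a, b = np.asarray(vehicle, float), np.asarray(bafa1, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (b.mean() - a.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = special.betainc(df / 2, 0.5, df / (df + t * t))
    return t, p


def imputed_matrix(rows, design, imputed=None):
    values = pd.DataFrame(
        np.asarray(rows, float),
        index=[f"P{i}" for i in range(len(rows))],
        columns=design.all_sample_ids,
    )
    if imputed is None:
        mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    else:
        mask = pd.DataFrame(
            np.asarray(imputed, bool), index=values.index, columns=values.columns
        )
    return ImputedMatrix(values=values, imputed_mask=mask)


class TestFilterBackground:
    def make(self, imputed_row, design):
        row = np.arange(len(design.all_sample_ids), dtype=float) + 20
        return imputed_matrix([row], design, [imputed_row])

    def test_two_observed_in_one_condition_kept(self, design44):
        # observed 2/4 vehicle, 0/4 bafa1 -> kept
        m = self.make([False, False, True, True] + [True] * 4, design44)
        assert len(filter_background(m, design44).values) == 1

    def test_one_observed_per_condition_removed(self, design44):
        m = self.make([False, True, True, True, False, True, True, True],
                      design44)
        assert len(filter_background(m, design44).values) == 0

    def test_fully_observed_kept(self, design44):
        m = self.make([False] * 8, design44)
        assert len(filter_background(m, design44).values) == 1

    def test_all_imputed_removed(self, design44):
        m = self.make([True] * 8, design44)
        assert len(filter_background(m, design44).values) == 0

    def test_min_observed_validation(self, design44):
        m = self.make([False] * 8, design44)
        with pytest.raises(ValueError):
            filter_background(m, design44, min_observed=0)


class TestTtestVolcano:
    def test_textbook_example(self):
        design = make_design(3, 3)
        m = imputed_matrix([[1, 2, 3, 4, 5, 6]], design)
        out = ttest_volcano(m, design)
        t_exp, p_exp = pooled_t_oracle([1, 2, 3], [4, 5, 6])
        assert out.loc[0, "log2fc"] == pytest.approx(3.0)
        assert out.loc[0, "t_stat"] == pytest.approx(t_exp, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(p_exp, abs=1e-12)
        assert out.loc[0, "neg_log10_p"] == pytest.approx(
            -math.log10(p_exp), abs=1e-10
        )
        assert bool(out.loc[0, "candidate"])

    def test_matches_pooled_oracle_on_random_instances(self, rng):
        design = make_design(4, 4)
        rows = rng.normal(22, 3, size=(20, 8))
        out = ttest_volcano(imputed_matrix(rows, design), design)
        for i, row in enumerate(rows):
            t_exp, p_exp = pooled_t_oracle(row[:4], row[4:])
            assert out.loc[i, "t_stat"] == pytest.approx(t_exp, abs=1e-10)
            assert out.loc[i, "p_value"] == pytest.approx(p_exp, abs=1e-10)

    def test_identical_groups(self):
        design = make_design(3, 3)
        out = ttest_volcano(imputed_matrix([[1, 2, 3, 1, 2, 3]], design), design)
        assert out.loc[0, "t_stat"] == 0.0
        assert out.loc[0, "p_value"] == 1.0
        assert not bool(out.loc[0, "candidate"])

    def test_zero_variance_identical_groups(self):
        design = make_design(3, 3)
        out = ttest_volcano(imputed_matrix([[5, 5, 5, 5, 5, 5]], design), design)
        assert out.loc[0, "t_stat"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_downregulated_never_candidate(self):
        design = make_design(4, 4)
        m = imputed_matrix([[10, 10.1, 9.9, 10, 4, 4.1, 3.9, 4]], design)
        out = ttest_volcano(m, design)
        assert out.loc[0, "p_value"] < 0.001
        assert out.loc[0, "log2fc"] < 0
        assert not bool(out.loc[0, "candidate"])

    def test_candidate_set_is_exact_intersection(self, rng):
        design = make_design(4, 4)
        rows = rng.normal(22, 3, size=(200, 8))
        out = ttest_volcano(imputed_matrix(rows, design), design, alpha=0.3)
        expected = (out["p_value"] < 0.3) & (out["log2fc"] > 0)
        pd.testing.assert_series_equal(out["candidate"], expected,
                                       check_names=False)

    def test_condition_swap_negates_effect(self, rng):
        design = make_design(4, 4)
        rows = rng.normal(22, 3, size=(15, 8))
        swapped = ExperimentDesign([
            SampleInfo(s.sample_id,
                       "bafa1" if s.condition == "vehicle" else "vehicle",
                       s.replicate, s.experiment)
            for s in design.samples
        ])
        a = ttest_volcano(imputed_matrix(rows, design), design)
        b = ttest_volcano(imputed_matrix(rows, design), swapped)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["t_stat"], -b["t_stat"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)

    def test_replicate_label_and_protein_order_invariance(self, rng):
        design = make_design(4, 4)
        rows = rng.normal(22, 3, size=(15, 8))
        m = imputed_matrix(rows, design)
        perm = rng.permutation(15)
        m_perm = ImputedMatrix(values=m.values.iloc[perm],
                               imputed_mask=m.imputed_mask.iloc[perm])
        relabelled = ExperimentDesign([
            SampleInfo(s.sample_id, s.condition, 5 - s.replicate, s.experiment)
            for s in design.samples
        ])
        a = ttest_volcano(m, design).set_index("protein_id")
        b = ttest_volcano(m_perm, relabelled).set_index("protein_id")
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_null_type_one_error_calibrated(self, rng):
        """Fully observed null data: p < alpha at about the nominal rate."""
        design = make_design(4, 4)
        n = 4000
        rows = rng.normal(22, 1, size=(n, 8))
        out = ttest_volcano(imputed_matrix(rows, design), design)
        rate = (out["p_value"] < 0.05).mean()
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < half_width

    def test_small_condition_rejected(self):
        design = ExperimentDesign([
            SampleInfo("a", "vehicle", 1, "e"),
            SampleInfo("b", "vehicle", 2, "e"),
            SampleInfo("c", "bafa1", 1, "e"),
            SampleInfo("d", "bafa1", 2, "e"),
        ])
        m = imputed_matrix([[1, 2, 3, 4]], design)
        bad = ExperimentDesign([
            SampleInfo("a", "vehicle", 1, "e"),
            SampleInfo("b", "vehicle", 2, "e"),
            SampleInfo("c", "bafa1", 1, "e"),
            SampleInfo("d", "bafa1", 2, "e"),
        ])
        # drop one bafa1 column from the matrix to break the precondition
        m2 = ImputedMatrix(values=m.values[["a", "b", "c"]],
                           imputed_mask=m.imputed_mask[["a", "b", "c"]])
        with pytest.raises((ValueError, KeyError)):
            ttest_volcano(m2, bad)


class TestReplicateCorrelation:
    def test_duplicate_columns_give_unit_r(self, rng):
        design = make_design(2, 2)
        col = rng.normal(22, 2, 30)
        rows = np.column_stack([col, col, col, col + rng.normal(0, 1, 30)])
        out = replicate_correlation(imputed_matrix(rows, design), design)
        assert out["vehicle"].iloc[0, 1] == pytest.approx(1.0)

    def test_negated_column_gives_minus_one(self, rng):
        design = make_design(2, 2)
        col = rng.normal(0, 2, 30)
        rows = np.column_stack([col, -col, col, col])
        out = replicate_correlation(imputed_matrix(rows, design), design)
        assert out["vehicle"].iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self, rng):
        design = make_design(2, 2)
        rows = rng.normal(22, 2, size=(10_000, 4))
        out = replicate_correlation(imputed_matrix(rows, design), design)
        x, y = rows[:, 0], rows[:, 1]
        n = len(x)
        r_oracle = (n * (x * y).sum() - x.sum() * y.sum()) / math.sqrt(
            (n * (x ** 2).sum() - x.sum() ** 2)
            * (n * (y ** 2).sum() - y.sum() ** 2)
        )
        assert abs(r_oracle) < 0.05  # independent columns
        assert out["vehicle"].iloc[0, 1] == pytest.approx(r_oracle, abs=1e-10)

    def test_uses_only_jointly_observed(self, rng):
        design = make_design(2, 2)
        rows = rng.normal(22, 2, size=(40, 4))
        imput = np.zeros((40, 4), bool)
        imput[:20, 0] = True  # first 20 imputed in vehicle replicate 1
        out = replicate_correlation(
            imputed_matrix(rows, design, imput), design
        )
        from scipy import stats

        expected = stats.pearsonr(rows[20:, 0], rows[20:, 1]).statistic
        assert out["vehicle"].iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_proteins_gives_nan(self):
        design = make_design(2, 2)
        rows = np.arange(8, dtype=float).reshape(2, 4) + 20
        imput = np.array([[True, False, False, False]] * 2)
        out = replicate_correlation(
            imputed_matrix(rows, design, imput), design
        )
        assert np.isnan(out["vehicle"].iloc[0, 1])
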