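"""Paired t-tests, BH-FDR, McNemar and Wilcoxon machinery."""

import numpy as np
import pytest
from scipy import stats

from fcstates.discrimination import CVResult
from fcstates.statscompare import (
    MultipleTestingConfig,
    PairedOutcome,
    bh_fdr,
    compare_pipelines,
    mcnemar_test,
    paired_edgewise_ttests,
    wilcoxon_signed_rank,
)


class TestPairedEdgewiseTtests:
    def test_identical_states_give_null(self, rng):
        a = rng.normal(size=(5, 10))
        res = paired_edgewise_ttests(a, a.copy())
        assert np.all(res["t"] == 0)
        assert np.all(res["p"] == 1)
        assert res["degenerate"].all()

    def test_hand_computed_example(self):
        # differences (1, 2, 3, 2) on one edge: t = 2 / (0.8165/2) = 4.899
        b = np.zeros((4, 1))
        a = np.array([[1.0], [2.0], [3.0], [2.0]])
        res = paired_edgewise_ttests(a, b)
        assert res["t"][0] == pytest.approx(4.89898, abs=1e-4)
        assert res["p"][0] == pytest.approx(2 * stats.t.sf(4.89898, df=3), abs=1e-5)
        assert res["p"][0] == pytest.approx(0.0163, abs=5e-4)

    def test_sign_flip_negates_t_keeps_p(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(6, 4))
        fwd = paired_edgewise_ttests(a, b)
        rev = paired_edgewise_ttests(b, a)
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_matrix_stack_input_vectorized(self, rng):
        m = rng.normal(size=(4, 5, 5))
        m = m + m.transpose(0, 2, 1)
        res = paired_edgewise_ttests(m, np.zeros_like(m))
        assert len(res) == 10  # 5*4/2 edges

    def test_type_i_error_near_nominal_under_null(self, rng):
        # exchangeable states: about 5% of edges significant at p < 0.05
        fractions = []
        for _ in range(60):
            a = rng.normal(size=(12, 30))
            b = rng.normal(size=(12, 30))
            res = paired_edgewise_ttests(a, b)
            fractions.append(np.mean(res["p"] < 0.05))
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.02)


class TestBhFdr:
    def test_step_up_accepts_all_when_largest_passes(self):
        # p(4) = 0.04 <= 4*0.05/4: all four rejected
        mask = bh_fdr([0.01, 0.02, 0.03, 0.04], MultipleTestingConfig(0.05))
        assert mask.all()

    def test_step_up_rejects_none(self):
        # 0.04 > 0.05/3: nothing rejected
        mask = bh_fdr([0.04, 0.5, 0.9], MultipleTestingConfig(0.05))
        assert not mask.any()

    def test_empty_input(self):
        assert bh_fdr([], MultipleTestingConfig(0.05)).size == 0

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=40)
        prev = np.zeros(40, dtype=bool)
        for q in (0.01, 0.05, 0.1, 0.2, 0.5):
            mask = bh_fdr(p, MultipleTestingConfig(q))
            assert np.all(prev <= mask)
            prev = mask

    def test_subset_of_uncorrected(self, rng):
        p = rng.uniform(size=50)
        q = 0.05
        mask = bh_fdr(p, MultipleTestingConfig(q))
        assert np.all(~mask | (p < q))


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        _, p = mcnemar_test(PairedOutcome(7, 7, 75))
        assert p == 1.0

    def test_exact_binomial_example(self):
        # b=5, c=1: p = 2*P(X<=1 | n=6, 1/2) = 2*7/64
        _, p = mcnemar_test(PairedOutcome(5, 1, 75))
        assert p == pytest.approx(0.21875, abs=1e-10)

    def test_chi2_continuity_corrected_example(self):
        stat, p = mcnemar_test(PairedOutcome(20, 8, 75), variant="chi2")
        # (|20-8|-1)^2 / 28
        assert stat == pytest.approx(121 / 28)
        assert p == pytest.approx(stats.chi2.sf(121 / 28, 1))

    def test_spec_chi2_value(self):
        stat, p = mcnemar_test(PairedOutcome(10, 2, 75), variant="chi2")
        assert stat == pytest.approx(4.0833, abs=1e-3)
        assert p == pytest.approx(0.0433, abs=1e-3)

    def test_no_discordance(self):
        _, p = mcnemar_test(PairedOutcome(0, 0, 75))
        assert p == 1.0

    def test_exact_and_chi2_agree_near_threshold(self):
        # continuity sanity around b + c ~ 25
        for b in range(14, 26):
            c = 25 - b if 25 - b >= 0 else 0
            if b + c < 10:
                continue
            _, p_exact = mcnemar_test(PairedOutcome(b, c, 200), variant="exact")
            _, p_chi2 = mcnemar_test(PairedOutcome(b, c, 200), variant="chi2")
            assert abs(p_exact - p_chi2) < 0.02

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[40, 5], [1, 29]]
        ours = mcnemar_test(PairedOutcome(5, 1, 75))[1]
        theirs = sm_mcnemar(table, exact=True).pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_type_i_calibration_under_null(self, rng):
        # two pipelines with independent coin-flip errors: ~5% rejections
        n_reps, n_samples = 2000, 75
        rejections = 0
        for _ in range(n_reps):
            a = rng.random(n_samples) < 0.6
            b = rng.random(n_samples) < 0.6
            _, p = mcnemar_test(PairedOutcome.from_correctness(a, b))
            rejections += p < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)


class TestWilcoxon:
    def test_identical_lists_degenerate(self):
        w, p, flag = wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p == 1.0 and flag

    def test_exact_five_concordant_differences(self):
        # all five differences positive: W = 0, p = 2/2^5
        w, p, flag = wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
        assert w == 0.0
        assert p == pytest.approx(0.0625, abs=1e-10)
        assert not flag

    def test_sign_symmetric(self):
        a = [60.0, 62, 65, 58, 71, 64]
        b = [55.0, 64, 60, 52, 66, 61]
        _, p_ab, _ = wilcoxon_signed_rank(a, b)
        _, p_ba, _ = wilcoxon_signed_rank(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2])


def _cv(y_true, y_pred):
    n = len(y_true)
    return CVResult(np.asarray(y_true), np.asarray(y_pred), np.zeros(n, dtype=int))


class TestComparePipelines:
    def test_self_comparison_not_significant(self):
        truth = np.repeat(np.arange(5), 15)
        pred = truth.copy()
        pred[:10] = (pred[:10] + 1) % 5
        results = {"base": _cv(truth, pred), "same": _cv(truth, pred.copy())}
        table = compare_pipelines(results, "base", MultipleTestingConfig(0.05))
        assert table["p_raw"].iloc[0] == 1.0
        assert not table["significant_q0.05"].iloc[0]

    def test_large_discordance_significant(self):
        truth = np.repeat(np.arange(5), 15)
        base_pred = truth.copy()
        base_pred[:30] = (base_pred[:30] + 1) % 5  # baseline wrong on 30
        better = truth.copy()
        better[:8] = (better[:8] + 1) % 5  # improved wrong only on 8
        results = {"base": _cv(truth, base_pred), "better": _cv(truth, better)}
        table = compare_pipelines(results, "base", MultipleTestingConfig(0.05))
        row = table.iloc[0]
        assert row["b"] == 22 and row["c"] == 0
        assert row["significant_q0.05"] and row["beats_baseline"]

    def test_sample_mismatch_errors(self):
        r1 = _cv(np.repeat(np.arange(5), 3), np.repeat(np.arange(5), 3))
        r2 = _cv(np.roll(np.repeat(np.arange(5), 3), 1), np.repeat(np.arange(5), 3))
        with pytest.raises(ValueError, match="different samples"):
            compare_pipelines({"a": r1, "b": r2}, "a")


def test_state_contrast_table_structure(rng):
    from fcstates.statscompare import state_contrast_table

    m = rng.normal(size=(6, 4, 4))
    m = m + m.transpose(0, 2, 1)
    table = state_contrast_table(m, np.zeros_like(m), n_nodes=4)
    assert list(table.columns) == ["node_i", "node_j", "t", "p", "fdr_reject", "degenerate"]
    assert len(table) == 6
    assert (table["node_i"] < table["node_j"]).all()
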