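"""Statistical stage: gated comparisons, ICC, correlations, logistic, ROC."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st

from eomhabitat import (
    chi_square,
    compare_feature,
    correlate,
    correlation_band,
    evaluate_response_markers,
    fit_logistic,
    icc,
    normality_gate,
    roc_analysis,
)
from helpers import (
    auc_pair_counting,
    icc21_variance_components,
    mannwhitney_exact_p,
    youden_bruteforce,
)


class TestNormalityGate:
    def test_skewed_samples_route_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.exponential(1.0, 50), "b": rng.exponential(1.0, 50)}
        assert normality_gate(groups) == "mann_whitney"

    def test_normal_quantile_sequences_route_to_t_test(self):
        # inverse-CDF points of a standard normal: as normal as n=30 gets
        q = ss.norm.ppf((np.arange(1, 31) - 0.5) / 30)
        assert normality_gate({"a": q, "b": q + 1.0}) == "t_test"

    def test_constant_group_routes_nonparametric(self):
        rng = np.random.default_rng(1)
        assert normality_gate({"a": np.full(10, 3.0), "b": rng.normal(size=10)}) == "mann_whitney"

    def test_tiny_group_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            normality_gate({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestCompareFeature:
    @staticmethod
    def _table(a, b, name="x"):
        return pd.DataFrame(
            {
                "response": ["responsive"] * len(a) + ["unresponsive"] * len(b),
                name: np.concatenate([a, b]),
            }
        )

    def test_mann_whitney_p_matches_exhaustive_permutation(self):
        # tie-free small samples: scipy's exact method vs full enumeration
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, 11.0))[:4]
            b = rng.permutation(np.arange(11.5, 21.5))[:5]
            res = compare_feature(self._table(a, b), "x")
            if res.test_used == "mann_whitney":
                assert res.p_value == pytest.approx(mannwhitney_exact_p(a, b), abs=1e-12)

    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.5, 4.0, 8.0])
        b = a + 0.25  # interleaved, tie-free, same ranks pattern
        res = compare_feature(self._table(np.concatenate([a, b[:0]]), b), "x")
        assert res.p_value > 0.6  # near-identical rank distributions

    def test_complete_separation_maximal_enrichment(self):
        # skewed, completely separated groups: gate -> Mann-Whitney, U = 0
        rng = np.random.default_rng(21)
        a = rng.exponential(1.0, 20)
        b = a.max() + 1 + rng.exponential(1.0, 20)
        res = compare_feature(self._table(a, b), "x")
        assert res.test_used == "mann_whitney"
        u = min(res.statistic, len(a) * len(b) - res.statistic)
        assert u == 0.0
        assert res.p_value < 1e-4

    def test_summaries_match_test_family(self):
        rng = np.random.default_rng(3)
        a, b = rng.exponential(1, 30), rng.exponential(2, 30)
        res = compare_feature(self._table(a, b), "x")
        assert res.test_used == "mann_whitney"
        first = next(iter(res.group_summaries.values()))
        assert {"median", "q1", "q3", "n"} <= set(first)

    def test_nan_rows_excluded_pairwise(self):
        a = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        res = compare_feature(self._table(a, b), "x")
        summaries = res.group_summaries
        assert summaries[sorted(summaries)[0]]["n"] == 4


class TestChiSquare:
    def test_balanced_table_gives_zero_statistic(self):
        res = chi_square(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_hand_computed(self):
        # E = 10 everywhere; sum (O-E)^2/E = 4 * 100/10 = 40, df = 1
        res = chi_square(np.array([[20, 0], [0, 20]]))
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value == pytest.approx(ss.chi2.sf(40.0, 1))

    def test_invariant_to_row_swap(self):
        t = np.array([[12, 5, 3], [7, 9, 4]])
        assert chi_square(t).statistic == pytest.approx(chi_square(t[::-1]).statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square(np.array([[5, 0], [7, 0]]))


class TestIcc:
    def test_duplicated_ratings_give_perfect_agreement(self):
        x = np.random.default_rng(4).normal(10, 2, 20)
        res = icc(np.column_stack([x, x]))
        assert res.icc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_noise_dominated_ratings_give_low_icc(self):
        rng = np.random.default_rng(5)
        subj = rng.normal(0, 1, 50)
        res = icc(np.column_stack([subj, subj + rng.normal(0, 10, 50)]))
        assert res.icc < 0.2

    def test_point_estimate_matches_variance_component_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(50, 10, size=(24, 2)) + rng.normal(0, 3, size=(24, 2))
        res = icc(x)
        assert res.icc == pytest.approx(icc21_variance_components(x), abs=1e-12)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_icc2_with_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        subj = rng.normal(20, 5, 30)
        x = np.column_stack([subj + rng.normal(0, 1, 30), subj + rng.normal(0, 1, 30) + 0.5])
        res = icc(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(30), 2),
                "rater": np.tile([0, 1], 30),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds the CI to 2 decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.0051)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.0051)

    def test_invariant_under_shared_shift_and_monotone_in_noise(self):
        rng = np.random.default_rng(8)
        subj = rng.normal(0, 2, 40)
        noise = rng.normal(0, 1, 40)
        base = np.column_stack([subj, subj + noise])
        shifted = icc(base + 7.5)
        assert shifted.icc == pytest.approx(icc(base).icc, abs=1e-12)
        iccs = [icc(np.column_stack([subj, subj + sd * noise])).icc for sd in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_zero_between_subject_variance_is_error(self):
        with pytest.raises(ValueError, match="between-subject"):
            icc(np.tile([[3.0, 3.0]], (10, 1)))


class TestCorrelate:
    def test_rank_identity_is_excellent_spearman(self):
        x = np.exp(np.random.default_rng(9).normal(0, 1, 40))  # lognormal: non-normal
        res = correlate(x, x)
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_independent_variables_band_poor(self):
        rng = np.random.default_rng(10)
        res = correlate(rng.normal(size=200), rng.normal(size=200))
        assert abs(res.r) < 0.2
        assert res.band == "poor"

    @pytest.mark.parametrize(
        "r, band",
        [
            (0.35, "poor"),
            (0.40, "moderate"),
            (0.5999, "moderate"),
            (0.60, "good"),
            (0.7999, "good"),
            (0.80, "excellent"),
            (-0.85, "excellent"),
            (-0.39, "poor"),
        ],
    )
    def test_band_steps_exactly_at_cutpoints(self, r, band):
        assert correlation_band(r) == band

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate(np.ones(10), np.arange(10.0))


class TestLogistic:
    @staticmethod
    def _table(x, y_labels, name="f"):
        return pd.DataFrame({name: x, "response": y_labels})

    def test_informative_feature_fits_labels(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 20)
        x = y * 4.0 + rng.normal(0, 0.3, 40)
        labels = np.where(y == 1, "responsive", "unresponsive")
        model = fit_logistic(self._table(x, labels), ["f"])
        preds = (model.fitted_probabilities > 0.5).astype(int)
        assert np.mean(preds == y) >= 0.95

    def test_null_feature_recovers_prevalence_intercept(self):
        y = np.repeat([0, 1], [30, 10])
        labels = np.where(y == 1, "responsive", "unresponsive")
        model = fit_logistic(self._table(np.zeros(40), labels), ["f"])
        assert model.coefficients["f"] == pytest.approx(0.0, abs=1e-6)
        assert model.coefficients["const"] == pytest.approx(np.log(10 / 30), abs=1e-3)

    def test_combined_model_dominates_single_features_in_sample(self):
        rng = np.random.default_rng(12)
        n = 60
        y = np.repeat([0, 1], n // 2)
        f1 = y + rng.normal(0, 1.2, n)
        f2 = y + rng.normal(0, 1.2, n)
        table = pd.DataFrame(
            {"f1": f1, "f2": f2, "response": np.where(y == 1, "responsive", "unresponsive")}
        )
        auc1 = roc_analysis(f1, y).auc
        auc2 = roc_analysis(f2, y).auc
        model = fit_logistic(table, ["f1", "f2"])
        auc_comb = roc_analysis(model.fitted_probabilities, y).auc
        assert auc_comb >= max(auc1, auc2)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_worked_four_point_example(self):
        res = roc_analysis([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.direction == "greater_is_positive"
        assert res.cutoff == 2.0  # positive iff score > 2, matching '>' convention
        assert res.cutoff_operator == ">"

    @given(
        n=st.integers(4, 30),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_auc_equals_pair_concordance(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, rng.integers(1, n), replace=False)] = 1
        if y.sum() in (0, n):
            return
        res = roc_analysis(scores, y, direction="greater_is_positive")
        assert res.auc == pytest.approx(auc_pair_counting(scores, y), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_youden_cutoff_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        scores = np.round(rng.normal(0, 1, n), 1)
        y = (rng.random(n) < 0.5).astype(int)
        if y.sum() in (0, n):
            return
        res = roc_analysis(scores, y)
        c, sens, spec = youden_bruteforce(scores, y, res.direction)
        assert res.cutoff == pytest.approx(c)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)

    def test_random_scores_near_half_and_direction_flip(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=500)
        y = (rng.random(500) < 0.5).astype(int)
        raw = roc_analysis(scores, y, direction="greater_is_positive")
        assert 0.45 < raw.auc < 0.55
        auto = roc_analysis(scores, y)
        assert auto.auc >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestEvaluateResponseMarkers:
    @staticmethod
    def _cohort_table(seed=14, n=50, effect=1.5):
        rng = np.random.default_rng(seed)
        y = np.repeat([1, 0], n // 2)
        return pd.DataFrame(
            {
                "dvol_LH": y * effect * 0.2 + rng.normal(0, 0.15, n),
                "dpct_volume_whole": -y * effect * 12 + rng.normal(5, 10, n),
                "response": np.where(y == 1, "responsive", "unresponsive"),
            }
        ), y

    def test_combined_dominates_and_schema(self):
        table, _ = self._cohort_table()
        report = evaluate_response_markers(table)
        assert list(report["parameter"]) == ["dvol_LH", "dpct_volume_whole", "combined"]
        aucs = report.set_index("parameter")["auc"]
        assert aucs["combined"] >= max(aucs["dvol_LH"], aucs["dpct_volume_whole"])
        assert report.set_index("parameter").loc["combined", "cutoff"] == "-"
        # responders have lower whole-volume change: reported with the '<=' operator
        assert report.set_index("parameter").loc["dpct_volume_whole", "cutoff"].startswith("<=")

    def test_label_permutation_collapses_auc(self):
        table, y = self._cohort_table(n=100)
        rng = np.random.default_rng(15)
        table["response"] = rng.permutation(table["response"].to_numpy())
        report = evaluate_response_markers(table)
        assert ((report["auc"] >= 0.4) & (report["auc"] <= 0.65)).all()

    def test_identical_groups_auc_half(self):
        x = np.tile(np.arange(10.0), 2)
        table = pd.DataFrame(
            {
                "dvol_LH": x,
                "dpct_volume_whole": x * 2,
                "response": ["responsive"] * 10 + ["unresponsive"] * 10,
            }
        )
        for feat in ("dvol_LH", "dpct_volume_whole"):
            assert roc_analysis(table[feat], table["response"]).auc == pytest.approx(0.5)
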