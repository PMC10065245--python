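"""Tests for group tests, stepwise selection, and ROC analysis.

Exact tests are checked against independent full-enumeration oracles;
the empirical AUC against both an all-pairs counting oracle and
sklearn's implementation.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from marrowquant import (CohortSpec, StepwiseRegression,
                         YoudenCutoffClassifier, binormal_auc, fisher_exact,
                         generate_cohort, mann_whitney, roc_analysis,
                         run_full_analysis, simulate_mean_empirical_auc,
                         stepwise_regression, univariate_screen)

rng = np.random.default_rng(123)


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by brute force over all labelings."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_stat(a, b)
    us = [u_stat(pooled[list(idx)],
                 pooled[[i for i in range(n) if i not in idx]])
          for idx in itertools.combinations(range(n), na)]
    us = np.asarray(us)
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return u_obs, min(1.0, p)


def fisher_2x2_oracle(table):
    """Probability-ordering two-sided p from the hypergeometric pmf."""
    (a, b), (c, d) = table
    n1, n0, ntot = a + b, c + d, a + b + c + d
    k = a + c
    dist = hypergeom(ntot, n1, k)
    p_obs = dist.pmf(a)
    support = np.arange(max(0, k - n0), min(k, n1) + 1)
    probs = dist.pmf(support)
    return probs[probs <= p_obs * (1 + 1e-9)].sum()


def fisher_rx2_oracle(table):
    """Exact r x 2 p by itertools enumeration of tables with fixed margins."""
    t = np.asarray(table)
    rows = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    n = int(t.sum())

    def prob(first_col):
        num = math.prod(math.comb(int(r), int(a)) for r, a in zip(rows, first_col))
        return num / math.comb(n, c1)

    p_obs = prob(t[:, 0])
    total = 0.0
    for combo in itertools.product(*(range(r + 1) for r in rows)):
        if sum(combo) != c1:
            continue
        p = prob(combo)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_small_separated_groups(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(9 / 2)  # n^2/2 with ties half
        assert res.p_value == 1.0
        assert res.method == "approximate"  # ties force the normal path

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_enumeration(self, data):
        na = data.draw(st.integers(2, 6))
        nb = data.draw(st.integers(2, 6))
        vals = data.draw(st.lists(st.integers(0, 1000), min_size=na + nb,
                                  max_size=na + nb, unique=True))
        a, b = np.array(vals[:na], float), np.array(vals[na:], float)
        res = mann_whitney(a, b)
        u_ref, p_ref = mw_exact_oracle(a, b)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(u_ref)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_large_samples_take_normal_path(self):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        assert mann_whitney(a, b).method == "approximate"


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    def test_bence_jones_association(self):
        """All 7 Bence-Jones patients in the poor group: p below 0.05."""
        res = fisher_exact([[0, 7], [16, 15]])
        assert res.p_value < 0.05
        assert res.p_value == pytest.approx(fisher_2x2_oracle([[0, 7], [16, 15]]),
                                            rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[0, 3], [0, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0.5, 1.5], [1, 2]])

    @given(st.lists(st.integers(0, 6), min_size=4, max_size=4))
    @settings(max_examples=80, deadline=None)
    def test_2x2_matches_hypergeometric_oracle(self, cells):
        t = np.array(cells).reshape(2, 2)
        if np.any(t.sum(0) == 0) or np.any(t.sum(1) == 0):
            return
        res = fisher_exact(t)
        assert res.p_value == pytest.approx(fisher_2x2_oracle(t), rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[3, 0], [1, 2], [0, 4]],
        [[5, 1], [2, 2], [1, 5], [0, 3]],
        [[13, 9], [3, 5], [0, 1], [0, 7]],  # M-protein x mobilization analogue
    ])
    def test_rx2_matches_enumeration_oracle(self, table):
        res = fisher_exact(table)
        assert res.p_value == pytest.approx(fisher_rx2_oracle(table), rel=1e-9)


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

class TestUnivariateScreen:
    def _null_cohort(self, n=150, seed=0):
        r = np.random.default_rng(seed)
        labels = np.array(["adequate"] * (n // 2) + ["poor"] * (n - n // 2))
        return pd.DataFrame({
            "median_adc_mm2_s": np.where(labels == "poor",
                                         r.normal(1.24e-3, 0.26e-3, n),
                                         r.normal(0.96e-3, 0.24e-3, n)),
            "noise_1": r.normal(size=n),
            "noise_2": r.normal(size=n),
            "constant": np.ones(n),
            "mobilization_class": labels,
        })

    def test_only_discriminating_variable_selected(self):
        screen = univariate_screen(self._null_cohort(), alpha=0.05)
        assert "median_adc_mm2_s" in screen.selected
        assert "noise_1" not in screen.selected or "noise_2" not in screen.selected

    def test_alpha_extremes(self):
        cohort = self._null_cohort(n=40)
        non_constant = ["median_adc_mm2_s", "noise_1", "noise_2"]
        all_sel = univariate_screen(cohort, alpha=1.0, variables=non_constant)
        assert set(all_sel.selected) == set(non_constant)
        none_sel = univariate_screen(cohort, alpha=0.0)
        assert none_sel.selected == []

    def test_constant_variable_flagged(self):
        screen = univariate_screen(self._null_cohort(n=30))
        row = screen.table.set_index("variable").loc["constant"]
        assert row["p_value"] == 1.0 and row["note"] == "constant"

    def test_categorical_variable_uses_fisher(self, default_cohort):
        screen = univariate_screen(default_cohort, variables=["mprotein_type"])
        assert screen.table.iloc[0]["test"] == "fisher_exact"


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

class TestStepwiseRegression:
    def test_pure_noise_mostly_selects_nothing(self):
        empty = 0
        reps = 40
        for seed in range(reps):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(200, 5)),
                             columns=[f"n{i}" for i in range(5)])
            y = r.normal(size=200)
            est = StepwiseRegression().fit(X, y)
            empty += not est.selected_
        # P(empty) ~ (1 - 0.05)^5 ~ 0.77 under independence
        assert empty / reps > 0.5

    def test_recovers_true_predictor(self):
        r = np.random.default_rng(1)
        x = r.normal(size=300)
        X = pd.DataFrame({"x": x, "noise1": r.normal(size=300),
                          "noise2": r.normal(size=300)})
        y = 2.0 * x + r.normal(scale=0.5, size=300)
        est = StepwiseRegression().fit(X, y)
        assert "x" in est.selected_
        row = est.table_.loc["x"]
        assert row["ci_low"] <= 2.0 <= row["ci_high"]
        # normal-approximation CI brackets beta +/- 1.96 se
        assert row["ci_low"] == pytest.approx(row["beta"] - 1.959964 * row["se"],
                                              rel=1e-5)

    def test_single_candidate_reduces_to_simple_regression(self):
        r = np.random.default_rng(2)
        x = r.normal(size=50)
        y = 1.5 * x + r.normal(scale=0.3, size=50)
        est = StepwiseRegression(p_enter=1.0).fit(pd.DataFrame({"x": x}), y)
        beta_closed = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert est.table_.loc["x", "beta"] == pytest.approx(beta_closed, rel=1e-9)

    def test_collinear_candidate_dropped_with_warning(self):
        r = np.random.default_rng(3)
        x = r.normal(size=100)
        X = pd.DataFrame({"x": x, "x_copy": x * 2.0})
        y = x + r.normal(scale=0.2, size=100)
        with pytest.warns(UserWarning, match="collinear"):
            est = StepwiseRegression().fit(X, y)
        assert est.selected_ == ["x"] or est.selected_ == ["x_copy"]
        assert len(est.dropped_collinear_) == 1

    def test_sklearn_protocol(self):
        est = StepwiseRegression(p_enter=0.01)
        assert est.get_params()["p_enter"] == 0.01
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        r = np.random.default_rng(4)
        X = pd.DataFrame({"x": r.normal(size=60)})
        y = 3.0 * X["x"].to_numpy() + r.normal(scale=0.1, size=60)
        est.fit(X, y)
        pred = est.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError, match="n_candidates"):
            StepwiseRegression().fit(X, np.ones(4))

    def test_functional_wrapper(self, default_cohort):
        res = stepwise_regression(default_cohort,
                                  outcome="cd34_yield_cells_per_kg",
                                  candidates=["median_adc_mm2_s", "ff_percent"])
        assert "median_adc_mm2_s" in res.selected
        assert res.family == "ols" and res.n == len(default_cohort)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.array([0.5, 0.6, 0.7, 1.5, 1.6, 1.7]) * 1e-3
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        roc = roc_analysis(scores, labels)
        assert roc.auc == 1.0
        assert roc.sens_at_cutoff == 1.0 and roc.spec_at_cutoff == 1.0
        assert roc.youden_cutoff == pytest.approx(0.7e-3)  # lowest tying cutoff

    def test_random_labels_approach_half(self):
        r = np.random.default_rng(0)
        scores = r.normal(size=4000)
        labels = r.random(4000) > 0.5
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pairwise_u_count(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 60))
        scores = r.integers(0, 8, size=n).astype(float)  # force heavy ties
        labels = r.random(n) > 0.5
        if labels.all() or not labels.any():
            return
        roc = roc_analysis(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), rel=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_curve_monotone_in_cutoff(self):
        r = np.random.default_rng(5)
        scores = r.normal(size=200)
        labels = scores + r.normal(size=200) > 0
        roc = roc_analysis(scores, labels)
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)
        assert np.all(np.diff(roc.cutoffs) > 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["poor", "poor"])

    def test_string_labels_accepted(self, default_cohort):
        roc = roc_analysis(default_cohort["median_adc_mm2_s"],
                           default_cohort["mobilization_class"])
        assert 0.5 < roc.auc <= 1.0


class TestYoudenCutoffClassifier:
    def test_learned_cutoff_predicts(self):
        scores = np.array([0.7, 0.8, 0.9, 1.3, 1.4, 1.5]) * 1e-3
        labels = np.array(["adequate"] * 3 + ["poor"] * 3)
        clf = YoudenCutoffClassifier().fit(scores, labels)
        assert clf.auc_ == 1.0
        assert list(clf.predict([0.5e-3, 2.0e-3])) == ["adequate", "poor"]
        # strictly-above rule at the cutoff itself
        assert clf.predict([clf.cutoff_])[0] == "adequate"

    def test_fixed_published_cutoff(self):
        clf = YoudenCutoffClassifier(cutoff=1.18e-3)
        clf.fit(np.array([1.0e-3, 1.5e-3]), np.array(["adequate", "poor"]))
        assert list(clf.predict([0.78e-3, 1.53e-3])) == ["adequate", "poor"]

    def test_clonable(self):
        clf = YoudenCutoffClassifier(cutoff=1.18e-3)
        assert clone(clf).get_params() == {"cutoff": 1.18e-3}


class TestBinormalAuc:
    def test_equal_means_half(self):
        assert binormal_auc(1.0, 0.3, 1.0, 0.4) == 0.5

    def test_published_group_parameters(self):
        """Group normals 0.96+/-0.24 vs 1.24+/-0.26 give AUC ~ 0.786."""
        auc = binormal_auc(0.96, 0.24, 1.24, 0.26)
        assert auc == pytest.approx(0.786, abs=0.001)

    def test_vanishing_sd_limit(self):
        assert binormal_auc(0.9, 1e-9, 1.3, 1e-9) == pytest.approx(1.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(1.0, 0.0, 2.0, 0.3)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

class TestRunFullAnalysis:
    def test_default_cohort_report(self, default_cohort):
        report = run_full_analysis(default_cohort)
        assert "median_adc_mm2_s" in report.screen.selected
        assert 0.5 < report.roc.auc <= 1.0
        assert report.n_used == 38 and report.n_dropped == 0
        d = report.to_dict()
        assert set(d) >= {"univariate_screen", "stepwise_regression",
                          "roc_median_adc", "n_used", "n_dropped"}

    def test_identical_groups_select_nothing(self):
        r = np.random.default_rng(1)
        n = 60
        cohort = pd.DataFrame({
            "median_adc_mm2_s": r.normal(1.0e-3, 0.2e-3, n),
            "tdv_ml": r.normal(70, 20, n),
            "ff_percent": r.normal(40, 10, n),
            "cd34_yield_cells_per_kg": r.normal(4e6, 1e6, n),
            "mobilization_class": np.where(np.arange(n) % 2 == 0,
                                           "adequate", "poor"),
        })
        report = run_full_analysis(
            cohort, variables=["median_adc_mm2_s", "tdv_ml", "ff_percent"])
        assert report.screen.selected == []
        assert report.regression.skipped_reason is not None
        assert report.roc.auc == pytest.approx(0.5, abs=0.2)

    def test_incomplete_rows_dropped_and_counted(self, default_cohort):
        cohort = default_cohort.copy()
        cohort.loc[cohort.index[:3], "ff_percent"] = np.nan
        report = run_full_analysis(cohort)
        assert report.n_dropped == 3
        assert report.n_used == len(cohort) - 3

    def test_too_small_classes_rejected(self, default_cohort):
        tiny = default_cohort.iloc[[0, 1, 2, 16]]  # one poor patient only
        with pytest.raises(ValueError, match="each mobilization class"):
            run_full_analysis(tiny)


class TestSimulatedAuc:
    def test_small_replicate_mean_matches_binormal(self):
        v = simulate_mean_empirical_auc(n_reps=300, seed=5)
        assert v == pytest.approx(binormal_auc(0.96, 0.24, 1.24, 0.26), abs=0.02)
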