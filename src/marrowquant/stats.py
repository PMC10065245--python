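"""Cohort statistics: group tests, stepwise regression, ROC analysis.

The analysis mirrors a small-cohort biomarker study: continuous markers
are compared between adequate and relatively poor mobilizers with the
Mann-Whitney U test (exact for small tie-free samples), categorical ones
with Fisher's exact test; variables significant in the univariate screen
enter a stepwise forward/backward regression on the CD34+ yield; and the
discriminatory power of median ADC is characterized by an empirical ROC
curve with a Youden-index cutoff.

Two sklearn-style estimators expose the fit/predict-shaped pieces:
:class:`StepwiseRegression` and :class:`YoudenCutoffClassifier`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TestResult",
    "RocResult",
    "RegressionResult",
    "ScreenResult",
    "AnalysisReport",
    "mann_whitney",
    "fisher_exact",
    "univariate_screen",
    "StepwiseRegression",
    "stepwise_regression",
    "YoudenCutoffClassifier",
    "roc_analysis",
    "binormal_auc",
    "simulate_mean_empirical_auc",
    "run_full_analysis",
]

_Z975 = 1.959963984540054  # Phi^{-1}(0.975)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "approximate"
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class RocResult:
    """Empirical ROC: one point per distinct score cutoff, sorted ascending."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


@dataclass
class RegressionResult:
    selected: list[str]
    table: pd.DataFrame  # index = predictor; columns beta, se, ci_low, ci_high, p
    r_squared: float
    family: str
    n: int
    dropped_collinear: list[str] = field(default_factory=list)
    skipped_reason: str | None = None


@dataclass
class ScreenResult:
    table: pd.DataFrame  # variable, test, statistic, p_value, note
    selected: list[str]
    alpha: float


@dataclass
class AnalysisReport:
    screen: ScreenResult
    regression: RegressionResult
    logistic_regression: RegressionResult | None
    roc: RocResult
    n_used: int
    n_dropped: int

    def to_dict(self) -> dict:
        def _tbl(df: pd.DataFrame) -> dict:
            return {str(k): {c: _plain(v) for c, v in row.items()}
                    for k, row in df.to_dict(orient="index").items()}

        def _reg(r: RegressionResult | None):
            if r is None:
                return None
            return {
                "selected": r.selected,
                "table": _tbl(r.table),
                "r_squared": _plain(r.r_squared),
                "family": r.family,
                "n": r.n,
                "dropped_collinear": r.dropped_collinear,
                "skipped_reason": r.skipped_reason,
            }

        return {
            "univariate_screen": {
                "alpha": self.screen.alpha,
                "selected": self.screen.selected,
                "table": _tbl(self.screen.table.set_index("variable")),
            },
            "stepwise_regression": _reg(self.regression),
            "logistic_regression": _reg(self.logistic_regression),
            "roc_median_adc": {
                "auc": _plain(self.roc.auc),
                "youden_cutoff": _plain(self.roc.youden_cutoff),
                "sensitivity_at_cutoff": _plain(self.roc.sens_at_cutoff),
                "specificity_at_cutoff": _plain(self.roc.spec_at_cutoff),
                "points": [
                    {"cutoff": _plain(c), "sensitivity": _plain(s), "specificity": _plain(p)}
                    for c, s, p in zip(self.roc.cutoffs, self.roc.sensitivity,
                                       self.roc.specificity)
                ],
            },
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
        }


def _plain(v):
    if v is None:
        return None
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return v if math.isfinite(v) else None
    if isinstance(v, (np.integer, int)):
        return int(v)
    return v


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _summaries(a: np.ndarray, b: np.ndarray) -> dict:
    def s(x):
        return {"n": int(x.size), "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "median": float(np.median(x))}
    return {"a": s(a), "b": s(b)}


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U test; U reported for ``group_a``.

    The exact null distribution (full enumeration over rank assignments)
    is used when n_a + n_b <= 20 and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity
    corrections applies.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= 20) and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "exact" if exact else "approximate", _summaries(a, b))


def fisher_exact(table) -> TestResult:
    """Fisher's exact test for a 2x2 or r x 2 contingency table.

    Two-sided by the probability-ordering rule: the p-value sums the
    null (multivariate hypergeometric) probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's.  The r x 2 case enumerates all such tables, which is
    feasible at clinical-cohort scale.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError(f"expected an r x 2 table with r >= 2, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all row and column margins must be positive")

    if t.shape[0] == 2:
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult(float(odds), float(min(p, 1.0)), "exact",
                          {"table": t.tolist()})

    p = _fisher_rx2_enumeration(t)
    return TestResult(float("nan"), p, "exact", {"table": t.tolist()})


def _log_hyper_prob(a: np.ndarray, rows: np.ndarray, n: int, c1: int) -> float:
    from scipy.special import gammaln

    def lc(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return float(np.sum(lc(rows, a)) - lc(n, c1))


def _fisher_rx2_enumeration(t: np.ndarray) -> float:
    rows = t.sum(axis=1)
    n = int(t.sum())
    c1 = int(t[:, 0].sum())
    log_obs = _log_hyper_prob(t[:, 0], rows, n, c1)
    total = 0.0
    a = np.zeros(len(rows), dtype=int)

    def rec(i: int, remaining: int):
        nonlocal total
        if i == len(rows) - 1:
            if remaining <= rows[i]:
                a[i] = remaining
                lp = _log_hyper_prob(a, rows, n, c1)
                if lp <= log_obs + 1e-9:  # tolerance against roundoff ties
                    total += math.exp(lp)
            return
        tail_cap = int(rows[i + 1:].sum())
        for v in range(max(0, remaining - tail_cap), min(rows[i], remaining) + 1):
            a[i] = v
            rec(i + 1, remaining - v)

    rec(0, c1)
    return min(1.0, total)


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

def univariate_screen(cohort: pd.DataFrame, alpha: float = 0.05,
                      variables: list[str] | None = None,
                      class_col: str = "mobilization_class") -> ScreenResult:
    """Per-variable group test against the mobilization class.

    Numeric variables use :func:`mann_whitney`, categorical ones
    :func:`fisher_exact` on the category-by-class count table.  Constant
    variables are flagged and assigned p = 1.  The selected set holds the
    variables with p < ``alpha``.
    """
    if class_col not in cohort.columns:
        raise ValueError(f"cohort lacks a {class_col!r} column")
    labels = cohort[class_col].astype(str)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, found {classes}")
    if variables is None:
        drop = {class_col, "patient_id", "group", "cd34_yield_cells_per_kg"}
        variables = [c for c in cohort.columns if c not in drop]
    if not variables:
        raise ValueError("no variables to screen")

    rows = []
    for var in variables:
        col = cohort[var]
        note = ""
        if col.nunique(dropna=True) <= 1:
            stat, p, test = float("nan"), 1.0, "none"
            note = "constant"
        elif pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            res = mann_whitney(col[labels == classes[0]], col[labels == classes[1]])
            stat, p, test = res.statistic, res.p_value, f"mann_whitney:{res.method}"
        else:
            counts = pd.crosstab(col.astype(str), labels).to_numpy()
            res = fisher_exact(counts)
            stat, p, test = res.statistic, res.p_value, "fisher_exact"
        rows.append({"variable": var, "test": test, "statistic": stat,
                     "p_value": p, "note": note})
    table = pd.DataFrame(rows)
    selected = table.loc[table["p_value"] < alpha, "variable"].tolist()
    return ScreenResult(table, selected, alpha)


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

class StepwiseRegression(RegressorMixin, BaseEstimator):
    """Stepwise forward/backward variable selection around an OLS or logit fit.

    At each forward step the candidate with the smallest partial-test
    p-value enters if p < ``p_enter``; at each backward step any included
    predictor with p >= ``p_remove`` leaves (largest first); iteration
    continues to a fixed point.  Candidates whose inclusion makes the
    design ill-conditioned are dropped with a warning.

    Parameters
    ----------
    p_enter, p_remove:
        Inclusion/removal significance levels (defaults 0.05 / 0.10).
    family:
        "ols" for a linear model of a continuous outcome, "logit" for a
        logistic model of a binary outcome.
    cond_threshold:
        Condition-number bound above which a candidate is considered
        collinear with the current design.

    Attributes
    ----------
    selected_ : list of retained predictor names, in inclusion order
    table_ : DataFrame with beta, se, ci_low, ci_high, p per retained
        predictor (normal-approximation 95% CI, beta +/- 1.96 se)
    rsquared_ : R^2 of the final model (pseudo-R^2 for logit)
    dropped_collinear_ : candidates dropped for collinearity
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 family: str = "ols", cond_threshold: float = 1e8):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.family = family
        self.cond_threshold = cond_threshold

    # -- internals ---------------------------------------------------------
    def _fit_model(self, X: pd.DataFrame, y: np.ndarray, cols: list[str]):
        design = sm.add_constant(X[cols], has_constant="add")
        if self.family == "ols":
            return sm.OLS(y, design).fit()
        if self.family == "logit":
            with warnings.catch_warnings():
                # quasi-separation in tiny cohorts floods the log otherwise
                warnings.simplefilter("ignore")
                return sm.Logit(y, design).fit(disp=0)
        raise ValueError(f"unknown family {self.family!r}")

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        X = X.astype(float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != y.size:
            raise ValueError("X and y lengths differ")
        if len(X) <= X.shape[1] + 2:
            raise ValueError(
                f"need n > n_candidates + 2 (n={len(X)}, candidates={X.shape[1]})")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        candidates = list(X.columns)
        self.dropped_collinear_ = []
        included: list[str] = []
        for _ in range(10 * len(candidates) + 10):
            changed = False
            # forward
            best_p, best_var = None, None
            for var in candidates:
                if var in included:
                    continue
                trial = included + [var]
                design = sm.add_constant(X[trial], has_constant="add")
                if np.linalg.cond(design.to_numpy()) > self.cond_threshold:
                    continue
                res = self._fit_model(X, y, trial)
                p = float(res.pvalues[var])
                if np.isnan(p):
                    continue
                if best_p is None or p < best_p:
                    best_p, best_var = p, var
            if best_var is not None and best_p < self.p_enter:
                included.append(best_var)
                changed = True
            # flag candidates that can never enter for conditioning reasons
            for var in list(candidates):
                if var not in included:
                    design = sm.add_constant(X[included + [var]], has_constant="add")
                    if np.linalg.cond(design.to_numpy()) > self.cond_threshold:
                        candidates.remove(var)
                        self.dropped_collinear_.append(var)
                        warnings.warn(f"candidate {var!r} dropped: collinear with "
                                      "the current design", stacklevel=2)
            # backward
            if included:
                res = self._fit_model(X, y, included)
                pv = res.pvalues[included]
                worst = pv.idxmax()
                if float(pv[worst]) >= self.p_remove:
                    included.remove(worst)
                    changed = True
            if not changed:
                break

        self.selected_ = included
        if included:
            res = self._fit_model(X, y, included)
            beta = res.params[included].to_numpy(dtype=float)
            se = res.bse[included].to_numpy(dtype=float)
            self.table_ = pd.DataFrame({
                "beta": beta, "se": se,
                "ci_low": beta - _Z975 * se, "ci_high": beta + _Z975 * se,
                "p": res.pvalues[included].to_numpy(dtype=float),
            }, index=included)
            self.rsquared_ = float(res.rsquared if self.family == "ols"
                                   else res.prsquared)
            self._result_ = res
        else:
            self.table_ = pd.DataFrame(
                columns=["beta", "se", "ci_low", "ci_high", "p"])
            self.rsquared_ = 0.0
            self._result_ = None
        return self

    def predict(self, X):
        check_is_fitted(self, "selected_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=list(self.feature_names_in_))
        if self._result_ is None:
            const = float(np.mean(self._y_mean_)) if hasattr(self, "_y_mean_") else 0.0
            return np.full(len(X), const)
        design = sm.add_constant(X[self.selected_].astype(float), has_constant="add")
        return np.asarray(self._result_.predict(design), dtype=float)


def stepwise_regression(cohort: pd.DataFrame, outcome: str,
                        candidates: list[str], p_enter: float = 0.05,
                        p_remove: float = 0.10,
                        family: str = "ols") -> RegressionResult:
    """Functional wrapper over :class:`StepwiseRegression` on a cohort table."""
    est = StepwiseRegression(p_enter=p_enter, p_remove=p_remove, family=family)
    est.fit(cohort[candidates], cohort[outcome])
    return RegressionResult(
        selected=list(est.selected_), table=est.table_,
        r_squared=est.rsquared_, family=family, n=len(cohort),
        dropped_collinear=list(est.dropped_collinear_),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _poor_indicator(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return arr.astype(str) == "poor"
    return arr.astype(bool)


def roc_analysis(scores, labels) -> RocResult:
    """Empirical ROC of a score with "score > cutoff => predicted poor".

    One operating point per distinct score value (sorted ascending by
    cutoff); the AUC is the trapezoidal area, which equals the normalized
    Mann-Whitney U with ties counted half.  The Youden cutoff maximizes
    sensitivity + specificity - 1, ties resolved to the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    pos = _poor_indicator(labels)
    if scores.size != pos.size:
        raise ValueError("scores and labels lengths differ")
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    sp = np.sort(scores[pos])
    sn = np.sort(scores[~pos])
    cutoffs = np.unique(scores)
    # sens(c) = P(score > c | poor); spec(c) = P(score <= c | adequate)
    sens = 1.0 - np.searchsorted(sp, cutoffs, side="right") / n_pos
    spec = np.searchsorted(sn, cutoffs, side="right") / n_neg

    # traverse the curve in descending-cutoff order: (0,0) at the top
    # cutoff through (1,1) at cutoff -inf; simultaneous tpr/fpr jumps at
    # tied scores become diagonal segments, counting tied pairs half
    fpr = np.concatenate([(1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first maximizer = lowest cutoff
    return RocResult(cutoffs, sens, spec, auc,
                     float(cutoffs[best]), float(sens[best]), float(spec[best]))


class YoudenCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Single-marker threshold classifier with a Youden-index learned cutoff.

    ``fit`` computes the empirical ROC of the marker against the binary
    outcome and stores the Youden-optimal cutoff; ``predict`` labels a
    sample poor when its score strictly exceeds the cutoff.  Pass a fixed
    ``cutoff`` (e.g. the published 1.18e-3 mm^2/s) to skip learning.
    """

    def __init__(self, cutoff: float | None = None):
        self.cutoff = cutoff

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).reshape(len(np.atleast_1d(np.asarray(y))), -1)[:, 0]
        roc = roc_analysis(scores, y)
        self.roc_ = roc
        self.auc_ = roc.auc
        self.cutoff_ = float(self.cutoff) if self.cutoff is not None else roc.youden_cutoff
        self.classes_ = np.array(["adequate", "poor"])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        scores = np.asarray(X, dtype=float).reshape(-1)
        return np.where(scores > self.cutoff_, "poor", "adequate")


def binormal_auc(mu_a: float, sd_a: float, mu_p: float, sd_p: float) -> float:
    """AUC of two normal score distributions: Phi(|mu_p - mu_a| / sqrt(sd_a^2 + sd_p^2))."""
    if sd_a <= 0 or sd_p <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf(abs(mu_p - mu_a) / math.hypot(sd_a, sd_p)))


def simulate_mean_empirical_auc(
    n_reps: int = 10_000,
    n_adequate: int = 16,
    n_poor: int = 22,
    adequate_params: tuple[float, float] = (0.96e-3, 0.24e-3),
    poor_params: tuple[float, float] = (1.24e-3, 0.26e-3),
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean empirical ROC AUC over Monte-Carlo cohorts of the two-group design.

    Each replicate draws per-group median-ADC values from the stated
    normals and scores them with :func:`roc_analysis` (higher ADC
    predicting poor mobilization); the replicate AUCs are averaged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.array([False] * n_adequate + [True] * n_poor)
    total = 0.0
    for _ in range(n_reps):
        a = rng.normal(*adequate_params, size=n_adequate)
        p = rng.normal(*poor_params, size=n_poor)
        total += roc_analysis(np.concatenate([a, p]), labels).auc
    return total / n_reps


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

_ANALYSIS_VARIABLES = [
    "age_years", "mprotein_type", "prior_lines",
    "wbc_10e3_per_ul", "neutrophil_10e3_per_ul", "platelet_10e4_per_ul",
    "hemoglobin_g_dl", "diagnosis_to_harvest_months",
    "tdv_ml", "median_adc_mm2_s", "ff_percent",
]


def run_full_analysis(cohort: pd.DataFrame, alpha: float = 0.05,
                      p_enter: float = 0.05, p_remove: float = 0.10,
                      variables: list[str] | None = None,
                      adc_col: str = "median_adc_mm2_s",
                      outcome_col: str = "cd34_yield_cells_per_kg",
                      class_col: str = "mobilization_class") -> AnalysisReport:
    """Univariate screen, stepwise model, and ROC of median ADC, in one report.

    Incomplete rows (missing any analysis column) are dropped complete-case
    with a recorded count.  Variables with p < ``alpha`` in the screen feed
    the stepwise regression of the continuous CD34+ yield (primary) and a
    logistic variant on the poor/adequate label (secondary); the M-protein
    category enters the regressions dichotomized as Bence-Jones or not.
    With too few patients for selection (n <= candidates + 2) the stepwise
    stage is recorded as skipped rather than failing the whole report.
    """
    if variables is None:
        variables = [v for v in _ANALYSIS_VARIABLES if v in cohort.columns]
    needed = list(dict.fromkeys(variables + [adc_col, outcome_col, class_col]))
    data = cohort.dropna(subset=[c for c in needed if c in cohort.columns]).copy()
    n_dropped = len(cohort) - len(data)
    counts = data[class_col].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 patients in each mobilization class")

    screen = univariate_screen(data, alpha=alpha, variables=variables,
                               class_col=class_col)

    candidates = []
    for var in screen.selected:
        if var == "mprotein_type":
            data["bence_jones"] = (data["mprotein_type"].astype(str) == "BJ").astype(float)
            candidates.append("bence_jones")
        else:
            candidates.append(var)

    def _stepwise(family: str, y_col_values) -> RegressionResult:
        if not candidates:
            return RegressionResult([], pd.DataFrame(
                columns=["beta", "se", "ci_low", "ci_high", "p"]),
                0.0, family, len(data),
                skipped_reason="no candidate passed the univariate screen")
        if len(data) <= len(candidates) + 2:
            return RegressionResult([], pd.DataFrame(
                columns=["beta", "se", "ci_low", "ci_high", "p"]),
                0.0, family, len(data),
                skipped_reason=f"too few patients (n={len(data)}) for "
                               f"{len(candidates)} candidates")
        est = StepwiseRegression(p_enter=p_enter, p_remove=p_remove, family=family)
        try:
            est.fit(data[candidates], y_col_values)
        except Exception as exc:  # perfect separation etc. in the logit variant
            return RegressionResult([], pd.DataFrame(
                columns=["beta", "se", "ci_low", "ci_high", "p"]),
                0.0, family, len(data), skipped_reason=f"fit failed: {exc}")
        return RegressionResult(list(est.selected_), est.table_, est.rsquared_,
                                family, len(data),
                                dropped_collinear=list(est.dropped_collinear_))

    regression = _stepwise("ols", data[outcome_col].to_numpy(dtype=float))
    logistic = _stepwise("logit",
                         (data[class_col].astype(str) == "poor").to_numpy(dtype=float))

    roc = roc_analysis(data[adc_col], data[class_col])
    return AnalysisReport(screen, regression, logistic, roc,
                          n_used=len(data), n_dropped=n_dropped)
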