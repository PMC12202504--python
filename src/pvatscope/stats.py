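"""Cohort statistics: normality-gated group tests, the logistic screening
cascade, ROC/Youden analysis, and summary-table assembly.

The analysis cascade mirrors common practice in clinical biomarker studies:

1. per-variable two-group comparison — Shapiro–Wilk in each group at
   alpha = 0.05 gates Student's t-test vs the Wilcoxon rank-sum test;
   categoricals use the chi-squared test;
2. univariate logistic screen — variables with P < 0.05 advance;
3. collinearity filter — variance inflation factors (VIF = 1/(1 − R²));
   the highest-VIF variable is dropped iteratively until all VIF <= 10;
4. multivariate logistic model with Wald 95% CIs;
5. ROC analysis with the Youden-index optimal cut-off.

No multiple-testing correction is applied anywhere in the cascade, matching
the screening character of the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import OUTCOME

__all__ = [
    "TestResult",
    "UnivariateFit",
    "LogisticFit",
    "ROCCurve",
    "compare_groups",
    "pooled_summary",
    "univariate_screen",
    "vif_filter",
    "multivariate_logistic",
    "roc_analysis",
    "binormal_auc",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class TestResult:
    variable: str
    method: str  # "t-test" | "rank-sum" | "chi-squared" | "none"
    statistic: float
    p_value: float
    summary_pos: str
    summary_neg: str
    note: str = ""


@dataclass
class UnivariateFit:
    variable: str
    coef: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    note: str = ""


@dataclass
class LogisticFit:
    """Joint maximum-likelihood logistic fit with Wald intervals."""

    variables: list[str]
    coef: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_value: dict[str, float]
    vif: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_value,
                "vif": {v: self.vif.get(v, np.nan) for v in self.variables},
            }
        ).loc[self.variables]


@dataclass
class ROCCurve:
    """Empirical ROC curve with the Youden-optimal operating point.

    ``direction`` is "greater" when high scores predict the event and
    "lesser" when low scores do (e.g. HU_ratio).  ``thresholds`` are on the
    original score scale; sensitivity/specificity arrays are parallel to
    them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    youden_cutoff: float
    youden_sensitivity: float
    youden_specificity: float

    @property
    def youden_index(self) -> float:
        return self.youden_sensitivity + self.youden_specificity - 1


def _is_binary(x: pd.Series) -> bool:
    vals = pd.unique(x.dropna())
    return len(vals) <= 2


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def compare_groups(
    table: pd.DataFrame,
    outcome: str = OUTCOME,
    variables: list[str] | None = None,
    categorical: list[str] | None = None,
) -> list[TestResult]:
    """Two-group comparison of every covariate, gated by normality.

    Continuous variables: Shapiro–Wilk per group at alpha = 0.05; if both
    groups pass, the independent-samples t-test, otherwise the Wilcoxon
    rank-sum (Mann–Whitney) test.  Binary/categorical variables: chi-squared
    on the contingency table.  All tests two-sided.  Variables constant in
    both groups are flagged untestable.
    """
    if variables is None:
        variables = [c for c in table.columns if c != outcome]
    if categorical is None:
        categorical = [v for v in variables if _is_binary(table[v])]
    g_pos = table[table[outcome] == 1]
    g_neg = table[table[outcome] == 0]
    if len(g_pos) == 0 or len(g_neg) == 0:
        raise ValueError("both outcome groups must be non-empty")

    results: list[TestResult] = []
    for v in variables:
        x_pos = g_pos[v].to_numpy(float)
        x_neg = g_neg[v].to_numpy(float)
        if np.ptp(table[v].to_numpy(float)) == 0:
            results.append(
                TestResult(v, "none", np.nan, np.nan, "", "", note="constant variable")
            )
            continue
        if v in categorical:
            ct = pd.crosstab(table[outcome], table[v])
            chi2, p, _, _ = sps.chi2_contingency(ct)
            results.append(
                TestResult(
                    v, "chi-squared", float(chi2), float(p),
                    summary_pos=f"{int(x_pos.sum())}/{len(x_pos)}",
                    summary_neg=f"{int(x_neg.sum())}/{len(x_neg)}",
                )
            )
            continue
        normal = all(
            len(np.unique(x)) > 2 and sps.shapiro(x).pvalue > SHAPIRO_ALPHA
            for x in (x_pos, x_neg)
        )
        if normal:
            stat, p = sps.ttest_ind(x_pos, x_neg)
            method = "t-test"
        else:
            stat, p = sps.mannwhitneyu(x_pos, x_neg, alternative="two-sided")
            method = "rank-sum"
        results.append(
            TestResult(
                v, method, float(stat), float(p),
                summary_pos=_fmt_mean_sd(x_pos), summary_neg=_fmt_mean_sd(x_neg),
            )
        )
    return results


def pooled_summary(groups: list[tuple[int, float, float]]) -> tuple[float, float]:
    """Overall (mean, SD) from per-group (n, mean, SD) summaries.

    The mean is the sample-size-weighted mean; the SD follows from the law
    of total variance with sample (ddof = 1) variances, so the result equals
    the summary of the concatenated raw samples exactly.
    """
    groups = [(int(n), float(m), float(s)) for n, m, s in groups]
    if any(n < 1 for n, _, _ in groups):
        raise ValueError("each group needs n >= 1")
    N = sum(n for n, _, _ in groups)
    mean = sum(n * m for n, m, _ in groups) / N
    if N < 2:
        return mean, float("nan")
    ss_within = sum((n - 1) * s**2 for n, _, s in groups)
    ss_between = sum(n * (m - mean) ** 2 for n, m, _ in groups)
    return mean, float(np.sqrt((ss_within + ss_between) / (N - 1)))


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """statsmodels Logit fit with convergence/separation detection."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=100, tol=1e-8
            )
        except Exception as exc:  # PerfectSeparationError and numerical failures
            return None, f"fit failed: {type(exc).__name__}"
    if not res.mle_retvals.get("converged", False):
        return res, "did not converge"
    # Wald machinery is meaningless under (quasi-)separation: enormous SEs
    if np.any(np.asarray(res.bse) > 1e3 * (1 + np.abs(np.asarray(res.params)))):
        return res, "quasi-separation (unstable standard errors)"
    return res, ""


def univariate_screen(
    table: pd.DataFrame,
    outcome: str = OUTCOME,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[UnivariateFit], list[str]]:
    """One single-covariate logistic fit per variable; P < alpha advances.

    Non-converged or separated fits are flagged and never advance.
    """
    if variables is None:
        variables = [c for c in table.columns if c != outcome]
    y = table[outcome].to_numpy(int)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    fits: list[UnivariateFit] = []
    advancing: list[str] = []
    for v in variables:
        res, note = _fit_logit(y, table[[v]])
        if res is None or note:
            fits.append(
                UnivariateFit(v, np.nan, np.nan, np.nan, np.nan, converged=False, note=note)
            )
            warnings.warn(f"univariate fit for {v!r} excluded: {note}", stacklevel=2)
            continue
        ci = res.conf_int()
        fits.append(
            UnivariateFit(
                v,
                coef=float(res.params[v]),
                ci_low=float(ci.loc[v, 0]),
                ci_high=float(ci.loc[v, 1]),
                p_value=float(res.pvalues[v]),
                converged=True,
            )
        )
        if res.pvalues[v] < alpha:
            advancing.append(v)
    return fits, advancing


def _vifs(table: pd.DataFrame, variables: list[str]) -> dict[str, float]:
    """VIF_j = 1/(1 − R²) of variable j regressed (with intercept) on the rest."""
    out = {}
    for v in variables:
        others = [w for w in variables if w != v]
        X = sm.add_constant(table[others], has_constant="add")
        r2 = sm.OLS(table[v], X).fit().rsquared
        out[v] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    table: pd.DataFrame, variables: list[str], limit: float = 10.0
) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop the highest-VIF variable until all VIF <= limit.

    Exact linear dependence yields infinite VIF and is removed first.
    Returns the retained variables and their final VIFs.
    """
    if len(variables) < 2:
        return list(variables), {v: 1.0 for v in variables}
    retained = list(variables)
    while len(retained) >= 2:
        vifs = _vifs(table, retained)
        worst = max(retained, key=lambda v: vifs[v])
        if vifs[worst] <= limit:
            return retained, vifs
        retained.remove(worst)
    return retained, {v: 1.0 for v in retained}


def multivariate_logistic(
    table: pd.DataFrame,
    variables: list[str],
    outcome: str = OUTCOME,
) -> LogisticFit:
    """Joint ML logistic fit of the outcome on the retained variables."""
    if not variables:
        raise ValueError("no variables to fit")
    y = table[outcome].to_numpy(int)
    res, note = _fit_logit(y, table[list(variables)])
    vifs = _vifs(table, list(variables)) if len(variables) >= 2 else {variables[0]: 1.0}
    if res is None:
        return LogisticFit(
            variables=list(variables),
            coef={v: np.nan for v in variables},
            ci_low={v: np.nan for v in variables},
            ci_high={v: np.nan for v in variables},
            p_value={v: np.nan for v in variables},
            vif=vifs,
            converged=False,
        )
    if note:
        warnings.warn(f"multivariate fit: {note}", stacklevel=2)
    ci = res.conf_int()
    return LogisticFit(
        variables=list(variables),
        coef={v: float(res.params[v]) for v in variables},
        ci_low={v: float(ci.loc[v, 0]) for v in variables},
        ci_high={v: float(ci.loc[v, 1]) for v in variables},
        p_value={v: float(res.pvalues[v]) for v in variables},
        vif=vifs,
        converged=not note,
    )


def roc_analysis(
    scores: np.ndarray, labels: np.ndarray, direction: str = "greater"
) -> ROCCurve:
    """Empirical ROC curve, AUC, and the Youden-optimal cut-off.

    The AUC is the pairwise concordance probability with ties counted 1/2
    (identical to the trapezoidal area under the empirical curve).  Candidate
    cut-points are placed at midpoints between adjacent distinct scores (plus
    open ends); among cut-points attaining the maximal Youden index, the one
    with the highest specificity is reported.  For ``direction="lesser"``
    (markers where low values predict the event, e.g. HU_ratio) a subject is
    test-positive when score <= cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if direction not in ("greater", "lesser"):
        raise ValueError("direction must be 'greater' or 'lesser'")

    s = scores if direction == "greater" else -scores
    # AUC via the rank-sum (Mann–Whitney) identity; average ranks give
    # exactly 1/2 credit to cross-class ties
    ranks = sps.rankdata(s)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2
    step = 1.0  # open-end sentinels beyond the observed range
    cand = np.concatenate([[distinct[0] - step], mids, [distinct[-1] + step]])
    pos = np.sort(s[labels == 1])
    neg = np.sort(s[labels == 0])
    # sens(c) = P(pos >= c), spec(c) = P(neg < c), vectorised via bisection
    sens = 1.0 - np.searchsorted(pos, cand, side="left") / n_pos
    spec = np.searchsorted(neg, cand, side="left") / n_neg
    youden = sens + spec - 1
    best = np.flatnonzero(youden == youden.max())
    j = best[np.argmax(spec[best])]

    thr = cand if direction == "greater" else -cand
    return ROCCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        direction=direction,
        youden_cutoff=float(thr[j]),
        youden_sensitivity=float(sens[j]),
        youden_specificity=float(spec[j]),
    )


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC when both classes' scores are Gaussian:
    Phi((mu_pos − mu_neg) / sqrt(sd_pos² + sd_neg²))."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("SDs must be positive")
    return float(sps.norm.cdf((mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))
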