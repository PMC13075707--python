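"""Survival evaluation statistics.

Harrell's concordance index and the univariate Cox fit are implemented
here with their exact conventions pinned down (tie credit 0.5, pairs
with a censored shorter time excluded, Breslow tie handling, flagged
±inf confidence intervals under monotone likelihood); Kaplan–Meier and
log-rank go through lifelines, and the Wilcoxon signed-rank test through
scipy (exact for small samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import SurvivalData
from .errors import AdsccaError, InvalidConfigError, ShapeError


# ---------------------------------------------------------------------------
# Concordance index


def concordance_index(risks: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's C over comparable pairs.

    A pair is comparable when the subject with the shorter time had an
    event and the times differ (ties in time are incomparable, as are
    pairs whose shorter time is censored). Concordant = higher risk for
    the shorter survivor; tied risks earn 0.5.
    """
    risks = np.asarray(risks, dtype=np.float64)
    if risks.shape != (len(surv),):
        raise ShapeError("one risk per record required")
    t, e = surv.time, surv.event
    # usable[i, j]: i is the earlier subject, had an event, t_i < t_j
    usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise AdsccaError("no comparable pairs: C-index undefined")
    diff = risks[:, None] - risks[None, :]
    concordant = float((usable & (diff > 0)).sum())
    tied = float((usable & (diff == 0)).sum())
    return (concordant + 0.5 * tied) / n_pairs


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate over distinct event times."""

    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.survival = np.asarray(self.survival, dtype=np.float64)
        self.at_risk = np.asarray(self.at_risk, dtype=np.int64)
        if np.any(self.survival < -1e-12) or np.any(self.survival > 1 + 1e-12):
            raise AdsccaError("survival probabilities outside [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise AdsccaError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time": self.time, "survival": self.survival,
                             "at_risk": self.at_risk})


def km_curve(surv: SurvivalData) -> KMCurve:
    """Kaplan–Meier estimator (lifelines backend), reported on the grid
    of distinct event times."""
    if len(surv) == 0:
        raise InvalidConfigError("need at least one record")
    from lifelines import KaplanMeierFitter
    event_times = np.unique(surv.time[surv.event == 1])
    if event_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([], dtype=int))
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    s = np.array([float(kmf.survival_function_at_times(t).iloc[0])
                  for t in event_times])
    at_risk = np.array([(surv.time >= t).sum() for t in event_times])
    return KMCurve(event_times, s, at_risk)


def dichotomize_median(risks: np.ndarray) -> list[str]:
    """Median split of predicted risks: strictly above the median →
    "high", at or below → "low" (ties deterministically low)."""
    risks = np.asarray(risks, dtype=np.float64)
    if risks.size < 2:
        raise InvalidConfigError("need ≥ 2 samples to dichotomize")
    med = float(np.median(risks))
    labels = ["high" if r > med else "low" for r in risks]
    if all(l == "low" for l in labels):
        warnings.warn("all risks at or below the median: single group")
    return labels


# ---------------------------------------------------------------------------
# Log-rank


def logrank_test(surv_a: SurvivalData, surv_b: SurvivalData
                 ) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df, hypergeometric variance)."""
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise InvalidConfigError("both groups must be non-empty")
    if surv_a.n_events + surv_b.n_events == 0:
        warnings.warn("no events in either group: log-rank undefined")
        return 0.0, 1.0
    from lifelines.statistics import logrank_test as ll_logrank
    res = ll_logrank(surv_a.time, surv_b.time,
                     event_observed_A=surv_a.event,
                     event_observed_B=surv_b.event)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


# ---------------------------------------------------------------------------
# Univariate Cox


@dataclass
class CoxFit:
    """One-covariate proportional-hazards fit (Breslow ties)."""

    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    se: float
    flagged: bool = False


def _cox_derivatives(beta: float, x: np.ndarray, t: np.ndarray,
                     e: np.ndarray) -> tuple[float, float, float]:
    """(log-likelihood, gradient, hessian) of the Breslow partial
    likelihood for a single covariate."""
    ll = grad = hess = 0.0
    w = np.exp(beta * x)
    for i in np.flatnonzero(e == 1):
        in_set = t >= t[i]
        s0 = w[in_set].sum()
        s1 = (w[in_set] * x[in_set]).sum()
        s2 = (w[in_set] * x[in_set] ** 2).sum()
        ll += beta * x[i] - np.log(s0)
        grad += x[i] - s1 / s0
        hess -= s2 / s0 - (s1 / s0) ** 2
    return ll, grad, hess


def cox_univariate(covariate: np.ndarray, surv: SurvivalData,
                   max_iter: int = 50, tol: float = 1e-10) -> CoxFit:
    """Newton maximization of the 1-D Breslow partial likelihood.

    Monotone likelihood (e.g. perfect separation) is flagged and returns
    a ±inf confidence interval rather than a silently huge estimate; a
    constant covariate returns the flagged null fit.
    """
    x = np.asarray(covariate, dtype=np.float64)
    if x.shape != (len(surv),):
        raise ShapeError("one covariate value per record required")
    if not np.isfinite(x).all():
        raise InvalidConfigError("covariate must be finite")
    if surv.n_events < 2:
        raise InvalidConfigError("need ≥ 2 events for a Cox fit")
    if np.ptp(x) == 0:
        warnings.warn("constant covariate: no information, returning null fit")
        return CoxFit(0.0, 1.0, 0.0, np.inf, 1.0, np.inf, flagged=True)
    t, e = surv.time, surv.event
    # scale-normalize so separation thresholds are unit-free
    scale = x.std()
    xs = x / scale
    beta = 0.0
    for _ in range(max_iter):
        _, grad, hess = _cox_derivatives(beta, xs, t, e)
        if hess > -1e-8 or abs(beta) > 15:
            warnings.warn("monotone partial likelihood: estimate flagged")
            return CoxFit(beta / scale, np.exp(beta / scale), 0.0, np.inf,
                          np.nan, np.inf, flagged=True)
        step = grad / (-hess)
        beta += np.clip(step, -5.0, 5.0)
        if abs(grad) < tol:
            break
    _, grad, hess = _cox_derivatives(beta, xs, t, e)
    if abs(beta) > 15 or hess > -1e-8:
        warnings.warn("monotone partial likelihood: estimate flagged")
        return CoxFit(beta / scale, np.exp(beta / scale), 0.0, np.inf,
                      np.nan, np.inf, flagged=True)
    beta = beta / scale
    se = 1.0 / np.sqrt(-hess) / scale
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(beta=float(beta), hr=float(np.exp(beta)),
                  ci_low=float(np.exp(beta - 1.96 * se)),
                  ci_high=float(np.exp(beta + 1.96 * se)),
                  p=float(p), se=float(se))


# ---------------------------------------------------------------------------
# Paired comparisons


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float],
                         alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value: exact enumeration for ≤ 25
    nonzero differences, normal approximation with continuity correction
    beyond."""
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero")
        return 1.0
    if nz.size < 5:
        raise InvalidConfigError(
            "need ≥ 5 nonzero differences for the signed-rank test")
    method = "exact" if nz.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                             alternative=alternative, method=method)
    except ValueError:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                             alternative=alternative, method="approx")
    return float(res.pvalue)


def bonferroni(p_values: Sequence[float] | float, m: int):
    """Family-wise adjustment p_adj = min(1, m·p)."""
    if m < 1:
        raise InvalidConfigError("m must be ≥ 1")
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim > 0 and m < p.size:
        raise InvalidConfigError("m must be at least the number of tests")
    adj = np.minimum(1.0, m * p)
    return float(adj) if adj.ndim == 0 else adj


def cohens_d(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Paired-design effect size: mean(diff) / sd(diff). A zero sd is
    flagged with a warning and returns 0."""
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError("paired samples must have equal length")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences: Cohen's d undefined, "
                      "returning 0")
        return 0.0
    return float(d.mean() / sd)


# ---------------------------------------------------------------------------
# Fold-level report


@dataclass
class EvalReport:
    """Per-fold evaluation bundle used by the cross-validation harness."""

    c_index: float
    logrank_stat: float
    logrank_p: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    groups: list[str]

    def to_dict(self) -> dict:
        return {"c_index": self.c_index, "logrank_stat": self.logrank_stat,
                "logrank_p": self.logrank_p, "hr": self.hr,
                "hr_ci_low": self.hr_ci_low, "hr_ci_high": self.hr_ci_high}


def evaluate_risks(risks: np.ndarray, surv: SurvivalData) -> EvalReport:
    """C-index plus median-dichotomized log-rank and hazard ratio (the
    high/low group indicator fed to a univariate Cox fit)."""
    c = concordance_index(risks, surv)
    groups = dichotomize_median(risks)
    indicator = np.array([1.0 if g == "high" else 0.0 for g in groups])
    high = [s for s, g in zip(surv.sample_ids, groups) if g == "high"]
    low = [s for s, g in zip(surv.sample_ids, groups) if g == "low"]
    if high and low:
        stat, p = logrank_test(surv.subset(high), surv.subset(low))
        fit = cox_univariate(indicator, surv)
        hr, lo_ci, hi_ci = fit.hr, fit.ci_low, fit.ci_high
    else:
        stat, p, hr, lo_ci, hi_ci = 0.0, 1.0, 1.0, 0.0, np.inf
    return EvalReport(c_index=float(c), logrank_stat=float(stat),
                      logrank_p=float(p), hr=float(hr),
                      hr_ci_low=float(lo_ci), hr_ci_high=float(hi_ci),
                      groups=groups)
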