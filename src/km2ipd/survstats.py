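"""Time-to-event estimators for (reconstructed or simulated) IPD.

Implements the product-limit (Kaplan-Meier) estimator with Greenwood
variance, median survival with complementary-log-log confidence bands, the
two-sample log-rank test, a Cox proportional-hazards fit for a multi-level
treatment factor (Efron tie handling, via lifelines), and the restricted
mean survival time (RMST) with its standard variance.

Conventions fixed here and relied on by the reconstruction module:

* survival curves are right-continuous step functions, S(t) = 1 before the
  first event time;
* subjects censored at an event time leave the risk set *after* the events
  at that time;
* CI quantiles use the exact normal quantile (1.959964 for 95%, 1.644854
  for 90%), with rounding only at presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import ExtrapolationError, InsufficientDataError, ValidationError


@dataclass
class KMEstimate:
    """Kaplan-Meier step-function estimate for one arm.

    Arrays are aligned on the distinct event times: ``surv[j]`` is the
    estimate just after ``event_times[j]``, ``var_greenwood[j]`` its
    Greenwood variance, ``n_risk_at[j]``/``n_events_at[j]`` the risk-set
    size and event count at that time.
    """

    event_times: np.ndarray
    surv: np.ndarray
    var_greenwood: np.ndarray
    n_risk_at: np.ndarray
    n_events_at: np.ndarray
    n_total: int
    max_time: float
    arm: Optional[str] = None

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the right-continuous step function at times ``t``."""
        t = np.asarray(t, dtype=float)
        steps = np.concatenate([[1.0], self.surv])
        return steps[np.searchsorted(self.event_times, t, side="right")]

    @property
    def greenwood_terms(self) -> np.ndarray:
        """d_j / (n_j (n_j - d_j)) per event time, 0 where n_j == d_j."""
        n = self.n_risk_at.astype(float)
        d = self.n_events_at.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(n > d, d / (n * (n - d)), 0.0)
        return term


@dataclass
class RMSTResult:
    """Restricted mean survival time on [0, tau], in event-free months."""

    tau: float
    estimate: float
    se: float
    ci: tuple[float, float]
    arm: Optional[str] = None


@dataclass
class CoxResult:
    """Treatment-factor Cox fit: per-arm log-HRs vs the reference arm."""

    reference_arm: str
    arms: list[str]  # non-reference arms, fit order
    coef: dict[str, float]
    se: dict[str, float]
    hr: dict[str, float]
    ci: dict[str, tuple[float, float]]
    ci_level: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    wald_stat: float
    wald_p: float
    log_likelihood: float
    cov: pd.DataFrame

    def _coef_full(self, arm: str) -> float:
        if arm == self.reference_arm:
            return 0.0
        if arm not in self.coef:
            raise ValidationError(f"arm {arm!r} not in fitted model")
        return self.coef[arm]

    def hr_between(self, arm_a: str, arm_b: str) -> float:
        """Hazard ratio of ``arm_a`` vs ``arm_b`` from the one fitted model."""
        return float(np.exp(self._coef_full(arm_a) - self._coef_full(arm_b)))

    def hr_between_ci(self, arm_a: str, arm_b: str) -> tuple[float, float]:
        """CI (at ``ci_level``) for the pairwise hazard ratio."""
        diff = self._coef_full(arm_a) - self._coef_full(arm_b)
        var = 0.0
        for x, sx in ((arm_a, 1.0), (arm_b, -1.0)):
            for y, sy in ((arm_a, 1.0), (arm_b, -1.0)):
                if x != self.reference_arm and y != self.reference_arm:
                    var += sx * sy * float(self.cov.loc[x, y])
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        half = z * np.sqrt(max(var, 0.0))
        return float(np.exp(diff - half)), float(np.exp(diff + half))


def kaplan_meier(ipd: pd.DataFrame, arm: Optional[str] = None) -> KMEstimate:
    """Product-limit estimate from an IPD table (optionally one arm of it)."""
    df = ipd if arm is None else ipd[ipd["arm"] == arm]
    if arm is not None and len(df) == 0:
        raise ValidationError(f"arm {arm!r} absent from IPD")
    if len(df) == 0:
        raise InsufficientDataError("empty dataset")
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    n_total = len(times)
    sorted_times = np.sort(times)

    ut = np.unique(times[events == 1])
    # at risk at t = number of subjects with observed time >= t
    n_at = n_total - np.searchsorted(sorted_times, ut, side="left")
    d_at = np.array([(times[events == 1] == t).sum() for t in ut], dtype=int)

    if len(ut):
        frac = 1.0 - d_at / n_at
        surv = np.cumprod(frac)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(n_at > d_at, d_at / (n_at * (n_at - d_at).astype(float)), 0.0)
        var = surv**2 * np.cumsum(terms)
    else:
        surv = np.array([])
        var = np.array([])

    return KMEstimate(
        event_times=ut,
        surv=surv,
        var_greenwood=var,
        n_risk_at=n_at,
        n_events_at=d_at,
        n_total=n_total,
        max_time=float(times.max()),
        arm=arm if arm is not None else (df["arm"].iloc[0] if df["arm"].nunique() == 1 else None),
    )


def median_survival(km: KMEstimate, level: float = 0.95):
    """Median survival time with a complementary-log-log band CI.

    Returns ``(median, (lower, upper))``; ``nan`` encodes "not reached".
    The CI bounds are the first times at which the lower/upper cll
    confidence band for S(t) drops to 0.5.
    """
    t, S = km.event_times, km.surv
    median = float(t[S <= 0.5][0]) if np.any(S <= 0.5) else float("nan")
    if len(t) == 0:
        return median, (float("nan"), float("nan"))

    z = stats.norm.ppf(0.5 + level / 2)
    cum = np.cumsum(km.greenwood_terms)
    lower = np.empty_like(S)
    upper = np.empty_like(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, s in enumerate(S):
            if s <= 0.0:
                lower[i] = upper[i] = 0.0
            elif s >= 1.0:
                lower[i] = upper[i] = 1.0
            else:
                se_cll = np.sqrt(cum[i]) / abs(np.log(s))
                lower[i] = s ** np.exp(z * se_cll)
                upper[i] = s ** np.exp(-z * se_cll)
    lo = float(t[lower <= 0.5][0]) if np.any(lower <= 0.5) else float("nan")
    hi = float(t[upper <= 0.5][0]) if np.any(upper <= 0.5) else float("nan")
    return median, (lo, hi)


def logrank(ipd: pd.DataFrame, arm_a: str, arm_b: str) -> tuple[float, float]:
    """Two-sample log-rank test between ``arm_a`` and ``arm_b``.

    Returns ``(chi_square, p)`` with p from chi-square(1).
    """
    for a in (arm_a, arm_b):
        if not (ipd["arm"] == a).any():
            raise ValidationError(f"arm {a!r} absent from IPD")
    da = ipd[ipd["arm"] == arm_a]
    db = ipd[ipd["arm"] == arm_b]
    res = _ll_logrank(
        da["time"], db["time"],
        event_observed_A=da["event"], event_observed_B=db["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    ipd: pd.DataFrame,
    reference_arm: str,
    ci_level: float = 0.95,
    strata: bool = False,
) -> CoxResult:
    """Cox proportional-hazards fit of the treatment factor.

    Non-reference arms enter as indicator covariates; ties use the Efron
    correction. ``strata=True`` stratifies the baseline hazard by
    ``trial_id``. Reports Wald and likelihood-ratio statistics against the
    null (no treatment effect) model on ``n_arms - 1`` df.
    """
    arms = sorted(ipd["arm"].unique())
    if reference_arm not in arms:
        raise ValidationError(f"reference arm {reference_arm!r} absent from IPD")
    if len(arms) < 2:
        raise ValidationError("need at least 2 arms")
    if int(ipd["event"].sum()) == 0:
        raise ValidationError("no events in dataset: Cox model has no information")
    others = [a for a in arms if a != reference_arm]

    df = pd.DataFrame({"time": ipd["time"].to_numpy(float), "event": ipd["event"].to_numpy(int)})
    for a in others:
        df[a] = (ipd["arm"] == a).to_numpy(int)
    fit_kwargs = {}
    if strata:
        if ipd["trial_id"].nunique() < 2:
            raise ValidationError("stratified fit needs >= 2 trials")
        df["trial_id"] = ipd["trial_id"].to_numpy()
        fit_kwargs["strata"] = ["trial_id"]

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event", **fit_kwargs)

    beta = cph.params_.reindex(others)
    se = cph.standard_errors_.reindex(others)
    cov = cph.variance_matrix_.loc[others, others]
    z = stats.norm.ppf(0.5 + ci_level / 2)
    ci = {a: (float(np.exp(beta[a] - z * se[a])), float(np.exp(beta[a] + z * se[a]))) for a in others}

    lrt = cph.log_likelihood_ratio_test()
    b = beta.to_numpy()
    wald_stat = float(b @ np.linalg.solve(cov.to_numpy(), b))
    k = len(others)

    return CoxResult(
        reference_arm=reference_arm,
        arms=others,
        coef={a: float(beta[a]) for a in others},
        se={a: float(se[a]) for a in others},
        hr={a: float(np.exp(beta[a])) for a in others},
        ci=ci,
        ci_level=ci_level,
        lrt_stat=float(lrt.test_statistic),
        lrt_df=k,
        lrt_p=float(lrt.p_value),
        wald_stat=wald_stat,
        wald_p=float(stats.chi2.sf(wald_stat, k)),
        log_likelihood=float(cph.log_likelihood_),
        cov=cov,
    )


def rmst(km: KMEstimate, tau: float, ci_level: float = 0.95) -> RMSTResult:
    """Restricted mean survival time: area under S(t) on [0, tau].

    Variance is the usual sum over event times t_j <= tau of
    (area from t_j to tau)^2 * d_j / (n_j (n_j - d_j)); the CI is
    normal-theory. Raises if tau exceeds the observed follow-up — the step
    function is not extrapolated.
    """
    if tau > km.max_time + 1e-12:
        raise ExtrapolationError(
            f"tau={tau} exceeds last observed time {km.max_time}; refusing to extrapolate"
        )
    keep = km.event_times <= tau
    t = km.event_times[keep]
    S = km.surv[keep]
    terms = km.greenwood_terms[keep]

    tt = np.concatenate([[0.0], t, [tau]])
    ss = np.concatenate([[1.0], S])
    widths = np.diff(tt)
    seg_area = ss * widths
    estimate = float(seg_area.sum())
    # area from each event time t_j to tau
    rev = np.cumsum(seg_area[::-1])[::-1]
    area_after = rev[1:] if len(t) else np.array([])
    var = float(np.sum(area_after**2 * terms))
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return RMSTResult(
        tau=float(tau), estimate=estimate, se=se,
        ci=(estimate - z * se, estimate + z * se), arm=km.arm,
    )
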