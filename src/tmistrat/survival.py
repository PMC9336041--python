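"""Two-group time-to-event machinery.

Kaplan-Meier curves and medians come from lifelines. The two-sample log-rank
observed/expected bookkeeping is computed here in vectorised numpy because it
is the inner loop of every cut-off scan and because the Mantel-Haenszel
hazard ratio needs the per-group O/E counts directly:

    HR = (O_a / E_a) / (O_b / E_b),   var(log HR) ~ 1/E_a + 1/E_b

which is the estimator classically produced by the GraphPad-Prism style
log-rank workflow. A univariable Cox proportional-hazards fit (lifelines,
Efron ties) is available as an alternative via ``method='cox'``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "GroupComparison",
    "km_estimate",
    "km_median",
    "logrank_test",
    "hazard_ratio",
    "compare_groups",
]

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class SurvivalSample:
    """Parallel arrays of follow-up times (months) and event indicators."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        if times.shape != events.shape or times.ndim != 1:
            raise ValueError("times and events must be parallel 1-d arrays")
        if len(times) == 0:
            raise ValueError("survival sample is empty")
        if np.any(times < 0) or np.any(~np.isfinite(times)):
            raise ValueError("survival times must be finite and non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit step function with risk-set bookkeeping."""

    times: np.ndarray       # distinct observed times (events and censorings)
    survival: np.ndarray    # S(t) at each time
    at_risk: np.ndarray     # number at risk just before each time
    n_events: np.ndarray    # events at each time

    def survival_at(self, t: float) -> float:
        """S(t); S(0) = 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass(frozen=True)
class GroupComparison:
    """Bundle of the low-vs-high style two-group survival comparison."""

    n_a: int
    n_b: int
    median_a: float  # months; inf when the curve never reaches 0.5
    median_b: float
    chi_square: float
    p_value: float
    hr: float        # group A vs group B
    hr_ci_low: float
    hr_ci_high: float
    method: str

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "hr": self.hr,
            "hr_ci_low": self.hr_ci_low,
            "hr_ci_high": self.hr_ci_high,
            "method": self.method,
        }

    def to_row(self) -> str:
        d = self.to_dict()
        return "\t".join(_fmt(d[k]) for k in d)


def _fmt(v) -> str:
    if isinstance(v, float):
        return "undefined" if math.isinf(v) else f"{v:.6g}"
    return str(v)


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survivor function."""
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, event_observed=sample.events)
    table = kmf.event_table.drop(index=0.0, errors="ignore")
    times = table.index.to_numpy(dtype=float)
    surv = (
        kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy(dtype=float)
    )
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
    )


def km_median(curve: KMCurve) -> float:
    """Smallest time with S(t) <= 0.5; ``inf`` when never reached ("undefined")."""
    hit = np.flatnonzero(curve.survival <= 0.5 + 1e-12)
    return float(curve.times[hit[0]]) if hit.size else math.inf


def _logrank_counts(
    times: np.ndarray, events: np.ndarray, group_a: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Pooled-risk-set O/E/V for the two-sample log-rank statistic.

    Returns (O_a, E_a, O_b, E_b, V) using the standard hypergeometric
    variance with ties handled by the d_j (N_j - d_j) / (N_j - 1) factor.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = group_a[order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_risk = (n - starts).astype(float)
    ga_suffix = np.r_[np.cumsum(g[::-1])[::-1], 0.0]
    na_risk = ga_suffix[starts]
    d = np.add.reduceat(e.astype(float), starts)
    da = np.add.reduceat((e & g).astype(float), starts)
    m = d > 0
    nr, nar, dd, dda = n_risk[m], na_risk[m], d[m], da[m]
    frac = nar / nr
    e_a = dd * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = dd * frac * (1.0 - frac) * (nr - dd) / (nr - 1.0)
    v[nr <= 1.0] = 0.0
    O_a = float(dda.sum())
    E_a = float(e_a.sum())
    D = float(dd.sum())
    return O_a, E_a, D - O_a, D - E_a, float(v.sum())


def logrank_test(a: SurvivalSample, b: SurvivalSample) -> tuple[float, float]:
    """Two-sample log-rank test: (chi_square, p) with 1 df.

    Symmetric under group swap. If neither group has any event the statistic
    is 0 and p is 1 (with a warning).
    """
    if a.n_events + b.n_events == 0:
        warnings.warn("log-rank test with no events in either group", stacklevel=2)
        return 0.0, 1.0
    times = np.concatenate([a.times, b.times])
    events = np.concatenate([a.events, b.events])
    group = np.r_[np.ones(a.n, dtype=bool), np.zeros(b.n, dtype=bool)]
    O_a, E_a, _, _, V = _logrank_counts(times, events, group)
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O_a - E_a) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hazard_ratio(
    a: SurvivalSample, b: SurvivalSample, method: str = "mantel_haenszel"
) -> tuple[float, float, float]:
    """Hazard ratio of group A relative to group B with a 95% CI.

    ``mantel_haenszel`` (default) uses the log-rank O/E counts; ``cox`` fits
    a univariable proportional-hazards model with a Wald interval. A group
    with zero expected events yields (nan, nan, nan) with a warning.
    """
    if a.n_events + b.n_events == 0:
        raise ValueError("hazard ratio requires at least one event")
    if method == "cox":
        df = pd.DataFrame(
            {
                "time": np.concatenate([a.times, b.times]),
                "event": np.concatenate([a.events, b.events]).astype(int),
                "group_a": np.r_[np.ones(a.n), np.zeros(b.n)],
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        summ = cph.summary.loc["group_a"]
        return (
            float(summ["exp(coef)"]),
            float(summ["exp(coef) lower 95%"]),
            float(summ["exp(coef) upper 95%"]),
        )
    if method != "mantel_haenszel":
        raise ValueError(f"unknown HR method {method!r}")
    times = np.concatenate([a.times, b.times])
    events = np.concatenate([a.events, b.events])
    group = np.r_[np.ones(a.n, dtype=bool), np.zeros(b.n, dtype=bool)]
    O_a, E_a, O_b, E_b, _ = _logrank_counts(times, events, group)
    if E_a <= 0 or E_b <= 0:
        warnings.warn("zero expected events in a group; HR undefined", stacklevel=2)
        return math.nan, math.nan, math.nan
    hr = (O_a / E_a) / (O_b / E_b) if O_b > 0 else math.inf
    if O_a == 0:
        hr = 0.0
    se = math.sqrt(1.0 / E_a + 1.0 / E_b)
    if hr in (0.0, math.inf) or not math.isfinite(hr):
        warnings.warn("zero observed events in a group; HR CI degenerate", stacklevel=2)
        return hr, 0.0, math.inf
    log_hr = math.log(hr)
    return hr, math.exp(log_hr - Z975 * se), math.exp(log_hr + Z975 * se)


def compare_groups(
    cohort,
    labels,
    endpoint: str = "os",
    method: str = "mantel_haenszel",
) -> GroupComparison:
    """Compare group A (labels True) vs group B (labels False) on one endpoint.

    ``labels`` may be a boolean array aligned to the cohort's clinical index
    or a pandas Series indexed by patient_id. Bundles the KM medians, the
    log-rank test and the hazard ratio into one :class:`GroupComparison`.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(cohort.clinical.index)
        if labels.isna().any():
            raise ValueError("labels do not cover every patient in the cohort")
        labels = labels.to_numpy(dtype=bool)
    else:
        labels = np.asarray(labels, dtype=bool)
        if len(labels) != cohort.n_patients:
            raise ValueError("labels length does not match cohort size")
    times, events = cohort.survival(endpoint)
    if labels.all():
        raise ValueError("group B is empty")
    if not labels.any():
        raise ValueError("group A is empty")
    a = SurvivalSample(times[labels], events[labels])
    b = SurvivalSample(times[~labels], events[~labels])
    chi2, p = logrank_test(a, b)
    hr, lo, hi = hazard_ratio(a, b, method=method)
    return GroupComparison(
        n_a=a.n,
        n_b=b.n,
        median_a=km_median(km_estimate(a)),
        median_b=km_median(km_estimate(b)),
        chi_square=chi2,
        p_value=p,
        hr=hr,
        hr_ci_low=lo,
        hr_ci_high=hi,
        method=method,
    )
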