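"""Responder-prediction and subgroup evaluation utilities.

ROC curves use the full threshold sweep (scikit-learn) with a DeLong-style
rank-based large-sample variance for the AUC confidence interval and the
null test of AUC = 0.5. Subgroup hazard-ratio tables reuse the two-group
survival comparison; burden-by-response uses the classical unpaired t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort import SUBGROUPS, Cohort, filter_cohort
from .survival import compare_groups

__all__ = [
    "ROCResult",
    "roc_auc",
    "define_outcome",
    "subgroup_hr_table",
    "burden_by_response",
    "efficacy_summary",
]

SUBGROUP_ORDER = (
    "all",
    "male",
    "female",
    "smoker",
    "non_smoker",
    "LUSC",
    "non_LUSC",
    "driver_positive",
    "driver_negative",
    "met_lt3",
    "met_ge3",
)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_null: float
    n_pos: int
    n_neg: int
    curve: np.ndarray          # ordered (1 - specificity, sensitivity) pairs
    orientation: str           # which score direction predicts the positive class

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["fpr", "tpr"])


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative score samples."""
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # placements of positives among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placements of negatives among positives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc_auc(scores, outcome) -> ROCResult:
    """ROC/AUC of a continuous score against a binary outcome.

    The orientation is chosen so that the reported AUC is >= 0.5 ("higher
    score predicts positive" or its reverse); the applied orientation is
    recorded on the result. CI and the null test of AUC = 0.5 use the
    DeLong rank-based variance.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(int)
    if scores.shape != y.shape:
        raise ValueError("scores and outcome must be parallel arrays")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    auc0, _ = _delong_auc_variance(scores[y == 1], scores[y == 0])
    if auc0 >= 0.5:
        oriented, orientation = scores, "higher_predicts_positive"
    else:
        oriented, orientation = -scores, "lower_predicts_positive"
    auc, var = _delong_auc_variance(oriented[y == 1], oriented[y == 0])
    se = np.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p_null = float(2.0 * stats.norm.sf(abs(z)))
        ci_low, ci_high = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    else:  # degenerate: perfect separation or constant scores
        p_null = 1.0 if np.isclose(auc, 0.5) else 0.0
        ci_low = ci_high = auc
    fpr, tpr, _ = roc_curve(y, oriented, drop_intermediate=False)
    return ROCResult(
        auc=float(auc),
        ci_low=float(np.clip(ci_low, 0.0, 1.0)),
        ci_high=float(np.clip(ci_high, 0.0, 1.0)),
        p_null=p_null,
        n_pos=n_pos,
        n_neg=n_neg,
        curve=np.column_stack([fpr, tpr]),
        orientation=orientation,
    )


def define_outcome(
    cohort: Cohort, endpoint: str = "os", landmark_months: float = 12.0
) -> tuple[pd.Series, pd.Index]:
    """Landmark survival outcome: positive = alive/event-free at the landmark.

    Patients censored before the landmark are excluded (returned separately),
    never imputed. Errors if every patient is excluded.
    """
    if landmark_months <= 0:
        raise ValueError("landmark must be positive")
    times, events = cohort.survival(endpoint)
    t = pd.Series(times, index=cohort.patient_ids)
    e = pd.Series(events, index=cohort.patient_ids)
    positive = t >= landmark_months
    excluded = (~positive) & (~e)  # censored before the landmark
    included = ~excluded
    if not included.any():
        raise ValueError("landmark excludes every patient")
    return positive[included].astype(int), cohort.patient_ids[excluded]


def subgroup_hr_table(
    cohort: Cohort, labels: pd.Series, endpoint: str = "os", min_per_group: int = 10
) -> pd.DataFrame:
    """Low-vs-high HR per clinical subgroup (plus the 'all' row).

    Subgroups where either label group has fewer than ``min_per_group``
    patients are flagged rather than computed.
    """
    if not isinstance(labels, pd.Series):
        labels = pd.Series(np.asarray(labels, dtype=bool), index=cohort.patient_ids)
    rows = []
    for name in SUBGROUP_ORDER:
        sub = cohort if name == "all" else filter_cohort(cohort, subgroup=name)
        n = sub.n_patients
        sub_labels = labels.reindex(sub.patient_ids)
        n_a = int(sub_labels.sum()) if n else 0
        n_b = n - n_a
        if min(n_a, n_b) < min_per_group:
            rows.append(
                {
                    "subgroup": name, "n": n, "n_a": n_a, "n_b": n_b,
                    "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p": np.nan, "flag": "too_small",
                }
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gc = compare_groups(sub, sub_labels, endpoint=endpoint)
        rows.append(
            {
                "subgroup": name, "n": n, "n_a": gc.n_a, "n_b": gc.n_b,
                "hr": gc.hr, "ci_low": gc.hr_ci_low, "ci_high": gc.hr_ci_high,
                "p": gc.p_value, "flag": "",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    flag: str = ""


def burden_by_response(burden_values, labels) -> TTestResult:
    """Unpaired two-sample t test of a burden between label groups (A=True)."""
    v = np.asarray(burden_values, dtype=float)
    g = np.asarray(labels, dtype=bool)
    a, b = v[g], v[~g]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both label groups must be non-empty")
    flag = ""
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, 1.0, float(a.mean()), float(b.mean()),
                               len(a), len(b), flag="zero_variance")
        flag = "zero_variance"
    if len(a) < 2 or len(b) < 2:
        warnings.warn("t test with a single patient in a group", stacklevel=2)
        flag = (flag + ";" if flag else "") + "df_degenerate"
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(p):
        p = 1.0
    return TTestResult(float(t), float(p), float(a.mean()), float(b.mean()),
                       len(a), len(b), flag=flag)


def efficacy_summary(cohort: Cohort, labels: pd.Series) -> pd.DataFrame:
    """Best-response counts and rates per label group.

    Rates are over evaluable patients (CR/PR/SD/PD); NE and unknown are
    counted and reported but excluded from the rate denominator.
    """
    if not isinstance(labels, pd.Series):
        labels = pd.Series(np.asarray(labels), index=cohort.patient_ids)
    resp = cohort.clinical["best_response"]
    if not resp.isin(RESPONSE_CATEGORIES).any():
        raise ValueError("no patient has a best_response assessment")
    rows = []
    for group in sorted(labels.unique(), key=str):
        members = resp[labels == group]
        counts = members.value_counts()
        evaluable = int(counts.reindex(["CR", "PR", "SD", "PD"]).fillna(0).sum())
        row = {"group": group, "n": len(members), "evaluable": evaluable,
               "unknown": int(counts.get("unknown", 0))}
        for cat in RESPONSE_CATEGORIES:
            c = int(counts.get(cat, 0))
            row[cat] = c
            if cat != "NE":
                row[f"{cat}_rate"] = c / evaluable if evaluable else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
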