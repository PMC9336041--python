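"""Optimal biomarker cut-offs by exhaustive log-rank p-value minimisation.

Two stratification shapes are supported:

* ``single`` — responders are ``value <= c1`` (low burden benefits, the
  chemotherapy-style rule);
* ``dual`` — responders are ``value <= c1 OR value > c2`` (U-shaped benefit,
  the immunotherapy-style rule where both tails of the burden distribution
  outperform the middle band).

Candidates are the distinct observed biomarker values; a split is admissible
only when both groups keep at least ``min_group_frac`` of the patients, which
prevents degenerate argmins in the extreme tails. Ties on the minimal p are
broken deterministically: larger responder group first, then smaller c1
(then smaller c2). No multiplicity correction is applied to the scan minimum
— the selected p is an optimistic, selection-biased quantity (see
docs/methods.md); ``permutation_adjusted_p`` offers a resampling correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survival import _logrank_counts
from scipy import stats

__all__ = [
    "BiomarkerCutoff",
    "CutpointScanner",
    "scan_single_cutoff",
    "scan_dual_cutoff",
    "label_responders",
    "permutation_adjusted_p",
    "PUBLISHED_CUTOFFS",
]

#: Cut-offs published for the deposited OAK/POPLAR data, shipped as fixture
#: constants for external reproduction runs (not used by any fit).
#: Keys: (arm, trial, biomarker, endpoint) -> c1 or (c1, c2).
PUBLISHED_CUTOFFS = {
    ("docetaxel", "oak", "btmb", "os"): 10,
    ("docetaxel", "oak", "sbtmb", "os"): 9,
    ("docetaxel", "oak", "ums", "os"): 9,
    ("docetaxel", "poplar", "btmb", "pfs"): 5,
    ("docetaxel", "poplar", "sbtmb", "os"): 4,
    ("atezolizumab", "oak", "btmb", "os"): (7, 20),
    ("atezolizumab", "oak", "sbtmb", "os"): (4, 17),
    ("atezolizumab", "oak", "ums", "os"): 3,
    ("atezolizumab", "poplar", "btmb", "os"): 3,
    ("atezolizumab", "poplar", "sbtmb", "os"): (4, 12),
}


@dataclass(frozen=True)
class BiomarkerCutoff:
    """A fitted stratification rule with its scan diagnostics."""

    biomarker: str
    shape: str                     # 'single' or 'dual'
    c1: float
    c2: float | None
    responder_rule: str
    p_min: float
    endpoint: str
    # (c1, c2, chi_square, p, n_responders) per admissible candidate
    scan_trace: tuple = field(repr=False, default=())

    def label(self, values) -> np.ndarray:
        """Apply the responder rule verbatim: True = predicted responder."""
        v = np.asarray(values, dtype=float)
        if self.shape == "single":
            return v <= self.c1
        return (v <= self.c1) | (v > self.c2)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.scan_trace),
            columns=["c1", "c2", "chi_square", "p", "n_responders"],
        )

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "shape": self.shape,
            "c1": self.c1,
            "c2": self.c2,
            "responder_rule": self.responder_rule,
            "p_min": self.p_min,
            "endpoint": self.endpoint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiomarkerCutoff":
        return cls(scan_trace=(), **d)


def _logrank_chi2_p(times, events, group_a) -> tuple[float, float]:
    O_a, E_a, _, _, V = _logrank_counts(times, events, group_a)
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O_a - E_a) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _check_survival(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times/events must be parallel 1-d arrays")
    return times, events


def _pick(rows: list[tuple]) -> tuple:
    """Deterministic argmin over (c1, c2, chi2, p, n_resp) candidate rows.

    Minimal p — selected as maximal chi-square, which is strictly monotone in
    p at 1 df and does not underflow where tiny p values would collapse to
    0.0 — with ties broken by larger responder group, then smaller c1, then
    smaller c2. Exact chi-square ties occur precisely when two cut-offs
    induce the same patient split.
    """
    return min(
        rows,
        key=lambda r: (
            -r[2],
            -r[4],
            r[0],
            r[1] if r[1] is not None else math.inf,
        ),
    )


def _scan_single(values, times, events, min_group_frac):
    n = len(values)
    floor = max(1, int(math.ceil(min_group_frac * n)))
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("biomarker is constant; no admissible cut-off")
    rows = []
    for c in distinct:
        g = values <= c
        n_resp = int(g.sum())
        if n_resp < floor or n - n_resp < floor:
            continue
        chi2, p = _logrank_chi2_p(times, events, g)
        rows.append((float(c), None, chi2, p, n_resp))
    if not rows:
        raise ValueError(
            "no admissible single cut-off under the group-size floor "
            f"(min_group_frac={min_group_frac})"
        )
    return _pick(rows), rows


def _scan_dual(values, times, events, min_group_frac):
    n = len(values)
    floor = max(1, int(math.ceil(min_group_frac * n)))
    distinct = np.unique(values)
    if distinct.size < 3:
        raise ValueError("dual cut-off scan needs at least 3 distinct values")
    # Precompute per-patient membership of (<= c) for each distinct value.
    le_counts = np.searchsorted(np.sort(values), distinct, side="right")
    rows = []
    for i, c1 in enumerate(distinct[:-1]):
        le_c1 = values <= c1
        for j in range(i + 1, distinct.size):
            c2 = distinct[j]
            g = le_c1 | (values > c2)
            n_resp = int(le_counts[i] + (n - le_counts[j]))
            if n_resp < floor or n - n_resp < floor:
                continue
            chi2, p = _logrank_chi2_p(times, events, g)
            rows.append((float(c1), float(c2), chi2, p, n_resp))
    if not rows:
        raise ValueError(
            "no admissible dual cut-off pair under the group-size floor "
            f"(min_group_frac={min_group_frac})"
        )
    return _pick(rows), rows


class CutpointScanner(BaseEstimator):
    """Exhaustive log-rank cut-off search as a scikit-learn style estimator.

    Parameters
    ----------
    shape : 'single' or 'dual'
        Stratification shape (threshold vs U-shaped low-or-high rule).
    min_group_frac : float in (0, 0.5)
        Minimum fraction of patients each side of the split must keep.
    biomarker, endpoint : str
        Metadata recorded on the fitted :class:`BiomarkerCutoff`.

    Attributes (after ``fit``)
    --------------------------
    cutoff_ : BiomarkerCutoff
    p_min_ : float
    scan_trace_ : list of (c1, c2, p, n_responders)
    """

    def __init__(
        self,
        shape: str = "single",
        min_group_frac: float = 0.10,
        biomarker: str = "biomarker",
        endpoint: str = "os",
    ):
        self.shape = shape
        self.min_group_frac = min_group_frac
        self.biomarker = biomarker
        self.endpoint = endpoint

    def fit(self, X, y):
        """Fit on biomarker values X (n,) or (n, 1) and survival y.

        ``y`` is (times, events) — a 2-tuple, an (n, 2) array with columns
        (time, event), or a structured array with 'time'/'event' fields.
        """
        if self.shape not in ("single", "dual"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0.0 < self.min_group_frac < 0.5:
            raise ValueError("min_group_frac must lie in (0, 0.5)")
        values = np.asarray(X, dtype=float).reshape(len(X) if np.ndim(X) else 1, -1)
        if values.shape[1] != 1:
            raise ValueError("X must be a single biomarker column")
        values = values[:, 0]
        times, events = _unpack_survival_y(y)
        if len(times) != len(values):
            raise ValueError("X and y have different lengths")
        if self.shape == "single":
            (c1, _, _, p, _), trace = _scan_single(
                values, times, events, self.min_group_frac
            )
            rule = f"value <= {c1:g}"
            c2 = None
        else:
            (c1, c2, _, p, _), trace = _scan_dual(
                values, times, events, self.min_group_frac
            )
            rule = f"value <= {c1:g} OR value > {c2:g}"
        self.cutoff_ = BiomarkerCutoff(
            biomarker=self.biomarker,
            shape=self.shape,
            c1=c1,
            c2=c2,
            responder_rule=rule,
            p_min=p,
            endpoint=self.endpoint,
            scan_trace=tuple(trace),
        )
        self.p_min_ = p
        self.scan_trace_ = trace
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("CutpointScanner is not fitted")
        values = np.asarray(X, dtype=float).reshape(len(X), -1)[:, 0]
        return self.cutoff_.label(values)


def _unpack_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, tuple) and len(y) == 2:
        return _check_survival(*y)
    arr = np.asarray(y)
    if arr.dtype.names:  # structured (scikit-survival style)
        names = {n.lower(): n for n in arr.dtype.names}
        return _check_survival(arr[names["time"]], arr[names["event"]])
    if arr.ndim == 2 and arr.shape[1] == 2:
        return _check_survival(arr[:, 0], arr[:, 1].astype(bool))
    raise ValueError("y must be (times, events), an (n,2) array, or structured")


def scan_single_cutoff(
    values, cohort, endpoint: str = "os", min_group_frac: float = 0.10
) -> BiomarkerCutoff:
    """Single-threshold scan over a cohort endpoint (thin estimator wrapper)."""
    values = _align_values(values, cohort)
    times, events = cohort.survival(endpoint)
    est = CutpointScanner(
        shape="single", min_group_frac=min_group_frac, endpoint=endpoint,
        biomarker=_biomarker_name(values),
    )
    return est.fit(np.asarray(values, float), (times, events)).cutoff_


def scan_dual_cutoff(
    values, cohort, endpoint: str = "os", min_group_frac: float = 0.10
) -> BiomarkerCutoff:
    """Dual (U-shaped) scan over a cohort endpoint (thin estimator wrapper)."""
    values = _align_values(values, cohort)
    times, events = cohort.survival(endpoint)
    est = CutpointScanner(
        shape="dual", min_group_frac=min_group_frac, endpoint=endpoint,
        biomarker=_biomarker_name(values),
    )
    return est.fit(np.asarray(values, float), (times, events)).cutoff_


def _align_values(values, cohort):
    if isinstance(values, pd.Series):
        aligned = values.reindex(cohort.patient_ids)
        if aligned.isna().any():
            raise ValueError("biomarker values do not cover every patient")
        return aligned
    if len(values) != cohort.n_patients:
        raise ValueError("biomarker values length does not match cohort size")
    return values


def _biomarker_name(values) -> str:
    return values.name if isinstance(values, pd.Series) and values.name else "biomarker"


def label_responders(values, cutoff: BiomarkerCutoff):
    """Apply a fitted rule to biomarker values; True = predicted responder."""
    labels = cutoff.label(np.asarray(values, dtype=float))
    if isinstance(values, pd.Series):
        return pd.Series(labels, index=values.index, name="responder")
    return labels


def permutation_adjusted_p(
    values,
    times,
    events,
    shape: str = "single",
    min_group_frac: float = 0.10,
    n_permutations: int = 200,
    rng=None,
) -> float:
    """Selection-bias-corrected p for a scan minimum by survival permutation.

    Re-runs the scan on cohorts whose (time, event) pairs are permuted
    against the biomarker, and reports the fraction of permutation minima at
    or below the observed minimum (with the +1 continuity correction).
    """
    rng = np.random.default_rng(rng)
    values = np.asarray(values, dtype=float)
    times, events = _check_survival(times, events)
    scan = _scan_single if shape == "single" else _scan_dual
    (_, _, chi2_obs, _, _), _ = scan(values, times, events, min_group_frac)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(times))
        (_, _, chi2_perm, _, _), _ = scan(values, times[perm], events[perm], min_group_frac)
        hits += chi2_perm >= chi2_obs
    return (hits + 1) / (n_permutations + 1)
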