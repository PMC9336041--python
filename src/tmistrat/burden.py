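"""Mutation-class burden scores and the unfavourable mutation score (UMS).

* bTMB counts a patient's ctDNA mutation rows whose effect class is
  missense, synonymous, splice or nonsense.
* sbTMB restricts the count to missense and splice.
* UMS sums, over the distinct "unfavourable" genes a patient carries, a
  1-5 score assigned by binning each gene's carrier-vs-non-carrier survival
  screening p-value (log-rank, one arm, OS by default). Genes qualify when
  p < 0.3 and the carrier hazard ratio exceeds 1 (unfavourable direction).

Per-gene screening p-values are deliberately not multiplicity-adjusted; the
score is a descriptive ranking device, not an inference (see docs/methods.md).
"""

from __future__ import annotations

import numbers
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .survival import SurvivalSample, hazard_ratio, logrank_test

__all__ = [
    "BTMB_EFFECTS",
    "SBTMB_EFFECTS",
    "compute_burdens",
    "score_from_p",
    "screen_unfavourable_genes",
    "compute_ums",
    "UnfavourableGeneScreen",
]

BTMB_EFFECTS = frozenset({"missense", "synonymous", "splice", "nonsense"})
SBTMB_EFFECTS = frozenset({"missense", "splice"})

# Left-closed p-value bins -> scores 5..1; p >= 0.3 falls outside the window.
_P_BIN_EDGES = np.array([0.05, 0.10, 0.15, 0.20, 0.30])
_P_BIN_SCORES = np.array([5, 4, 3, 2, 1, 0])

GENE_TABLE_COLUMNS = ("gene", "carriers", "p_value", "carrier_hr", "score")


def compute_burdens(cohort: Cohort, count_rows: bool = True) -> pd.DataFrame:
    """Per-patient bTMB and sbTMB counts, indexed by patient_id.

    Counts mutation rows by default; ``count_rows=False`` counts distinct
    (gene, effect-class) instead, for panels where multiple calls per gene
    should collapse.
    """
    muts = cohort.mutations
    if not count_rows:
        muts = muts.drop_duplicates(subset=["patient_id", "gene", "effect"])
    btmb = (
        muts[muts["effect"].isin(BTMB_EFFECTS)]
        .groupby("patient_id")
        .size()
        .reindex(cohort.patient_ids, fill_value=0)
    )
    sbtmb = (
        muts[muts["effect"].isin(SBTMB_EFFECTS)]
        .groupby("patient_id")
        .size()
        .reindex(cohort.patient_ids, fill_value=0)
    )
    return pd.DataFrame({"btmb": btmb.astype(int), "sbtmb": sbtmb.astype(int)})


def score_from_p(p) -> int | np.ndarray:
    """Map a screening p-value onto the 5..1 score (0 = outside the window).

    Bins are left-closed: [0, 0.05) -> 5, [0.05, 0.10) -> 4, [0.10, 0.15) -> 3,
    [0.15, 0.20) -> 2, [0.20, 0.30) -> 1, [0.30, 1] -> 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError("p-value must lie in [0, 1]")
    scores = _P_BIN_SCORES[np.digitize(arr, _P_BIN_EDGES, right=False)]
    if isinstance(p, numbers.Number):
        return int(scores)
    return scores


def screen_unfavourable_genes(
    cohort: Cohort,
    endpoint: str = "os",
    min_carriers: int = 3,
    p_window: float = 0.30,
) -> pd.DataFrame:
    """Per-gene carrier-vs-non-carrier survival screening within one arm.

    Every gene with at least ``min_carriers`` carriers is tested by log-rank
    on ``endpoint``; genes are retained when p < ``p_window`` and the carrier
    Mantel-Haenszel HR exceeds 1. Returns a frame with columns
    (gene, carriers, p_value, carrier_hr, score) sorted by p-value.
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    arms = cohort.clinical["arm"].unique()
    if len(arms) > 1:
        raise ValueError("gene screening requires a single-arm cohort")
    times, events = cohort.survival(endpoint)
    pid_pos = pd.Series(np.arange(cohort.n_patients), index=cohort.patient_ids)

    carriers_by_gene = cohort.mutations.drop_duplicates(
        subset=["patient_id", "gene"]
    ).groupby("gene")["patient_id"]

    rows = []
    for gene, pids in carriers_by_gene:
        idx = pid_pos[pids].to_numpy()
        n_car = len(idx)
        if n_car < min_carriers or n_car > cohort.n_patients - 1:
            continue
        mask = np.zeros(cohort.n_patients, dtype=bool)
        mask[idx] = True
        a = SurvivalSample(times[mask], events[mask])
        b = SurvivalSample(times[~mask], events[~mask])
        if a.n_events + b.n_events == 0:
            continue
        _, p = logrank_test(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hr, _, _ = hazard_ratio(a, b, method="mantel_haenszel")
        if p < p_window and np.isfinite(hr) and hr > 1.0:
            rows.append((gene, n_car, p, hr, score_from_p(p)))

    table = pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS))
    if table.empty:
        warnings.warn("gene screening retained no gene", stacklevel=2)
        return table
    return table.sort_values(["p_value", "gene"]).reset_index(drop=True)


def compute_ums(cohort: Cohort, table: pd.DataFrame) -> pd.Series:
    """Per-patient UMS: sum of the scores of the distinct retained genes carried.

    Carrying a retained gene more than once counts once; patients carrying no
    retained gene score 0.
    """
    ums = pd.Series(0, index=cohort.patient_ids, dtype=int, name="ums")
    if table.empty:
        return ums
    scores = table.set_index("gene")["score"]
    carried = cohort.mutations[cohort.mutations["gene"].isin(scores.index)]
    per_patient = (
        carried.drop_duplicates(subset=["patient_id", "gene"])
        .assign(score=lambda d: d["gene"].map(scores))
        .groupby("patient_id")["score"]
        .sum()
    )
    ums.update(per_patient.astype(int))
    return ums.astype(int)


class UnfavourableGeneScreen(BaseEstimator):
    """Estimator wrapper: fit the unfavourable-gene table, transform to UMS.

    Parameters
    ----------
    endpoint : 'os' or 'pfs'
        Survival endpoint driving the per-gene screening.
    min_carriers : int
        Genes with fewer carriers are not tested (degenerate log-rank groups).
    p_window : float
        Upper p-value limit of the screening window.
    """

    def __init__(self, endpoint: str = "os", min_carriers: int = 3, p_window: float = 0.30):
        self.endpoint = endpoint
        self.min_carriers = min_carriers
        self.p_window = p_window

    def fit(self, cohort: Cohort, y=None):
        self.table_ = screen_unfavourable_genes(
            cohort,
            endpoint=self.endpoint,
            min_carriers=self.min_carriers,
            p_window=self.p_window,
        )
        return self

    def transform(self, cohort: Cohort) -> pd.Series:
        if not hasattr(self, "table_"):
            raise RuntimeError("UnfavourableGeneScreen is not fitted")
        return compute_ums(cohort, self.table_)

    def fit_transform(self, cohort: Cohort, y=None) -> pd.Series:
        return self.fit(cohort).transform(cohort)
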