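"""The composite tumour mutation index (TMI).

The TMI integrates three ctDNA burden biomarkers (bTMB, sbTMB, UMS) with five
clinical characteristics (sex, smoking history, histology, driver-gene
status, metastasis-site count dichotomised at 3). Fitting on a discovery
cohort proceeds per (characteristic, stratum, biomarker) cell:

1. restrict the cohort to the stratum (e.g. males only);
2. scan the biomarker for its optimal cut-off by log-rank minimisation
   (single threshold, or dual low-or-high rule where the arm calls for it);
3. record the responder-vs-non-responder hazard ratio within the stratum.

A patient's TMI is then a sum over the 15 (characteristic x biomarker) pairs:
under the default ``hr_if_responder`` rule, each pair contributes the fitted
stratum HR when the patient satisfies that cell's responder rule, and 1.0
otherwise (also 1.0 when the characteristic level is unknown or the stratum
component was skipped for size). With predictive components the stratum HRs
sit below 1, so a lower TMI means a more favourable predicted outcome. The
median TMI of the discovery cohort is frozen as the low/high threshold
(ties go to low) and is never re-fit on validation cohorts.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .cutpoint import BiomarkerCutoff, CutpointScanner
from .survival import GroupComparison, SurvivalSample, compare_groups, hazard_ratio

__all__ = [
    "CHARACTERISTICS",
    "TMIComponent",
    "TMIModel",
    "TMIStratifier",
    "fit_tmi",
    "score_patients",
    "apply_tmi",
]

SCHEMA_VERSION = 1

#: characteristic -> (stratum levels). Metastasis sites dichotomise at <3 / >=3.
CHARACTERISTICS = {
    "sex": ("male", "female"),
    "smoking": ("smoker", "non_smoker"),
    "histology": ("LUSC", "non_LUSC"),
    "driver_gene": ("positive", "negative"),
    "metastases": ("lt3", "ge3"),
}

BIOMARKERS = ("btmb", "sbtmb", "ums")


def stratum_mask(clinical: pd.DataFrame, characteristic: str, stratum: str) -> pd.Series:
    """Boolean membership of a stratum; unknown levels belong to no stratum."""
    if characteristic == "metastases":
        mets = clinical["metastasis_sites"]
        if stratum == "lt3":
            return (mets < 3).fillna(False)
        if stratum == "ge3":
            return (mets >= 3).fillna(False)
        raise ValueError(f"unknown metastasis stratum {stratum!r}")
    return clinical[characteristic] == stratum


@dataclass(frozen=True)
class TMIComponent:
    """One fitted (characteristic, stratum, biomarker) cell of the model."""

    characteristic: str
    stratum: str
    biomarker: str
    cutoff: BiomarkerCutoff
    hr: float  # responder vs non-responder within the stratum

    def to_dict(self) -> dict:
        return {
            "characteristic": self.characteristic,
            "stratum": self.stratum,
            "biomarker": self.biomarker,
            "cutoff": self.cutoff.to_dict(),
            "hr": self.hr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TMIComponent":
        return cls(
            characteristic=d["characteristic"],
            stratum=d["stratum"],
            biomarker=d["biomarker"],
            cutoff=BiomarkerCutoff.from_dict(d["cutoff"]),
            hr=d["hr"],
        )


@dataclass(frozen=True)
class TMIModel:
    """Portable fitted TMI: components, score rule and frozen median threshold."""

    arm: str
    endpoint: str
    score_rule: str
    components: tuple
    skipped: tuple              # (characteristic, stratum, biomarker, reason)
    median_threshold: float

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "arm": self.arm,
            "endpoint": self.endpoint,
            "score_rule": self.score_rule,
            "median_threshold": self.median_threshold,
            "components": [c.to_dict() for c in self.components],
            "skipped": [list(s) for s in self.skipped],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TMIModel":
        d = json.loads(text)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported TMI model schema {d.get('schema_version')}")
        return cls(
            arm=d["arm"],
            endpoint=d["endpoint"],
            score_rule=d["score_rule"],
            components=tuple(TMIComponent.from_dict(c) for c in d["components"]),
            skipped=tuple(tuple(s) for s in d["skipped"]),
            median_threshold=d["median_threshold"],
        )

    def model_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _biomarker_frame(cohort: Cohort, burdens: pd.DataFrame, ums: pd.Series) -> pd.DataFrame:
    biom = pd.concat([burdens[["btmb", "sbtmb"]], ums.rename("ums")], axis=1)
    biom = biom.reindex(cohort.patient_ids)
    missing = biom.columns[biom.isna().any()].tolist()
    if missing:
        raise ValueError(f"biomarker value(s) missing for some patients: {missing}")
    return biom.astype(float)


def _component_contribution(
    model: TMIModel, clinical: pd.DataFrame, biom: pd.DataFrame
) -> pd.Series:
    """Sum the score rule over the 15 (characteristic x biomarker) pairs."""
    if model.score_rule != "hr_if_responder":
        raise ValueError(f"unknown score rule {model.score_rule!r}")
    total = pd.Series(0.0, index=clinical.index)
    by_cell = {
        (c.characteristic, c.stratum, c.biomarker): c for c in model.components
    }
    for characteristic, strata in CHARACTERISTICS.items():
        for biomarker in BIOMARKERS:
            contrib = pd.Series(1.0, index=clinical.index)  # neutral default
            for stratum in strata:
                comp = by_cell.get((characteristic, stratum, biomarker))
                if comp is None:
                    continue  # skipped stratum stays neutral
                members = stratum_mask(clinical, characteristic, stratum)
                responder = pd.Series(
                    comp.cutoff.label(biom[biomarker].to_numpy()),
                    index=clinical.index,
                )
                contrib[members & responder] = comp.hr
            total += contrib
    return total


def score_patients(
    model: TMIModel, cohort: Cohort, burdens: pd.DataFrame, ums: pd.Series
) -> pd.DataFrame:
    """Score every patient; returns columns (tmi, label) indexed by patient_id.

    ``label`` is 'low' when tmi <= the model's frozen median threshold.
    """
    biom = _biomarker_frame(cohort, burdens, ums)
    tmi = _component_contribution(model, cohort.clinical, biom)
    label = np.where(tmi <= model.median_threshold, "low", "high")
    return pd.DataFrame({"tmi": tmi, "label": label})


class TMIStratifier(BaseEstimator):
    """Fit/apply the composite TMI as a scikit-learn style estimator.

    Parameters
    ----------
    endpoint : 'os' or 'pfs'
        Endpoint driving the per-stratum scans and HRs (OS by default).
    shapes : dict or None
        Per-biomarker scan shape, e.g. ``{'btmb': 'dual', 'sbtmb': 'dual',
        'ums': 'single'}`` for the immunotherapy-style arm. Default: single
        for all three biomarkers.
    min_stratum_size : int
        Strata smaller than this are skipped (flagged, neutral contribution).
    min_group_frac : float
        Group-size floor forwarded to every cut-off scan.
    score_rule : str
        Patient scoring rule; ``hr_if_responder`` adds the stratum HR when
        the patient satisfies the cell's responder rule, else 1.0.
    hr_method : str
        'mantel_haenszel' (default) or 'cox' for the component HRs.

    Attributes (after ``fit``)
    --------------------------
    model_ : TMIModel
    components_ : tuple of TMIComponent
    median_threshold_ : float
    skipped_ : tuple of (characteristic, stratum, biomarker, reason)
    """

    def __init__(
        self,
        endpoint: str = "os",
        shapes: dict | None = None,
        min_stratum_size: int = 20,
        min_group_frac: float = 0.10,
        score_rule: str = "hr_if_responder",
        hr_method: str = "mantel_haenszel",
    ):
        self.endpoint = endpoint
        self.shapes = shapes
        self.min_stratum_size = min_stratum_size
        self.min_group_frac = min_group_frac
        self.score_rule = score_rule
        self.hr_method = hr_method

    def fit(self, cohort: Cohort, burdens: pd.DataFrame, ums: pd.Series):
        arms = cohort.clinical["arm"].unique()
        if len(arms) != 1:
            raise ValueError("TMI fitting requires a single-arm discovery cohort")
        arm = str(arms[0])
        shapes = dict.fromkeys(BIOMARKERS, "single")
        if self.shapes:
            unknown = set(self.shapes) - set(BIOMARKERS)
            if unknown:
                raise ValueError(f"unknown biomarker(s) in shapes: {sorted(unknown)}")
            shapes.update(self.shapes)
        biom = _biomarker_frame(cohort, burdens, ums)
        times, events = cohort.survival(self.endpoint)
        components: list[TMIComponent] = []
        skipped: list[tuple] = []
        for characteristic, strata in CHARACTERISTICS.items():
            for stratum in strata:
                members = stratum_mask(cohort.clinical, characteristic, stratum)
                m = members.to_numpy()
                for biomarker in BIOMARKERS:
                    if m.sum() < self.min_stratum_size:
                        skipped.append(
                            (characteristic, stratum, biomarker, "stratum_too_small")
                        )
                        continue
                    values = biom.loc[members, biomarker].to_numpy()
                    try:
                        scanner = CutpointScanner(
                            shape=shapes[biomarker],
                            min_group_frac=self.min_group_frac,
                            biomarker=biomarker,
                            endpoint=self.endpoint,
                        ).fit(values, (times[m], events[m]))
                    except ValueError as exc:
                        skipped.append((characteristic, stratum, biomarker, str(exc)))
                        continue
                    resp = scanner.cutoff_.label(values)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        hr, _, _ = hazard_ratio(
                            SurvivalSample(times[m][resp], events[m][resp]),
                            SurvivalSample(times[m][~resp], events[m][~resp]),
                            method=self.hr_method,
                        )
                    if not (np.isfinite(hr) and hr > 0):
                        skipped.append(
                            (characteristic, stratum, biomarker, "degenerate_hr")
                        )
                        continue
                    components.append(
                        TMIComponent(
                            characteristic=characteristic,
                            stratum=stratum,
                            biomarker=biomarker,
                            cutoff=scanner.cutoff_,
                            hr=float(hr),
                        )
                    )
        if not components:
            raise ValueError("every TMI component was skipped; cannot fit")
        provisional = TMIModel(
            arm=arm,
            endpoint=self.endpoint,
            score_rule=self.score_rule,
            components=tuple(components),
            skipped=tuple(skipped),
            median_threshold=math.nan,
        )
        tmi = _component_contribution(provisional, cohort.clinical, biom)
        self.model_ = TMIModel(
            arm=arm,
            endpoint=self.endpoint,
            score_rule=self.score_rule,
            components=tuple(components),
            skipped=tuple(skipped),
            median_threshold=float(np.median(tmi)),
        )
        self.components_ = self.model_.components
        self.median_threshold_ = self.model_.median_threshold
        self.skipped_ = self.model_.skipped
        return self

    def transform(
        self, cohort: Cohort, burdens: pd.DataFrame, ums: pd.Series
    ) -> pd.DataFrame:
        self._check_fitted()
        return score_patients(self.model_, cohort, burdens, ums)

    def predict(self, cohort: Cohort, burdens: pd.DataFrame, ums: pd.Series) -> pd.Series:
        return self.transform(cohort, burdens, ums)["label"]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("TMIStratifier is not fitted")


def fit_tmi(
    discovery: Cohort,
    burdens: pd.DataFrame,
    ums: pd.Series,
    shapes: dict | None = None,
    **kwargs,
) -> TMIModel:
    """Fit the TMI on a single-arm discovery cohort (thin estimator wrapper)."""
    return TMIStratifier(shapes=shapes, **kwargs).fit(discovery, burdens, ums).model_


def apply_tmi(
    model: TMIModel,
    cohort: Cohort,
    burdens: pd.DataFrame,
    ums: pd.Series,
    hr_method: str = "mantel_haenszel",
) -> tuple[pd.DataFrame, GroupComparison]:
    """Score a cohort with a FROZEN model and compare low vs high survival.

    The discovery median threshold is applied as-is (never re-fit). Errors if
    the cohort's arm does not match the model's, or a score group is empty.
    """
    if isinstance(model, TMIStratifier):
        model._check_fitted()
        model = model.model_
    arms = set(cohort.clinical["arm"].unique())
    if arms != {model.arm}:
        raise ValueError(
            f"cohort arm(s) {sorted(arms)} do not match model arm {model.arm!r}"
        )
    scores = score_patients(model, cohort, burdens, ums)
    low = scores["label"] == "low"
    comparison = compare_groups(cohort, low, endpoint=model.endpoint, method=hr_method)
    return scores, comparison
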