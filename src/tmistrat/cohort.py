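"""Cohort data model: per-patient clinical records joined to ctDNA mutation calls.

A :class:`Cohort` bundles two tables:

* ``clinical`` — one row per patient (trial arm, clinical characteristics and
  the OS/PFS endpoints), indexed by ``patient_id``;
* ``mutations`` — one row per somatic mutation call (``patient_id``, ``gene``,
  ``effect``), where ``effect`` is one of the five canonical classes
  missense / synonymous / splice / nonsense / other.

Readers accept plain tab-separated tables (the canonical dialect) and a
MAF-dialect convenience mapping. Unknown categorical labels degrade to
``unknown`` with a warning; they are never dropped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "CohortWarning",
    "EFFECTS",
    "ARMS",
    "DEFAULT_MAF_MAP",
    "SUBGROUPS",
    "read_mutations",
    "read_clinical",
    "build_cohort",
    "filter_cohort",
    "write_clinical",
    "write_mutations",
]


class CohortWarning(UserWarning):
    """Non-fatal data-quality issue found while reading or joining tables."""


EFFECTS = ("missense", "synonymous", "splice", "nonsense", "other")
ARMS = ("docetaxel", "atezolizumab")
SEX_LEVELS = ("male", "female", "unknown")
SMOKING_LEVELS = ("smoker", "non_smoker", "unknown")
HISTOLOGY_LEVELS = ("LUSC", "non_LUSC", "unknown")
DRIVER_LEVELS = ("positive", "negative", "unknown")
RESPONSE_LEVELS = ("CR", "PR", "SD", "PD", "NE", "unknown")

#: Variant_Classification -> effect class. Overridable via ``maf_map``.
DEFAULT_MAF_MAP: Mapping[str, str] = {
    "Missense_Mutation": "missense",
    "Silent": "synonymous",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Nonsense_Mutation": "nonsense",
}

MUTATION_COLUMNS = ("patient_id", "gene", "effect")
CLINICAL_COLUMNS = (
    "arm",
    "cohort",
    "sex",
    "smoking",
    "histology",
    "driver_gene",
    "metastasis_sites",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "best_response",
)
_REQUIRED_CLINICAL = ("patient_id", "arm", "os_months", "os_event")

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class Cohort:
    """Joined clinical + mutation tables for one or more trial arms.

    Invariants (enforced by :func:`build_cohort`): patient ids unique in
    ``clinical``; every mutation's patient id exists in ``clinical``. A
    patient with zero mutation rows is legal (burden 0).
    """

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    provenance: str = ""

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def patient_ids(self) -> pd.Index:
        return self.clinical.index

    def survival(self, endpoint: str = "os") -> tuple[np.ndarray, np.ndarray]:
        """Return (times, events) arrays for ``endpoint`` in {'os', 'pfs'}."""
        if endpoint not in ("os", "pfs"):
            raise ValueError(f"unknown endpoint {endpoint!r}; expected 'os' or 'pfs'")
        times = self.clinical[f"{endpoint}_months"].to_numpy(dtype=float)
        events = self.clinical[f"{endpoint}_event"].to_numpy(dtype=bool)
        return times, events

    def genes_by_patient(self) -> pd.Series:
        """Map patient_id -> set of distinct mutated genes (empty set if none)."""
        carried = self.mutations.groupby("patient_id")["gene"].agg(set)
        return carried.reindex(self.patient_ids).apply(
            lambda s: s if isinstance(s, set) else set()
        )


def _fold_categorical(series: pd.Series, levels: Iterable[str], column: str) -> pd.Series:
    """Case-insensitively map values onto ``levels``; off-vocabulary -> unknown."""
    lookup = {lvl.lower(): lvl for lvl in levels}
    raw = series.fillna("unknown").astype(str).str.strip()
    mapped = raw.str.lower().map(lookup)
    bad = mapped.isna()
    if bad.any():
        examples = sorted(raw[bad].unique())[:5]
        warnings.warn(
            f"column {column!r}: {int(bad.sum())} value(s) outside vocabulary "
            f"{tuple(levels)} set to 'unknown' (e.g. {examples})",
            CohortWarning,
            stacklevel=3,
        )
        mapped = mapped.fillna("unknown")
    return mapped


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    raw = series.astype(str).str.strip().str.lower()
    out = pd.Series(index=series.index, dtype=bool)
    ok_true = raw.isin(_TRUE)
    ok_false = raw.isin(_FALSE)
    if not (ok_true | ok_false).all():
        bad = sorted(raw[~(ok_true | ok_false)].unique())[:5]
        raise ValueError(f"column {column!r}: unparseable boolean value(s) {bad}")
    out[:] = ok_true
    return out


def read_mutations(
    path,
    dialect: str = "simple_tsv",
    maf_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a mutation table into the canonical (patient_id, gene, effect) frame.

    ``dialect='simple_tsv'`` expects columns patient_id, gene, effect;
    ``dialect='maf'`` expects Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification and maps classifications through ``maf_map``
    (default :data:`DEFAULT_MAF_MAP`); unmapped classes become ``other``.
    """
    if dialect not in ("simple_tsv", "maf"):
        raise ValueError(f"unknown mutation dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"empty mutation file {path}", CohortWarning, stacklevel=2)
        return pd.DataFrame(columns=list(MUTATION_COLUMNS))
    if dialect == "maf":
        required = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")
    else:
        required = MUTATION_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"mutation table missing required column {col!r}")
    if dialect == "maf":
        mapping = dict(DEFAULT_MAF_MAP if maf_map is None else maf_map)
        effect = df["Variant_Classification"].map(mapping).fillna("other")
        out = pd.DataFrame(
            {
                "patient_id": df["Tumor_Sample_Barcode"].astype(str),
                "gene": df["Hugo_Symbol"].astype(str),
                "effect": effect,
            }
        )
    else:
        out = df.loc[:, list(MUTATION_COLUMNS)].copy()
        known = out["effect"].str.lower().isin(EFFECTS)
        if not known.all():
            warnings.warn(
                f"{int((~known).sum())} mutation row(s) with unrecognised effect "
                "label mapped to 'other'",
                CohortWarning,
                stacklevel=2,
            )
        out["effect"] = out["effect"].str.lower().where(known, "other")
    if out.empty:
        warnings.warn(f"mutation file {path} has no rows", CohortWarning, stacklevel=2)
    if (out["gene"].fillna("") == "").any():
        raise ValueError("mutation table contains empty gene symbols")
    return out.reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table; returns a frame indexed by patient_id.

    Required columns: patient_id, arm, os_months, os_event. Optional
    categorical columns fall back to 'unknown'; missing optional numeric
    columns become NaN. Negative survival times and duplicate patient ids
    are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_CLINICAL:
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    pid = df["patient_id"].astype(str)
    if pid.duplicated().any():
        dups = sorted(pid[pid.duplicated()].unique())[:5]
        raise ValueError(f"duplicate patient_id(s) in clinical table: {dups}")

    out = pd.DataFrame(index=pd.Index(pid, name="patient_id"))

    def col_or_default(name: str, default=None) -> pd.Series:
        if name in df.columns:
            return df[name].set_axis(out.index)
        return pd.Series(default, index=out.index, dtype=object)

    out["arm"] = _fold_categorical(col_or_default("arm"), ARMS, "arm")
    if (out["arm"] == "unknown").any():
        raise ValueError("clinical table contains rows with unrecognised arm")
    out["cohort"] = (
        col_or_default("cohort", "unlabelled").fillna("unlabelled").astype(str)
    )
    out["sex"] = _fold_categorical(col_or_default("sex"), SEX_LEVELS, "sex")
    out["smoking"] = _fold_categorical(col_or_default("smoking"), SMOKING_LEVELS, "smoking")
    out["histology"] = _fold_categorical(
        col_or_default("histology"), HISTOLOGY_LEVELS, "histology"
    )
    out["driver_gene"] = _fold_categorical(
        col_or_default("driver_gene"), DRIVER_LEVELS, "driver_gene"
    )

    mets = pd.to_numeric(col_or_default("metastasis_sites"), errors="coerce")
    neg = mets < 0
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} negative metastasis_sites value(s) set to unknown",
            CohortWarning,
            stacklevel=2,
        )
        mets = mets.mask(neg)
    out["metastasis_sites"] = mets.astype(float)

    for ep in ("os", "pfs"):
        tcol, ecol = f"{ep}_months", f"{ep}_event"
        if tcol in df.columns:
            t = pd.to_numeric(df[tcol], errors="raise").set_axis(out.index).astype(float)
            if (t < 0).any():
                raise ValueError(f"negative {tcol} in clinical table")
            out[tcol] = t
            out[ecol] = _parse_bool(df[ecol].set_axis(out.index), ecol)
        else:
            warnings.warn(
                f"clinical table has no {tcol}; endpoint '{ep}' unavailable",
                CohortWarning,
                stacklevel=2,
            )
            out[tcol] = np.nan
            out[ecol] = False

    out["best_response"] = _fold_categorical(
        col_or_default("best_response"), RESPONSE_LEVELS, "best_response"
    )

    both = out["os_months"].notna() & out["pfs_months"].notna()
    viol = both & (out["pfs_months"] > out["os_months"])
    if viol.any():
        warnings.warn(
            f"{int(viol.sum())} patient(s) with pfs_months > os_months (kept as-is)",
            CohortWarning,
            stacklevel=2,
        )
    return out


def build_cohort(
    clinical: pd.DataFrame, mutations: pd.DataFrame, provenance: str = ""
) -> Cohort:
    """Join the two tables into a validated :class:`Cohort`.

    Mutations whose patient is absent from the clinical table are dropped
    with a counted warning; patients with zero mutation rows are retained.
    """
    if clinical.index.duplicated().any():
        raise ValueError("clinical table has duplicate patient ids")
    mutations = mutations.reset_index(drop=True)
    keep = mutations["patient_id"].isin(clinical.index)
    n_orphan = int((~keep).sum())
    if n_orphan:
        warnings.warn(
            f"dropped {n_orphan} mutation row(s) whose patient_id is not in the "
            "clinical table",
            CohortWarning,
            stacklevel=2,
        )
        mutations = mutations.loc[keep].reset_index(drop=True)
    return Cohort(clinical=clinical.copy(), mutations=mutations.copy(), provenance=provenance)


# Named subgroup selectors over the clinical frame. Unknown levels are
# excluded from the corresponding subgroup (they stratify nothing).
SUBGROUPS: Mapping[str, Callable[[pd.DataFrame], pd.Series]] = {
    "male": lambda c: c["sex"] == "male",
    "female": lambda c: c["sex"] == "female",
    "smoker": lambda c: c["smoking"] == "smoker",
    "non_smoker": lambda c: c["smoking"] == "non_smoker",
    "LUSC": lambda c: c["histology"] == "LUSC",
    "non_LUSC": lambda c: c["histology"] == "non_LUSC",
    "driver_positive": lambda c: c["driver_gene"] == "positive",
    "driver_negative": lambda c: c["driver_gene"] == "negative",
    "met_lt3": lambda c: c["metastasis_sites"] < 3,
    "met_ge3": lambda c: c["metastasis_sites"] >= 3,
}


def filter_cohort(
    cohort: Cohort,
    arm: str | None = None,
    subgroup: str | Callable[[pd.DataFrame], pd.Series] | None = None,
) -> Cohort:
    """Restrict a cohort to one trial arm and/or a named clinical subgroup.

    Mutations are restricted to retained patients. An empty result is legal
    (returned with a warning), never an error.
    """
    mask = pd.Series(True, index=cohort.clinical.index)
    if arm is not None:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
        mask &= cohort.clinical["arm"] == arm
    if subgroup is not None:
        selector = SUBGROUPS[subgroup] if isinstance(subgroup, str) else subgroup
        mask &= selector(cohort.clinical).fillna(False)
    clinical = cohort.clinical.loc[mask]
    if clinical.empty:
        warnings.warn("filter produced an empty cohort", CohortWarning, stacklevel=2)
    mutations = cohort.mutations[
        cohort.mutations["patient_id"].isin(clinical.index)
    ].reset_index(drop=True)
    return Cohort(clinical=clinical.copy(), mutations=mutations, provenance=cohort.provenance)


def write_clinical(cohort_or_frame, path) -> None:
    """Write the clinical table as canonical TSV (stable column order)."""
    frame = (
        cohort_or_frame.clinical
        if isinstance(cohort_or_frame, Cohort)
        else cohort_or_frame
    )
    frame = frame.reset_index()
    cols = ["patient_id"] + [c for c in CLINICAL_COLUMNS if c in frame.columns]
    out = frame.loc[:, cols].copy()
    for bcol in ("os_event", "pfs_event"):
        if bcol in out.columns:
            out[bcol] = out[bcol].astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_mutations(cohort_or_frame, path) -> None:
    frame = (
        cohort_or_frame.mutations
        if isinstance(cohort_or_frame, Cohort)
        else cohort_or_frame
    )
    frame.loc[:, list(MUTATION_COLUMNS)].to_csv(path, sep="\t", index=False)
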