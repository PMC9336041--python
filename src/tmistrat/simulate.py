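"""Seeded synthetic NSCLC trial cohorts with plantable biomarker effects.

The generator emulates the statistical structure the downstream analysis
assumes: overdispersed per-patient ctDNA mutation counts classified into the
five effect classes, clinical covariates at trial-like prevalences,
exponential (constant-baseline-hazard) overall survival with independent
exponential censoring, and progression-free survival as a faster companion
process bounded by death. Effects can be planted as

* a single burden threshold (hazard multiplied above c*),
* a U-shaped band (hazard multiplied inside (c1*, c2*]),
* unfavourable genes (carrier hazard multiplied, carriers at a set
  prevalence).

Every draw flows from one global seed through a documented stream-splitting
scheme (:data:`_STREAMS`), so adding a generator stage never perturbs
earlier draws and identical seeds yield byte-identical tables. The realised
ground truth is returned as a :class:`SimTruth` for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .burden import BTMB_EFFECTS, SBTMB_EFFECTS
from .cohort import Cohort, build_cohort

__all__ = [
    "PlantedCutoff",
    "PlantedUShape",
    "PlantedGene",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "make_fixture_suite",
    "tiny_cohort",
    "FIXTURE_SEEDS",
]

# Order of the child seed streams split from the global seed. New stages
# must be appended, never inserted.
_STREAMS = (
    "mutation_counts",
    "effects",
    "genes",
    "planted_genes",
    "covariates",
    "os_times",
    "censoring",
    "pfs_times",
    "response",
)

EFFECT_CLASSES = ("missense", "synonymous", "splice", "nonsense", "other")


@dataclass(frozen=True)
class PlantedCutoff:
    """Hazard multiplied by ``multiplier`` for patients with biomarker > cutoff."""

    biomarker: str
    cutoff: float
    multiplier: float


@dataclass(frozen=True)
class PlantedUShape:
    """Hazard multiplied inside the middle band c1 < biomarker <= c2."""

    biomarker: str
    c1: float
    c2: float
    middle_multiplier: float


@dataclass(frozen=True)
class PlantedGene:
    """Carriers (at ``prevalence``) of gene ``gene_index`` have hazard x multiplier."""

    gene_index: int
    multiplier: float
    prevalence: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated single-arm cohort.

    Defaults emulate a second-line NSCLC trial arm: ~60% male, ~80% smokers,
    ~25% squamous histology, ~17% driver-gene positive, roughly a third with
    3+ metastatic sites; median OS near 9 months (baseline hazard
    log(2)/9 per month) with light independent censoring; per-patient ctDNA
    mutation totals negative-binomial with mean 10 (matching burden cut-offs
    in the 5-20 range) and moderate overdispersion.
    """

    seed: int
    n_patients: int = 400
    n_genes: int = 150
    mutation_mean: float = 10.0
    mutation_dispersion: float = 2.5   # NB size parameter; smaller = more spread
    effect_probs: tuple = (0.55, 0.18, 0.07, 0.10, 0.10)  # per EFFECT_CLASSES
    covariate_prevalences: tuple = (   # (name, probability of the first level)
        ("male", 0.61),
        ("smoker", 0.81),
        ("lusc", 0.26),
        ("driver_positive", 0.17),
        ("met_ge3", 0.32),
    )
    baseline_hazard: float = math.log(2) / 9.0   # events per month
    censoring_rate: float = 0.02                 # independent, per month
    pfs_hazard_scale: float = 2.2                # PFS hazard multiple of OS hazard
    arm: str = "docetaxel"
    cohort_label: str = "discovery"
    planted_single_cutoff: PlantedCutoff | None = None
    planted_u_shape: PlantedUShape | None = None
    planted_unfavourable_genes: tuple = ()

    def __post_init__(self):
        probs = np.asarray(self.effect_probs, dtype=float)
        if probs.min() < 0 or probs.max() > 1 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("effect_probs must be probabilities summing to 1")
        if (
            self.planted_single_cutoff is not None
            and self.planted_u_shape is not None
            and self.planted_single_cutoff.biomarker == self.planted_u_shape.biomarker
        ):
            raise ValueError(
                "contradictory planted rules on biomarker "
                f"{self.planted_single_cutoff.biomarker!r}"
            )
        if self.planted_single_cutoff is not None and self.planted_single_cutoff.multiplier <= 0:
            raise ValueError("hazard multipliers must be positive")
        if self.planted_u_shape is not None and self.planted_u_shape.middle_multiplier <= 0:
            raise ValueError("hazard multipliers must be positive")
        for pg in self.planted_unfavourable_genes:
            if pg.multiplier <= 0 or not 0.0 <= pg.prevalence <= 1.0:
                raise ValueError("planted gene multiplier/prevalence out of range")


@dataclass(frozen=True)
class SimTruth:
    """Realised ground truth: planted parameters + per-patient latent state."""

    config: SimConfig
    per_patient: pd.DataFrame  # hazard, biomarkers, latent group memberships
    realised_prevalences: dict

    def to_json(self) -> str:
        cfg = asdict(self.config)
        return json.dumps(
            {"config": cfg, "realised_prevalences": self.realised_prevalences},
            indent=2,
            sort_keys=True,
            default=str,
        )


def _planted_gene_name(index: int) -> str:
    return f"G{index:03d}"


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Generate one cohort and its ground-truth record, reproducibly from seed."""
    n = config.n_patients
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            _STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
        )
    }
    patient_ids = [f"P{i:05d}" for i in range(n)]

    # --- mutations ---------------------------------------------------------
    r = config.mutation_dispersion
    p_nb = r / (r + config.mutation_mean)
    counts = streams["mutation_counts"].negative_binomial(r, p_nb, size=n)

    planted_idx = {pg.gene_index for pg in config.planted_unfavourable_genes}
    background_pool = np.array(
        [g for g in range(config.n_genes) if g not in planted_idx]
    )
    total_rows = int(counts.sum())
    gene_draw = streams["genes"].choice(background_pool, size=total_rows)
    effect_draw = streams["effects"].choice(
        EFFECT_CLASSES, size=total_rows, p=np.asarray(config.effect_probs)
    )
    mut_pid = np.repeat(patient_ids, counts)
    mutations = pd.DataFrame(
        {
            "patient_id": mut_pid,
            "gene": [_planted_gene_name(g) for g in gene_draw],
            "effect": effect_draw,
        }
    )

    carrier_flags = {}
    extra_rows = []
    rng_pg = streams["planted_genes"]
    for pg in config.planted_unfavourable_genes:
        flags = rng_pg.random(n) < pg.prevalence
        carrier_flags[pg.gene_index] = flags
        gene_name = _planted_gene_name(pg.gene_index)
        for pid in np.asarray(patient_ids)[flags]:
            extra_rows.append((pid, gene_name, "missense"))
    if extra_rows:
        mutations = pd.concat(
            [mutations, pd.DataFrame(extra_rows, columns=mutations.columns)],
            ignore_index=True,
        )
    mutations = mutations.sort_values(
        ["patient_id", "gene", "effect"], kind="stable"
    ).reset_index(drop=True)

    # realised burdens drive the planted burden effects
    btmb = (
        mutations[mutations["effect"].isin(BTMB_EFFECTS)]
        .groupby("patient_id").size().reindex(patient_ids, fill_value=0)
    )
    sbtmb = (
        mutations[mutations["effect"].isin(SBTMB_EFFECTS)]
        .groupby("patient_id").size().reindex(patient_ids, fill_value=0)
    )
    biomarkers = {"btmb": btmb.to_numpy(float), "sbtmb": sbtmb.to_numpy(float)}

    # --- covariates --------------------------------------------------------
    rng_cov = streams["covariates"]
    prev = dict(config.covariate_prevalences)
    male = rng_cov.random(n) < prev["male"]
    smoker = rng_cov.random(n) < prev["smoker"]
    lusc = rng_cov.random(n) < prev["lusc"]
    driver = rng_cov.random(n) < prev["driver_positive"]
    met_ge3 = rng_cov.random(n) < prev["met_ge3"]
    met_sites = np.where(
        met_ge3, rng_cov.integers(3, 6, size=n), rng_cov.integers(0, 3, size=n)
    )

    # --- hazards -----------------------------------------------------------
    log_mult = np.zeros(n)
    high_group = np.zeros(n, dtype=bool)
    middle_group = np.zeros(n, dtype=bool)
    if config.planted_single_cutoff is not None:
        pc = config.planted_single_cutoff
        high_group = biomarkers[pc.biomarker] > pc.cutoff
        log_mult += np.where(high_group, math.log(pc.multiplier), 0.0)
    if config.planted_u_shape is not None:
        pu = config.planted_u_shape
        v = biomarkers[pu.biomarker]
        middle_group = (v > pu.c1) & (v <= pu.c2)
        log_mult += np.where(middle_group, math.log(pu.middle_multiplier), 0.0)
    for pg in config.planted_unfavourable_genes:
        log_mult += np.where(carrier_flags[pg.gene_index], math.log(pg.multiplier), 0.0)
    hazard = config.baseline_hazard * np.exp(log_mult)

    # --- survival ----------------------------------------------------------
    os_latent = streams["os_times"].exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor = streams["censoring"].exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    os_months = np.minimum(os_latent, censor)
    os_event = os_latent <= censor
    prog_latent = streams["pfs_times"].exponential(
        1.0 / (hazard * config.pfs_hazard_scale)
    )
    pfs_latent = np.minimum(prog_latent, os_latent)  # progression or death
    pfs_months = np.minimum(pfs_latent, censor)
    pfs_event = pfs_latent <= censor

    # best response from the latent progression clock (RECIST-flavoured bands)
    rng_resp = streams["response"]
    response = np.select(
        [prog_latent < 2.0, prog_latent < 6.0, prog_latent < 12.0],
        ["PD", "SD", "PR"],
        default="CR",
    )
    response = np.where(rng_resp.random(n) < 0.05, "NE", response)

    clinical = pd.DataFrame(
        {
            "arm": config.arm,
            "cohort": config.cohort_label,
            "sex": np.where(male, "male", "female"),
            "smoking": np.where(smoker, "smoker", "non_smoker"),
            "histology": np.where(lusc, "LUSC", "non_LUSC"),
            "driver_gene": np.where(driver, "positive", "negative"),
            "metastasis_sites": met_sites.astype(float),
            "os_months": np.round(os_months, 4),
            "os_event": os_event,
            "pfs_months": np.round(pfs_months, 4),
            "pfs_event": pfs_event,
            "best_response": response,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )

    cohort = build_cohort(clinical, mutations, provenance=f"simulated(seed={config.seed})")

    per_patient = pd.DataFrame(
        {
            "hazard": hazard,
            "btmb": biomarkers["btmb"],
            "sbtmb": biomarkers["sbtmb"],
            "planted_high": high_group,
            "planted_middle": middle_group,
        },
        index=clinical.index,
    )
    for pg in config.planted_unfavourable_genes:
        per_patient[f"carrier_{_planted_gene_name(pg.gene_index)}"] = carrier_flags[
            pg.gene_index
        ]
    realised = {
        "event_rate_os": float(os_event.mean()),
        "mean_mutations": float(counts.mean()),
    }
    for pg in config.planted_unfavourable_genes:
        realised[f"prevalence_{_planted_gene_name(pg.gene_index)}"] = float(
            carrier_flags[pg.gene_index].mean()
        )
    truth = SimTruth(config=config, per_patient=per_patient, realised_prevalences=realised)
    return cohort, truth


#: Seeds of the standard named fixtures (documented, frozen).
FIXTURE_SEEDS = {
    "null": 101,
    "single_cutoff": 202,
    "u_shape": 303,
    "unfavourable_gene": 404,
}


def tiny_cohort() -> Cohort:
    """Six hand-checkable patients; burdens verifiable by eye.

    T1 carries one of each effect class (btmb 4, sbtmb 2); T2 has no
    mutations (burden 0); T3 has two missense rows in the same gene (btmb 2,
    sbtmb 2, one distinct gene); T4-T6 exercise the clinical vocabularies.
    """
    clinical = pd.DataFrame(
        {
            "arm": ["docetaxel"] * 6,
            "cohort": ["tiny"] * 6,
            "sex": ["male", "female", "male", "female", "male", "unknown"],
            "smoking": ["smoker", "non_smoker", "smoker", "smoker", "unknown", "smoker"],
            "histology": ["LUSC", "non_LUSC", "non_LUSC", "LUSC", "non_LUSC", "non_LUSC"],
            "driver_gene": ["negative", "positive", "negative", "unknown", "negative", "negative"],
            "metastasis_sites": [1.0, 3.0, 5.0, 0.0, 2.0, np.nan],
            "os_months": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
            "os_event": [True, True, True, True, False, True],
            "pfs_months": [1.0, 2.0, 2.0, 3.0, 5.0, 6.0],
            "pfs_event": [True, True, False, True, True, True],
            "best_response": ["PD", "SD", "PR", "SD", "PR", "NE"],
        },
        index=pd.Index([f"T{i}" for i in range(1, 7)], name="patient_id"),
    )
    mutations = pd.DataFrame(
        {
            "patient_id": ["T1", "T1", "T1", "T1", "T1", "T3", "T3", "T4", "T5", "T6"],
            "gene": ["TP53", "KRAS", "EGFR", "STK11", "KEAP1", "TP53", "TP53", "KRAS", "TP53", "EGFR"],
            "effect": [
                "missense", "synonymous", "splice", "nonsense", "other",
                "missense", "missense", "splice", "nonsense", "missense",
            ],
        }
    )
    return build_cohort(clinical, mutations, provenance="tiny-fixture")


def make_fixture_suite() -> dict[str, tuple[Cohort, SimTruth]]:
    """The standard named test cohorts, regenerated identically every call.

    * ``null`` — n=300, no planted effect (calibration).
    * ``single_cutoff`` — n=500, hazard x2.5 above btmb 10.
    * ``u_shape`` — n=600, hazard x2.5 inside the middle btmb band (6, 13].
    * ``unfavourable_gene`` — n=400, carriers of gene G007 (prevalence 0.3)
      at hazard x3.
    * ``tiny`` — the 6-patient hand-checkable cohort (truth is None).
    """
    suite: dict[str, tuple[Cohort, SimTruth | None]] = {}
    suite["null"] = simulate_cohort(SimConfig(seed=FIXTURE_SEEDS["null"], n_patients=300))
    suite["single_cutoff"] = simulate_cohort(
        SimConfig(
            seed=FIXTURE_SEEDS["single_cutoff"],
            n_patients=500,
            planted_single_cutoff=PlantedCutoff("btmb", 10, 2.5),
        )
    )
    suite["u_shape"] = simulate_cohort(
        SimConfig(
            seed=FIXTURE_SEEDS["u_shape"],
            n_patients=600,
            planted_u_shape=PlantedUShape("btmb", 6, 13, 2.5),
        )
    )
    suite["unfavourable_gene"] = simulate_cohort(
        SimConfig(
            seed=FIXTURE_SEEDS["unfavourable_gene"],
            n_patients=400,
            planted_unfavourable_genes=(PlantedGene(7, 3.0, 0.3),),
        )
    )
    suite["tiny"] = (tiny_cohort(), None)
    return suite
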