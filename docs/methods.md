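# Methods

`tmistrat` re-implements, as a tested and reusable pipeline, a family of
blood-ctDNA biomarkers for stratifying advanced NSCLC patients receiving
second-line docetaxel (chemotherapy) or atezolizumab (anti-PD-L1
immunotherapy) into predicted responders and non-responders on overall
survival, and a composite score — the tumour mutation index (TMI) — that
integrates the biomarkers with five clinical characteristics. This note
records the model, the interpretive choices made where the procedure was
genuinely open, the numerical conventions, what the synthetic-data generator
does and does not emulate, and the known statistical liberties.

## Burden biomarkers

Input is a per-patient table of somatic ctDNA mutation calls, each
classified as missense, synonymous, splice, nonsense or other (unknown
labels map to `other`, never dropped silently).

* **bTMB** (blood tumour mutation burden): count of a patient's mutation
  rows with effect in {missense, synonymous, splice, nonsense}.
* **sbTMB** (sensitive bTMB): the count restricted to {missense, splice}.

Counting is per mutation row, not per gene (a gene mutated twice contributes
twice); `compute_burdens(..., count_rows=False)` collapses repeated
(gene, class) calls for panels where that is preferable. `other` counts
toward neither burden, so sbTMB ≤ bTMB always.

## Unfavourable mutation score (UMS)

Within one trial arm, every gene with at least `min_carriers` carriers
(default 3, to avoid degenerate log-rank groups) is screened by a two-sample
log-rank test of carriers vs non-carriers on the chosen endpoint (OS by
default). A gene is retained as *unfavourable* when its screening p-value
falls in [0, 0.3) **and** the carrier Mantel-Haenszel hazard ratio exceeds 1.
The direction filter matters: the p-window alone would admit protective
genes. Retained genes receive a score by left-closed p-value bin:

| p-value bin | score |
|---|---|
| [0.00, 0.05) | 5 |
| [0.05, 0.10) | 4 |
| [0.10, 0.15) | 3 |
| [0.15, 0.20) | 2 |
| [0.20, 0.30) | 1 |
| [0.30, 1.00] | 0 (excluded) |

A patient's UMS is the **sum** of the scores of the distinct retained genes
they carry (carrying a gene twice counts once). Summation is an
interpretation: the source procedure says only that multi-gene patients are
scored "according to their p-values", but a sum is the only aggregation
consistent with published UMS cut-offs (e.g. ≤ 9) exceeding the maximum
single-gene score of 5.

Two deliberate statistical liberties, kept for fidelity to the original
procedure and flagged here: per-gene p-values are **not**
multiplicity-adjusted, and the screening endpoint's p-value is used for both
retention and scoring. The UMS is a descriptive ranking device, not an
inferential quantity. Crucially, the gene table is **part of the fitted
model**: a validation cohort's UMS is computed with the discovery table.
Re-screening on the validation cohort would select genes on that cohort's
own outcomes (the HR > 1 filter guarantees it) and bias any "independent"
validation toward success — in null simulations this leak alone pushed the
low/high hazard ratio visibly away from 1.

## Optimal cut-offs by log-rank minimisation

For each biomarker the stratification threshold is chosen by exhaustive
scan: candidates are the distinct observed values; for each admissible
candidate the two groups are compared by log-rank, and the cut-off with the
smallest p-value wins.

* **single** shape: responders are `value ≤ c1` (low burden benefits — the
  chemotherapy-style rule).
* **dual** shape: responders are `value ≤ c1 OR value > c2` (U-shaped
  benefit — the immunotherapy-style rule, where both burden tails outperform
  the middle band). The original two-step heuristic ("first cut-off, then
  the value after intersection") is under-specified; we search all pairs
  c1 < c2 exhaustively, which subsumes it. The published cut-offs for the
  deposited OAK/POPLAR data ship as constants (`PUBLISHED_CUTOFFS`) for
  external reproduction runs; no fit ever reads them.

Numerical conventions:

* **Group-size floor** `min_group_frac` (default 0.10): every admissible
  split must keep at least this fraction of patients on each side,
  preventing degenerate argmins in the extreme tails. The source procedure
  states no floor; this is a documented deviation knob.
* **Selection statistic**: the argmin of p is computed as the argmax of the
  log-rank chi-square, which is strictly monotone in p at 1 df and does not
  underflow where p itself collapses to 0 in double precision (p-values
  below ~1e-300, and ties below 1e-16, are routine on strong effects).
* **Tie-break** on exactly equal chi-square (which happens precisely when
  two cut-offs induce the same patient split): larger responder group, then
  smaller c1, then smaller c2. Deterministic.
* **No multiplicity correction** for the scan minimum: the reported p_min is
  an optimistic, selection-biased quantity, again faithful to the original
  workflow. `permutation_adjusted_p` provides a resampling correction for
  users who want an honest scan-level p.

## Survival machinery

Kaplan-Meier estimation and medians use lifelines; the median is the
smallest time with S(t) ≤ 0.5 and is `inf` ("undefined") when the curve
never reaches 0.5. The two-sample log-rank statistic uses the standard
pooled-risk-set observed/expected counts with the hypergeometric variance
(ties handled by the d(N−d)/(N−1) factor). The default hazard-ratio
estimator is **Mantel-Haenszel**, HR = (O_a/E_a)/(O_b/E_b) with
var(log HR) ≈ 1/E_a + 1/E_b — the estimator a GraphPad-Prism-style log-rank
workflow produces — with a univariable Cox fit (lifelines, Efron tie
handling) available via `method="cox"`. The two agree within ~15% on
proportional-hazards simulations at n ≥ 500 (asserted in tests). The O/E/V
computation is implemented in-package (vectorised numpy) because the MH
estimator needs the per-group counts and the scans call it thousands of
times per fit; lifelines' log-rank is the independent cross-check in the
test suite, never the scan backend.

At n ≤ 10 the chi-square p is compared in tests against an exact permutation
oracle (all label assignments enumerated). The comparison point is the
permutation **mid-p** (half weight on ties at the observed statistic) with a
one-atom granularity allowance — the appropriate way to compare a continuous
approximation with a discrete exact distribution whose support has as few as
15 atoms. Observed agreement is within 0.1 + 1/#atoms on all tested
instances.

## The TMI model

Fitting runs on a single-arm discovery cohort over a 5 × 2 × 3 grid:
five clinical characteristics (sex, smoking history, histology LUSC vs
non-LUSC, driver-gene status, metastasis sites dichotomised at < 3 vs ≥ 3) ×
two strata each × three biomarkers (bTMB, sbTMB, UMS). Per cell: restrict to
the stratum, scan the biomarker for its optimal cut-off (single shape for
the docetaxel-style arm; dual permitted for bTMB/sbTMB on the
atezolizumab-style arm, UMS stays single), and record the
responder-vs-non-responder Mantel-Haenszel HR within the stratum. Strata
smaller than `min_stratum_size` (default 20) are skipped with a flag and
contribute neutrally.

A patient's TMI sums one term per (characteristic, biomarker) pair — 15
terms. Under the default `hr_if_responder` rule a term is the fitted stratum
HR when the patient is in that stratum and satisfies the cell's responder
rule, and 1.0 otherwise (non-responder, unknown characteristic level, or
skipped stratum). The rule is an interpretation — the source never prints
the "score of HR" formula — chosen because with predictive components
(HR < 1) it makes lower TMI mean better predicted outcome, matching every
published usage of the score; it is pluggable for alternatives. Patients are
labelled low/high at the **median TMI of the discovery cohort** (ties to
low, the convention every other cut-off uses), and that threshold — like the
components and the UMS gene table — is frozen: applying the model to a
validation cohort never re-fits anything (asserted via model hash).
Endpoint for component fitting is OS by default; PFS is an option.

## Evaluation

* **ROC/AUC**: full threshold sweep (scikit-learn), AUC with a DeLong-style
  rank-based large-sample variance for the 95% CI and the null test of
  AUC = 0.5. Orientation is chosen so the reported AUC is ≥ 0.5 and is
  recorded on the result.
* **Landmark outcome**: "responder" for ROC is not defined in the source;
  the default binary outcome is survival beyond a landmark (12 months by
  default, configurable); patients censored before the landmark are
  excluded, not imputed.
* **Subgroup HR table**: the ten clinical subgroups plus "all"; subgroups
  with fewer than 10 patients in either label group are flagged rather than
  computed.
* **Burden by response**: classical unpaired two-sample t test
  (equal-variance), with degenerate inputs flagged.
* **Efficacy summary**: best-response counts per label group with rates over
  evaluable (CR/PR/SD/PD) patients; NE and unknown counted separately.

## Synthetic cohorts

`simulate_cohort(SimConfig(...))` generates both tables plus a ground-truth
record. What it emulates: overdispersed per-patient mutation totals
(negative binomial, default mean 10 and size 2.5 — placing burden values in
the 0-35 range where the published cut-offs live), multinomial effect
classes (55/18/7/10/10% missense/synonymous/splice/nonsense/other),
trial-like covariate prevalences (61% male, 81% smokers, 26% LUSC, 17%
driver-positive, 32% with ≥ 3 metastatic sites), exponential OS with
baseline hazard log(2)/9 per month (median ≈ 9 months, second-line NSCLC
scale) under independent exponential censoring (0.02/month), and PFS as a
faster companion clock (hazard × 2.2) bounded by death. Plantable effects:
a burden threshold (hazard × m above c*), a U-shaped band (hazard × m inside
(c1, c2]), and unfavourable genes (carrier hazard × m at a set prevalence;
carrier status is exact by construction and excluded from the background
gene pool). One global seed drives a fixed stream-splitting scheme
(`_STREAMS`), so outputs are byte-identical across runs and adding a
generator stage cannot perturb earlier draws.

What it does **not** emulate — and hence what passing tests do not show
about real trial data: mutational signatures or panel footprints, variant
allele fractions and sequencing noise, correlation between covariates and
burden (independent by default so that component effects are attributable;
a correlation knob exists for stress tests), non-proportional hazards,
informative censoring, and cohort-to-cohort shift in the burden
distribution (the published cut-offs differ between trials; the generator
draws validation cohorts from the same process unless configured otherwise).

Problem sizes used throughout the tests and the acceptance script — 50
seeded cohorts of n = 500 for threshold recovery, n = 600 for the U-shape
and the end-to-end TMI fit, n = 300-400 for screening and calibration,
n = 2000 for the null AUC — are the package's chosen study conditions: large
enough that planted effects of the stated sizes are recoverable, small
enough to keep every check fast and reproducible.

## Known limitations

* The Mantel-Haenszel CI is a large-sample approximation; measured null
  coverage in our simulations is ≈ 96% at n = 200-300 per cohort.
* The scan minimum p is selection-biased (see above); downstream HRs for
  scan-derived groups inherit optimism on the discovery cohort. Frozen-model
  validation on fresh cohorts is the honest check, and the end-to-end
  simulations show the expected dilution there (fitted low-TMI HR ≈ 0.5 on
  discovery vs ≈ 0.66 on held-out cohorts when the true favourable
  multiplier is 0.5).
* UMS inherits every instability of unadjusted per-gene screening; with
  ~200 genes and no true signal, ~15% of screenable genes are retained by
  construction (asserted as a calibration property).
* The per-gene screening test is log-rank (the source does not state its
  test); the choice is exposed.
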