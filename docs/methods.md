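# Methods

This note documents the models and procedures implemented in `vkrpipe`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## 1. The vKR decision rule (`classifier`)

A knee-year at visit `t0` is evaluated from four patient-reported-outcome
visits: baseline (month 0), `t0−12`, `t0`, and `t0+12`. KOOS pain (KP) and
KOOS quality of life (QoL) are 0–100, higher = better. The composite score
is

    score = KP_t0 + 0.54 · max(QoL_t0, QoL_t−1)            (pain not worse)
    score = KP_t0 + 0.54 · max(QoL_t0, QoL_t−1)
            − 1.06 · |KP_t−1 − KP_t0|                       (pain worse)

with the worsening branch taken only when `KP_t0 < KP_t−1` strictly; equal
pain routes to the not-worse branch. Case status requires all of

1. `score < 95.7` (strict) — the published threshold, corresponding to a
   90 % specificity calibration against non-replaced knees;
2. `KP_t0` and `QoL_t0` strictly below their baseline values;
3. `KP_t0+12 ≤ KP_t0` and `QoL_t0+12 ≤ QoL_t0` (non-strict sustainment),

and is attributed to month `t0+12`. A knee-year with any required visit
absent is *not evaluable* and never a case — no imputation. A knee with a
surgical KR on or before `t0+12` is likewise not evaluable: replaced knees
are handled by the exclusion cascade, not by the classifier.

**Threshold calibration.** `calibrate_threshold` returns the lower
empirical `(1−specificity)`-quantile of the non-KR score sample, without
interpolation, so the achieved false-positive rate (scores strictly below
the cut) never exceeds the nominal rate and converges to it from below as
the sample grows. Lower score = higher predicted KR risk; the module treats
score rank as the risk rank throughout (the underlying probability model
behind the published constants is not re-derived — the constants are
inputs).

**72 M maintenance.** For knees first becoming cases at attributed month
60, `maintenance_status` re-applies the sustainment comparison one cycle
on: vKR+/+ iff `KP_72 ≤ KP_60` and `QoL_72 ≤ QoL_60`. Whether the original
definition additionally re-checks the score threshold at 60 M is not
specified in the source material; this package deliberately applies only
the sustainment comparison and isolates the choice in one function.

## 2. Selection and matching (`selection`)

The exclusion cascade applies, in order: surgical KR before 12 M; no
follow-up data at any month ≥ 12; no continuous health coverage;
insufficient KOOS data (baseline or 12 M PRO missing); no baseline
radiographic KL-grade reading. A knee is counted at the first step that
removes it, and every removal carries a machine-readable reason code in the
run log. Report arithmetic is validated (initial − Σremoved = final).

Cases: first vKR case status exactly at the target month (default 60 M),
composite score within the highest-risk `case_top_fraction` (default 10 %)
of the eligible population's scores at the `t0 = 48 M` cross-section
(inclusive rank cut: the ⌊f·n⌋ lowest scores), and readable MRI at every
annual visit 0–48 M. Controls: score at or above the empirical 80th
percentile (lowest-risk 20 %), excluding case knees and knees whose
contralateral is a vKR case or had surgical KR by the target month. The
percentile population is the t0 cross-section of eligible knees; at which
visit and over which population the original percentiles were computed is
not stated, so this choice is flagged here.

Matching is greedy 1:1 without replacement: cases in ascending knee-id
order; exact strata on sex, KL-grade stratum (0–1, 2, 3, 4) and
JSN-dominant compartment (medial/lateral/both, plus "none" for knees
without narrowing — "none" matches only "none"); within a stratum the
control minimizing |age difference| wins, ties broken by a seeded draw;
cases with no candidate within the ±5-year caliper are reported unmatched.
Greedy rather than optimal assignment because only the constraints, not the
algorithm, are published, and greedy is auditable; the unmatched fraction
is part of the output. Age is age at baseline. Participants may contribute
two case knees or two control knees; the dependence is handled by the
statistics, not forbidden by the matcher.

## 3. Cartilage metrics (`metrics`)

Sixteen femorotibial subregions: five per tibial plateau (c/e/i/a/p × MT,
LT) and three per weight-bearing femoral condyle (c/e/i × cMF, cLF). A
*plate* value is the (equal-weighted by default, configurable) mean of its
subregions; a *compartment* value is tibial plate + femoral plate. In
particular cMFTC = cMT + ccMF and MFTC = mean(5 MT subregions) + mean(3 cMF
subregions). Interval change is `thickness(to) − thickness(from)` in µm,
loss negative; mJSW change converts mm to µm in exactly one place.
Location-independent scores sum negative (thinning ≤ 0) and positive
(thickening ≥ 0) subregion changes; with the default
smallest-detectable-change threshold of 0 they partition the total summed
change exactly. A threshold hook exists because some implementations only
count changes beyond a detectability limit. Unreadable or missing visits
make a change undefined; the affected pair is dropped for that variable
only (pairwise-complete analysis), never imputed.

## 4. Matched-pair statistics (`stats`)

**Paired t**: on case−control differences, two-sided, df = n−1; degenerate
(zero-variance) difference vectors are an error, not a silent zero.

**Conditional logistic regression.** The 1:1 conditional likelihood
`Π_j exp(βᵀx_case,j) / (exp(βᵀx_case,j) + exp(βᵀx_control,j))` depends on
covariates only through within-pair differences and is maximized by Newton
iteration (gradient norm < 1e−10, damped steps far from the optimum). The
exposure is pre-divided by the control-group SD of the same variable and
interval, computed over pairwise-complete controls, so `exp(β)` is the OR
per control-SD. Change variables enter in the *loss* direction (negated
change) so that OR > 1 means greater structural deterioration among cases;
the thickening score, a gain measure, enters on its raw scale. Complete
separation (monotone likelihood) is declared, never "fixed" by
penalization. Model covariance is the inverse observed information; the
robust covariance is the sandwich A⁻¹BA⁻¹ with B built from per-pair score
contributions `(1−σ_j)d_j` summed over clusters. Clusters are connected
components of shared participant ids across pairs (covering both
bilateral-case participants and a participant contributing two control
knees); this pair-level aggregation is invariant to covariate translation.
Confidence intervals are Wald on the log scale with z = 1.96 (the CI method
is not stated in the source material). BMI adjustment appends within-pair
differences of overweight/obese indicators with WHO half-open bounds
[25, 30) and ≥ 30; indicator columns that are identically zero in a given
table row are dropped (they carry no information and would make the
information matrix singular).

**Kruskal–Wallis** (two groups, mid-ranks, tie correction, χ² with 1 df)
compares maintained vs non-maintained case knees; it is retained over the
equivalent rank-sum test for report fidelity. Two identical constant groups
return H = 0, p = 1.

No multiplicity correction is applied; rows are labelled by their role
(the 2-year cMFTC interval is primary, MFTC secondary, the rest
descriptive), mirroring the reporting convention of the study design this
package implements.

## 5. Synthetic cohort generator (`cohort`)

The generator emulates an OAI-like cohort: `n_participants` (default 4796,
two knees each → 9592 knees), annual visits at months 0–72, and the
following latent structure.

* **Severity.** Participant factor `u ~ N(0,1)`; knee latent severity
  `z = √ρ_w·u + √(1−ρ_w)·ε` with `ρ_w = within_person_corr` (default 0.5,
  a free parameter — the published material reports no between-knee
  correlations), so the two knees' severities correlate at exactly ρ_w.
* **Progressors.** The top `progressor_fraction` (default 0.10) of `z` are
  progressors: the knees whose symptom trajectories will meet the endpoint.
* **Symptoms.** KP and QoL follow intercept + linear slope + visit noise,
  with severity entering the *intercept* only (KP: 82 − 8z, slope
  −1.3 ± 0.8/y, noise SD 4; QoL: 62 − 7z, slope −1.6 ± 0.9/y, noise SD
  4.5). Progressors additionally decline 9 points/year on both scales after
  month 48 — the steep pre-endpoint worsening the endpoint definition keys
  on — and about half of them relapse (rebound 6 points at 72 M), so the
  72 M sustainment check splits the case group roughly in half. Scores are
  clipped to their bounds after noise; clipping is counted and logged, and
  the truncation bias at the extremes is accepted. Because severity shifts
  levels rather than slopes, pre-48 M symptom *change* is
  progressor-independent by construction.
* **Cartilage.** The knee's six annual cMFTC increments decompose into a
  stable knee-level rate carrying `rate_variance_fraction` (default 0.5) of
  the 2-year-change variance plus independent annual shocks, scaled so that
  *every* 2-year window has exactly the configured group mean and SD:
  progressors −151 ± 337 µm, non-progressors −38 ± 249 µm (the published
  case/control values, used as generator defaults). The annual increment is
  split cMT/ccMF (0.47/0.53 with a zero-sum reallocation noise), peripheral
  subregions scale it by fixed fractions chosen so the MFTC/cMFTC change
  ratio ≈ 0.67, and the lateral compartment runs at 0.55× the medial path
  with its own noise — the published tables report only region-level
  summaries, so within-region structure is the package's own choice.
  `symptom_structure_corr` couples the knee-level loss rate to the
  *within-group standardized* severity residual (higher severity → greater
  loss) without moving the group means or SDs; its default is 0 because the
  residual coupling is unidentifiable from published group summaries — the
  case/control contrast already arises entirely through progressor status.
  Its square may not exceed `rate_variance_fraction`.
* **mJSW** declines as an affine function of the medial annual increment
  (slope 1.59, drift −109 µm/y, noise SD 275 µm/y), calibrated so 2-year
  case/control means land near the published −458/−278 µm; the implied SDs
  are approximate.
* **Events.** Surgical KR probability is logistic in severity
  (intercept −4.6, slope 1.5 → ≈2–3 % of knees), with the event month drawn
  from a late-weighted schedule and all data truncated from that month.
  Knee-level dropout (`dropout_prob`, default 0.03) removes all follow-up;
  independent per-visit missingness (`missing_visit_prob`, default 0.05)
  marks PRO visits absent and MRI visits unreadable, never at baseline.
  Coverage is missing for 5 % of knees, the baseline radiograph for 2 %,
  the baseline PRO for 0.5 % — small rates chosen so every cascade step has
  work to do. The KL-grade distribution defaults to the published case-knee
  baseline distribution (26/6/26/28/14 %) and is drawn independently of
  severity, which keeps case and control strata comparable but understates
  the real association between radiographic grade and symptoms.
* **Determinism.** All randomness flows from one root seed through named,
  id-keyed substreams (participant, knee, missingness), so identical
  configs produce byte-identical cohorts and adding participants never
  perturbs existing knees.

`sample_matched_changes` draws matched-pair 2-year cMFTC changes directly
from the same increment decomposition (with an unconditional standard-
normal severity residual), for pair-level statistical validation without
simulating full cohorts.

**What the generator does and does not emulate.** It reproduces the
marginal group change distributions, the endpoint's symptom phenomenology,
within-person correlation, missingness and the cascade's bookkeeping. It
does not model radiograph–symptom association, femoropatellar disease,
realistic recruitment demographics, reader/measurement drift between
processing batches, or serial correlation structures beyond the single
rate-plus-shock decomposition. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not epidemiological fidelity
of any particular rate in real cohorts.

## 6. Pipeline scale and numerical choices

The default pipeline run uses the full cohort scale (9592 knees), which
yields on the order of 130–150 matched pairs; pair-level statistical
validation (estimator consistency, sandwich validity, type-I calibration,
effect recovery) runs on pairs drawn by `sample_matched_changes` at 500
pairs per replicate, and generator-calibration checks use ≥ 2000 knees —
sizes chosen to make Monte-Carlo bands tight relative to the assertions
they support. Selected case knees are a ~85 %-pure subset of progressors
(condition 3 admits some non-progressors by noise), so the *selected-case*
mean loss sits ≈ 20–30 µm above the configured progressor mean at cohort
scale; the configured distributions are recovered exactly at pair level and
group level. Newton iteration converges in < 10 steps on all realistic
inputs; steps are norm-capped at 5 and divergence (‖β‖ > 50) is reported as
separation. Quantile conventions are lower-empirical without interpolation
throughout (threshold calibration, case/control percentile cuts). All
thickness outputs are µm; the single mm→µm conversion lives in
`mjsw_change`.

## 7. Known limitations

* The score→probability link behind "highest 10 % predicted probability"
  is approximated by score rank; the published constants are inputs, not
  re-derived.
* Greedy matching is order-dependent by design (auditable, reported
  unmatched fraction); an optimal assignment could match more cases.
* The sandwich estimator's exact correspondence to the original software's
  options is unknown; this package documents its estimator precisely
  (pair-level scores, participant connected components) instead.
* The generator's maintenance split and selected-case purity depend on the
  symptom-noise and acceleration constants; they are fixed, documented
  values, not fitted quantities.
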