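# Methods

## Measurement model

Session content is rated with the CHANGE observational system: thirteen
ordinal variables per session (positive and negative View of Self, Hope,
Relationships, Emotion, Behavior, Somatic, plus Emotional Processing), each
0–3, by two independent coders.  All analysis runs on coder-averaged
ratings; with two coders these live on a half-point grid.  A missing rating
is an explicit sentinel (NaN) and never imputed: a node without any rated
source is *missing*, and a session with a missing node is excluded from
grids and endpoint extraction rather than rescaled, because rescaling would
silently change the 0–4 activation semantics.  The cognitive node is the
mean of the *available* cognitive-triad variables and is missing only when
all three are missing.

**Strength vs activation.**  Pattern strength (sum of the four nodes, 0–12)
measures overall intensity; activation (count of nodes at or above the
moderate threshold, 0–4) measures multimodal breadth.  They are
deliberately non-redundant: sessions with equal activation can differ in
strength.

**Activation threshold.**  The default applies `≥ 2.0` to the node score
after coder averaging and, for the cognitive node, after the triad mean; a
strict reading of "moderate" as a rating of 2 or 3 means an averaged 1.5
does not activate but 2.0 does.  Because one could equally threshold the
raw variables, a `per-variable` mode is exposed (cognitive node active when
a majority — 2 of 3 — of its sources reach threshold); the default is the
node-level rule.

## State-space grids and dispersion

Each coded session is one point (positive activation, negative activation)
on a 5×5 grid.  Dispersion for a patient-phase is

    disp = 1 − (n Σ (dᵢ/D)² − 1) / (n − 1),

algebraically the normalized Simpson diversity `n(1 − Σpᵢ²)/(n − 1)`.  Two
conventions matter and are fixed here:

* `n` is the **total** cell count of the grid (25), not the number of
  visited cells.  Consequently the maximum 1.00 is attained only when
  occupancy is even across all 25 cells; with the study's sparse sampling
  (4–6 coded sessions per phase) the attainable ceiling is
  `1 − (25/D − 1)/24` (e.g. 0.868 at D = 6 all-distinct, 0.833 at D = 5).
* `D` is the number of coded sessions in the phase, so unequal sampling
  density across phases is reflected, not rescaled.

`D = 1` grids return 0 (formula-consistent) but are flagged degenerate;
`D = 0` is an explicit error.  Phase-1 grids exclude the baseline session
and phase-2 grids exclude the posttreatment session, so the endpoint
measurements are not double-counted as process variability.

## Phases and endpoints

Phase 1 is sessions 1–10 (symptom reduction), phase 2 sessions 11–34
(schema focus); both are configurable.  Baseline strengths come from
session 1; posttreatment strengths from the coded session closest to
session 34, choosing the *earlier* session on ties (deterministic, and the
post measurement never precedes itself).  Peak emotional processing is the
maximum averaged processing rating in the phase — peaks detect transient
processing shifts that means wash out.  Phase-1 peaks are taken over the
first ten sessions including baseline; phase-2 peaks exclude the
posttreatment session so the peak always precedes the outcome measurement.
Patients lacking a baseline coding, a post-window coding or an outcome
record are dropped with a logged reason; patients with other missing fields
are kept — the correlation matrix uses pairwise deletion while each
regression deletes listwise, which keeps every analysis internally coherent
under unequal per-variable coverage.

## Statistics

* Paired t: `t = m̄ / (s_d/√n)`, df = n − 1, two-tailed; Cohen's
  `d = m̄ / s_d` on the difference scores, so `|t| = |d|√n` exactly.  A
  from-summary-statistics constructor reproduces printed results from
  (mean diff, SD, n).
* Hierarchical regression: OLS per cumulative step (statsmodels);
  standardized `β = B·sd(x)/sd(y)`;
  `ΔF = (ΔR²/q) / ((1 − R²_full)/(n − k_full − 1))` with q predictors added
  and k_full in the current step — the standard R²-change convention using
  the current step's residual variance.
* `regression_from_correlations` solves `β = Rxx⁻¹ rxy`, `R² = βᵀrxy` per
  step from a printed correlation matrix (positive-definiteness checked by
  Cholesky).  On complete data it agrees with the sample regression to
  ≤ 1e-8, which the suite uses as an equivalence oracle.
* Coder agreement: two-way random-effects, absolute-agreement, single-rater
  ICC (via pingouin).  The variant is this package's choice; the form is
  recorded in the result metadata.

## Synthetic cohorts

The generator emulates the study design: 27 patients by default, sessions
coded every other session in 1–10 and every fourth in 11–34, sessions 1 and
34 always coded, other tapes missing with probability 0.18 (at least one
non-anchor tape per phase is kept so every patient is analyzable).

* **Latent dynamics.** A two-state chain (negative-dominant vs
  positive-dominant) per patient flickers with a per-phase switching rate
  drawn from (0.10, 0.60); the two phases' rates share a patient propensity
  so early and late destabilization correlate.  Two-state flickering is the
  minimal generative model consistent with the attractor framing; richer
  continuous-state dynamics are out of scope.
* **Emissions.** Each variable draws around the active state's mean
  (negative-dominant: negative variables 2.2, positive 0.6;
  positive-dominant: 0.8 / 2.1) with SD 0.40, truncated to [0, 3]; each
  coder adds N(0, 0.33) noise and the result is rounded to {0..3}.  The
  emission SD and switching ranges were calibrated once so cohort mean
  dispersion lands near 0.5–0.7 and the two-coder ICC near the 0.80 target
  (the suite checks ICC within ±0.05 at > 500 paired sessions); rounding to
  the nearest integer reproduces the rating scale and the half-point
  averaged values.
* **Processing** ramps from a patient-specific phase-1 level (N(1.2, 0.4))
  to a phase-2 peak (N(2.2, 0.45)) at a peak session drawn from
  {15, 19, 23}, then eases off slightly.
* **Outcomes.** Standardized post score
  `z_y = b₁ z(pre) + b₂ z(disp2) + b₃ z(proc2) + ε`, with planted
  standardized coefficients (SCID-II: 0.24, −0.35, −0.45; positive pattern:
  0.25, 0.39, 0.46; negative pattern: 0.16, −0.27, −0.10) and residual
  variance set so Var(z_y) = 1 given the realized predictor correlations.
  The predictors are the *measured* values (the same functions the pipeline
  uses), so recovery error isolates the planted residual plus ordinal
  discretization.  SCID-II pre is drawn near the study's intake severity
  (mean 10.82, SD 2.18, range 0–16); post scores are mapped mid-range
  (SCID-II 8 ± 3 on [0, 16]; strengths 5.5 ± 2.5 on [0, 12]) so the range
  clip is rarely active and the planted model stays effectively linear —
  a deliberate departure from the floor-adjacent posttreatment means seen
  in real cohorts, where clipping would attenuate the planted
  coefficients.  Strength outcomes are *encoded into the posttreatment
  session's ratings* and then measured back by the pipeline, like real
  data; the residual discretization noise inflates sd(y) and attenuates
  standardized estimates by roughly 2–4% — visible as a small negative bias
  in recovered βs.
* **Reproducibility.** A per-patient seed sequence is spawned from the
  global seed: fixed config ⇒ bit-identical cohorts, and a patient's coded
  sessions do not change when the cohort grows.  The posttreatment session
  is the one exception, since outcome planting standardizes predictors over
  the generated cohort.

What the generator does **not** emulate: real CHANGE ratings'
item-level dependence structure, therapist effects, non-stationary coder
drift, floor-heavy outcome distributions, or any transcript content.
Passing parameter-recovery tests therefore demonstrates pipeline
correctness under the assumed generative structure, not the validity of
the coding system on real sessions.

## Test and check sizes

Parameter recovery uses cohorts of n = 500 patients; recovered step-2
standardized coefficients are averaged over 4 seeded cohorts (Monte-Carlo
SE of a single-cohort β is ≈ 0.03, so averaging keeps the ±0.05 check
informative about bias rather than noise).  The ΔF type-I check runs 1000
study-sized (27-patient) null cohorts through the full pipeline and
expects the 5% rate within ±2 binomial SEs.  Property suites
(hypothesis) are derandomized for reproducibility.

## Known limitations

* Dispersion with 4–6 points on 25 cells has a hard ceiling well below
  1.00 and a coarse support; between-patient differences at the study's
  sampling density are dominated by how many distinct cells are visited.
* Standardized-β recovery carries the small discretization attenuation
  noted above; raw-coefficient recovery does not.
* The ICC calibration is specific to the default emission geometry;
  changing state means or emission SD changes the between-item variance
  and hence the realized ICC for a given coder noise.
* GridWare-style trajectory export writes unit-duration events (one coded
  session = one event); real-time duration weighting is not modeled.
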