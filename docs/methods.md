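# Methods

## The synthetic ward

The generator produces cohorts with the statistical structure the pipeline
assumes, not a mechanistic patient model.

Admissions arrive as a Poisson process at `admission_rate` (default 14
encounters/day). Length of stay is log-normal (`los_meanlog=4.725`,
`los_sdlog=0.70` on hours, mean ≈ 6 days), clipped to [2 h, 60 days]. By
Little's law the default mean census is 14 × 6 = 84 concurrent patients,
and the simulated daily census is checked against that product in the
tests. Ages are normal (67, 18) clipped to [18, 100]; sex is balanced.
Outcomes are drawn from `outcome_mix` (default: none 0.88, death 0.04, ICU
0.05, step-up 0.02, palliative 0.01 — roughly one deteriorating encounter
in eight). Half of ICU transfers return to the ward 24–96 h later, which
exercises the post-ICU alert silence.

Each encounter carries a latent severity s(t), sampled hourly as a
deterministic mean path plus zero-mean Ornstein–Uhlenbeck fluctuations
(stationary SD 1, 24-h correlation time, exact discretization). For
event-free encounters the mean path is 0. For outcome encounters it is
elevated by `severity_admission_shift` (default +1 SD — deteriorating
patients are on average sicker from admission, which is what makes the
admission-window "baseline" score informative) and ramps linearly to
`severity_peak` (default +3 SD) over the `severity_lead_hours` (default
48 h) before the outcome timestamp. The mean path is the process mean
itself, not a target the process chases: an OU process pursuing a moving
target lags it by its relaxation time and would reach barely half the
intended shift, burying the planted signal.

Observations are sampled per feature at exponential inter-measurement
times (vitals every ~4 h, most labs daily, HbA1c every ~3 days). A value
at time t is `healthy_mean + healthy_sd × (loading × s(t) + 0.7 × ε)`,
ε ~ N(0, 1). Loadings encode clinical direction: respiratory rate (+1.0),
troponin (+0.9), temperature (+0.6), ALT (+0.5), glucose (+0.4) rise;
systolic (−0.8) and diastolic (−0.6) pressure and hemoglobin (−0.5) fall;
HbA1c and basophils carry no acute signal and act as distractors. Healthy
means sit near values typical of GIM training extracts (temperature 36.91,
systolic BP 129.9, respirations 20.5, …).

Artifacts are magnitude corruptions only: with probability
`artifact_rate` (default 0.001) an observation's value is replaced by an
entry from its feature's artifact catalog, all outside the physiologic
range (temperature 700 or 6932, systolic BP 16,070, respirations 20,147,
and similar digit-duplication extremes for the labs). No wrong-patient or
unit-swap errors are modeled.

What the generator does **not** emulate: case-mix drift and seasonality,
informative sampling (sicker patients being measured more often),
correlated multi-feature physiology beyond the single severity factor,
free-text or medication data, and readmission dependence. Passing tests
therefore demonstrate that the pipeline's computational rules are
implemented correctly and that the model recovers a planted signal — not
that any particular AUC would transfer to real patients.

## Preprocessing

Windows are 6 hours, indexed from the admission timestamp; the span ends
at the first of discharge, outcome, or (when scoring mid-stay) the clock
time, and the final partial window is kept — deployment scores patients
hourly, mid-window. Duplicate measurements in a window are averaged.
`time_since_last_measured` is referenced to the window's end, and to time
since admission when the feature has never been measured.

Trimming/normalization uses the training set's empirical 1st/99th
percentiles (linear interpolation) of *measured* values only; values are
clipped to that range then mapped onto [0, 1], so a 700-degree temperature
maps to exactly 1.0 rather than dominating a least-squares fit. A constant
training feature is flagged degenerate and maps to 0.5 with a warning.
Imputation is last-observation-carried-forward within the encounter, then
the training mean of the normalized feature for leading gaps; the
`_measured`/`_time_since` descriptors are never imputed. Imputation is
idempotent.

Training-cohort exclusions drop stays strictly under 8 h or strictly over
40 days (both boundaries retained; the ceiling is read as days — an
8-to-40-*hour* band would discard most admissions — and is configurable).
Exclusions never apply at scoring time.

Assay changes (e.g. a switch to high-sensitivity troponin) are handled by
a per-feature list of (effective-from, scale, offset) entries applied
piecewise by timestamp; the conversion factor is configuration, not a
constant.

Normalization parameters carry a content-hash version tag
(`norm-<sha1 prefix>`). Models record the tag at fit time and refuse to
score windows preprocessed under a different tag.

## The two-stage model

Stage 1 is classical least-squares MARS on the full window design (per
feature: normalized value, measured flag, staleness hours; plus age and
sex). The forward pass adds, at each step, the reflected hinge pair
(parent basis × h(x_j − t), parent basis × h(t − x_j)) with the largest
RSS reduction, computed in the orthogonal complement of the current basis
via an updated QR factorization. Candidate knots are at most 100
quantile-subsampled unique values per predictor; ties break toward the
lowest predictor index then the smallest knot, making fits exactly
reproducible. Defaults: `max_terms=21` basis functions (including the
intercept), `degree=2` (pairwise interactions, a variable at most once per
product), GCV penalty d=3 (the classical choice when interactions are
allowed). The backward pass deletes one term at a time (intercept fixed),
tracking the GCV-minimal subset; pruning can only lower GCV relative to
the forward model. Fitting a 0/1 outcome by least squares is deliberate —
stage 2 supplies the probabilistic link.

Stage-1 scores are clamped to [0, 1] before anything downstream sees
them. The unconstrained hinge basis extrapolates linearly (quadratically
for interaction terms) outside the training hull — on held-out data we
observed raw score SDs near 4 for a 0/1 target — and the clamp keeps the
score-timeline features on the probability scale where the logistic stage
is stable.

Stage 2 is a maximum-likelihood logistic regression on four score-timeline
features per window: current score, baseline (window-0) score, change
from the previous window, change since baseline. "Baseline" means the
admission window. At window 0 the baseline equals the current score and
both deltas are 0. Because delta_baseline ≡ current − baseline, the
four-feature design is rank-deficient; the fit runs on the identifiable
triple (current, baseline, delta_prev) and reports delta_baseline as
aliased (coefficient 0, SE undefined), exactly as a rank-revealing GLM
does. Separation or instability falls back to a ridge-stabilized fit
(α = 10⁻³) with a warning. The training label defaults to
`outcome_within_48h` — whether the (four-outcome composite) endpoint
occurs within 48 h of the window's end — since that is the horizon alerts
are meant to anticipate; `outcome_ever` is available by configuration.

Scoring is causal: the risk at window w is a function of windows 0..w
only, so appending future data never changes past scores. For speed on
large cohorts the stage-1 forward search can run on a seeded row subsample
(`stage1_max_rows`, default 20,000); stage 2 always uses every window.

## Threshold calibration

Candidates are the unique observed encounter-maximum scores. Folds
(default 10) are assigned to encounters, never windows, with a seeded
shuffle; each candidate's PPV/NPV is the pooled held-out estimate (counts
summed over folds — numerically identical to the full-sample estimate
because the folds partition the encounters, but computed through the fold
machinery so the procedure generalizes to fold-fitted variants). The
selected cutoff is the one whose estimate is closest to target, ties going
to the lower cutoff (maximizing sensitivity). The high and low cutoffs are
searched independently; if they cross, both collapse to their midpoint
with a warning — expected on small or poorly separated validation sets.
Group assignment: score ≥ thr_high → High (alerts fire exactly at the
threshold), score < thr_low → Low, otherwise Medium.

## Alerting

Five conjunctive predicates gate a page (High at t; not already High at
the previous step; ≥ 48 h since the patient's last alert; fewer than 5
alerts so far; not within 24 h of an ICU return). The transition rule and
the 48-h clock are deliberately conjunctive — a transition inside the 48-h
window does not re-arm early; this is the fewest-alerts reading consistent
with minimizing alert fatigue. The 5-alert cap is on by default and can be
disabled to reproduce pre-cap behavior. Suppression governs pages only:
the census email and sign-out feed keep displaying High. State is per
encounter and resets at discharge (not during a temporary ICU absence);
consequently the palliative digest's "first High" is first-ever within the
encounter. Each firing is delivered on both the team-phone and
charge-nurse-phone channels.

## Replay and downtime

The hourly cycle extracts census + observations as of the clock time; on
extraction failure it reuses the last extract while it is at most 3 h old
(`stale_ok`), then declares unplanned downtime, emitting one notification
payload on entry and one on recovery. Planned windows are announced once.
All ward patients are re-scored in full every cycle (idempotent, and
robust to backfilled data). Per-cycle `down_hours` record the fractional
overlap of the fault window with the hour, so sub-hour outages aggregate
exactly. Notifications are structured payloads in a log — content and
timing are what is testable; no mail or paging transport is included.

## Evaluation choices

AUC is rank-based (Mann–Whitney; ties count 1/2) and computed at window
level for both labelings, since predictions are per-window. Both outcome
composites (ICU/death and ICU/death/step-up/palliative) are reported side
by side. Adherence has two operationalizations: the default counts ≥ 4
distinct vital-sign assessment timestamps in the 24 h after an alert; the
strict mode requires every inter-assessment gap (including the edges of
the 24-h span) to be ≤ 4 h, and can never exceed the default. Daily alert
statistics count firings (not channel deliveries) and include zero-alert
days; the SD is the sample SD and is reported as absent for a single day.
Uptime percentages and downtime shares are rounded to one decimal for
reporting.

## Problem sizes

The test suite fits the model on a 300-encounter cohort (~7,300 windows,
34 design columns), holds out a third of encounters for the signal checks,
and uses a 2,000-encounter validation set for the calibration study — the
sizes at which the planted-signal and calibration behaviors are stable
across seeds while the full suite stays quick to run. The deployment-scale
replay test drives the full 14,016-hour (584-day) period with a small
ward so every hour is exercised.

## Known limitations

* The stage-1 fit is least-squares, so very rare outcomes (window
  prevalence ≪ 1%) degrade knot selection before stage 2 can compensate.
* Stage-2 standard errors treat windows as independent; within-encounter
  clustering means they are optimistic (the aliased design is reported,
  but no cluster-robust covariance is computed).
* The calibration search assumes encounter-maximum scores are monotone in
  risk; pathological non-monotone score timelines would calibrate but with
  degraded operating points.
* Categorical observations (e.g. oxygen delivery device) are out of
  scope; only numeric features are windowed.
* The replay scores every admitted patient every hour with no
  incremental caching, which is simple and exactly idempotent but scales
  linearly in census × stay length.
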