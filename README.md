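# chartward

A tested, self-contained re-implementation of a hospital early-warning
pipeline for general internal medicine (GIM) wards: from raw vitals/labs
extracts to risk groups, pager alerts, and deployment monitoring. It is
aimed at clinical data-science teams who want to study, stress-test, or
teach the computational machinery of ward deterioration systems without
access to protected patient data — every input is generated by a seeded
synthetic cohort simulator.

## What it implements

**Data model.** Encounters (admission/discharge, demographics, a
four-outcome deterioration endpoint: death on the ward, ICU transfer,
step-up-unit transfer, palliative transfer) and long-format timestamped
observations. The synthetic generator emulates a ~78-bed ward with a mean
census near 84 patients (admission rate × mean length of stay), irregular
hourly-to-daily sampling per feature, a latent severity process that ramps
over the 48 h before an outcome, and rare data-entry artifacts (a body
temperature of 700, a systolic pressure of 16,070).

**Preprocessing.** Each stay becomes a time series of 6-hour windows from
admission to the first of discharge or outcome. Numeric features are
averaged within windows, trimmed to the training set's 1st/99th
percentiles and mapped linearly onto [0, 1] (so artifacts saturate at the
boundary), accompanied by `<feature>_measured` flags and
`<feature>_time_since_last_measured` hours, and imputed by last
observation carried forward then training-mean fill. Training cohorts
exclude stays under 8 h or over 40 days; scoring cohorts never do.

**Model — "time-aware MARS".** Stage 1 is a from-scratch multivariate
adaptive regression spline: hinge functions h(x − t) = max(0, x − t) grown
greedily in reflected pairs (interactions up to degree 2) and pruned
backward by generalized cross-validation,

GCV(M) = (RSS/N) / (1 − C(M)/N)², C(M) = M + d·(M − 1)/2,

producing a deterioration score per window. Stage 2 is a logistic
regression on four score-timeline features — current score, admission
(baseline) score, change from the previous window, change since baseline —
yielding a per-window probability that reflects both level and velocity.

**Calibration.** Continuous risks become {High, Medium, Low} groups via
two cutoffs found by a 10-fold, encounter-level cross-validated grid
search targeting a visit-level positive predictive value of 40% (about two
false alerts per true positive) and a negative predictive value of 99%.

**Alerting.** A deterministic suppression engine: alerts fire only on
transitions into High risk, at most once per 48 h per patient, at most 5
per patient (configurable), and never within 24 h of a return from the
ICU. It also builds the twice-daily charge-nurse census email and the
daily palliative-care digest (patients first classified High in the past
24 h).

**Monitoring.** Window-level AUC (outcome ever / within 48 h),
encounter-level PPV of alerted visits, sensitivity partitioned by each
visit's maximum risk group, daily alert-volume statistics, weekly
adherence (vital-sign assessments in the 24 h after an alert), and
pipeline uptime with planned/unplanned downtime shares.

**Replay driver.** An hourly batch loop over simulated time with a
≤ 3-hour stale-extract fallback, downtime/recovery notifications, and
scheduled communications — a pure function of (cohort seed, fault
scenario, config).

## Worked example

```python
from chartward import SimConfig, simulate_cohort, calibrate_thresholds
from chartward.preprocessing import preprocess_cohort
from chartward.timeaware import TimeAwareDeterioration
from chartward.evaluation import compute_auc, composite_outcomes

cfg = SimConfig(n_encounters=300, seed=42)
encounters, observations = simulate_cohort(cfg)
features = [f.name for f in cfg.feature_catalog]
windows, norm = preprocess_cohort(encounters, observations, features,
                                  mode="train")

model = TimeAwareDeterioration(windows, features, seed=0).fit()
print(model.summary())
```

The summary shows the pruned hinge basis (18 basis functions here, led by
respiratory rate and systolic blood pressure, the two most severity-loaded
vitals) and the stage-2 coefficients:

```
Stage 2: logistic regression on score-timeline features
----------------------------------------------------------------
feature                     coef     std err
----------------------------------------------------------------
const                   -4.51234     0.10918
current                 11.05092     0.53869
baseline                10.01882     1.64077
delta_prev              -4.21856     0.56591
delta_baseline           0.00000         nan
----------------------------------------------------------------
log-likelihood: -791.19   (intercept-only: -1176.32)
```

(`delta_baseline` is an exact linear combination of `current` and
`baseline`, so it is aliased with coefficient 0, as any rank-revealing GLM
would report.) Continuing:

```python
risk = model.predict_risk(windows)
outcomes = composite_outcomes(encounters)
thresholds = calibrate_thresholds(risk, outcomes, seed=0, score_col="risk")
```

prints, via the attributes on `thresholds`:

```
thr_high=0.1137  thr_low=0.0207
achieved PPV=0.400  NPV=0.990
in-sample AUC (next 48 h) = 0.895
```

i.e. a window risk of ≥ 0.114 classifies a patient High (alerting the ward
team), < 0.021 classifies Low, and at these cutoffs 40% of alerted visits
truly deteriorate while 99% of never-above-Low visits do not.

The same flow is available from the shell:

```bash
chartward simulate --config cfg.yaml --seed 17 --out cohort/
chartward train    --cohort cohort/ --out model/
chartward calibrate --cohort cohort/ --model model/model.json \
    --norm model/normalization.json --out thresholds.json
chartward replay   --cohort cohort/ --model model/model.json \
    --norm model/normalization.json --thresholds thresholds.json \
    --hours 720 --out run/
```

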