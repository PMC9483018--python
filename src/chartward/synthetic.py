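"""Seeded synthetic GIM ward cohorts.

Generates encounter and long-format observation tables with the statistical
structure the downstream pipeline assumes:

* admissions arrive as a Poisson process tuned so the mean ward census sits
  near 84 concurrent patients (admission rate x mean length of stay,
  Little's law);
* each encounter carries a latent severity process (mean-reverting
  Ornstein-Uhlenbeck) that, for encounters ending in an outcome, drifts
  upward over the 48 h preceding the outcome timestamp, so fitted models
  have recoverable 48-h-ahead signal;
* vitals and labs are sampled at irregular, feature-specific intervals and
  loaded on severity with feature-specific signs (e.g. systolic blood
  pressure falls, respiratory rate rises);
* a small fraction of observations is corrupted with data-entry artifacts of
  the kind real extracts contain (a body temperature of 700 or 6932,
  a systolic blood pressure of 16,070).

All randomness flows from a single integer seed; identical config + seed
yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from chartward.exceptions import ConfigurationError, SchemaError

OUTCOME_TYPES = ("none", "death", "icu", "stepup", "palliative")

ENCOUNTER_COLUMNS = [
    "encounter_id",
    "admit_ts",
    "discharge_ts",
    "age",
    "sex",
    "outcome_type",
    "outcome_ts",
    "icu_return_ts",
]
OBSERVATION_COLUMNS = ["encounter_id", "timestamp", "feature", "value"]

_TS_COLUMNS = ("admit_ts", "discharge_ts", "outcome_ts", "icu_return_ts")


@dataclass(frozen=True)
class FeatureSpec:
    """Sampling and distributional description of one vital or lab.

    Parameters
    ----------
    name : str
        Feature identifier used in the long-format observation table.
    healthy_mean, healthy_sd : float
        Mean and SD of the measurement for a stable ward patient, in the
        feature's native units.
    interval_hours : float
        Mean of the exponential inter-measurement waiting time. Vitals are
        measured every few hours, labs daily or less often.
    loading : float
        Shift of the observed mean per unit latent severity, in units of
        ``healthy_sd``. Sign encodes direction (negative: the feature falls
        as the patient deteriorates).
    physiologic_range : (float, float)
        Bounds outside which a value is physiologically impossible; used
        only to construct and recognize data-entry artifacts.
    artifact_values : tuple of float
        Catalog of corrupt values for this feature, all outside
        ``physiologic_range``.
    """

    name: str
    healthy_mean: float
    healthy_sd: float
    interval_hours: float
    loading: float
    physiologic_range: tuple[float, float]
    artifact_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.healthy_sd <= 0:
            raise ConfigurationError(
                f"feature_catalog[{self.name}].healthy_sd must be > 0"
            )
        if self.interval_hours <= 0:
            raise ConfigurationError(
                f"feature_catalog[{self.name}].interval_hours must be > 0"
            )
        lo, hi = self.physiologic_range
        if not lo < hi:
            raise ConfigurationError(
                f"feature_catalog[{self.name}].physiologic_range must satisfy lo < hi"
            )
        arts = self.artifact_values or _default_artifacts(lo, hi)
        object.__setattr__(self, "artifact_values", tuple(arts))
        for v in self.artifact_values:
            if lo <= v <= hi:
                raise ConfigurationError(
                    f"feature_catalog[{self.name}].artifact_values contains "
                    f"{v}, which lies inside the physiologic range"
                )


def _default_artifacts(lo: float, hi: float) -> tuple[float, ...]:
    # magnitude corruptions: digit-duplication style blow-ups and impossible
    # low values, mirroring what hospital extracts actually contain
    return (hi * 100 + 32, hi * 1000 + 70, lo - max(10.0, abs(lo)))


def default_feature_catalog() -> list[FeatureSpec]:
    """Ten vitals/labs with healthy means near typical GIM training data.

    Loadings encode clinical direction: deterioration raises temperature,
    respiratory rate, troponin, glucose and ALT and lowers blood pressures
    and hemoglobin; HbA1c and basophils carry no acute signal.
    """
    return [
        FeatureSpec("temperature", 36.91, 0.55, 4.0, 0.6, (30.0, 43.0),
                    (700.0, 6932.0, 0.0)),
        FeatureSpec("systolic_bp", 129.89, 19.0, 4.0, -0.8, (40.0, 260.0),
                    (16070.0, 1.0)),
        FeatureSpec("diastolic_bp", 71.49, 11.0, 4.0, -0.6, (20.0, 160.0),
                    (7149.0, 0.0)),
        FeatureSpec("respirations", 20.53, 2.6, 4.0, 1.0, (4.0, 60.0),
                    (20147.0, 0.0)),
        FeatureSpec("troponin", 0.28, 1.5, 24.0, 0.9, (-3.0, 8.0),
                    (280.0, 1000.0)),
        FeatureSpec("hba1c", -2.73, 0.27, 72.0, 0.0, (-4.0, 3.0),
                    (229.0, -330.0)),
        FeatureSpec("glucose_random", 1.95, 0.45, 24.0, 0.4, (0.0, 5.0),
                    (451.0, 1950.0)),
        FeatureSpec("hemoglobin", 106.09, 21.0, 24.0, -0.5, (20.0, 230.0),
                    (10609.0, 1.0)),
        FeatureSpec("basophils", 0.03, 0.028, 24.0, 0.0, (0.0, 3.0),
                    (269.0, -1.0)),
        FeatureSpec("alt", 3.38, 1.2, 48.0, 0.5, (0.0, 9.0),
                    (878.0, 338.0)),
    ]


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults emulate a 78-bed GIM ward taking ~14 admissions/day with a mean
    stay of 6 days, which by Little's law yields a mean census of ~84
    concurrent patients. Outcome mix gives ~12% of encounters a
    deterioration endpoint (death / ICU / step-up / palliative).
    """

    n_encounters: int = 500
    admission_rate: float = 14.0  # encounters per day
    los_meanlog: float = 4.725   # log-normal parameters for stay length, hours
    los_sdlog: float = 0.70      # mean exp(mu + s^2/2) ~ 144 h = 6 days
    feature_catalog: list[FeatureSpec] = field(default_factory=default_feature_catalog)
    outcome_mix: dict[str, float] = field(default_factory=lambda: {
        "none": 0.88, "death": 0.04, "icu": 0.05, "stepup": 0.02,
        "palliative": 0.01,
    })
    artifact_rate: float = 0.001
    severity_peak: float = 3.0     # latent severity reached at outcome time
    severity_lead_hours: float = 48.0  # drift starts this long before outcome
    severity_admission_shift: float = 1.0  # baseline elevation, outcome stays
    noise_scale: float = 0.7       # measurement noise, units of healthy_sd
    icu_return_prob: float = 0.5   # ICU outcomes that bounce back to the ward
    start: str = "2022-01-01T00:00:00+00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_encounters, (int, np.integer)) and self.n_encounters > 0):
            raise ConfigurationError("n_encounters must be a positive integer")
        for name in ("admission_rate", "artifact_rate", "severity_lead_hours",
                     "noise_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must lie in [0, 1]")
        if not self.feature_catalog:
            raise ConfigurationError("feature_catalog must be non-empty")
        unknown = set(self.outcome_mix) - set(OUTCOME_TYPES)
        if unknown:
            raise ConfigurationError(f"outcome_mix has unknown outcome types: {sorted(unknown)}")
        total = sum(self.outcome_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"outcome_mix must sum to 1 (got {total})")
        if any(p < 0 for p in self.outcome_mix.values()):
            raise ConfigurationError("outcome_mix probabilities must be >= 0")

    @property
    def mean_los_hours(self) -> float:
        return math.exp(self.los_meanlog + self.los_sdlog**2 / 2.0)

    @property
    def expected_census(self) -> float:
        """Little's law: arrival rate x mean time in system."""
        return self.admission_rate * self.mean_los_hours / 24.0

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "feature_catalog" in d:
            d["feature_catalog"] = [
                f if isinstance(f, FeatureSpec) else FeatureSpec(
                    name=f["name"],
                    healthy_mean=f["healthy_mean"],
                    healthy_sd=f["healthy_sd"],
                    interval_hours=f["interval_hours"],
                    loading=f.get("loading", 0.0),
                    physiologic_range=tuple(f["physiologic_range"]),
                    artifact_values=tuple(f.get("artifact_values", ())),
                )
                for f in d["feature_catalog"]
            ]
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config fields: {sorted(bad)}")
        return cls(**d)


def _simulate_severity(rng: np.random.Generator, hours: int,
                       mean_path: np.ndarray) -> np.ndarray:
    """Hourly severity: m(t) plus zero-mean OU fluctuations (stationary SD 1,
    24-h correlation time, exact discretization)."""
    theta = 1.0 / 24.0
    a = math.exp(-theta)
    s = math.sqrt(1.0 - a * a)
    x = np.empty(hours + 1)
    x[0] = rng.normal(0.0, 1.0)
    shocks = rng.normal(0.0, s, size=hours)
    for t in range(hours):
        x[t + 1] = a * x[t] + shocks[t]
    return mean_path + x


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort.

    Returns
    -------
    encounters : DataFrame
        Columns ``encounter_id, admit_ts, discharge_ts, age, sex,
        outcome_type, outcome_ts, icu_return_ts`` (timestamps tz-aware UTC;
        absent timestamps are NaT).
    observations : DataFrame
        Long format: ``encounter_id, timestamp, feature, value``, sorted by
        encounter, timestamp, feature.

    Deterministic given ``config`` (including its seed). Encounters with an
    outcome carry a latent severity trajectory that rises over the
    ``severity_lead_hours`` before the outcome and shifts observed feature
    means through each feature's loading.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")

    n = config.n_encounters
    interarrival_h = rng.exponential(24.0 / config.admission_rate, size=n)
    admit_offsets = np.cumsum(interarrival_h)
    los = np.exp(rng.normal(config.los_meanlog, config.los_sdlog, size=n))
    los = np.clip(los, 2.0, 24.0 * 60)
    ages = np.clip(rng.normal(67.0, 18.0, size=n), 18.0, 100.0).round(0)
    sexes = rng.choice(np.array(["F", "M"]), size=n)
    mix_types = list(config.outcome_mix)
    mix_p = np.array([config.outcome_mix[t] for t in mix_types])
    outcomes = rng.choice(np.array(mix_types, dtype=object), size=n, p=mix_p)

    enc_rows = []
    obs_frames = []
    for i in range(n):
        eid = f"E{i + 1:05d}"
        admit = start + pd.Timedelta(hours=round(admit_offsets[i] * 3600) / 3600)
        stay_h = float(los[i])
        outcome = str(outcomes[i])
        outcome_ts = pd.NaT
        icu_return_ts = pd.NaT
        if outcome == "none":
            discharge = admit + pd.Timedelta(hours=stay_h)
            observed_until = stay_h
        else:
            outcome_ts = admit + pd.Timedelta(hours=stay_h)
            observed_until = stay_h
            discharge = outcome_ts
            if outcome == "icu" and rng.random() < config.icu_return_prob:
                back = stay_h + rng.uniform(24.0, 96.0)
                icu_return_ts = admit + pd.Timedelta(hours=back)
                discharge = icu_return_ts + pd.Timedelta(
                    hours=rng.exponential(48.0) + 2.0)

        hours = int(math.ceil(observed_until)) + 1
        mean_path = np.zeros(hours + 1)
        if outcome != "none":
            # deteriorating patients are somewhat sicker from admission, and
            # their severity ramps to its peak over the final lead window
            mean_path += config.severity_admission_shift
            if config.severity_lead_hours > 0:
                t_axis = np.arange(hours + 1, dtype=float)
                ramp_start = observed_until - config.severity_lead_hours
                frac = np.clip((t_axis - ramp_start)
                               / config.severity_lead_hours, 0.0, 1.0)
                mean_path += (config.severity_peak
                              - config.severity_admission_shift) * frac
        sev = _simulate_severity(rng, hours, mean_path)

        for spec in config.feature_catalog:
            t = rng.exponential(spec.interval_hours)
            times = []
            while t < observed_until:
                times.append(t)
                t += rng.exponential(spec.interval_hours)
            if not times:
                continue
            times_arr = np.array(times)
            sev_at = np.interp(times_arr, np.arange(hours + 1, dtype=float), sev)
            vals = (spec.healthy_mean
                    + spec.healthy_sd * (spec.loading * sev_at
                                         + config.noise_scale
                                         * rng.normal(size=len(times_arr))))
            obs_frames.append(pd.DataFrame({
                "encounter_id": eid,
                "timestamp": admit + pd.to_timedelta(
                    np.round(times_arr * 60.0) , unit="m"),
                "feature": spec.name,
                "value": np.round(vals, 4),
            }))
        enc_rows.append({
            "encounter_id": eid,
            "admit_ts": admit,
            "discharge_ts": discharge,
            "age": float(ages[i]),
            "sex": str(sexes[i]),
            "outcome_type": outcome,
            "outcome_ts": outcome_ts,
            "icu_return_ts": icu_return_ts,
        })

    encounters = pd.DataFrame(enc_rows, columns=ENCOUNTER_COLUMNS)
    for col in _TS_COLUMNS:  # whole seconds: survives ISO-8601 round trips
        encounters[col] = encounters[col].dt.round("s")
    if obs_frames:
        observations = pd.concat(obs_frames, ignore_index=True)
    else:
        observations = pd.DataFrame(columns=OBSERVATION_COLUMNS)
    observations = observations.sort_values(
        ["encounter_id", "timestamp", "feature"], kind="mergesort"
    ).reset_index(drop=True)
    # keep observations strictly inside the stay
    disch = encounters.set_index("encounter_id")["discharge_ts"]
    observations = observations[
        observations["timestamp"] <= observations["encounter_id"].map(disch)
    ].reset_index(drop=True)

    if config.artifact_rate > 0:
        observations = inject_artifacts(
            observations, config.artifact_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            catalog=config.feature_catalog,
        )
    return encounters, observations


def inject_artifacts(observations: pd.DataFrame, artifact_rate: float,
                     seed: int,
                     catalog: Sequence[FeatureSpec] | None = None
                     ) -> pd.DataFrame:
    """Corrupt a seeded fraction of observation values with catalog extremes.

    Each selected record's value is replaced by an artifact value drawn from
    its feature's catalog (all outside that feature's physiologic range).
    The input frame is not modified.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ConfigurationError("artifact_rate must lie in [0, 1]")
    out = observations.copy()
    if artifact_rate == 0.0 or out.empty:
        return out
    specs = {s.name: s for s in (catalog or default_feature_catalog())}
    rng = np.random.default_rng(seed)
    hit = rng.random(len(out)) < artifact_rate
    values = out["value"].to_numpy(dtype=float, copy=True)
    feats = out["feature"].to_numpy()
    for idx in np.flatnonzero(hit):
        spec = specs.get(feats[idx])
        if spec is None:
            lo, hi = 0.0, abs(values[idx]) * 10 + 1
            choices = _default_artifacts(lo, hi)
        else:
            choices = spec.artifact_values
        values[idx] = choices[rng.integers(0, len(choices))]
    out["value"] = values
    return out


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort(encounters: pd.DataFrame, observations: pd.DataFrame,
                 directory: str | Path) -> dict[str, Path]:
    """Write ``encounters.csv`` and ``observations.csv`` (ISO-8601 UTC)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    enc = encounters.copy()
    for col in _TS_COLUMNS:
        enc[col] = _to_iso(enc[col])
    obs = observations.copy()
    obs["timestamp"] = _to_iso(obs["timestamp"])
    enc_path = directory / "encounters.csv"
    obs_path = directory / "observations.csv"
    enc[ENCOUNTER_COLUMNS].to_csv(enc_path, index=False)
    obs[OBSERVATION_COLUMNS].to_csv(obs_path, index=False)
    return {"encounters": enc_path, "observations": obs_path}


def read_cohort(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`, validating schemas."""
    directory = Path(directory)
    enc = pd.read_csv(directory / "encounters.csv", dtype={"encounter_id": str})
    _require_columns(enc, ENCOUNTER_COLUMNS, "encounters.csv")
    for col in _TS_COLUMNS:
        enc[col] = _parse_ts(enc[col], col, "encounters.csv",
                             required=col in ("admit_ts", "discharge_ts"))
    obs = pd.read_csv(directory / "observations.csv",
                      dtype={"encounter_id": str, "feature": str})
    _require_columns(obs, OBSERVATION_COLUMNS, "observations.csv")
    obs["timestamp"] = _parse_ts(obs["timestamp"], "timestamp",
                                 "observations.csv", required=True)
    if not np.issubdtype(obs["value"].dtype, np.number):
        bad = obs.index[pd.to_numeric(obs["value"], errors="coerce").isna()]
        row = int(bad[0]) + 2 if len(bad) else "?"
        raise SchemaError(
            f"observations.csv: non-numeric 'value' at file row {row}")
    return enc, obs


def _to_iso(col: pd.Series) -> pd.Series:
    ts = pd.to_datetime(col, utc=True)
    out = ts.dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    return out.where(ts.notna(), "")


def _parse_ts(col: pd.Series, name: str, fname: str, required: bool) -> pd.Series:
    raw = col.fillna("").astype(str)
    parsed = pd.to_datetime(raw.where(raw != "", None), utc=True,
                            format="ISO8601", errors="coerce")
    bad = parsed.isna() & (raw != "")
    if required:
        bad |= raw == ""
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is row 1
        raise SchemaError(f"{fname}: unparseable '{name}' at file row {row}")
    return parsed


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Calibrated score cohorts (for threshold-calibration studies)


def simulate_calibrated_timelines(
    n_encounters: int, prevalence: float, seed: int,
    windows_per_encounter: int = 8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Encounter risk timelines whose maximum score is a calibrated probability.

    Each encounter draws a true deterioration probability p from a Beta
    distribution with the requested mean prevalence, receives a monotone
    timeline peaking at p, and an outcome label drawn Bernoulli(p) — so by
    construction P(outcome | max score = p) = p, the well-calibrated regime
    threshold calibration assumes.

    Returns a (timelines, outcomes) pair: timelines has columns
    ``encounter_id, window_index, score``; outcomes is a 0/1 Series indexed
    by encounter_id.
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    a = 0.5
    b = a * (1.0 - prevalence) / prevalence
    p = rng.beta(a, b, size=n_encounters)
    y = (rng.random(n_encounters) < p).astype(int)
    ids = [f"V{i + 1:05d}" for i in range(n_encounters)]
    frames = []
    for i, eid in enumerate(ids):
        k = windows_per_encounter
        ramp = np.linspace(0.2, 1.0, k) * p[i]
        frames.append(pd.DataFrame({
            "encounter_id": eid,
            "window_index": np.arange(k),
            "score": ramp,
        }))
    timelines = pd.concat(frames, ignore_index=True)
    outcomes = pd.Series(y, index=pd.Index(ids, name="encounter_id"),
                         name="outcome")
    return timelines, outcomes
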