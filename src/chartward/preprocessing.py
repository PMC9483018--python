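"""Raw tables -> model-ready 6-hour window feature matrix.

The transform chain, in order:

1. cohort exclusions (training only): drop stays shorter than 8 h or longer
   than 40 days;
2. assay conversion: piecewise rescaling of a lab after an assay change
   date (e.g. conventional -> high-sensitivity troponin);
3. windowing: one row per 6-hour interval from admission to the first of
   discharge or outcome, with within-window means, ``<feature>_measured``
   flags and ``<feature>_time_since_measured`` hours;
4. trimming + normalization: clip to the training 1st/99th percentiles and
   map linearly onto [0, 1] — data-entry artifacts (a temperature of 700)
   saturate at the boundary instead of poisoning the model;
5. imputation: last observation carried forward within an encounter, then
   training-mean imputation for leading gaps.

Normalization parameters are fitted on training data only and carried under
a content-hashed version tag so a model can refuse mismatched features.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from chartward.exceptions import ConfigurationError, SchemaError

WINDOW_HOURS = 6.0
MIN_STAY_HOURS = 8.0
MAX_STAY_DAYS = 40.0
LABEL_HORIZON_HOURS = 48.0

STATIC_COLUMNS = ["age", "sex"]
LABEL_COLUMNS = ["outcome_ever", "outcome_within_48h"]
INDEX_COLUMNS = ["encounter_id", "window_index"]


def apply_exclusions(encounters: pd.DataFrame, mode: str,
                     min_hours: float = MIN_STAY_HOURS,
                     max_days: float = MAX_STAY_DAYS) -> pd.DataFrame:
    """Apply cohort exclusion criteria.

    ``mode='train'`` drops encounters with length of stay strictly below
    ``min_hours`` or strictly above ``max_days`` (boundaries retained).
    ``mode='deploy'`` returns the input unchanged: exclusions are a
    training-set hygiene measure and are never applied at scoring time.
    """
    if mode not in ("train", "deploy"):
        raise ConfigurationError(f"mode must be 'train' or 'deploy', got {mode!r}")
    if mode == "deploy":
        return encounters
    los_h = (encounters["discharge_ts"] - encounters["admit_ts"]
             ).dt.total_seconds() / 3600.0
    if (los_h <= 0).any():
        raise SchemaError("encounters contain non-positive length of stay")
    keep = (los_h >= min_hours) & (los_h <= max_days * 24.0)
    return encounters[keep].reset_index(drop=True)


def convert_assay(observations: pd.DataFrame,
                  assay_map: Mapping[str, Sequence[tuple]] | None
                  ) -> pd.DataFrame:
    """Piecewise linear rescaling of lab values after assay change dates.

    ``assay_map`` maps feature name -> sequence of
    ``(effective_from, scale, offset)`` with strictly increasing
    effective-from timestamps. An observation at/after an effective-from
    timestamp gets ``scale * value + offset`` using the latest applicable
    entry. An empty or None map is the identity.
    """
    if not assay_map:
        return observations
    out = observations.copy()
    present = set(out["feature"].unique())
    for feat, entries in assay_map.items():
        if feat not in present:
            warnings.warn(f"assay map feature {feat!r} not in observations; ignored")
            continue
        times = [pd.Timestamp(e[0]) for e in entries]
        times = [t.tz_localize("UTC") if t.tzinfo is None else t for t in times]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigurationError(
                f"assay map for {feat!r}: effective-from timestamps must be "
                "strictly increasing")
        mask_feat = out["feature"] == feat
        ts = out.loc[mask_feat, "timestamp"]
        vals = out.loc[mask_feat, "value"].to_numpy(dtype=float, copy=True)
        for (eff, scale, offset), t0 in zip(entries, times):
            seg = (ts >= t0).to_numpy()
            vals[seg] = float(scale) * vals[seg] + float(offset)
        out.loc[mask_feat, "value"] = vals
    return out


# ---------------------------------------------------------------------------
# Windowing


def effective_end(encounter: Mapping) -> pd.Timestamp:
    """Observation horizon: the first of discharge or outcome timestamp."""
    end = encounter["discharge_ts"]
    out_ts = encounter.get("outcome_ts", pd.NaT)
    if pd.notna(out_ts) and out_ts < end:
        end = out_ts
    return end


def build_windows(encounter: Mapping, observations: pd.DataFrame,
                  features: Sequence[str],
                  as_of: pd.Timestamp | None = None) -> pd.DataFrame:
    """Aggregate one encounter's observations into 6-hour windows.

    Windows run from the admission timestamp to the first of discharge,
    outcome, or ``as_of`` (for mid-stay scoring); the final partial window is
    kept. Within-window duplicates are averaged. For each feature the output
    carries the raw window mean (NaN when unmeasured), a 0/1 ``_measured``
    flag and ``_time_since_measured`` — hours from the latest measurement at
    or before the window's end, or hours since admission if the feature has
    never been measured.

    Observations outside the stay are dropped with a warning.
    """
    admit = encounter["admit_ts"]
    end = effective_end(encounter)
    if as_of is not None and as_of < end:
        end = as_of
    if end <= admit:
        raise SchemaError(
            f"encounter {encounter['encounter_id']}: empty observation span")
    stay_h = (end - admit).total_seconds() / 3600.0
    n_windows = max(1, math.ceil(stay_h / WINDOW_HOURS - 1e-12))

    obs = observations
    if len(obs):
        hours = (obs["timestamp"] - admit).dt.total_seconds().to_numpy() / 3600.0
        outside = (hours < 0) | (
            obs["timestamp"] > encounter["discharge_ts"]).to_numpy()
        if outside.any():
            warnings.warn(
                f"encounter {encounter['encounter_id']}: dropped "
                f"{int(outside.sum())} observation(s) outside the stay")
        inside = ~outside
        obs = obs[inside]
        hours = hours[inside]
        horizon = hours <= stay_h + 1e-12  # beyond outcome/as_of: not modeled
        obs = obs[horizon]
        hours = hours[horizon]
    else:
        hours = np.empty(0)

    win_idx = np.arange(n_windows)
    win_end_h = np.minimum((win_idx + 1) * WINDOW_HOURS, stay_h)
    out = pd.DataFrame({
        "encounter_id": encounter["encounter_id"],
        "window_index": win_idx,
        "window_start": admit + pd.to_timedelta(win_idx * WINDOW_HOURS, unit="h"),
        "window_end": admit + pd.to_timedelta(win_end_h, unit="h"),
    })

    by_feature = {f: np.flatnonzero((obs["feature"] == f).to_numpy())
                  for f in features} if len(obs) else {f: np.empty(0, int)
                                                       for f in features}
    values = obs["value"].to_numpy(dtype=float) if len(obs) else np.empty(0)
    for f in features:
        idx = by_feature[f]
        t_f = np.sort(hours[idx]) if len(idx) else np.empty(0)
        w_of = np.minimum((hours[idx] // WINDOW_HOURS).astype(int), n_windows - 1) \
            if len(idx) else np.empty(0, int)
        sums = np.bincount(w_of, weights=values[idx], minlength=n_windows)
        counts = np.bincount(w_of, minlength=n_windows)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        measured = (counts > 0).astype(int)
        # latest measurement at or before each window end; never measured
        # falls back to hours since admission
        if len(t_f):
            pos = np.searchsorted(t_f, win_end_h + 1e-9) - 1
            last_t = np.where(pos >= 0, t_f[np.maximum(pos, 0)], 0.0)
            since = np.where(pos >= 0, win_end_h - last_t, win_end_h)
        else:
            since = win_end_h
        out[f] = means
        out[f + "_measured"] = measured
        out[f + "_time_since_measured"] = np.where(measured == 1, 0.0,
                                                   np.round(since, 6))

    out["age"] = float(encounter["age"])
    out["sex"] = 1.0 if str(encounter["sex"]).upper().startswith("M") else 0.0
    has_outcome = str(encounter.get("outcome_type", "none")) != "none" and \
        pd.notna(encounter.get("outcome_ts", pd.NaT))
    out["outcome_ever"] = int(has_outcome)
    if has_outcome:
        horizon_ok = (out["window_end"]
                      + pd.Timedelta(hours=LABEL_HORIZON_HOURS)
                      ) >= encounter["outcome_ts"]
        out["outcome_within_48h"] = horizon_ok.astype(int)
    else:
        out["outcome_within_48h"] = 0
    return out


def build_cohort_windows(encounters: pd.DataFrame, observations: pd.DataFrame,
                         features: Sequence[str],
                         as_of: pd.Timestamp | None = None) -> pd.DataFrame:
    """Windows for every encounter, concatenated."""
    grouped = dict(tuple(observations.groupby("encounter_id", sort=False)))
    empty = observations.iloc[0:0]
    frames = []
    for _, enc in encounters.iterrows():
        if as_of is not None and enc["admit_ts"] >= as_of:
            continue
        frames.append(build_windows(enc, grouped.get(enc["encounter_id"], empty),
                                    features, as_of=as_of))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class FeatureNorm:
    q01: float
    q99: float
    train_mean_normalized: float
    degenerate: bool = False


@dataclass
class NormalizationParams:
    """Training-set trimming percentiles and normalized means, versioned."""

    features: dict[str, FeatureNorm] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            self.version = self._content_hash()

    def _content_hash(self) -> str:
        payload = json.dumps(
            {k: [v.q01, v.q99, v.train_mean_normalized, v.degenerate]
             for k, v in sorted(self.features.items())},
            sort_keys=True)
        return "norm-" + hashlib.sha1(payload.encode()).hexdigest()[:10]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "version": self.version,
            "features": {k: {"q01": v.q01, "q99": v.q99,
                             "train_mean_normalized": v.train_mean_normalized,
                             "degenerate": v.degenerate}
                         for k, v in self.features.items()},
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return cls(features={k: FeatureNorm(**v) for k, v in d["features"].items()},
                   version=d["version"])

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)


def fit_normalization(windows: pd.DataFrame,
                      features: Sequence[str]) -> NormalizationParams:
    """Fit per-feature 1st/99th percentiles and normalized training means.

    Percentiles use linear interpolation over the *measured* window values
    (imputed cells never enter). A constant feature is flagged degenerate
    and will normalize to 0.5 with a warning.
    """
    params: dict[str, FeatureNorm] = {}
    for f in features:
        measured = windows[windows[f + "_measured"] == 1][f].to_numpy(dtype=float)
        measured = measured[~np.isnan(measured)]
        if len(measured) < 2:
            raise ConfigurationError(
                f"feature {f!r}: need >= 2 measured values to fit normalization")
        q01, q99 = np.percentile(measured, [1.0, 99.0])
        if q01 == q99:
            warnings.warn(f"feature {f!r} is constant on training data; "
                          "normalizing to 0.5")
            params[f] = FeatureNorm(float(q01), float(q99), 0.5, degenerate=True)
            continue
        norm = (np.clip(measured, q01, q99) - q01) / (q99 - q01)
        params[f] = FeatureNorm(float(q01), float(q99), float(norm.mean()))
    return NormalizationParams(features=params)


def normalize(value, feature: str, params: NormalizationParams):
    """Clip to [q01, q99], then map linearly onto [0, 1]. Vectorized."""
    if feature not in params.features:
        raise KeyError(f"no normalization parameters for feature {feature!r}")
    p = params.features[feature]
    arr = np.asarray(value, dtype=float)
    if p.degenerate:
        out = np.where(np.isnan(arr), np.nan, 0.5)
    else:
        out = (np.clip(arr, p.q01, p.q99) - p.q01) / (p.q99 - p.q01)
    return float(out) if np.isscalar(value) else out


def normalize_windows(windows: pd.DataFrame,
                      params: NormalizationParams) -> pd.DataFrame:
    out = windows.copy()
    for f in params.feature_names:
        out[f] = normalize(out[f].to_numpy(dtype=float), f, params)
    return out


def impute(windows: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """LOCF within encounter then training-mean fill; leaves no missing cells.

    Expects normalized windows sorted by encounter and window index. The
    ``_measured`` and ``_time_since_measured`` descriptors are untouched.
    Idempotent.
    """
    out = windows.sort_values(INDEX_COLUMNS, kind="mergesort").reset_index(drop=True)
    grp = out.groupby("encounter_id", sort=False)
    for f in params.feature_names:
        out[f] = grp[f].ffill()
        out[f] = out[f].fillna(params.features[f].train_mean_normalized)
    return out


def preprocess_cohort(encounters: pd.DataFrame, observations: pd.DataFrame,
                      features: Sequence[str] | None = None,
                      params: NormalizationParams | None = None,
                      mode: str = "deploy",
                      assay_map: Mapping | None = None,
                      as_of: pd.Timestamp | None = None
                      ) -> tuple[pd.DataFrame, NormalizationParams]:
    """Full chain: exclusions -> assay -> windows -> normalize -> impute.

    When ``params`` is None (training), normalization is fitted on the
    windowed data and returned alongside the matrix.
    """
    if features is None:
        if params is not None:
            features = params.feature_names
        else:
            features = sorted(observations["feature"].unique())
    encounters = apply_exclusions(encounters, mode)
    observations = convert_assay(observations, assay_map)
    windows = build_cohort_windows(encounters, observations, features,
                                   as_of=as_of)
    if windows.empty:
        return windows, params if params is not None else NormalizationParams()
    if params is None:
        params = fit_normalization(windows, features)
    windows = normalize_windows(windows, params)
    windows = impute(windows, params)
    windows.attrs["normalization_version"] = params.version
    return windows, params


def model_matrix(windows: pd.DataFrame, features: Sequence[str]
                 ) -> tuple[np.ndarray, list[str]]:
    """Assemble the numeric design matrix MARS consumes."""
    cols: list[str] = []
    for f in features:
        cols += [f, f + "_measured", f + "_time_since_measured"]
    cols += STATIC_COLUMNS
    X = windows[cols].to_numpy(dtype=float)
    return X, cols
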