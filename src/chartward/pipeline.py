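"""Hourly batch loop, replayed over simulated time.

Each cycle attempts a fresh extract of the ward census and observations as
of the clock time. If extraction fails, the previous extract is reused as
long as it is at most 3 h old (``stale_ok``); beyond that the cycle is
declared unplanned downtime and a notification payload is emitted, with a
recovery notification on the next successful cycle. Planned downtime
windows in the scenario are recorded without notification spam (a single
pre-announced payload per window).

On a successful cycle the pipeline preprocesses each admitted patient's
data up to the clock time, scores them with the fitted two-stage model,
assigns risk groups, steps the alert engine, and emits the scheduled
communications (twice-daily charge-nurse census, daily palliative digest).
Replays are pure functions of (cohort, scenario, config) — no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from chartward.alerting import (
    AlertEngine,
    AlertEvent,
    CommunicationPayload,
    alerts_to_frame,
    build_charge_nurse_census,
    build_palliative_digest,
)
from chartward.calibration import RiskThresholds, assign_risk_group
from chartward.evaluation import evaluation_report
from chartward.exceptions import ConfigurationError, VersionMismatchError
from chartward.preprocessing import (
    NormalizationParams,
    build_cohort_windows,
    effective_end,
    impute,
    normalize_windows,
)
from chartward.timeaware import TimeAwareResults


class ExtractionFault(RuntimeError):
    """The hourly extract from the source systems failed."""


def _parse_window(w) -> tuple[pd.Timestamp, pd.Timestamp]:
    start, end = pd.Timestamp(w["start"]), pd.Timestamp(w["end"])
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    if end.tzinfo is None:
        end = end.tz_localize("UTC")
    if end <= start:
        raise ConfigurationError(f"fault window end {end} <= start {start}")
    return start, end


@dataclass
class Scenario:
    """Replay fault-injection schedule.

    ``planned`` windows switch the pipeline off (maintenance);
    ``extract_faults`` make the hourly extract fail, exercising the
    stale-cache fallback. Windows may not overlap one another.
    """

    planned: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    extract_faults: list[tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list)

    def __post_init__(self) -> None:
        wins = sorted(list(self.planned) + list(self.extract_faults))
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            if b0 < a1:
                raise ConfigurationError(
                    f"overlapping fault windows: [{a0}, {a1}) and [{b0}, {b1})")

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(planned=[_parse_window(w) for w in d.get("planned", [])],
                   extract_faults=[_parse_window(w)
                                   for w in d.get("extract_faults", [])])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @staticmethod
    def _overlap_hours(windows, t: pd.Timestamp) -> float:
        t1 = t + pd.Timedelta(hours=1)
        total = 0.0
        for a, b in windows:
            lo, hi = max(a, t), min(b, t1)
            if hi > lo:
                total += (hi - lo).total_seconds() / 3600.0
        return total

    def planned_at(self, t: pd.Timestamp) -> bool:
        return any(a <= t < b for a, b in self.planned)

    def faulted_at(self, t: pd.Timestamp) -> bool:
        return any(a <= t < b for a, b in self.extract_faults)


@dataclass
class ExtractCache:
    snapshot_ts: pd.Timestamp
    census: pd.DataFrame
    observations: pd.DataFrame

    def age_hours(self, t: pd.Timestamp) -> float:
        return (t - self.snapshot_ts).total_seconds() / 3600.0


class CohortSource:
    """Replay data source over a synthetic cohort, with fault injection."""

    def __init__(self, encounters: pd.DataFrame, observations: pd.DataFrame,
                 scenario: Scenario | None = None):
        self.encounters = encounters.reset_index(drop=True)
        self.observations = observations.sort_values("timestamp",
                                                     kind="mergesort")
        self.scenario = scenario or Scenario()

    def on_ward(self, t: pd.Timestamp) -> pd.DataFrame:
        e = self.encounters
        mask = (e["admit_ts"] <= t) & (t < e["discharge_ts"])
        away = (e["outcome_type"] == "icu") & e["icu_return_ts"].notna() & \
            (e["outcome_ts"] <= t) & (t < e["icu_return_ts"])
        return e[mask & ~away]

    def extract(self, t: pd.Timestamp) -> ExtractCache:
        if self.scenario.faulted_at(t):
            raise ExtractionFault(f"extract failed at {t}")
        census = self.on_ward(t)
        obs = self.observations[
            (self.observations["timestamp"] <= t)
            & self.observations["encounter_id"].isin(census["encounter_id"])]
        return ExtractCache(t, census, obs)


@dataclass
class CycleResult:
    timestamp: pd.Timestamp
    status: str  # ok | stale_ok | down_planned | down_unplanned
    n_scored: int
    alerts: list[AlertEvent] = field(default_factory=list)
    comms: list[CommunicationPayload] = field(default_factory=list)
    notifications: list[dict] = field(default_factory=list)
    down_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.status.startswith("down") and self.n_scored:
            raise ConfigurationError("a down cycle cannot have scored patients")


class Pipeline:
    """Holds the fitted model, thresholds, alert engine and cycle state."""

    def __init__(self, model: TimeAwareResults, thresholds: RiskThresholds,
                 norm_params: NormalizationParams,
                 engine: AlertEngine | None = None,
                 census_times: tuple[int, ...] = (7, 19),
                 digest_time: int = 8, stale_max_h: float = 3.0):
        if model.normalization_version != norm_params.version:
            raise VersionMismatchError(
                f"model normalization {model.normalization_version!r} != "
                f"params version {norm_params.version!r}")
        self.model = model
        self.thresholds = thresholds
        self.params = norm_params
        self.engine = engine or AlertEngine()
        self.census_times = census_times
        self.digest_time = digest_time
        self.stale_max_h = stale_max_h
        self.cache: ExtractCache | None = None
        self._in_unplanned_down = False
        self._announced_planned: set[pd.Timestamp] = set()
        self._current_groups: dict[str, str] = {}

    # -- scoring -----------------------------------------------------------

    def _score_census(self, cache: ExtractCache, t: pd.Timestamp
                      ) -> dict[str, str]:
        census = cache.census
        if census.empty:
            return {}
        windows = build_cohort_windows(census, cache.observations,
                                       self.model.base_features, as_of=t)
        if windows.empty:
            return {}
        windows = normalize_windows(windows, self.params)
        windows = impute(windows, self.params)
        windows.attrs["normalization_version"] = self.params.version
        risk = self.model.predict_risk(windows)
        latest = risk.loc[risk.groupby("encounter_id")["window_index"].idxmax()]
        return {row["encounter_id"]: assign_risk_group(row["risk"],
                                                       self.thresholds)
                for _, row in latest.iterrows()}

    # -- one hourly cycle ----------------------------------------------------

    def run_cycle(self, t: pd.Timestamp, source: CohortSource) -> CycleResult:
        scenario = source.scenario
        if scenario.planned_at(t):
            notes = []
            for a, b in scenario.planned:
                if a <= t < b and a not in self._announced_planned:
                    self._announced_planned.add(a)
                    notes.append({"kind": "planned_downtime", "timestamp": t,
                                  "message": f"planned downtime {a} to {b}"})
            return CycleResult(t, "down_planned", 0, notifications=notes,
                               down_hours=Scenario._overlap_hours(
                                   scenario.planned, t))
        try:
            self.cache = source.extract(t)
            status = "ok"
        except ExtractionFault:
            if (self.cache is not None
                    and self.cache.age_hours(t) <= self.stale_max_h):
                status = "stale_ok"
            else:
                notes = []
                if not self._in_unplanned_down:
                    self._in_unplanned_down = True
                    notes.append({"kind": "unplanned_downtime", "timestamp": t,
                                  "message": "pipeline extract failed and "
                                             "cache is too stale"})
                return CycleResult(t, "down_unplanned", 0,
                                   notifications=notes,
                                   down_hours=Scenario._overlap_hours(
                                       scenario.extract_faults, t))
        notes = []
        if self._in_unplanned_down:
            self._in_unplanned_down = False
            notes.append({"kind": "recovery", "timestamp": t,
                          "message": "pipeline recovered"})

        groups = self._score_census(self.cache, t)
        # per-encounter state resets at discharge (not during a temporary
        # ICU absence, whose silence rule needs the state kept)
        e = source.encounters
        disch = e.set_index("encounter_id")["discharge_ts"]
        for pid in set(self._current_groups) - set(groups):
            if pid in disch.index and disch[pid] <= t:
                self.engine.discharge(pid)
        self._current_groups = groups

        prev = t - pd.Timedelta(hours=1)
        returns = e[e["icu_return_ts"].notna()
                    & (e["icu_return_ts"] > prev)
                    & (e["icu_return_ts"] <= t)]["encounter_id"].tolist()
        alerts = self.engine.step(groups, returns, t)

        comms: list[CommunicationPayload] = []
        if t.minute == 0 and t.hour in self.census_times:
            comms.append(build_charge_nurse_census(groups, t))
        if t.minute == 0 and t.hour == self.digest_time:
            comms.append(build_palliative_digest(
                self.engine.first_high_times(), t))
        return CycleResult(t, status, len(groups), alerts=alerts,
                           comms=comms, notifications=notes)


def replay(encounters: pd.DataFrame, observations: pd.DataFrame,
           model: TimeAwareResults, thresholds: RiskThresholds,
           norm_params: NormalizationParams, scenario: Scenario | None = None,
           start: pd.Timestamp | None = None, hours: int = 24 * 30,
           engine: AlertEngine | None = None,
           census_times: tuple[int, ...] = (7, 19), digest_time: int = 8,
           ) -> dict:
    """Iterate the hourly cycle over a period against a synthetic cohort.

    Returns a dict with the alert log, communication payloads, notification
    payloads, the hour-by-hour run log (feeding the uptime metric), and the
    list of per-cycle results.
    """
    scenario = scenario or Scenario()
    source = CohortSource(encounters, observations, scenario)
    pipe = Pipeline(model, thresholds, norm_params, engine=engine,
                    census_times=census_times, digest_time=digest_time)
    if start is None:
        start = encounters["admit_ts"].min().floor("h")
    results: list[CycleResult] = []
    for h in range(hours):
        t = start + pd.Timedelta(hours=h)
        results.append(pipe.run_cycle(t, source))
    run_log = pd.DataFrame({
        "timestamp": [r.timestamp for r in results],
        "status": [r.status for r in results],
        "down_hours": [r.down_hours for r in results],
        "n_scored": [r.n_scored for r in results],
    })
    alert_log = alerts_to_frame([a for r in results for a in r.alerts])
    comms = [c for r in results for c in r.comms]
    notifications = [n for r in results for n in r.notifications]
    return {"run_log": run_log, "alert_log": alert_log, "comms": comms,
            "notifications": notifications, "cycles": results}


def replay_report(replay_out: dict, encounters: pd.DataFrame,
                  windows: pd.DataFrame, risk: pd.DataFrame,
                  thresholds: RiskThresholds,
                  vitals: pd.DataFrame | None = None) -> dict:
    """Evaluation report over a finished replay's logs."""
    run_log = replay_out["run_log"]
    dr = (run_log["timestamp"].iloc[0], run_log["timestamp"].iloc[-1])
    return evaluation_report(risk, windows, encounters, thresholds,
                             alert_log=replay_out["alert_log"],
                             vitals=vitals, run_log=run_log, date_range=dr)
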