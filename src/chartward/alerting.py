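"""Alert engine with fatigue-suppression rules and communication payloads.

A "High risk" classification triggers a page to the team and charge-nurse
phones only when every suppression predicate passes:

1. the patient is High risk at this step;
2. the patient was not already High at the previous step (alerts fire on
   *transitions into* High, including the first classification);
3. at least 48 h have passed since the patient's last alert — a transition
   inside that window does not re-arm early;
4. fewer than 5 alerts have already fired for the patient (cap
   configurable, introduced after deployment feedback);
5. the patient is not inside the 24-h silence that follows a return from
   the ICU.

Suppressed patients keep displaying as High risk in the census email and
sign-out feed; suppression governs pages only. State is per encounter and
resets at discharge.

Two scheduled communication payloads are built here as pure functions: the
twice-daily charge-nurse census (all ward patients with risk groups, High
first) and the daily palliative-care digest (patients whose first-ever
High classification fell in the past 24 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from chartward.exceptions import ConfigurationError

CHANNELS = ("team_phone", "charge_nurse_phone")

PAGER_TEMPLATE = ("[{last}, {first}, {mrn}] is high risk for transfer to ICU "
                  "or death. Please refer to {link} for more information.")

GROUP_ORDER = {"High": 0, "Medium": 1, "Low": 2}


def format_pager_message(last_name: str, first_name: str, mrn: str,
                         link: str = "LINK") -> str:
    """Exact pager text for a High-risk alert."""
    for nm, v in (("last name", last_name), ("first name", first_name),
                  ("MRN", mrn)):
        if not v:
            raise ConfigurationError(f"pager message requires a non-empty {nm}")
    return PAGER_TEMPLATE.format(last=last_name, first=first_name, mrn=mrn,
                                 link=link)


@dataclass
class AlertState:
    """Per-patient suppression bookkeeping."""

    last_alert_ts: pd.Timestamp | None = None
    alert_count: int = 0
    last_group: str = "unseen"
    icu_silence_until: pd.Timestamp | None = None
    first_high_ts: pd.Timestamp | None = None


@dataclass(frozen=True)
class AlertEvent:
    patient_id: str
    timestamp: pd.Timestamp
    message: str
    channel: str


@dataclass(frozen=True)
class CommunicationPayload:
    kind: str  # charge_nurse_census | palliative_digest
    timestamp: pd.Timestamp
    rows: tuple


class AlertEngine:
    """Stateful, deterministic alert-suppression engine.

    Parameters
    ----------
    suppression_h : float
        Minimum hours between two alerts for one patient (rule 3).
    icu_silence_h : float
        Silence after a return from the ICU (rule 5).
    max_alerts : int or None
        Per-patient alert cap (rule 4); None disables the cap
        (pre-cap behavior).
    link_url : str
        Substituted into the pager template.
    identity : callable, optional
        Maps patient id -> (last, first, mrn) for message formatting;
        defaults to using the id for all three fields.
    """

    def __init__(self, suppression_h: float = 48.0, icu_silence_h: float = 24.0,
                 max_alerts: int | None = 5, link_url: str = "LINK",
                 identity: Callable[[str], tuple[str, str, str]] | None = None):
        self.suppression_h = suppression_h
        self.icu_silence_h = icu_silence_h
        self.max_alerts = max_alerts
        self.link_url = link_url
        self.identity = identity or (lambda pid: (pid, pid, pid))
        self.states: dict[str, AlertState] = {}
        self._last_t: pd.Timestamp | None = None

    def state(self, patient_id: str) -> AlertState:
        return self.states.setdefault(patient_id, AlertState())

    def discharge(self, patient_id: str) -> None:
        """Drop per-encounter state when the patient leaves the ward."""
        self.states.pop(patient_id, None)

    def step(self, classifications: Mapping[str, str],
             icu_returns: Iterable[str], t: pd.Timestamp
             ) -> list[AlertEvent]:
        """Advance the engine one time step; returns the alerts fired at t.

        Each firing is delivered on both phone channels (two events, one
        logical alert). ``icu_returns`` lists patients who came back from
        the ICU at this step.
        """
        t = pd.Timestamp(t)
        if self._last_t is not None and t <= self._last_t:
            raise ConfigurationError(
                f"time regression: step at {t} after {self._last_t}")
        self._last_t = t
        for pid in icu_returns:
            self.state(pid).icu_silence_until = (
                t + pd.Timedelta(hours=self.icu_silence_h))
        events: list[AlertEvent] = []
        for pid in sorted(classifications):
            group = classifications[pid]
            if group not in GROUP_ORDER:
                raise ConfigurationError(f"unknown risk group {group!r}")
            st = self.state(pid)
            if group == "High" and st.first_high_ts is None:
                st.first_high_ts = t
            fire = (
                group == "High"
                and st.last_group != "High"
                and (st.last_alert_ts is None
                     or t >= st.last_alert_ts
                     + pd.Timedelta(hours=self.suppression_h))
                and (self.max_alerts is None
                     or st.alert_count < self.max_alerts)
                and (st.icu_silence_until is None
                     or t >= st.icu_silence_until)
            )
            if fire:
                st.last_alert_ts = t
                st.alert_count += 1
                last, first, mrn = self.identity(pid)
                msg = format_pager_message(last, first, mrn, self.link_url)
                for ch in CHANNELS:
                    events.append(AlertEvent(pid, t, msg, ch))
            st.last_group = group
        return events

    def first_high_times(self) -> dict[str, pd.Timestamp]:
        return {pid: st.first_high_ts for pid, st in self.states.items()
                if st.first_high_ts is not None}


def step_alert_engine(engine: AlertEngine, classifications: Mapping[str, str],
                      icu_returns: Iterable[str], t) -> list[AlertEvent]:
    """Functional wrapper over :meth:`AlertEngine.step`."""
    return engine.step(classifications, icu_returns, t)


def build_charge_nurse_census(census: Mapping[str, str], t
                              ) -> CommunicationPayload:
    """Twice-daily census email: every ward patient with their risk group,
    sorted High -> Medium -> Low, then by patient id."""
    rows = tuple(sorted(census.items(),
                        key=lambda kv: (GROUP_ORDER.get(kv[1], 9), kv[0])))
    rows = tuple((pid, grp) for pid, grp in rows)
    return CommunicationPayload("charge_nurse_census", pd.Timestamp(t), rows)


def build_palliative_digest(first_high_ts: Mapping[str, pd.Timestamp], t
                            ) -> CommunicationPayload:
    """Daily digest: patients whose first-ever High classification occurred
    in the window (t - 24 h, t]."""
    t = pd.Timestamp(t)
    lo = t - pd.Timedelta(hours=24)
    rows = tuple(sorted((pid, ts) for pid, ts in first_high_ts.items()
                        if ts is not None and lo < ts <= t))
    return CommunicationPayload("palliative_digest", t, rows)


def alerts_to_frame(events: Iterable[AlertEvent]) -> pd.DataFrame:
    """Alert log as a DataFrame (patient id, timestamp, channel, message)."""
    rows = [{"patient_id": e.patient_id, "timestamp": e.timestamp,
             "channel": e.channel, "message": e.message} for e in events]
    if not rows:
        return pd.DataFrame(columns=["patient_id", "timestamp", "channel",
                                     "message"])
    return pd.DataFrame(rows)
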