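"""Deployment performance and process measures.

Model metrics: window-level AUC for the "ever during stay" and "within the
next 48 h" labelings; encounter-level PPV of alerted visits; sensitivity
partitioned by each visit's maximum risk group. Process metrics: daily
alert volume, weekly adherence (vital-sign assessments after an alert),
and pipeline uptime with planned/unplanned downtime shares.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from chartward import calibration
from chartward.calibration import RiskThresholds, assign_risk_group
from chartward.exceptions import ConfigurationError

OUTCOME_COMPOSITES = {
    "icu_death": {"icu", "death"},
    "icu_death_stepup_palliative": {"icu", "death", "stepup", "palliative"},
}


def compute_auc(scores, labels) -> float | None:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2.

    Returns None with a warning when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("AUC undefined: one class absent")
        return None
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def ppv_alerted_encounters(timelines: pd.DataFrame, outcomes: pd.Series,
                           thr_high: float,
                           score_col: str | None = None) -> float | None:
    """Encounter-level PPV of alerted visits.

    Identical, by construction, to the calibration module's visit-level PPV
    (single definition, single implementation).
    """
    return calibration.visit_level_ppv(timelines, outcomes, thr_high,
                                       score_col=score_col)


def sensitivity_by_max_group(timelines: pd.DataFrame, outcomes: pd.Series,
                             thresholds: RiskThresholds,
                             score_col: str | None = None
                             ) -> dict[str, float]:
    """Among outcome encounters, the share whose maximum group was High /
    Medium / Low. The three shares partition outcome visits and sum to 1."""
    mx = calibration.encounter_max_scores(timelines, score_col)
    y = outcomes.reindex(mx.index)
    if y.isna().any():
        raise ConfigurationError("every timeline needs an outcome label")
    pos = mx[y.astype(int) == 1]
    if len(pos) == 0:
        raise ConfigurationError("no outcome encounters: sensitivity undefined")
    groups = pd.Series(assign_risk_group(pos.to_numpy(), thresholds),
                       index=pos.index)
    return {g: float((groups == g).mean()) for g in calibration.RISK_GROUPS}


def alert_stats(alert_log: pd.DataFrame,
                date_range: tuple[pd.Timestamp, pd.Timestamp]) -> dict:
    """Daily alert-count statistics over a date range (zero days included).

    One alert *firing* per patient per timestamp is counted even when it is
    delivered on several channels.
    """
    start, end = (pd.Timestamp(d) for d in date_range)
    days = pd.date_range(start.normalize(), end.normalize(), freq="D",
                         tz=start.tz)
    if len(days) == 0:
        raise ConfigurationError("empty date range")
    if len(alert_log):
        fires = alert_log.drop_duplicates(subset=["patient_id", "timestamp"])
        counts = (fires["timestamp"].dt.normalize()
                  .value_counts().reindex(days, fill_value=0).sort_index())
    else:
        counts = pd.Series(0, index=days)
    c = counts.to_numpy(dtype=float)
    q25, q75 = np.percentile(c, [25, 75])
    return {
        "daily_counts": counts,
        "mean": float(c.mean()),
        "sd": float(c.std(ddof=1)) if len(c) > 1 else None,
        "median": float(np.median(c)),
        "iqr": (float(q25), float(q75)),
        "zero_alert_days": int((c == 0).sum()),
    }


def _alert_adherent(alert_ts: pd.Timestamp, vit: np.ndarray,
                    mode: str) -> bool:
    """vit: sorted vitals timestamps (ns since epoch) for this patient."""
    t0 = alert_ts.value
    t1 = (alert_ts + pd.Timedelta(hours=24)).value
    inside = vit[(vit > t0) & (vit <= t1)]
    if mode == "count":
        return len(np.unique(inside)) >= 4
    # strict: every gap in [alert, alert+24h], including the edges, <= 4 h
    four_h = int(4 * 3600 * 1e9)
    pts = np.concatenate([[t0], np.unique(inside), [t1]])
    return bool(len(inside) > 0 and np.diff(pts).max() <= four_h)


def adherence_weekly(alert_log: pd.DataFrame, vitals: pd.DataFrame,
                     mode: str = "count") -> pd.Series:
    """Weekly % of alerts followed by adequate vital-sign assessment.

    ``mode='count'`` (default): at least 4 distinct assessment timestamps in
    the 24 h after the alert. ``mode='strict'``: assessments at most 4 h
    apart throughout those 24 h (the full every-4-hours pathway). Strict
    adherence can never exceed count adherence.
    """
    if mode not in ("count", "strict"):
        raise ConfigurationError("mode must be 'count' or 'strict'")
    if alert_log.empty:
        return pd.Series(dtype=float)
    fires = alert_log.drop_duplicates(subset=["patient_id", "timestamp"])
    vit_by_pid = {
        pid: np.sort(g["timestamp"].astype("int64").to_numpy())
        for pid, g in vitals.groupby("encounter_id")
    }
    empty = np.empty(0, dtype=np.int64)
    adherent = [
        _alert_adherent(row["timestamp"], vit_by_pid.get(row["patient_id"],
                                                         empty), mode)
        for _, row in fires.iterrows()
    ]
    weeks = fires["timestamp"].dt.tz_localize(None).dt.to_period("W")
    df = pd.DataFrame({"week": weeks.to_numpy(), "ok": adherent})
    return df.groupby("week")["ok"].mean() * 100.0


def uptime(run_log: pd.DataFrame) -> dict:
    """Uptime percentage and planned/unplanned downtime shares.

    ``run_log`` has one row per hourly cycle: ``timestamp``, ``status`` in
    {up, stale_ok, down_planned, down_unplanned} and optionally
    ``down_hours`` (fraction of the hour actually lost; defaults to 1 for
    down statuses). Stale-cache cycles still produced outputs and count as
    up. Percentages are rounded to one decimal for reporting; shares are
    None when there was no downtime.
    """
    if run_log.empty:
        raise ConfigurationError("empty run log")
    ts = pd.to_datetime(run_log["timestamp"])
    gaps = ts.diff().dropna()
    if (gaps != pd.Timedelta(hours=1)).any():
        raise ConfigurationError("run log has gaps: cycles must be hourly")
    aliases = {"ok": "up", "up": "up", "stale_ok": "up",
               "planned_down": "down_planned", "down_planned": "down_planned",
               "unplanned_down": "down_unplanned",
               "down_unplanned": "down_unplanned"}
    bad = set(run_log["status"]) - set(aliases)
    if bad:
        raise ConfigurationError(f"unknown cycle status values: {sorted(bad)}")
    status = run_log["status"].map(aliases)
    down_mask = status.str.startswith("down")
    if "down_hours" in run_log.columns:
        down_h = run_log["down_hours"].where(down_mask, 0.0)
    else:
        down_h = down_mask.astype(float)
    total_h = float(len(run_log))
    planned_h = float(down_h[status == "down_planned"].sum())
    unplanned_h = float(down_h[status == "down_unplanned"].sum())
    down_total = planned_h + unplanned_h
    up_pct = round(100.0 * (total_h - down_total) / total_h, 1)
    if down_total == 0:
        return {"uptime_pct": up_pct, "planned_share_pct": None,
                "unplanned_share_pct": None, "down_hours": 0.0,
                "total_hours": total_h}
    return {
        "uptime_pct": up_pct,
        "planned_share_pct": round(100.0 * planned_h / down_total, 1),
        "unplanned_share_pct": round(100.0 * unplanned_h / down_total, 1),
        "down_hours": down_total,
        "total_hours": total_h,
    }


def composite_outcomes(encounters: pd.DataFrame,
                       composite: str = "icu_death_stepup_palliative"
                       ) -> pd.Series:
    """0/1 outcome labels per encounter under a named outcome composite."""
    if composite not in OUTCOME_COMPOSITES:
        raise ConfigurationError(f"unknown composite {composite!r}")
    members = OUTCOME_COMPOSITES[composite]
    y = encounters["outcome_type"].isin(members).astype(int)
    return pd.Series(y.to_numpy(), index=encounters["encounter_id"],
                     name="outcome")


def evaluation_report(risk: pd.DataFrame, windows: pd.DataFrame,
                      encounters: pd.DataFrame, thresholds: RiskThresholds,
                      alert_log: pd.DataFrame | None = None,
                      vitals: pd.DataFrame | None = None,
                      run_log: pd.DataFrame | None = None,
                      date_range=None) -> dict:
    """Full metric table over both outcome composites, plus process metrics.

    ``risk`` is the per-window output of ``predict_risk`` aligned with
    ``windows`` (which carries the label columns).
    """
    merged = risk.merge(
        windows[["encounter_id", "window_index", "outcome_within_48h"]],
        on=["encounter_id", "window_index"], how="left")
    report: dict = {"thresholds": {"thr_high": thresholds.thr_high,
                                   "thr_low": thresholds.thr_low}}
    for name in OUTCOME_COMPOSITES:
        y_enc = composite_outcomes(encounters, name)
        y_enc = y_enc[y_enc.index.isin(merged["encounter_id"].unique())]
        ever = merged["encounter_id"].map(y_enc).to_numpy()
        within = merged["outcome_within_48h"].to_numpy() * ever
        sub = {
            "auc_ever": compute_auc(merged["risk"], ever),
            "auc_48h": compute_auc(merged["risk"], within),
            "ppv_alerted": ppv_alerted_encounters(
                merged, y_enc, thresholds.thr_high, score_col="risk"),
        }
        try:
            sub["sensitivity_by_max_group"] = sensitivity_by_max_group(
                merged, y_enc, thresholds, score_col="risk")
        except ConfigurationError:
            sub["sensitivity_by_max_group"] = None
        report[name] = sub
    if alert_log is not None and date_range is not None:
        stats = alert_stats(alert_log, date_range)
        stats.pop("daily_counts")
        report["alerts"] = stats
    if alert_log is not None and vitals is not None and len(alert_log):
        weekly = adherence_weekly(alert_log, vitals)
        report["adherence_weekly_pct"] = {str(k): float(v)
                                          for k, v in weekly.items()}
    if run_log is not None and len(run_log):
        report["uptime"] = uptime(run_log)
    return report
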