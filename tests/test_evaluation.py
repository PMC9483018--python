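"""Performance/process metrics: AUC, PPV, max-group sensitivity, alerts,
adherence, uptime arithmetic."""

import numpy as np
import pandas as pd
import pytest

from chartward import calibration
from chartward.calibration import RiskThresholds
from chartward.evaluation import (
    adherence_weekly,
    alert_stats,
    composite_outcomes,
    compute_auc,
    ppv_alerted_encounters,
    sensitivity_by_max_group,
    uptime,
)
from chartward.exceptions import ConfigurationError

UTC = "UTC"


# -- AUC ---------------------------------------------------------------------


def test_perfectly_ranked_scores_give_auc_one():
    assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_random_labels_auc_near_half():
    rng = np.random.default_rng(0)
    s = rng.random(10_000)
    y = rng.integers(0, 2, 10_000)
    assert compute_auc(s, y) == pytest.approx(0.5, abs=0.02)


def test_small_fixture_pair_counting():
    # positives at 0.8, 0.4; negatives at 0.6, 0.3, 0.2, 0.4(tie)
    s = [0.8, 0.4, 0.6, 0.3, 0.2, 0.4]
    y = [1, 1, 0, 0, 0, 0]
    # concordant pairs: 0.8 beats all 4 (4); 0.4 beats 0.3, 0.2 (2);
    # tie 0.4 vs 0.4 contributes 1/2 -> (4 + 2 + 0.5) / 8
    assert compute_auc(s, y) == pytest.approx(6.5 / 8)


def test_auc_matches_bruteforce_pair_count():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(5, 50))
        s = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        num, den = 0.0, 0
        for i in range(n):
            for j in range(n):
                if y[i] == 1 and y[j] == 0:
                    den += 1
                    num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0)
        assert compute_auc(s, y) == pytest.approx(num / den)


def test_one_class_auc_absent():
    with pytest.warns(UserWarning):
        assert compute_auc([0.1, 0.9], [1, 1]) is None


# -- encounter-level PPV -----------------------------------------------------


def _tl(scores):
    return pd.DataFrame({"encounter_id": [f"V{i}" for i in range(len(scores))],
                         "window_index": 0, "score": scores})


def _y(labels):
    return pd.Series(list(labels),
                     index=pd.Index([f"V{i}" for i in range(len(labels))],
                                    name="encounter_id"))


def test_ppv_alerted_fixture():
    # 8 alerted encounters, 2 with outcomes -> 0.25
    tl = _tl([0.9] * 8 + [0.1] * 4)
    y = _y([1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0])
    assert ppv_alerted_encounters(tl, y, 0.5) == pytest.approx(0.25)


def test_ppv_no_alerts_absent():
    assert ppv_alerted_encounters(_tl([0.1]), _y([1]), 0.9) is None


def test_ppv_all_alerted_have_outcomes():
    assert ppv_alerted_encounters(_tl([0.9, 0.8]), _y([1, 1]), 0.5) == 1.0


def test_ppv_single_source_of_truth():
    """Evaluation and calibration compute the identical quantity."""
    rng = np.random.default_rng(9)
    tl = _tl(rng.random(60))
    y = _y(rng.integers(0, 2, 60))
    for thr in (0.2, 0.5, 0.8):
        assert ppv_alerted_encounters(tl, y, thr) == \
            calibration.visit_level_ppv(tl, y, thr)


# -- max-group sensitivity ---------------------------------------------------


THR = RiskThresholds(thr_high=0.6, thr_low=0.2)


def test_sensitivity_counting():
    # 10 outcome encounters: 5 max-High, 4 max-Medium, 1 max-Low
    scores = [0.9] * 5 + [0.4] * 4 + [0.1] + [0.5] * 10
    y = _y([1] * 10 + [0] * 10)
    out = sensitivity_by_max_group(_tl(scores), y, THR)
    assert out == {"High": 0.5, "Medium": 0.4, "Low": 0.1}


def test_all_outcomes_reach_high():
    out = sensitivity_by_max_group(_tl([0.9, 0.95]), _y([1, 1]), THR)
    assert out == {"High": 1.0, "Medium": 0.0, "Low": 0.0}


def test_sensitivity_partition_sums_to_one():
    rng = np.random.default_rng(1)
    for _ in range(10):
        n = int(rng.integers(3, 40))
        scores = rng.random(n)
        y = _y(np.clip(rng.integers(0, 2, n), 0, 1))
        if y.sum() == 0:
            continue
        out = sensitivity_by_max_group(_tl(scores), y, THR)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)


def test_zero_outcome_encounters_error():
    with pytest.raises(ConfigurationError):
        sensitivity_by_max_group(_tl([0.5]), _y([0]), THR)


# -- alert stats -------------------------------------------------------------


def _alert_log(day_counts, start="2022-01-01"):
    rows = []
    for d, k in enumerate(day_counts):
        for i in range(k):
            rows.append({"patient_id": f"P{d}_{i}",
                         "timestamp": pd.Timestamp(start, tz=UTC)
                         + pd.Timedelta(days=d, hours=i + 1),
                         "channel": "team_phone", "message": "m"})
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "channel",
                                       "message"])


def test_alert_stats_counting():
    log = _alert_log([2, 0, 4])
    out = alert_stats(log, (pd.Timestamp("2022-01-01", tz=UTC),
                            pd.Timestamp("2022-01-03", tz=UTC)))
    assert out["mean"] == pytest.approx(2.0)
    assert out["zero_alert_days"] == 1
    assert out["median"] == 2.0


def test_alert_stats_empty_log():
    out = alert_stats(_alert_log([]), (pd.Timestamp("2022-01-01", tz=UTC),
                                       pd.Timestamp("2022-01-05", tz=UTC)))
    assert out["mean"] == 0.0 and out["zero_alert_days"] == 5


def test_alert_stats_single_day_sd_absent():
    out = alert_stats(_alert_log([3]), (pd.Timestamp("2022-01-01", tz=UTC),
                                        pd.Timestamp("2022-01-01", tz=UTC)))
    assert out["sd"] is None


def test_alert_stats_counts_firings_not_channels():
    log = _alert_log([1])
    dup = pd.concat([log, log.assign(channel="charge_nurse_phone")],
                    ignore_index=True)
    out = alert_stats(dup, (pd.Timestamp("2022-01-01", tz=UTC),
                            pd.Timestamp("2022-01-01", tz=UTC)))
    assert out["mean"] == 1.0


def test_alert_stats_empty_range_errors():
    with pytest.raises(ConfigurationError):
        alert_stats(_alert_log([1]), (pd.Timestamp("2022-01-05", tz=UTC),
                                      pd.Timestamp("2022-01-01", tz=UTC)))


# -- adherence ---------------------------------------------------------------


def _vitals(pid, alert_ts, offsets_h):
    return pd.DataFrame({
        "encounter_id": pid,
        "timestamp": [alert_ts + pd.Timedelta(hours=h) for h in offsets_h],
        "feature": "heart_rate", "value": 80.0,
    })


def test_adherent_alert_six_vitals():
    t = pd.Timestamp("2022-01-03 10:00", tz=UTC)
    log = pd.DataFrame([{"patient_id": "P", "timestamp": t,
                         "channel": "team_phone", "message": "m"}])
    weekly = adherence_weekly(log, _vitals("P", t, [2, 5, 9, 13, 17, 21]))
    assert list(weekly) == [100.0]


def test_three_vitals_not_adherent_default_mode():
    t = pd.Timestamp("2022-01-03 10:00", tz=UTC)
    log = pd.DataFrame([{"patient_id": "P", "timestamp": t,
                         "channel": "team_phone", "message": "m"}])
    weekly = adherence_weekly(log, _vitals("P", t, [2, 5, 9]))
    assert list(weekly) == [0.0]


def test_weekly_percentage():
    t0 = pd.Timestamp("2022-01-03 08:00", tz=UTC)  # Monday
    rows, vit = [], []
    for i in range(4):
        t = t0 + pd.Timedelta(hours=6 * i)
        rows.append({"patient_id": f"P{i}", "timestamp": t,
                     "channel": "team_phone", "message": "m"})
        offs = [2, 6, 10, 14] if i < 3 else [2]
        vit.append(_vitals(f"P{i}", t, offs))
    weekly = adherence_weekly(pd.DataFrame(rows), pd.concat(vit))
    assert list(weekly) == [75.0]


def test_strict_mode_never_exceeds_default():
    rng = np.random.default_rng(2)
    t0 = pd.Timestamp("2022-01-03 08:00", tz=UTC)
    rows, vit = [], []
    for i in range(12):
        t = t0 + pd.Timedelta(hours=7 * i)
        rows.append({"patient_id": f"P{i}", "timestamp": t,
                     "channel": "team_phone", "message": "m"})
        offs = np.sort(rng.uniform(0.1, 23.9, size=rng.integers(0, 9)))
        if len(offs):
            vit.append(_vitals(f"P{i}", t, offs))
    log = pd.DataFrame(rows)
    vitals = pd.concat(vit)
    strict = adherence_weekly(log, vitals, mode="strict")
    default = adherence_weekly(log, vitals, mode="count")
    assert (strict <= default + 1e-9).all()


def test_strict_mode_every_four_hours_passes():
    t = pd.Timestamp("2022-01-03 10:00", tz=UTC)
    log = pd.DataFrame([{"patient_id": "P", "timestamp": t,
                         "channel": "team_phone", "message": "m"}])
    weekly = adherence_weekly(log, _vitals("P", t, [4, 8, 12, 16, 20, 24]),
                              mode="strict")
    assert list(weekly) == [100.0]


# -- uptime ------------------------------------------------------------------


def _run_log(n, down):
    """down: list of (index, status, hours)."""
    status = np.array(["up"] * n, dtype=object)
    down_h = np.zeros(n)
    for i, s, h in down:
        status[i] = s
        down_h[i] = h
    return pd.DataFrame({
        "timestamp": pd.date_range("2020-08-01", periods=n, freq="h", tz=UTC),
        "status": status, "down_hours": down_h})


def test_uptime_printed_deployment_arithmetic():
    """52.5 down-hours of 14,016 -> 99.6% uptime; 20 planned of 52.5 ->
    38.1% / 61.9% shares."""
    down = [(i, "down_planned", 1.0) for i in range(20)]
    down += [(100 + i, "down_unplanned", 1.0) for i in range(32)]
    down += [(132, "down_unplanned", 0.5)]
    out = uptime(_run_log(14_016, down))
    assert out["uptime_pct"] == 99.6
    assert out["planned_share_pct"] == 38.1
    assert out["unplanned_share_pct"] == 61.9
    assert out["down_hours"] == 52.5


def test_uptime_zero_downtime():
    out = uptime(_run_log(48, []))
    assert out["uptime_pct"] == 100.0
    assert out["planned_share_pct"] is None


def test_uptime_gap_in_log_errors():
    log = _run_log(10, [])
    log = log.drop(index=4).reset_index(drop=True)
    with pytest.raises(ConfigurationError, match="gap"):
        uptime(log)


# -- outcome composites ------------------------------------------------------


def test_composite_outcomes():
    enc = pd.DataFrame({
        "encounter_id": list("abcde"),
        "outcome_type": ["none", "death", "icu", "stepup", "palliative"],
    })
    narrow = composite_outcomes(enc, "icu_death")
    broad = composite_outcomes(enc, "icu_death_stepup_palliative")
    assert list(narrow) == [0, 1, 1, 0, 0]
    assert list(broad) == [0, 1, 1, 1, 1]
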