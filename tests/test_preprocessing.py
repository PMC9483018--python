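"""Windowing, trimming/normalization, imputation, exclusions, assay shifts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chartward.preprocessing import (
    FeatureNorm,
    NormalizationParams,
    apply_exclusions,
    build_windows,
    convert_assay,
    fit_normalization,
    impute,
    normalize,
    normalize_windows,
    preprocess_cohort,
)
from chartward.synthetic import SimConfig, simulate_cohort

UTC = "UTC"


def _enc(stay_hours, outcome_ts=None, eid="E1"):
    admit = pd.Timestamp("2022-01-01 00:00", tz=UTC)
    return {
        "encounter_id": eid,
        "admit_ts": admit,
        "discharge_ts": admit + pd.Timedelta(hours=stay_hours),
        "age": 70.0,
        "sex": "F",
        "outcome_type": "none" if outcome_ts is None else "death",
        "outcome_ts": outcome_ts if outcome_ts is not None else pd.NaT,
        "icu_return_ts": pd.NaT,
    }


def _obs(eid, hour_value_pairs, feature="heart_rate"):
    admit = pd.Timestamp("2022-01-01 00:00", tz=UTC)
    return pd.DataFrame({
        "encounter_id": eid,
        "timestamp": [admit + pd.Timedelta(hours=h) for h, _ in hour_value_pairs],
        "feature": feature,
        "value": [v for _, v in hour_value_pairs],
    })


# -- exclusions --------------------------------------------------------------


@pytest.mark.parametrize("stay_h,mode,kept", [
    (6, "train", False),     # below the 8-h floor
    (6, "deploy", True),     # exclusions never apply at scoring time
    (8, "train", True),      # boundary retained
    (40 * 24, "train", True),   # boundary retained
    (40 * 24 + 1, "train", False),  # above the 40-day ceiling
    (100, "train", True),
])
def test_exclusion_rules(stay_h, mode, kept):
    enc = pd.DataFrame([_enc(stay_h)])
    out = apply_exclusions(enc, mode)
    assert (len(out) == 1) is kept


# -- windowing ---------------------------------------------------------------


def test_window_count_is_ceiling_of_stay_over_six():
    win = build_windows(_enc(13), _obs("E1", [(1, 80)]), ["heart_rate"])
    assert len(win) == 3  # ceil(13/6): two full windows + one partial
    assert list(win["window_index"]) == [0, 1, 2]


def test_within_window_mean():
    win = build_windows(_enc(13), _obs("E1", [(1, 80), (5, 90)]),
                        ["heart_rate"])
    assert win.loc[0, "heart_rate"] == 85.0
    assert win.loc[0, "heart_rate_measured"] == 1
    assert win.loc[0, "heart_rate_time_since_measured"] == 0.0


def test_hours_since_measured_references_window_end():
    # last measurement at hour 5; window 1 ends at hour 12 -> 7 h stale
    win = build_windows(_enc(13), _obs("E1", [(1, 80), (5, 90)]),
                        ["heart_rate"])
    assert win.loc[1, "heart_rate_measured"] == 0
    assert win.loc[1, "heart_rate_time_since_measured"] == 7.0
    assert np.isnan(win.loc[1, "heart_rate"])


def test_never_measured_uses_hours_since_admission():
    win = build_windows(_enc(13), _obs("E1", [])[0:0], ["heart_rate"])
    assert (win["heart_rate_measured"] == 0).all()
    assert list(win["heart_rate_time_since_measured"]) == [6.0, 12.0, 13.0]


def test_windows_stop_at_outcome():
    admit = pd.Timestamp("2022-01-01 00:00", tz=UTC)
    enc = _enc(30, outcome_ts=admit + pd.Timedelta(hours=14))
    win = build_windows(enc, _obs("E1", [(1, 80)]), ["heart_rate"])
    assert len(win) == 3  # ceil(14/6), not ceil(30/6)
    assert win["outcome_ever"].eq(1).all()
    assert win.loc[2, "outcome_within_48h"] == 1  # final window always labeled


def test_observation_outside_stay_warns_and_is_dropped():
    obs = _obs("E1", [(1, 80), (-2, 99)])
    with pytest.warns(UserWarning, match="outside the stay"):
        win = build_windows(_enc(13), obs, ["heart_rate"])
    assert win.loc[0, "heart_rate"] == 80.0


def test_label_consistency(prepped):
    windows, _ = prepped
    assert (windows.loc[windows["outcome_within_48h"] == 1, "outcome_ever"]
            == 1).all()
    last = windows.loc[windows.groupby("encounter_id")["window_index"].idxmax()]
    outcome_last = last[last["outcome_ever"] == 1]
    assert (outcome_last["outcome_within_48h"] == 1).all()


# -- normalization -----------------------------------------------------------


def _params(q01=34.8, q99=38.3, mean=0.5, feature="temperature"):
    return NormalizationParams(features={feature: FeatureNorm(q01, q99, mean)})


def test_percentiles_linear_interpolation():
    vals = np.arange(1, 101, dtype=float)
    win = pd.DataFrame({
        "f": vals, "f_measured": 1, "f_time_since_measured": 0.0,
    })
    p = fit_normalization(win, ["f"])
    # linear interpolation at p over sorted x: index (n-1)p, so for 1..100
    # q01 = 1 + 0.99 = 1.99 and, symmetrically, q99 = 99 + 0.01 = 99.01
    assert p.features["f"].q01 == pytest.approx(1.99)
    assert p.features["f"].q99 == pytest.approx(99.01)


def test_constant_feature_flagged_degenerate():
    win = pd.DataFrame({"f": 5.0, "f_measured": 1,
                        "f_time_since_measured": 0.0}, index=range(10))
    with pytest.warns(UserWarning, match="constant"):
        p = fit_normalization(win, ["f"])
    assert p.features["f"].degenerate
    assert normalize(123.0, "f", p) == 0.5


@pytest.mark.parametrize("value,expected", [
    (700.0, 1.0),     # data-entry artifact saturates at the upper bound
    (6932.0, 1.0),
    (34.8, 0.0),
    (38.3, 1.0),
    (36.55, 0.5),     # (36.55-34.8)/(38.3-34.8)
    (0.0, 0.0),
])
def test_normalize_trims_then_scales(value, expected):
    assert normalize(value, "temperature", _params()) == pytest.approx(expected)


def test_normalize_unknown_feature_errors():
    with pytest.raises(KeyError):
        normalize(1.0, "nope", _params())


def test_refit_on_synthetic_temperature_near_expected_band(prepped):
    _, params = prepped
    p = params.features["temperature"]
    assert 33.5 < p.q01 < 36.2
    assert 37.2 < p.q99 < 39.5


# -- imputation --------------------------------------------------------------


def _wframe(values, mean=0.3):
    df = pd.DataFrame({
        "encounter_id": "E1",
        "window_index": range(len(values)),
        "f": values,
        "f_measured": [0 if v is None else 1 for v in values],
        "f_time_since_measured": 0.0,
    })
    df["f"] = df["f"].astype(float)
    params = NormalizationParams(features={"f": FeatureNorm(0, 1, mean)})
    return df, params


def test_locf_then_mean():
    df, params = _wframe([None, 0.4, None])
    out = impute(df, params)
    assert list(out["f"]) == [0.3, 0.4, 0.4]


def test_fully_observed_unchanged():
    df, params = _wframe([0.1, 0.2, 0.9])
    assert list(impute(df, params)["f"]) == [0.1, 0.2, 0.9]


def test_fully_missing_takes_train_mean():
    df, params = _wframe([None, None, None])
    assert list(impute(df, params)["f"]) == [0.3, 0.3, 0.3]


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.one_of(st.none(),
                          st.floats(0, 1, allow_nan=False)), min_size=1,
                max_size=12))
def test_impute_idempotent_and_complete(pattern):
    df, params = _wframe(pattern)
    once = impute(df, params)
    assert not once["f"].isna().any()
    assert once["f"].between(0, 1).all()
    pd.testing.assert_frame_equal(impute(once, params), once)


def test_pipeline_output_fully_in_unit_interval(prepped, feature_names):
    windows, _ = prepped
    for f in feature_names:
        assert not windows[f].isna().any()
        assert windows[f].between(0, 1).all()


def test_artifact_saturated_even_at_rate_one():
    cfg = SimConfig(n_encounters=15, seed=2, artifact_rate=1.0)
    enc, obs = simulate_cohort(cfg)
    feats = [f.name for f in cfg.feature_catalog]
    windows, _ = preprocess_cohort(enc, obs, feats, mode="deploy")
    for f in feats:
        assert windows[f].between(0, 1).all()


# -- assay conversion --------------------------------------------------------


def test_empty_map_is_identity():
    obs = _obs("E1", [(1, 0.3), (5, 0.4)], feature="troponin")
    pd.testing.assert_frame_equal(convert_assay(obs, None), obs)
    pd.testing.assert_frame_equal(convert_assay(obs, {}), obs)


def test_mid_stay_scale_applies_piecewise():
    obs = _obs("E1", [(1, 0.3), (5, 0.4)], feature="troponin")
    eff = pd.Timestamp("2022-01-01 03:00", tz=UTC)
    out = convert_assay(obs, {"troponin": [(eff, 1000.0, 0.0)]})
    assert list(out["value"]) == [0.3, 400.0]


def test_two_effective_entries_piecewise():
    obs = _obs("E1", [(1, 1.0), (5, 1.0), (9, 1.0)], feature="troponin")
    t3 = pd.Timestamp("2022-01-01 03:00", tz=UTC)
    t7 = pd.Timestamp("2022-01-01 07:00", tz=UTC)
    out = convert_assay(obs, {"troponin": [(t3, 10.0, 0.0), (t7, 0.0, 5.0)]})
    # second entry applies on top for t >= t7 (value -> 10*1 then -> 5)
    assert list(out["value"]) == [1.0, 10.0, 5.0]


def test_unknown_feature_in_map_warns():
    obs = _obs("E1", [(1, 0.3)], feature="troponin")
    with pytest.warns(UserWarning, match="not in observations"):
        out = convert_assay(obs, {"mystery": [(pd.Timestamp("2022-01-01",
                                                            tz=UTC), 2, 0)]})
    assert list(out["value"]) == [0.3]


def test_window_count_matches_ceiling_for_cohort(cohort, prepped):
    enc, _ = cohort
    windows, _ = prepped
    counts = windows.groupby("encounter_id")["window_index"].max() + 1
    enc_kept = enc[enc["encounter_id"].isin(counts.index)].set_index(
        "encounter_id")
    end = enc_kept["outcome_ts"].fillna(enc_kept["discharge_ts"])
    end = end.where(end < enc_kept["discharge_ts"],
                    enc_kept["discharge_ts"])
    stay_h = (end - enc_kept["admit_ts"]).dt.total_seconds() / 3600.0
    expected = np.ceil(stay_h / 6.0 - 1e-12).astype(int).clip(lower=1)
    assert (counts.sort_index() == expected.sort_index()).all()
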