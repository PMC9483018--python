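"""Shared fixtures: one seeded synthetic cohort and a fitted model.

Session-scoped so the simulate -> preprocess -> fit chain runs once for the
whole suite.
"""

import numpy as np
import pytest

from chartward.evaluation import composite_outcomes
from chartward.preprocessing import preprocess_cohort
from chartward.synthetic import SimConfig, simulate_cohort
from chartward.timeaware import fit_time_aware

COHORT_SEED = 42
SPLIT_SEED = 0
N_ENCOUNTERS = 300


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_encounters=N_ENCOUNTERS, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def feature_names(sim_config):
    return [f.name for f in sim_config.feature_catalog]


@pytest.fixture(scope="session")
def prepped(cohort, feature_names):
    enc, obs = cohort
    windows, params = preprocess_cohort(enc, obs, feature_names, mode="train")
    return windows, params


@pytest.fixture(scope="session")
def split(prepped):
    """Encounter-level train/test masks (one third held out)."""
    windows, _ = prepped
    ids = windows["encounter_id"].unique()
    rng = np.random.default_rng(SPLIT_SEED)
    test_ids = set(rng.choice(ids, len(ids) // 3, replace=False))
    mask_te = windows["encounter_id"].isin(test_ids).to_numpy()
    return ~mask_te, mask_te


@pytest.fixture(scope="session")
def fitted(prepped, split, feature_names):
    windows, params = prepped
    tr = windows[split[0]]
    tr.attrs["normalization_version"] = params.version
    return fit_time_aware(tr, feature_names, seed=0)


@pytest.fixture(scope="session")
def heldout_windows(prepped, split):
    windows, params = prepped
    te = windows[split[1]].copy()
    te.attrs["normalization_version"] = params.version
    return te


@pytest.fixture(scope="session")
def heldout_risk(fitted, heldout_windows):
    risk = fitted.predict_risk(heldout_windows)
    return risk.merge(
        heldout_windows[["encounter_id", "window_index", "outcome_ever",
                         "outcome_within_48h"]],
        on=["encounter_id", "window_index"])


@pytest.fixture(scope="session")
def outcome_labels(cohort):
    enc, _ = cohort
    return composite_outcomes(enc, "icu_death_stepup_palliative")
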