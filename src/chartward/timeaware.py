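"""Two-stage "time-aware MARS" deterioration model.

Stage 1 is a MARS regression on the per-window feature matrix (normalized
values, ``_measured`` flags, ``_time_since_measured`` hours, age, sex),
producing a raw deterioration score per 6-hour window. Stage 2 is a
logistic regression on four score-timeline features derived per encounter —

* ``current``        — this window's stage-1 score,
* ``baseline``       — the admission (window 0) score,
* ``delta_prev``     — change from the previous window,
* ``delta_baseline`` — change since admission,

so the final risk is a probability that reflects not just where a patient
is but how fast they are moving. Scoring is causal: the risk at window w
depends only on windows 0..w.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from chartward.exceptions import ConfigurationError, VersionMismatchError
from chartward.mars import MARS, MARSResults, BasisTerm, Hinge
from chartward.preprocessing import model_matrix

TIME_FEATURE_NAMES = ["current", "baseline", "delta_prev", "delta_baseline"]


def derive_time_features(scores) -> np.ndarray:
    """Score-timeline features for one encounter's ordered stage-1 scores.

    Returns an (n, 4) array with columns ``current, baseline, delta_prev,
    delta_baseline``. At window 0 the baseline equals the current score and
    both deltas are 0.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if len(s) == 0:
        raise ConfigurationError("score timeline is empty")
    baseline = np.full_like(s, s[0])
    delta_prev = np.concatenate([[0.0], np.diff(s)])
    delta_baseline = s - s[0]
    return np.column_stack([s, baseline, delta_prev, delta_baseline])


def _time_features_frame(windows: pd.DataFrame, scores: np.ndarray) -> np.ndarray:
    """Per-encounter time features over a multi-encounter window frame.

    ``windows`` must be sorted by (encounter_id, window_index) and aligned
    with ``scores`` row-for-row.
    """
    out = np.empty((len(scores), 4))
    start = 0
    for _, grp in windows.groupby("encounter_id", sort=False):
        k = len(grp)
        out[start:start + k] = derive_time_features(scores[start:start + k])
        start += k
    return out


def _fit_logistic(T: np.ndarray, y: np.ndarray):
    """ML logistic on the identifiable score-timeline basis.

    ``delta_baseline`` is an exact linear combination of the other features
    (current - baseline), so it is aliased out of the optimization — its
    reported coefficient is 0 with an undefined standard error, exactly as
    a rank-revealing GLM fit would report it. Separation or instability
    falls back to a ridge-stabilized fit with a warning.
    """
    X = sm.add_constant(T[:, :3], has_constant="add")  # const, cur, base, dprev

    def expand(params, bse):
        p = np.concatenate([np.asarray(params, dtype=float), [0.0]])
        b = np.concatenate([np.asarray(bse, dtype=float), [np.nan]])
        return p, b

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 1e3):
            raise np.linalg.LinAlgError("unstable logistic fit")
        params, bse = expand(res.params, res.bse)
        return params, bse, float(res.llf), res
    except Exception:
        warnings.warn("logistic stage showed separation/instability; "
                      "falling back to ridge-stabilized fit")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0)
        params, bse = expand(res.params, np.full(X.shape[1], np.nan))
        eta = X @ np.asarray(res.params)
        llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        return params, bse, llf, res


class TimeAwareDeterioration:
    """Model object for the two-stage window-risk architecture.

    Parameters
    ----------
    windows : DataFrame
        Preprocessed (normalized, imputed) window matrix as produced by
        :func:`chartward.preprocessing.preprocess_cohort`, sorted by
        encounter and window index, carrying the label columns.
    features : sequence of str
        Base clinical feature names; the design expands each into
        value / measured / time-since columns plus age and sex.
    label : str
        Training label column; the 48-hour look-ahead label is the default
        because that is the horizon alerts are meant to anticipate.
    stage1_max_rows : int, optional
        Row cap for the stage-1 forward search (seeded subsample); stage 2
        always uses every window.
    """

    def __init__(self, windows: pd.DataFrame, features: Sequence[str],
                 label: str = "outcome_within_48h", max_terms: int = 21,
                 degree: int = 2, penalty: float = 3.0, max_knots: int = 100,
                 stage1_max_rows: int | None = 20_000, seed: int = 0):
        if label not in windows.columns:
            raise ConfigurationError(f"label column {label!r} missing")
        y = windows[label].to_numpy()
        if len(np.unique(y)) < 2:
            raise ConfigurationError("training labels contain a single class")
        self.windows = windows.sort_values(
            ["encounter_id", "window_index"], kind="mergesort"
        ).reset_index(drop=True)
        self.features = list(features)
        self.label = label
        self.max_terms = max_terms
        self.degree = degree
        self.penalty = penalty
        self.max_knots = max_knots
        self.stage1_max_rows = stage1_max_rows
        self.seed = seed
        self.normalization_version = windows.attrs.get(
            "normalization_version", "")

    @classmethod
    def from_windows(cls, windows: pd.DataFrame, features: Sequence[str],
                     **kwargs) -> "TimeAwareDeterioration":
        return cls(windows, features, **kwargs)

    def fit(self) -> "TimeAwareResults":
        X, cols = model_matrix(self.windows, self.features)
        y = self.windows[self.label].to_numpy(dtype=float)
        if self.stage1_max_rows is not None and len(y) > self.stage1_max_rows:
            rng = np.random.default_rng(self.seed)
            sel = np.sort(rng.choice(len(y), self.stage1_max_rows,
                                     replace=False))
        else:
            sel = slice(None)
        stage1 = MARS(y[sel], X[sel], feature_names=cols,
                      max_terms=self.max_terms, degree=self.degree,
                      penalty=self.penalty, max_knots=self.max_knots).fit()
        scores = np.clip(stage1.predict(X), 0.0, 1.0)
        T = _time_features_frame(self.windows, scores)
        params, bse, llf, _ = _fit_logistic(T, y)
        # intercept-only reference for the convergence diagnostic
        p0 = max(min(y.mean(), 1 - 1e-12), 1e-12)
        llnull = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
        return TimeAwareResults(
            stage1=stage1, stage2_params=params, stage2_bse=bse,
            stage2_llf=llf, stage2_llnull=llnull,
            feature_columns=cols, base_features=self.features,
            label=self.label,
            normalization_version=self.normalization_version,
            hyperparams={"max_terms": self.max_terms, "degree": self.degree,
                         "penalty": self.penalty, "max_knots": self.max_knots,
                         "seed": self.seed},
        )


@dataclass
class TimeAwareResults:
    """Fitted two-stage model: MARS basis plus stage-2 logistic coefficients."""

    stage1: MARSResults
    stage2_params: np.ndarray   # [const, current, baseline, d_prev, d_base]
    stage2_bse: np.ndarray
    stage2_llf: float
    stage2_llnull: float
    feature_columns: list[str]
    base_features: list[str]
    label: str
    normalization_version: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stage2_params) != 5:
            raise ConfigurationError(
                "stage 2 must have an intercept plus exactly 4 slopes")

    # -- prediction --------------------------------------------------------

    def score_windows(self, windows: pd.DataFrame) -> np.ndarray:
        """Stage-1 window scores, clamped to [0, 1].

        The least-squares basis approximates P(outcome) and can extrapolate
        outside the unit interval on unseen regions of feature space; the
        clamp keeps the score-timeline features on the probability scale.
        """
        X = windows[self.feature_columns].to_numpy(dtype=float)
        return np.clip(self.stage1.predict(X), 0.0, 1.0)

    def predict_risk(self, windows: pd.DataFrame,
                     check_version: bool = True) -> pd.DataFrame:
        """Per-window deterioration probabilities for one or more encounters.

        The input must have been preprocessed with the same normalization
        version the model was trained under (checked via
        ``windows.attrs['normalization_version']`` when present).
        """
        if check_version:
            v = windows.attrs.get("normalization_version")
            if v is not None and v != self.normalization_version:
                raise VersionMismatchError(
                    f"model expects normalization {self.normalization_version!r}"
                    f" but windows carry {v!r}")
        ordered = windows.sort_values(["encounter_id", "window_index"],
                                      kind="mergesort").reset_index(drop=True)
        scores = self.score_windows(ordered)
        T = _time_features_frame(ordered, scores)
        eta = self.stage2_params[0] + T @ self.stage2_params[1:]
        risk = 1.0 / (1.0 + np.exp(-eta))
        out = ordered[["encounter_id", "window_index"]].copy()
        if "window_end" in ordered.columns:
            out["window_end"] = ordered["window_end"]
        out["stage1_score"] = scores
        out["risk"] = risk
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [self.stage1.summary(), "",
                 "Stage 2: logistic regression on score-timeline features",
                 "-" * 64,
                 f"{'feature':<20s}{'coef':>12s}{'std err':>12s}",
                 "-" * 64]
        names = ["const"] + TIME_FEATURE_NAMES
        for nm, b, se in zip(names, self.stage2_params, self.stage2_bse):
            lines.append(f"{nm:<20s}{b:>12.5f}{se:>12.5f}")
        lines += ["-" * 64,
                  f"log-likelihood: {self.stage2_llf:.2f}   "
                  f"(intercept-only: {self.stage2_llnull:.2f})",
                  f"normalization version: {self.normalization_version}"]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "chartward-timeaware-v1",
            "normalization_version": self.normalization_version,
            "label": self.label,
            "base_features": self.base_features,
            "feature_columns": self.feature_columns,
            "hyperparams": self.hyperparams,
            "stage1": {
                "terms": [[{"var": h.var, "knot": h.knot,
                            "direction": h.direction} for h in t.factors]
                          for t in self.stage1.terms],
                "coefficients": [repr(float(c)) for c in self.stage1.params],
                "gcv": self.stage1.gcv,
            },
            "stage2": {
                "coefficients": [repr(float(c)) for c in self.stage2_params],
                "bse": [repr(float(c)) for c in self.stage2_bse],
                "llf": self.stage2_llf,
                "llnull": self.stage2_llnull,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path,
             expect_normalization_version: str | None = None
             ) -> "TimeAwareResults":
        try:
            doc = json.loads(Path(path).read_text())
            if doc.get("format") != "chartward-timeaware-v1":
                raise ConfigurationError(
                    f"{path}: unrecognized model format "
                    f"{doc.get('format')!r}")
            terms = [BasisTerm(tuple(Hinge(f["var"], f["knot"], f["direction"])
                                     for f in t))
                     for t in doc["stage1"]["terms"]]
            stage1 = MARSResults.from_state(
                terms, [float(c) for c in doc["stage1"]["coefficients"]],
                doc["feature_columns"], gcv=doc["stage1"]["gcv"])
            obj = cls(
                stage1=stage1,
                stage2_params=np.array([float(c) for c in
                                        doc["stage2"]["coefficients"]]),
                stage2_bse=np.array([float(c) for c in doc["stage2"]["bse"]]),
                stage2_llf=doc["stage2"]["llf"],
                stage2_llnull=doc["stage2"]["llnull"],
                feature_columns=doc["feature_columns"],
                base_features=doc["base_features"],
                label=doc["label"],
                normalization_version=doc["normalization_version"],
                hyperparams=doc.get("hyperparams", {}),
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ConfigurationError(f"{path}: corrupt model file ({exc})")
        if (expect_normalization_version is not None
                and obj.normalization_version != expect_normalization_version):
            raise VersionMismatchError(
                f"model saved under normalization "
                f"{obj.normalization_version!r}; current data uses "
                f"{expect_normalization_version!r}")
        return obj


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_time_aware(windows: pd.DataFrame, features: Sequence[str],
                   **kwargs) -> TimeAwareResults:
    """Fit the two-stage model on a preprocessed, labeled window frame."""
    return TimeAwareDeterioration(windows, features, **kwargs).fit()


def predict_risk(model: TimeAwareResults, windows: pd.DataFrame,
                 **kwargs) -> pd.DataFrame:
    return model.predict_risk(windows, **kwargs)


def save_model(model: TimeAwareResults, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path, expect_normalization_version: str | None = None
               ) -> TimeAwareResults:
    return TimeAwareResults.load(
        path, expect_normalization_version=expect_normalization_version)
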