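"""PPV/NPV-targeted risk-group thresholds.

Continuous window risks become {High, Medium, Low} groups via two cutoffs.
The high cutoff is chosen so that the *visit-level* positive predictive
value — among encounters whose maximum score ever reaches the cutoff, the
fraction with a true outcome — hits a clinician-set target (default 40%,
i.e. about two false alerts per true positive). The low cutoff targets a
visit-level negative predictive value (default 99%). Both searches scan
the observed maximum scores as the candidate grid and estimate each
candidate's PPV/NPV by 10-fold cross-validation with folds split at the
encounter level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chartward.exceptions import ConfigurationError

RISK_GROUPS = ("High", "Medium", "Low")


def encounter_max_scores(timelines: pd.DataFrame,
                         score_col: str | None = None) -> pd.Series:
    """Maximum per-encounter score from a (encounter_id, score) frame."""
    if timelines.empty:
        raise ConfigurationError("timelines are empty")
    if score_col is None:
        score_col = "risk" if "risk" in timelines.columns else "score"
    return timelines.groupby("encounter_id")[score_col].max()


def _align(timelines: pd.DataFrame, outcomes: pd.Series,
           score_col: str | None) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    mx = encounter_max_scores(timelines, score_col)
    missing = mx.index.difference(outcomes.index)
    if len(missing):
        raise ConfigurationError(
            f"{len(missing)} encounter(s) lack an outcome label "
            f"(e.g. {missing[0]!r})")
    y = outcomes.reindex(mx.index).to_numpy(dtype=float)
    return mx.to_numpy(dtype=float), y, mx.index


def visit_level_ppv(timelines: pd.DataFrame, outcomes: pd.Series,
                    thr_high: float, score_col: str | None = None
                    ) -> float | None:
    """P(outcome | max score >= thr_high); None when nothing alerts."""
    m, y, _ = _align(timelines, outcomes, score_col)
    alerted = m >= thr_high
    if not alerted.any():
        return None
    return float(y[alerted].mean())


def visit_level_npv(timelines: pd.DataFrame, outcomes: pd.Series,
                    thr_low: float, score_col: str | None = None
                    ) -> float | None:
    """P(no outcome | max score < thr_low); None when nothing is below."""
    m, y, _ = _align(timelines, outcomes, score_col)
    below = m < thr_low
    if not below.any():
        return None
    return float(1.0 - y[below].mean())


@dataclass
class RiskThresholds:
    """Calibrated cutoffs plus their cross-validated operating estimates."""

    thr_high: float
    thr_low: float
    target_ppv: float = 0.40
    target_npv: float = 0.99
    cv_folds: int = 10
    seed: int = 0
    achieved_ppv: float | None = None
    achieved_npv: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.thr_low <= self.thr_high < 1.0):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < thr_low <= thr_high < 1 "
                f"(got low={self.thr_low}, high={self.thr_high})")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskThresholds":
        return cls(**json.loads(Path(path).read_text()))


def _cv_counts(m: np.ndarray, y: np.ndarray, candidates: np.ndarray,
               folds: np.ndarray, n_folds: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled held-out counts per candidate cutoff.

    For each fold, counts are taken on the held-out encounters only and
    summed across folds: alerted encounters / alerted-with-outcome (for
    PPV) and below-threshold / below-without-outcome (for NPV).
    """
    n_c = len(candidates)
    alerted = np.zeros(n_c)
    alerted_pos = np.zeros(n_c)
    below = np.zeros(n_c)
    below_neg = np.zeros(n_c)
    for f in range(n_folds):
        held = folds == f
        mf, yf = m[held], y[held]
        order = np.argsort(mf, kind="mergesort")
        ms, ys = mf[order], yf[order]
        cum_pos = np.concatenate([[0.0], np.cumsum(ys)])
        k = np.searchsorted(ms, candidates, side="left")
        n_f = len(ms)
        alerted += n_f - k
        alerted_pos += cum_pos[-1] - cum_pos[k]
        below += k
        below_neg += k - cum_pos[k]
    return alerted, alerted_pos, below, below_neg


def calibrate_thresholds(timelines: pd.DataFrame, outcomes: pd.Series,
                         target_ppv: float = 0.40, target_npv: float = 0.99,
                         cv_folds: int = 10, seed: int = 0,
                         score_col: str | None = None) -> RiskThresholds:
    """Grid-search cutoffs whose cross-validated PPV/NPV are closest to target.

    Candidates are the unique observed encounter-maximum scores. Folds are
    assigned to encounters (never windows) with a seeded shuffle. Ties in
    closeness prefer the lower cutoff, which maximizes sensitivity. If the
    selected low cutoff crosses above the high one, both collapse to their
    midpoint with a warning.
    """
    m, y, _ = _align(timelines, outcomes, score_col)
    if len(np.unique(y)) < 2:
        raise ConfigurationError(
            "validation set must contain both outcome classes")
    candidates = np.unique(m)
    if len(candidates) == 1:
        warnings.warn("all encounter maximum scores identical; "
                      "returning the single candidate cutoff")
        c = float(np.clip(candidates[0], 1e-9, 1 - 1e-9))
        return RiskThresholds(thr_high=c, thr_low=c, target_ppv=target_ppv,
                              target_npv=target_npv, cv_folds=cv_folds,
                              seed=seed,
                              achieved_ppv=visit_level_ppv(
                                  timelines, outcomes, c, score_col),
                              achieved_npv=visit_level_npv(
                                  timelines, outcomes, c, score_col))
    rng = np.random.default_rng(seed)
    folds = rng.permutation(len(m)) % cv_folds

    alerted, alerted_pos, below, below_neg = _cv_counts(
        m, y, candidates, folds, cv_folds)

    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(alerted > 0, alerted_pos / np.maximum(alerted, 1), np.nan)
        npv = np.where(below > 0, below_neg / np.maximum(below, 1), np.nan)

    def pick(est: np.ndarray, target: float) -> tuple[float, float]:
        ok = ~np.isnan(est)
        if not ok.any():
            raise ConfigurationError("no candidate cutoff has a defined estimate")
        dist = np.abs(est - target)
        dist[~ok] = np.inf
        best = int(np.argmin(dist))  # argmin takes the first (lowest cutoff)
        return float(candidates[best]), float(est[best])

    thr_high, ach_ppv = pick(ppv, target_ppv)
    thr_low, ach_npv = pick(npv, target_npv)
    if thr_low > thr_high:
        mid = 0.5 * (thr_low + thr_high)
        warnings.warn(
            f"low cutoff {thr_low:.4g} crossed above high cutoff "
            f"{thr_high:.4g}; collapsing both to the midpoint {mid:.4g}")
        thr_low = thr_high = mid
        ach_ppv = visit_level_ppv(timelines, outcomes, thr_high, score_col)
        ach_npv = visit_level_npv(timelines, outcomes, thr_low, score_col)
    eps = 1e-9
    return RiskThresholds(
        thr_high=float(np.clip(thr_high, eps, 1 - eps)),
        thr_low=float(np.clip(thr_low, eps, 1 - eps)),
        target_ppv=target_ppv, target_npv=target_npv, cv_folds=cv_folds,
        seed=seed, achieved_ppv=ach_ppv, achieved_npv=ach_npv)


def assign_risk_group(score, thresholds: RiskThresholds):
    """Map scores to groups: >= thr_high is High (alerts fire at the
    threshold), < thr_low is Low, otherwise Medium. Vectorized."""
    arr = np.asarray(score, dtype=float)
    out = np.where(arr >= thresholds.thr_high, "High",
                   np.where(arr < thresholds.thr_low, "Low", "Medium"))
    return str(out[()]) if arr.ndim == 0 else out
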