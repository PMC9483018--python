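"""Multivariate adaptive regression splines (MARS), fitted from scratch.

The model is a linear combination of hinge-function products,

    f(x) = b0 + sum_m b_m * prod_k h_k(x),   h(x) = max(0, x_j - t)
                                                  or max(0, t - x_j),

grown greedily (forward pass: at each step add the reflected hinge pair
that most reduces the residual sum of squares) and then pruned backward to
minimize the generalized cross-validation criterion

    GCV(M) = (RSS / N) / (1 - C(M) / N)^2,
    C(M)   = M + penalty * (M - 1) / 2,

with M the number of basis functions including the intercept. The fit is
ordinary least squares on the basis — for a 0/1 outcome the raw score is
mapped through a downstream logistic stage rather than a GLM link.

Candidate knots are restricted to at most ``max_knots`` quantiles of each
predictor's observed unique values; forward selection breaks ties toward
the lowest predictor index, then the smallest knot, so fits are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from chartward.exceptions import ConfigurationError, FeatureMismatchError

_EPS = 1e-10


class ResourceBudgetError(RuntimeError):
    """The forward search would exceed the configured candidate budget."""


@dataclass(frozen=True)
class Hinge:
    """One factor max(0, s*(x_j - t)) with s = +1 or -1."""

    var: int
    knot: float
    direction: int  # +1: max(0, x - t); -1: max(0, t - x)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        z = self.direction * (X[:, self.var] - self.knot)
        return np.maximum(0.0, z)


@dataclass(frozen=True)
class BasisTerm:
    """A product of hinge factors; the empty product is the intercept."""

    factors: tuple[Hinge, ...] = ()

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> frozenset[int]:
        return frozenset(h.var for h in self.factors)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for h in self.factors:
            out *= h(X)
        return out

    def describe(self, names: Sequence[str] | None = None) -> str:
        if not self.factors:
            return "(intercept)"
        parts = []
        for h in self.factors:
            nm = names[h.var] if names else f"x{h.var}"
            parts.append(f"h({nm} - {h.knot:g})" if h.direction > 0
                         else f"h({h.knot:g} - {nm})")
        return " * ".join(parts)


def evaluate_basis(terms: Sequence[BasisTerm], X: np.ndarray) -> np.ndarray:
    return np.column_stack([t.evaluate(X) for t in terms])


def _candidate_knots(x: np.ndarray, max_knots: int) -> np.ndarray:
    u = np.unique(x)
    if len(u) <= max_knots:
        return u
    qs = (np.arange(max_knots) + 0.5) / max_knots
    return np.unique(np.quantile(u, qs, method="nearest"))


class MARS:
    """MARS regression model.

    Parameters
    ----------
    endog : array_like
        Response, shape (n,). Binary 0/1 outcomes are fitted by least
        squares (classical MARS).
    exog : array_like
        Predictors, shape (n, p). No missing values.
    feature_names : sequence of str, optional
        Column names for reporting; defaults to ``x0 .. x{p-1}``.
    max_terms : int
        Maximum number of basis functions (including the intercept) the
        forward pass may grow.
    degree : int
        Maximum number of hinge factors per term (2 allows pairwise
        interactions). A variable enters a product at most once.
    penalty : float
        GCV cost per knot (the classical smoothing parameter d; 3 is the
        standard choice when interactions are allowed).
    max_knots : int
        Cap on candidate knots per predictor (quantile-subsampled).
    candidate_budget : int
        Upper bound on max_terms x predictors x knots the forward search
        may enumerate; exceeding it raises :class:`ResourceBudgetError`.
    """

    def __init__(self, endog, exog, feature_names: Sequence[str] | None = None,
                 max_terms: int = 21, degree: int = 2, penalty: float = 3.0,
                 max_knots: int = 100, candidate_budget: int = 50_000_000):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if len(self.endog) != self.exog.shape[0]:
            raise ConfigurationError("endog and exog lengths differ")
        if np.isnan(self.endog).any() or np.isnan(self.exog).any():
            raise ConfigurationError("MARS requires imputed (non-missing) data")
        if max_terms < 1:
            raise ConfigurationError("max_terms must be >= 1")
        if degree < 1:
            raise ConfigurationError("degree must be >= 1")
        p = self.exog.shape[1]
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{j}" for j in range(p)])
        if len(self.feature_names) != p:
            raise ConfigurationError("feature_names length != number of columns")
        self.max_terms = int(max_terms)
        self.degree = int(degree)
        self.penalty = float(penalty)
        self.max_knots = int(max_knots)
        if max_terms * p * max_knots > candidate_budget:
            raise ResourceBudgetError(
                f"forward search of ~{max_terms * p * max_knots} candidates "
                f"exceeds the budget of {candidate_budget}")

    # -- forward pass -----------------------------------------------------

    def _forward(self) -> list[BasisTerm]:
        X, y = self.exog, self.endog
        n, p = X.shape
        knots = [_candidate_knots(X[:, j], self.max_knots) for j in range(p)]
        terms: list[BasisTerm] = [BasisTerm()]
        B = np.ones((n, 1))
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        rss = float(r @ r)

        while len(terms) < self.max_terms:
            best = None  # (drss, parent_idx, var, knot, cols)
            for m, parent in enumerate(terms):
                if parent.degree >= self.degree:
                    continue
                bm = B[:, m]
                if not np.any(bm > 0):
                    continue
                for j in range(p):
                    if j in parent.variables:
                        continue
                    ks = knots[j]
                    if len(ks) == 0:
                        continue
                    xj = X[:, j]
                    Hp = np.maximum(0.0, xj[:, None] - ks[None, :]) * bm[:, None]
                    Hm = np.maximum(0.0, ks[None, :] - xj[:, None]) * bm[:, None]
                    drss, which = self._pair_gains(Q, r, Hp, Hm)
                    k_best = int(np.argmax(drss))
                    gain = float(drss[k_best])
                    if gain <= _EPS * max(rss, 1.0):
                        continue
                    if best is None or gain > best[0] * (1 + 1e-12):
                        cols = []
                        if which[k_best] in (0, 2):
                            cols.append((Hp[:, k_best],
                                         Hinge(j, float(ks[k_best]), +1)))
                        if which[k_best] in (1, 2):
                            cols.append((Hm[:, k_best],
                                         Hinge(j, float(ks[k_best]), -1)))
                        best = (gain, m, j, float(ks[k_best]), cols)
            if best is None:
                break
            _, m, _, _, cols = best
            parent = terms[m]
            for col, hinge in cols:
                if len(terms) >= self.max_terms:
                    break
                terms.append(BasisTerm(parent.factors + (hinge,)))
                B = np.column_stack([B, col])
            Q, _ = np.linalg.qr(B)
            r = y - Q @ (Q.T @ y)
            rss = float(r @ r)
        self._forward_B = B
        return terms

    @staticmethod
    def _pair_gains(Q: np.ndarray, r: np.ndarray, Hp: np.ndarray,
                    Hm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """RSS reduction for each knot's reflected pair.

        Works in the orthogonal complement of the current basis: with
        c_perp = c - Q Q^T c and r already orthogonal to span(B),
        the joint 2-column gain is b' A^{-1} b for A the Gram matrix of the
        projected pair. Near-singular pairs fall back to the better single
        column; returns (gains, which) with which in {0:+ only, 1:- only,
        2:both}.
        """
        Gp = Q.T @ Hp
        Gm = Q.T @ Hm
        a11 = np.einsum("ij,ij->j", Hp, Hp) - np.einsum("ij,ij->j", Gp, Gp)
        a22 = np.einsum("ij,ij->j", Hm, Hm) - np.einsum("ij,ij->j", Gm, Gm)
        a12 = np.einsum("ij,ij->j", Hp, Hm) - np.einsum("ij,ij->j", Gp, Gm)
        b1 = r @ Hp
        b2 = r @ Hm
        scale = np.maximum(a11 * a22, _EPS)
        det = a11 * a22 - a12 * a12
        ok1 = a11 > _EPS * np.maximum(np.einsum("ij,ij->j", Hp, Hp), 1.0)
        ok2 = a22 > _EPS * np.maximum(np.einsum("ij,ij->j", Hm, Hm), 1.0)
        g1 = np.where(ok1, b1 * b1 / np.where(ok1, a11, 1.0), 0.0)
        g2 = np.where(ok2, b2 * b2 / np.where(ok2, a22, 1.0), 0.0)
        joint_ok = ok1 & ok2 & (det > 1e-9 * scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            gj = (a22 * b1 * b1 - 2 * a12 * b1 * b2 + a11 * b2 * b2) / det
        gj = np.where(joint_ok, gj, -np.inf)
        gains = np.maximum.reduce([g1, g2, np.where(joint_ok, gj, 0.0)])
        which = np.where(joint_ok & (gj >= np.maximum(g1, g2) - _EPS), 2,
                         np.where(g1 >= g2, 0, 1))
        return gains, which

    # -- backward pass ----------------------------------------------------

    def _gcv(self, rss: float, m_terms: int) -> float:
        n = len(self.endog)
        c = m_terms + self.penalty * (m_terms - 1) / 2.0
        denom = (1.0 - c / n) ** 2
        if denom <= 0:
            return np.inf
        return (rss / n) / denom

    def _prune(self, terms: list[BasisTerm]) -> tuple[list[BasisTerm], np.ndarray, float]:
        y = self.endog
        B_full = self._forward_B

        def rss_of(idx: list[int]) -> tuple[float, np.ndarray]:
            coef, *_ = np.linalg.lstsq(B_full[:, idx], y, rcond=None)
            resid = y - B_full[:, idx] @ coef
            return float(resid @ resid), coef

        current = list(range(len(terms)))
        rss, coef = rss_of(current)
        best_idx, best_coef = list(current), coef
        best_gcv = self._gcv(rss, len(current))
        while len(current) > 1:
            trial_best = None
            for drop in current[1:]:  # intercept (position 0) stays
                idx = [i for i in current if i != drop]
                rss_t, coef_t = rss_of(idx)
                g = self._gcv(rss_t, len(idx))
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, idx, coef_t)
            g, idx, coef_t = trial_best
            current = idx
            if g < best_gcv:
                best_gcv, best_idx, best_coef = g, list(idx), coef_t
        return [terms[i] for i in best_idx], best_coef, best_gcv

    # -- public API --------------------------------------------------------

    def fit(self) -> "MARSResults":
        terms = self._forward()
        rss_full = float(np.sum((self.endog
                                 - self._forward_B @ np.linalg.lstsq(
                                     self._forward_B, self.endog,
                                     rcond=None)[0]) ** 2))
        forward_gcv = self._gcv(rss_full, len(terms))
        pruned, coef, gcv = self._prune(terms)
        del self._forward_B
        return MARSResults(model=self, terms=pruned, params=coef,
                           gcv=gcv, forward_gcv=forward_gcv)


@dataclass
class MARSResults:
    """Fitted MARS basis, coefficients, and fit diagnostics."""

    model: MARS | None
    terms: list[BasisTerm]
    params: np.ndarray
    gcv: float
    forward_gcv: float
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.model is not None:
            self.feature_names = list(self.model.feature_names)
            y = self.model.endog
            fitted = self.predict(self.model.exog)
            self.rss = float(np.sum((y - fitted) ** 2))
            tss = float(np.sum((y - y.mean()) ** 2))
            self.rsquared = 1.0 - self.rss / tss if tss > 0 else 0.0
            self.nobs = len(y)
        else:
            self.rss = float("nan")
            self.rsquared = float("nan")
            self.nobs = 0
        if self.feature_names is None:
            raise ConfigurationError("feature_names required when model absent")

    @classmethod
    def from_state(cls, terms: list[BasisTerm], params,
                   feature_names: Sequence[str], gcv: float = 0.0,
                   forward_gcv: float = 0.0) -> "MARSResults":
        return cls(model=None, terms=list(terms),
                   params=np.asarray(params, dtype=float), gcv=gcv,
                   forward_gcv=forward_gcv, feature_names=list(feature_names))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def selected_variables(self) -> list[str]:
        names = self.feature_names
        out: list[str] = []
        for t in self.terms:
            for v in sorted(t.variables):
                if names[v] not in out:
                    out.append(names[v])
        return out

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != len(self.feature_names):
            raise FeatureMismatchError(
                f"expected {len(self.feature_names)} features "
                f"({self.feature_names}), got {X.shape[1]}")
        return evaluate_basis(self.terms, X) @ self.params

    def summary(self) -> str:
        names = self.feature_names
        lines = [
            "MARS regression results",
            "=" * 64,
            f"No. observations: {self.nobs:>8d}    Basis functions: {self.n_terms}",
            f"GCV:             {self.gcv:>9.5g}    R-squared:      {self.rsquared:.4f}",
            "-" * 64,
            f"{'term':<44s}{'coef':>12s}",
            "-" * 64,
        ]
        for t, c in zip(self.terms, self.params):
            lines.append(f"{t.describe(names):<44s}{c:>12.5f}")
        lines.append("=" * 64)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_mars(X, y, max_terms: int = 21, degree: int = 2,
             gcv_penalty: float = 3.0, feature_names=None,
             max_knots: int = 100) -> MARSResults:
    """Fit a MARS model (forward growth + GCV backward pruning)."""
    return MARS(y, X, feature_names=feature_names, max_terms=max_terms,
                degree=degree, penalty=gcv_penalty, max_knots=max_knots).fit()


def predict_mars(results: MARSResults, X) -> np.ndarray:
    """Evaluate a fitted MARS model on new rows."""
    return results.predict(X)
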