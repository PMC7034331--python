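"""Nonparametric estimation of conditional means from posterior draws.

The VoI estimators require the conditional mean g(phi) = E(alpha | phi),
estimated by regressing Monte Carlo draws of an output alpha on draws of
the conditioning quantities phi.  Two backends are provided:

``gam``
    Additive cubic B-spline basis (quantile knots) fitted by ordinary
    least squares via :mod:`statsmodels`.  Deterministic, with an exact
    asymptotic covariance for the coefficients.  Default, for p <= 5.
``mars``
    Multivariate adaptive regression splines: a greedy forward pass adds
    reflected pairs of hinge functions (optionally products of two
    hinges), followed by a backward pass pruning terms by generalized
    cross-validation.  Handles interactions between components of phi.

Both backends expose the fitted values, residuals, and a simulator for
fitted values under the asymptotic normal distribution of the regression
coefficients, which drives the VoI standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline

__all__ = ["RegressionFit", "fit_conditional_mean"]

_GAM_MAX_P = 5


@dataclass
class RegressionFit:
    """A fitted conditional-mean regression of one response on phi."""

    design: np.ndarray = field(repr=False)
    coef: np.ndarray = field(repr=False)
    coef_cov: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    sigma2: float
    diagnostics: dict

    @property
    def K(self) -> int:
        return self.fitted.shape[0]

    def coefficient_draw(self, rng: np.random.Generator, n_sims: int = 1) -> np.ndarray:
        """Simulate fitted values under coefficient uncertainty.

        Returns a K x n_sims array; column j is X @ beta_j with beta_j
        drawn from N(coef, sigma2 (X'X)^+).  Computed in the orthonormal
        column space of the design (fitted + sigma Q z), which is the
        same distribution but immune to ill-conditioning of X'X.
        """
        Q = self._column_space()
        z = rng.standard_normal((Q.shape[1], n_sims))
        return self.fitted[:, None] + np.sqrt(self.sigma2) * (Q @ z)

    def _column_space(self) -> np.ndarray:
        if not hasattr(self, "_Q"):
            u, s, _ = np.linalg.svd(self.design, full_matrices=False)
            rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
            self._Q = u[:, :rank]
        return self._Q


def _ols(design: np.ndarray, response: np.ndarray, diagnostics: dict) -> RegressionFit:
    model = sm.OLS(response, design)
    res = model.fit(method="pinv")
    fitted = np.asarray(res.fittedvalues)
    residuals = response - fitted
    diagnostics = dict(diagnostics)
    diagnostics["n_basis"] = design.shape[1]
    diagnostics["r_squared"] = float(res.rsquared) if np.var(response) > 0 else 1.0
    sigma2 = float(res.mse_resid) if design.shape[0] > design.shape[1] else 0.0
    return RegressionFit(
        design=design,
        coef=np.asarray(res.params),
        coef_cov=np.asarray(res.cov_params()),
        fitted=fitted,
        residuals=residuals,
        sigma2=sigma2,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Spline (additive) backend


def _bspline_basis(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis with interior knots at quantiles, no intercept.

    A predictor with only a few distinct values (e.g. a count-based
    statistic y/n at small n) gets an indicator basis instead — the
    saturated fit whose fitted values are the exact per-level means —
    since spline knots degenerate under heavy ties.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:  # constant column; caller screens this out
        return np.empty((x.shape[0], 0))
    levels = np.unique(x)
    if levels.size <= max(df + 2, 12):
        # one indicator per level, first level absorbed by the intercept
        idx = np.searchsorted(levels, x)
        basis = np.zeros((x.shape[0], levels.size - 1))
        pos = idx > 0
        basis[np.nonzero(pos)[0], idx[pos] - 1] = 1.0
        return basis
    n_interior = max(df - degree, 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.unique(np.quantile(x, qs))
        interior = interior[(interior > lo) & (interior < hi)]
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    basis = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    return basis[:, 1:]  # drop one column; intercept added separately


def _fit_gam(X: np.ndarray, y: np.ndarray, settings: dict) -> RegressionFit:
    df = int(settings.get("df", 10))
    degree = int(settings.get("degree", 3))
    K, p = X.shape
    if p > _GAM_MAX_P:
        raise ValueError(
            f"spline backend supports at most {_GAM_MAX_P} conditioning quantities, got {p}; "
            "reduce the set of columns (e.g. analyse parameters in smaller groups) or use "
            "method='mars'"
        )
    blocks = [np.ones((K, 1))]
    for j in range(p):
        blocks.append(_bspline_basis(X[:, j], df=df, degree=degree))
    design = np.hstack(blocks)
    return _ols(design, y, {"method": "gam", "df": df})


# ---------------------------------------------------------------------------
# MARS backend


def _hinge_pair(x: np.ndarray, knot: float) -> tuple[np.ndarray, np.ndarray]:
    return np.maximum(x - knot, 0.0), np.maximum(knot - x, 0.0)


def _forward_pass(X: np.ndarray, y: np.ndarray, max_terms: int, max_degree: int,
                  n_knots: int) -> tuple[np.ndarray, list]:
    """Greedy forward selection of reflected hinge pairs.

    Returns the design matrix (first column intercept) and the term
    descriptions: lists of (variable, knot, sign) factors.
    """
    K, p = X.shape
    knots = [np.unique(np.quantile(X[:, j], np.linspace(0.05, 0.95, n_knots)))
             for j in range(p)]
    design = np.ones((K, 1))
    terms: list[list] = [[]]
    # orthonormal basis of the current design, for fast RSS-gain screening
    Q, _ = np.linalg.qr(design)
    resid = y - Q @ (Q.T @ y)
    while design.shape[1] + 2 <= max_terms:
        best = None  # (gain, parent_idx, var, knot, cols)
        for parent_idx, parent in enumerate(terms):
            if len(parent) >= max_degree:
                continue
            parent_col = design[:, parent_idx]
            if np.count_nonzero(parent_col) < 10:
                continue
            used_vars = {f[0] for f in parent}
            for j in range(p):
                if j in used_vars:
                    continue
                xj = X[:, j]
                for knot in knots[j]:
                    up, down = _hinge_pair(xj, knot)
                    cols = np.column_stack([parent_col * up, parent_col * down])
                    # residualize against current fit space
                    C = cols - Q @ (Q.T @ cols)
                    norms = np.linalg.norm(C, axis=0)
                    keep = norms > 1e-10 * max(1.0, np.linalg.norm(cols))
                    C = C[:, keep]
                    if C.shape[1] == 0:
                        continue
                    Qc, _ = np.linalg.qr(C)
                    gain = float(np.sum((Qc.T @ resid) ** 2))
                    if best is None or gain > best[0]:
                        best = (gain, parent_idx, j, float(knot), cols)
        if best is None or best[0] <= 1e-12 * max(np.sum(resid**2), 1e-300):
            break
        _, parent_idx, j, knot, cols = best
        design = np.hstack([design, cols])
        parent = terms[parent_idx]
        terms.append(parent + [(j, knot, +1)])
        terms.append(parent + [(j, knot, -1)])
        Q, _ = np.linalg.qr(design)
        resid = y - Q @ (Q.T @ y)
        if np.sum(resid**2) <= 1e-14 * max(np.sum((y - y.mean()) ** 2), 1e-300):
            break
    return design, terms


def _gcv(rss: float, K: int, n_terms: int, penalty: float) -> float:
    c = n_terms + penalty * max(n_terms - 1, 0) / 2.0
    denom = (1.0 - min(c, K - 1) / K) ** 2
    return rss / K / denom


def _backward_pass(design: np.ndarray, y: np.ndarray, penalty: float) -> list[int]:
    """Prune terms by GCV; returns indices of the retained columns."""
    K, m = design.shape
    G = design.T @ design
    b = design.T @ y
    yy = float(y @ y)

    def rss_of(idx: list[int]) -> float:
        Gs = G[np.ix_(idx, idx)]
        bs = b[idx]
        beta = np.linalg.lstsq(Gs, bs, rcond=None)[0]
        return max(yy - float(bs @ beta), 0.0)

    current = list(range(m))
    best_idx = list(current)
    best_gcv = _gcv(rss_of(current), K, len(current), penalty)
    while len(current) > 1:
        candidates = []
        for drop in current:
            if drop == 0:  # keep the intercept
                continue
            idx = [i for i in current if i != drop]
            candidates.append((rss_of(idx), idx))
        if not candidates:
            break
        rss, idx = min(candidates, key=lambda t: t[0])
        current = idx
        gcv = _gcv(rss, K, len(current), penalty)
        if gcv < best_gcv:
            best_gcv, best_idx = gcv, list(current)
    return best_idx


def _fit_mars(X: np.ndarray, y: np.ndarray, settings: dict) -> RegressionFit:
    max_terms = int(settings.get("max_terms", 21))
    max_degree = int(settings.get("max_degree", 2))
    n_knots = int(settings.get("n_knots", 20))
    penalty = float(settings.get("penalty", 3.0 if max_degree > 1 else 2.0))
    design, _terms = _forward_pass(X, y, max_terms, max_degree, n_knots)
    keep = _backward_pass(design, y, penalty)
    design = design[:, keep]
    return _ols(design, y, {"method": "mars", "max_degree": max_degree})


# ---------------------------------------------------------------------------


def fit_conditional_mean(predictors: np.ndarray, response: np.ndarray,
                         method: str = "gam", settings: dict | None = None) -> RegressionFit:
    """Fit g(phi) = E(alpha | phi) by nonparametric regression.

    Parameters
    ----------
    predictors : array-like, K x p (or K,)
        Draws of the conditioning quantities phi.
    response : array-like, length K
        Draws of the output alpha.
    method : {"gam", "mars"}
        Regression backend (see module docstring).
    settings : dict, optional
        Backend options: ``df``/``degree`` for gam; ``max_terms``,
        ``max_degree``, ``n_knots``, ``penalty`` for mars.
    """
    settings = dict(settings or {})
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float).ravel()
    K, p = X.shape
    if p < 1:
        raise ValueError("at least one predictor is required")
    if y.shape[0] != K:
        raise ValueError("predictors and response must have the same number of draws")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("predictors and response must be finite")
    if K <= 10 * p:
        raise ValueError(f"too few draws (K={K}) for p={p} predictors; need K > 10 p")

    # constant predictors carry no information; drop them so the basis is well posed
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    if X.shape[1] == 0:
        # all predictors degenerate: conditional mean is the overall mean
        design = np.ones((K, 1))
        return _ols(design, y, {"method": method, "note": "all predictors constant"})

    if method == "gam":
        return _fit_gam(X, y, settings)
    if method == "mars":
        return _fit_mars(X, y, settings)
    raise ValueError(f"unknown regression method {method!r}; choose 'gam' or 'mars'")
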