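"""Decision problems and their expected-loss functionals.

Value-of-information quantities are defined relative to a decision
problem.  Four kinds are supported, all satisfying the condition that the
expected loss under the optimal decision is a known function h of the mean
of the decision-relevant outputs alpha:

``finite_action``
    Choose one of D >= 2 actions; alpha_d is the loss of action d, and
    h(E(alpha)) = min_d E(alpha_d).
``scalar_quadratic``
    Point estimation of a scalar alpha under squared error; the optimal
    estimate is the posterior mean and the expected loss is var(alpha).
``a_optimal``
    Point estimation of a vector alpha under quadratic loss with
    H = c c'; the expected loss is c' cov(alpha) c (the weighted-sum
    variance; with unit weights, the sum of all covariance entries).
``d_optimal``
    Point estimation of a vector alpha where the expected loss is
    det(cov(alpha)), or its standardized form det(cov)^(1/S) — a
    geometric-mean variance adjusted for covariance — so that equal
    *relative* variance reductions are valued equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

VALID_KINDS = ("finite_action", "scalar_quadratic", "a_optimal", "d_optimal")

#: Relative tolerance for declaring a covariance matrix non-PSD.
_PSD_RTOL = 1e-8


@dataclass
class LossSpec:
    """Specification of the decision problem for a VoI analysis.

    Parameters
    ----------
    kind : str
        One of ``finite_action``, ``scalar_quadratic``, ``a_optimal``,
        ``d_optimal``.
    output_columns : sequence of str
        Labels of the decision-relevant outputs alpha in the draws table.
    weights : array-like, optional
        Weight vector c for ``a_optimal``; defaults to equal weights.
    standardize : bool
        For ``d_optimal``: report det(cov)^(1/S) instead of det(cov).
    """

    kind: str
    output_columns: Sequence[str]
    weights: np.ndarray | None = None
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {VALID_KINDS}")
        self.output_columns = [str(c) for c in self.output_columns]
        n_out = len(self.output_columns)
        if n_out == 0:
            raise ValueError("at least one output column is required")
        if self.kind == "finite_action" and n_out < 2:
            raise ValueError("finite_action requires >= 2 output columns (one loss per action)")
        if self.kind == "scalar_quadratic" and n_out != 1:
            raise ValueError("scalar_quadratic requires exactly 1 output column")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.kind != "a_optimal":
                raise ValueError("weights are only meaningful for a_optimal")
            if self.weights.shape != (n_out,):
                raise ValueError(f"weights must have length {n_out}")
        elif self.kind == "a_optimal":
            self.weights = np.ones(n_out)

    @property
    def n_outputs(self) -> int:
        return len(self.output_columns)

    @property
    def is_point_estimation(self) -> bool:
        return self.kind != "finite_action"


def _check_psd(cov: np.ndarray) -> None:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, rtol=0, atol=_PSD_RTOL * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    tol = _PSD_RTOL * max(1.0, eigvals.max(initial=0.0))
    if eigvals.min(initial=0.0) < -tol:
        raise ValueError(f"covariance matrix is not PSD (min eigenvalue {eigvals.min()})")


def loss_functional(cov_or_means: np.ndarray, loss: LossSpec) -> float:
    """Scalar expected loss v(.) for a decision problem.

    For the point-estimation kinds, ``cov_or_means`` is the covariance
    matrix (or scalar variance) of alpha; for ``finite_action`` it is the
    vector of action-specific expected losses, and the minimum is returned
    (first index on ties).
    """
    if loss.kind == "finite_action":
        means = np.asarray(cov_or_means, dtype=float).ravel()
        if means.size != loss.n_outputs:
            raise ValueError(f"expected {loss.n_outputs} action means, got {means.size}")
        return float(means.min())

    cov = np.atleast_2d(np.asarray(cov_or_means, dtype=float))
    if cov.shape != (loss.n_outputs, loss.n_outputs):
        raise ValueError(f"expected a {loss.n_outputs}x{loss.n_outputs} covariance, got {cov.shape}")
    _check_psd(cov)
    if loss.kind == "scalar_quadratic":
        return float(cov[0, 0])
    if loss.kind == "a_optimal":
        c = loss.weights
        return float(c @ cov @ c)
    # d_optimal
    det = float(np.linalg.det(cov))
    det = max(det, 0.0)  # clip tiny negative round-off
    if loss.standardize:
        return det ** (1.0 / loss.n_outputs)
    return det


def sample_cov(values: np.ndarray) -> np.ndarray:
    """Empirical covariance (denominator K-1) of a K x S matrix of draws."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1:
        pass  # single draw of S outputs: cov undefined
    return np.atleast_2d(np.cov(values, rowvar=False, ddof=1))
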