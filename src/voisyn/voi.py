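"""Expected value of information from a single set of posterior draws.

Definitions.  Let alpha be the decision-relevant model outputs and L the
loss of the decision problem (:mod:`voisyn.loss`).  Writing EL* for the
expected loss under the optimal decision given a state of knowledge:

* EVPI   = EL*(current posterior) - E[EL*(alpha known exactly)]
* EVPPI  = EL*(current) - E_phi[EL*(posterior given phi)]
* EVSI   = EL*(current) - E_y[EL*(posterior given future data y)]

All three are estimated from one Monte Carlo sample of the joint posterior
(and, for EVSI, of posterior-predictive summary statistics T(y)), using
the regression trick: the conditional mean E(alpha | phi) is estimated by
nonparametric regression of alpha draws on phi draws, and the inner
expected loss is evaluated at the fitted values.  For quadratic loss the
expected residual loss is the mean squared residual of the regression;
for finite-action problems it is the Monte Carlo mean of the minimum
fitted action loss.  Standard errors come from simulating the regression
coefficients from their asymptotic normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .draws import DEFAULT_MIN_DRAWS, DrawsTable
from .loss import LossSpec, loss_functional, sample_cov
from .regression import RegressionFit, fit_conditional_mean

__all__ = ["VoiEstimate", "evpi", "evppi", "evsi", "voi_standard_error"]

_SE_CHUNK = 25  # coefficient-simulation batch size (memory control)


@dataclass
class VoiEstimate:
    """A value-of-information estimate, in the units of the loss.

    ``value = baseline_loss - residual_loss`` where ``baseline_loss`` is
    the expected loss under current information (e.g. var(alpha)) and
    ``residual_loss`` the expected loss after the prospective information.
    """

    value: float
    standard_error: float
    baseline_loss: float
    residual_loss: float
    proportion: float | None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise ValueError("standard_error must be nonnegative")
        self.diagnostics.setdefault("negative_value", bool(self.value < 0))

    def to_record(self) -> dict:
        """JSON-ready record of the estimate and its provenance."""
        rec = {
            "voi_kind": self.diagnostics.get("voi_kind"),
            "loss_kind": self.diagnostics.get("loss_kind"),
            "targets": self.diagnostics.get("targets"),
            "conditioning": self.diagnostics.get("conditioning"),
            "value": self.value,
            "se": self.standard_error,
            "baseline": self.baseline_loss,
            "residual": self.residual_loss,
            "proportion": self.proportion,
        }
        rec.update({k: v for k, v in self.diagnostics.items()
                    if np.isscalar(v) and k not in rec})
        return rec


def _proportion(value: float, baseline: float) -> float | None:
    return value / baseline if baseline > 0 else None


# ---------------------------------------------------------------------------
# EVPI


def evpi(draws: DrawsTable, loss: LossSpec, n_boot: int = 200, seed: int = 0) -> VoiEstimate:
    """Expected value of perfect information.

    Under perfect information the residual loss is zero for point
    estimation (the truth is known), so EVPI equals var(alpha) for scalar
    quadratic loss and v(cov(alpha)) for the multivariate criteria.  For
    finite actions it is min_d E(alpha_d) - E(min_d alpha_d).  The
    standard error is a draw-level bootstrap (Monte Carlo error only).
    """
    A = draws.matrix(loss.output_columns)

    def statistic(M: np.ndarray) -> tuple[float, float]:
        if loss.kind == "finite_action":
            base = float(M.mean(axis=0).min())
            resid = float(M.min(axis=1).mean())
        elif loss.kind == "scalar_quadratic":
            base = float(np.var(M[:, 0], ddof=1))
            resid = 0.0
        else:
            base = loss_functional(sample_cov(M), loss)
            resid = 0.0
        return base, resid

    base, resid = statistic(A)
    rng = np.random.default_rng(seed)
    K = A.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, K, size=K)
        bb, rr = statistic(A[idx])
        boots[b] = bb - rr
    value = base - resid
    return VoiEstimate(
        value=value,
        standard_error=float(boots.std(ddof=1)),
        baseline_loss=base,
        residual_loss=resid,
        proportion=_proportion(value, base),
        diagnostics={"voi_kind": "evpi", "loss_kind": loss.kind},
    )


# ---------------------------------------------------------------------------
# Regression-based EVPPI / EVSI


def _mean_sq_residual(residuals: np.ndarray) -> float:
    # K-1 denominator, matching the sample-variance convention, so that
    # var(alpha) = var(fitted) + residual_loss holds exactly for OLS fits
    return float(residuals @ residuals) / (residuals.shape[0] - 1)


def _regression_voi(draws: DrawsTable, predictor_columns: Sequence[str], loss: LossSpec,
                    method: str, settings: dict | None, seed: int, n_se_sims: int,
                    voi_kind: str, min_draws: int) -> VoiEstimate:
    draws.require_min_draws(min_draws)
    X = draws.matrix(predictor_columns)
    A = draws.matrix(loss.output_columns)
    fits = [fit_conditional_mean(X, A[:, s], method=method, settings=settings)
            for s in range(A.shape[1])]

    if loss.kind == "finite_action":
        ghat = np.column_stack([f.fitted for f in fits])
        base = float(A.mean(axis=0).min())
        resid_loss = float(ghat.min(axis=1).mean())
    elif loss.kind == "scalar_quadratic":
        base = float(np.var(A[:, 0], ddof=1))
        resid_loss = _mean_sq_residual(fits[0].residuals)
    else:
        base = loss_functional(sample_cov(A), loss)
        R = np.column_stack([f.residuals for f in fits])
        resid_loss = loss_functional(sample_cov(R), loss)

    value = base - resid_loss
    se = voi_standard_error(fits, loss, n_sims=n_se_sims, seed=seed)
    diag = {
        "voi_kind": voi_kind,
        "loss_kind": loss.kind,
        "method": method,
        "targets": list(loss.output_columns),
        "n_basis": [f.diagnostics.get("n_basis") for f in fits],
        "r_squared": [f.diagnostics.get("r_squared") for f in fits],
        "conditioning": list(predictor_columns),
    }
    return VoiEstimate(
        value=value,
        standard_error=se,
        baseline_loss=base,
        residual_loss=resid_loss,
        proportion=_proportion(value, base),
        diagnostics=diag,
    )


def evppi(draws: DrawsTable, phi_columns: Sequence[str], loss: LossSpec,
          method: str = "gam", settings: dict | None = None, seed: int = 0,
          n_se_sims: int = 200, min_draws: int = DEFAULT_MIN_DRAWS) -> VoiEstimate:
    """Expected value of partial perfect information on ``phi_columns``.

    One regression of each output on the phi draws; the expected residual
    loss is evaluated from the fitted conditional means (see module
    docstring).  ``seed`` controls only the standard-error simulation.
    """
    return _regression_voi(draws, phi_columns, loss, method, settings, seed,
                           n_se_sims, "evppi", min_draws)


def evsi(draws: DrawsTable, statistic_columns: Sequence[str], loss: LossSpec,
         method: str = "gam", settings: dict | None = None, seed: int = 0,
         n_se_sims: int = 200, min_draws: int = DEFAULT_MIN_DRAWS) -> VoiEstimate:
    """Expected value of sample information for a future study design.

    ``statistic_columns`` must hold, per posterior draw, the sufficient
    statistic T(y) of a dataset y simulated from the posterior predictive
    for that draw (see :mod:`voisyn.future_studies`).  The estimator is
    the EVPPI regression with T(y) in place of phi; for quadratic loss
    the residual loss is the estimated residual variance, i.e. the
    expected posterior variance remaining after collecting the data.
    """
    return _regression_voi(draws, statistic_columns, loss, method, settings, seed,
                           n_se_sims, "evsi", min_draws)


# ---------------------------------------------------------------------------
# Standard errors


def voi_standard_error(fit: RegressionFit | Sequence[RegressionFit], loss: LossSpec,
                       n_sims: int = 200, seed: int = 0) -> float:
    """Standard error of a regression-based VoI estimate.

    Simulates ``n_sims`` coefficient vectors from the asymptotic normal
    distribution of each regression's coefficients, recomputes the VoI
    from the perturbed fitted values, and returns the standard deviation
    across simulations.  Deterministic given ``seed``.
    """
    fits = [fit] if isinstance(fit, RegressionFit) else list(fit)
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a stable standard error")
    for f in fits:
        if not hasattr(f, "coefficient_draw"):
            raise TypeError(
                "regression backend does not expose coefficient uncertainty "
                "(no coefficient_draw); standard errors unavailable for this fit"
            )
    rng = np.random.default_rng(seed)
    values = np.empty(n_sims)
    done = 0
    while done < n_sims:
        m = min(_SE_CHUNK, n_sims - done)
        sims = [f.coefficient_draw(rng, m) for f in fits]  # each K x m
        for j in range(m):
            ghat = np.column_stack([s[:, j] for s in sims])
            if loss.kind == "finite_action":
                values[done + j] = -float(ghat.min(axis=1).mean())
            elif loss.kind == "scalar_quadratic":
                values[done + j] = float(np.var(ghat[:, 0], ddof=1))
            else:
                R = np.column_stack([f.fitted + f.residuals for f in fits]) - ghat
                values[done + j] = -loss_functional(sample_cov(R), loss)
        done += m
    return float(values.std(ddof=1))
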