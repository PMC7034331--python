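"""Posterior sampling for the HIV evidence-synthesis model.

The posterior is sampled on an unconstrained scale (log / logit / scaled
logit / stick-breaking transforms with Jacobians) with the affine-
invariant ensemble sampler of Goodman & Weare (emcee).  Several
independent ensembles are run from overdispersed, data-informed starting
points; each ensemble plays the role of a chain for split-R-hat and
effective-sample-size diagnostics (arviz).  The returned
:class:`~voisyn.draws.DrawsTable` contains the founders plus every
derived output, one column per quantity, and carries a ``diagnostics``
attribute with the convergence report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd

from ..draws import DrawsTable
from .data import AssumptionVariant, HivObservations
from .model import (
    derived_outputs,
    founder_names,
    founders_from_unconstrained,
    log_posterior_unconstrained,
    n_unconstrained,
)

__all__ = ["McmcSettings", "sample_posterior", "posterior_summaries"]

RHAT_LIMIT = 1.01


@dataclass
class McmcSettings:
    """Ensemble-MCMC settings.

    ``chains`` independent ensembles of ``walkers`` walkers each run for
    ``burn + steps`` iterations; the post-burn iterations are flattened
    and evenly thinned to ``draws_per_chain`` retained draws per chain.
    """

    chains: int = 4
    walkers: int = 64
    burn: int = 5000
    steps: int = 3000
    draws_per_chain: int = 5000

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if self.draws_per_chain > self.walkers * self.steps:
            raise ValueError("draws_per_chain exceeds the post-burn sample")


def _initial_points(rng: np.random.Generator, n: int, data: HivObservations,
                    variant: AssumptionVariant) -> np.ndarray:
    """Overdispersed starting points centred on crude data-based values."""
    d = n_unconstrained(variant)
    from scipy.special import logit

    center = np.zeros(d)
    center[0] = np.log(max(data.ypop, 1))
    # stick-breaking coords matching the observed NATSAL proportions
    props = np.array([data.y_G, data.y_N, data.y_P], dtype=float) / data.y_NAT
    rem = 1.0
    for k in range(3):
        v = props[k] / rem
        center[1 + k] = logit(v) + np.log(3 - k)
        rem -= props[k]
    center[4] = 0.0  # a_S
    names = [nm for nm in founder_names(variant)
             if nm not in ("log_mu_pop", "rho_G", "rho_N", "rho_P", "a_S")]
    cascade = [data.g1, data.g2, data.g3, data.g4, data.g5]
    gamma_obs = {f"gamma{i + 1}": cascade[i + 1] / cascade[i] for i in range(4)}
    for j, nm in enumerate(names):
        if nm in gamma_obs:
            p = gamma_obs[nm]
            center[5 + j] = logit(p / 0.15) if nm == "gamma4" else logit(p)
        elif nm == "p_G_GM":
            center[5 + j] = logit(data.y_G_GM / data.n_G_GM)
        elif nm == "p_N_GM":
            center[5 + j] = logit(data.y_N_GM / data.n_N_GM)
        elif nm == "pibar_G_free":
            center[5 + j] = logit(0.02)
        else:
            center[5 + j] = 0.0

    scale = np.full(d, 0.5)
    scale[0] = 2e-3   # mu_pop is Poisson-tight
    scale[4] = 0.015  # a_S prior is tight
    return center + scale * rng.standard_normal((n, d))


def _prior_points_unconstrained(rng: np.random.Generator, n: int,
                                variant: AssumptionVariant) -> np.ndarray:
    """Exact draws from the joint prior, mapped to the unconstrained scale.

    Used to initialize prior-only runs at stationarity (the bounded
    founders are independent under the prior; the stick-breaking and
    logit maps are inverted coordinate-wise).  log(mu_pop) is truncated
    to +-690 to keep exp(log_mu_pop) inside floating-point range — a
    real restriction of that astronomically diffuse N(0, 1000^2) prior,
    matching the support guard in the density itself; the likelihood
    confines mu_pop far inside the truncation in every posterior fit.
    """
    from scipy.special import logit
    from .model import FOUNDER_BOUNDS, founder_names, n_unconstrained

    d = n_unconstrained(variant)
    Z = np.empty((n, d))
    Z[:, 0] = np.clip(rng.normal(0.0, 1000.0, n), -690.0, 690.0)
    rho = rng.dirichlet(np.ones(4), size=n)
    rem = np.ones(n)
    for k in range(3):
        v = rho[:, k] / rem
        Z[:, 1 + k] = logit(np.clip(v, 1e-12, 1 - 1e-12)) + np.log(3 - k)
        rem = rem - rho[:, k]
    Z[:, 4] = np.log(np.abs(rng.normal(1.0, 0.018, n)))  # a_S = log N(1, 0.018^2)
    names = [nm for nm in founder_names(variant)
             if nm not in ("log_mu_pop", "rho_G", "rho_N", "rho_P", "a_S")]
    for j, _nm in enumerate(names):
        # all remaining founders are uniform on their (lo, hi) interval,
        # so a uniform draw on the logit scale inverts the transform
        u = rng.uniform(0.0, 1.0, n)
        Z[:, 5 + j] = logit(np.clip(u, 1e-12, 1 - 1e-12))
    return Z


def sample_posterior(data: HivObservations, variant: AssumptionVariant,
                     mcmc_settings: McmcSettings | None = None, seed: int = 0,
                     include=None) -> DrawsTable:
    """Sample the posterior and return founders + outputs as a DrawsTable.

    ``include`` restricts the likelihood to a subset of data sources
    (``()`` gives prior-only sampling).  Reproducible given ``seed``.
    Non-convergence (split-R-hat above 1.01) raises a warning; the draws
    are still returned, with diagnostics attached.
    """
    settings = mcmc_settings or McmcSettings()
    d = n_unconstrained(variant)
    names = founder_names(variant)

    def logp(Z):
        return log_posterior_unconstrained(Z, data, variant, include=include)

    per_chain = []
    acc_fracs = []
    n_dropped = []
    for chain in range(settings.chains):
        chain_seed = (seed * 1009 + chain) % (2**31 - 1)
        rng = np.random.default_rng(chain_seed)
        prior_only = include is not None and len(tuple(include)) == 0
        init = (_prior_points_unconstrained(rng, settings.walkers, variant)
                if prior_only else _initial_points(rng, settings.walkers, data, variant))

        def _resample_invalid(points, maker):
            lp = logp(points)
            tries = 0
            while (~np.isfinite(lp)).any() and tries < 200:
                bad = ~np.isfinite(lp)
                points[bad] = maker(int(bad.sum()))
                lp[bad] = logp(points[bad])
                tries += 1
            if (~np.isfinite(lp)).any():
                raise RuntimeError("could not initialize walkers inside the support")
            return points

        if prior_only:
            # prior draws are a stationary start: no exploration stage needed
            p1 = _resample_invalid(init, lambda m: _prior_points_unconstrained(rng, m, variant))
        else:
            p0 = _resample_invalid(init, lambda m: _initial_points(rng, m, data, variant))
            # stage 1: short exploration, then restart every walker in a tight
            # ball around the best point found (prevents slow escape of walkers
            # initialized far in the tails under stretch moves)
            pre = emcee.EnsembleSampler(settings.walkers, d, logp, vectorize=True)
            state = emcee.State(p0, random_state=np.random.RandomState(chain_seed).get_state())
            pre.run_mcmc(state, 200, progress=False, skip_initial_state_check=True)
            flat_lp = pre.get_log_prob().reshape(-1)
            best = pre.get_chain().reshape(-1, d)[int(np.argmax(flat_lp))]
            p1 = best + 0.02 * rng.standard_normal((settings.walkers, d))
            p1 = _resample_invalid(p1, lambda m: best + 0.02 * rng.standard_normal((m, d)))

        sampler = emcee.EnsembleSampler(settings.walkers, d, logp, vectorize=True)
        state = emcee.State(p1, random_state=np.random.RandomState(chain_seed + 1).get_state())
        sampler.run_mcmc(state, settings.burn + settings.steps, progress=False,
                         skip_initial_state_check=True)
        chain_draws = sampler.get_chain(discard=settings.burn)  # (steps, walkers, d)
        chain_lp = sampler.get_log_prob(discard=settings.burn)
        # stuck-walker guard: drop walkers whose mean log-posterior sits far
        # below the ensemble (equilibrated walkers differ by O(sqrt(d)))
        walker_lp = chain_lp.mean(axis=0)
        if prior_only:  # diffuse target: spread in log density is legitimate
            healthy = np.ones(walker_lp.shape[0], dtype=bool)
        else:
            healthy = walker_lp > np.median(walker_lp) - 25.0
        n_dropped.append(int((~healthy).sum()))
        per_chain.append(chain_draws[:, healthy, :])
        acc_fracs.append(float(sampler.acceptance_fraction[healthy].mean()))

    # thin each chain's flattened post-burn sample to draws_per_chain
    kept = []
    for chain_draws in per_chain:
        flat = chain_draws.reshape(-1, d)  # step-major ordering
        idx = np.linspace(0, flat.shape[0] - 1, settings.draws_per_chain).round().astype(int)
        kept.append(flat[idx])
    kept = np.stack(kept)  # (chains, draws_per_chain, d)

    # Split-R-hat across independent ensembles: each chain is its ensemble's
    # post-burn sample in step order, so between-ensemble disagreement and
    # within-run drift are both detected.  ESS is computed on per-walker
    # chains, where autocorrelation is estimated honestly — flattened
    # walker pools would look spuriously independent.
    founders_by_chain = [founders_from_unconstrained(c, variant)[0] for c in kept]
    pooled = {nm: np.stack([fc[nm] for fc in founders_by_chain]) for nm in names}
    diag_steps = min(min(c.shape[0] for c in per_chain), 4000)
    walker_chains = np.concatenate(
        [c[-diag_steps:].transpose(1, 0, 2) for c in per_chain], axis=0
    )  # (total_walkers, diag_steps, d)
    diag_founders = founders_from_unconstrained(
        walker_chains.reshape(-1, d), variant)[0]
    nw, ns = walker_chains.shape[0], diag_steps
    per_walker = {nm: diag_founders[nm].reshape(nw, ns) for nm in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.from_dict(posterior=pooled)).to_array().values
        ess = az.ess(az.from_dict(posterior=per_walker)).to_array().values
    diagnostics = {
        "rhat": dict(zip(names, np.asarray(rhat, dtype=float).ravel())),
        "ess": dict(zip(names, np.asarray(ess, dtype=float).ravel())),
        "max_rhat": float(np.max(rhat)),
        "min_ess": float(np.min(ess)),
        "acceptance_fraction": acc_fracs,
        "walkers_dropped": n_dropped,
        "converged": bool(np.max(rhat) <= RHAT_LIMIT),
        "seed": seed,
        "variant": variant.label,
    }
    if not diagnostics["converged"]:
        worst = max(diagnostics["rhat"], key=diagnostics["rhat"].get)
        warnings.warn(
            f"MCMC may not have converged: max split-R-hat "
            f"{diagnostics['max_rhat']:.3f} ({worst}); draws returned anyway",
            RuntimeWarning,
        )

    kept_founders = founders_from_unconstrained(kept.reshape(-1, d), variant)[0]
    flat_founders = {nm: kept_founders[nm] for nm in names}
    outputs = derived_outputs(flat_founders, variant)
    table = {nm: flat_founders[nm] for nm in names}
    table.update({k: np.asarray(v) for k, v in outputs.items()})
    draws = DrawsTable(pd.DataFrame(table))
    draws.diagnostics = diagnostics
    return draws


def posterior_summaries(draws: DrawsTable, quantities=None) -> pd.DataFrame:
    """Median, mean, SD and 95% credible interval per quantity."""
    quantities = list(quantities) if quantities is not None else draws.names
    if not quantities:
        raise ValueError("no quantities selected for summary")
    M = draws.matrix(quantities)
    return pd.DataFrame(
        {
            "median": np.median(M, axis=0),
            "mean": M.mean(axis=0),
            "sd": M.std(axis=0, ddof=1),
            "q2.5": np.quantile(M, 0.025, axis=0),
            "q97.5": np.quantile(M, 0.975, axis=0),
        },
        index=quantities,
    )
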