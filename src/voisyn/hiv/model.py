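"""The HIV-prevalence evidence-synthesis model for MSM in London.

Structure.  Founder parameters (each with a substantive prior) feed a
network of deterministic links producing the outputs of interest; seven
independent likelihood terms tie intermediate nodes to the observed
surveillance counts.  For each MSM subgroup g in {G, N, P} (GUM-attending,
non-attending, previous MSM) the model tracks the subgroup proportion
rho_g, the undiagnosed prevalence pibar_g = pi_g (1 - delta_g), the
diagnosed prevalence pidelta_g = pi_g delta_g, and the case counts
mu_Dg = pidelta_g rho_g mu_pop and mu_Ug = pibar_g rho_g mu_pop.

Key links:

* delta_g = a_delta_g (1 - pibar_g) with a_delta_g ~ U(0,1), which
  enforces 1 - delta_g > pibar_g so that pi_g = pibar_g / (1 - delta_g)
  is a valid prevalence.
* Base case: pibar_G = pi_UN + pi_OP, decomposing undiagnosed infection
  among clinic attenders into test-not-offered and test-refused parts
  built from the GUMCAD cascade probabilities gamma_1..gamma_4.
* GUM Anon observes pi_GA = (pibar_G + pi_GD) / gamma1 with
  pi_GD = gamma1 gamma2 gamma3 gamma4.
* GMSHS informs the odds ratio or_GM linking pibar_N to pibar_G:
  odds(pibar_N) = odds(pibar_G) * or_GM.
* PMSM mirror the NGMSM structure with pibar_P ~ U(0, pibar_N),
  expressing the belief that prevalence among previous MSM is much lower.

Variant (a) replaces the pi_UN + pi_OP construction by a free U(0,1)
prior on pibar_G (GUM Anon becomes its only direct source); variant (b)
sets the diagnosed GMSM prevalence directly from the cascade,
pidelta_G = (1 - gamma1) + gamma1 gamma2 gamma3 gamma4.

All functions are vectorized: founder values may be scalars or equal-
length arrays, and a batch of points is evaluated in one call.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, logit, xlogy

from .data import AssumptionVariant, HivObservations

__all__ = [
    "FOUNDER_BOUNDS", "founder_names", "n_unconstrained",
    "founders_from_unconstrained", "derived_outputs",
    "log_prior", "log_likelihood", "log_posterior",
    "log_posterior_unconstrained", "LIKELIHOOD_TERMS", "OUTPUT_NAMES",
]

GAMMA4_UPPER = 0.15
A_UN_LO, A_UN_HI = np.log(0.5), np.log(1.5)

#: Likelihood terms, keyed by data source.
LIKELIHOOD_TERMS = ("ons", "natsal", "sophid", "handd", "gumcad", "gum_anon", "gmshs")

#: (lower, upper) bounds for bounded founders; None means unbounded.
FOUNDER_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "log_mu_pop": (None, None),
    "rho_G": (0.0, 1.0), "rho_N": (0.0, 1.0), "rho_P": (0.0, 1.0),
    "a_S": (None, None),
    "a_H": (0.0, 1.0),
    "a_delta_G": (0.0, 1.0), "a_delta_N": (0.0, 1.0), "a_delta_P": (0.0, 1.0),
    "gamma1": (0.0, 1.0), "gamma2": (0.0, 1.0), "gamma3": (0.0, 1.0),
    "gamma4": (0.0, GAMMA4_UPPER),
    "a_UN": (A_UN_LO, A_UN_HI),
    "a_OP": (0.0, 1.0),
    "p_G_GM": (0.0, 1.0), "p_N_GM": (0.0, 1.0),
    "u_pibar_P": (0.0, 1.0),
    "pibar_G_free": (0.0, 1.0),
}

_UNIT_FOUNDERS = ("a_H", "a_delta_G", "a_delta_N", "a_delta_P",
                  "gamma1", "gamma2", "gamma3", "a_OP",
                  "p_G_GM", "p_N_GM", "u_pibar_P")

OUTPUT_NAMES = [
    "mu_pop", "r_G", "r_N", "r_P",
    "pibar_G", "pibar_N", "pibar_P",
    "delta_G", "delta_N", "delta_P",
    "pidelta_G", "pidelta_N", "pidelta_P",
    "pi_G", "pi_N", "pi_P",
    "mu_DG", "mu_DN", "mu_DP", "mu_UG", "mu_UN", "mu_UP",
    "mu_D", "mu_M", "p_H",
    "p_UN", "a_EX", "pi_UN", "pi_OP", "pi_GD", "pi_GA", "or_GM",
    "mu_U_2grp", "mu_U_3grp", "mu",
]


def founder_names(variant: AssumptionVariant) -> list[str]:
    names = [
        "log_mu_pop", "rho_G", "rho_N", "rho_P", "a_S", "a_H",
        "a_delta_G", "a_delta_N", "a_delta_P",
        "gamma1", "gamma2", "gamma3", "gamma4", "a_UN", "a_OP",
        "p_G_GM", "p_N_GM", "u_pibar_P",
    ]
    if variant.free_pibar_G:
        names.append("pibar_G_free")
    return names


def n_unconstrained(variant: AssumptionVariant) -> int:
    # the 4-simplex rho has 3 named components and 3 stick-breaking coordinates
    return len(founder_names(variant))


def _as_arrays(founders: dict) -> tuple[dict, bool]:
    scalar = all(np.ndim(v) == 0 for v in founders.values())
    out = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in founders.items()}
    n = max(v.shape[0] for v in out.values())
    out = {k: np.broadcast_to(v, (n,)) for k, v in out.items()}
    return out, scalar


# ---------------------------------------------------------------------------
# Unconstrained parameterization (sampler scale)


def _log_expit(z):
    return -np.logaddexp(0.0, -z)


def founders_from_unconstrained(Z: np.ndarray, variant: AssumptionVariant):
    """Map unconstrained coordinates to founders, with the log-Jacobian.

    Layout: [log_mu_pop, 3 stick-breaking coords for rho, a_S, then logits
    of the bounded founders in the `founder_names` order].  Returns
    (founders dict of (n,) arrays, log_jacobian (n,)).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, d = Z.shape
    if d != n_unconstrained(variant):
        raise ValueError(f"expected {n_unconstrained(variant)} coordinates, got {d}")
    log_jac = np.zeros(n)
    founders: dict[str, np.ndarray] = {"log_mu_pop": Z[:, 0]}

    # stick-breaking for the 4-simplex (rho_G, rho_N, rho_P, remainder)
    rem = np.ones(n)
    rho = []
    for k in range(3):
        z = Z[:, 1 + k] - np.log(3 - k)
        v = expit(z)
        log_jac += _log_expit(z) + _log_expit(-z) + np.log(rem)
        rho.append(rem * v)
        rem = rem * (1.0 - v)
    founders["rho_G"], founders["rho_N"], founders["rho_P"] = rho

    founders["a_S"] = Z[:, 4]
    bounded = [name for name in founder_names(variant)
               if name not in ("log_mu_pop", "rho_G", "rho_N", "rho_P", "a_S")]
    for j, name in enumerate(bounded):
        z = Z[:, 5 + j]
        lo, hi = FOUNDER_BOUNDS[name]
        founders[name] = lo + (hi - lo) * expit(z)
        log_jac += np.log(hi - lo) + _log_expit(z) + _log_expit(-z)
    return founders, log_jac


# ---------------------------------------------------------------------------
# Deterministic links


def _odds(p):
    return p / (1.0 - p)


def _inv_odds(o):
    return o / (1.0 + o)


def _derived(f: dict, variant: AssumptionVariant):
    """Outputs and a validity mask; no bounds checking on the founders."""
    g1, g2, g3, g4 = f["gamma1"], f["gamma2"], f["gamma3"], f["gamma4"]
    with np.errstate(over="ignore"):  # masked later by the support guard
        mu_pop = np.exp(f["log_mu_pop"])

    p_UN = expit(logit(g4) + f["a_UN"])
    a_EX = f["a_OP"] * (GAMMA4_UPPER - g4)
    pi_UN = g1 * (1.0 - g2) * p_UN
    pi_OP = g1 * g2 * (1.0 - g3) * (g4 + a_EX)
    pi_GD = g1 * g2 * g3 * g4

    if variant.free_pibar_G:
        pibar_G = f["pibar_G_free"]
    else:
        pibar_G = pi_UN + pi_OP
    pi_GA = (pibar_G + pi_GD) / g1

    or_GM = _odds(f["p_N_GM"]) / _odds(f["p_G_GM"])
    pibar_N = _inv_odds(_odds(pibar_G) * or_GM)
    pibar_P = f["u_pibar_P"] * pibar_N

    out = {
        "mu_pop": mu_pop,
        "p_UN": p_UN, "a_EX": a_EX, "pi_UN": pi_UN, "pi_OP": pi_OP,
        "pi_GD": pi_GD, "pi_GA": pi_GA, "or_GM": or_GM,
        "pibar_G": pibar_G, "pibar_N": pibar_N, "pibar_P": pibar_P,
    }
    valid = (pi_GA > 0) & (pi_GA < 1) & (pibar_G > 0) & (pibar_G < 1)

    for g, pibar in (("G", pibar_G), ("N", pibar_N), ("P", pibar_P)):
        if g == "G" and variant.gumcad_informs_diagnosed:
            pidelta = (1.0 - g1) + pi_GD
            pi = pidelta + pibar
            with np.errstate(divide="ignore", invalid="ignore"):
                delta = np.where(pi > 0, pidelta / np.maximum(pi, 1e-300), 0.0)
        else:
            delta = f[f"a_delta_{g}"] * (1.0 - pibar)
            pi = pibar / (1.0 - delta)
            pidelta = pi * delta
        valid = valid & (pi < 1) & (pi > 0) & (delta >= 0) & (delta < 1)
        out[f"delta_{g}"] = delta
        out[f"pi_{g}"] = pi
        out[f"pidelta_{g}"] = pidelta

    for g in ("G", "N", "P"):
        out[f"r_{g}"] = f[f"rho_{g}"] * mu_pop
        out[f"mu_D{g}"] = out[f"pidelta_{g}"] * out[f"r_{g}"]
        out[f"mu_U{g}"] = out[f"pibar_{g}"] * out[f"r_{g}"]

    out["mu_D"] = out["mu_DG"] + out["mu_DN"] + out["mu_DP"]
    out["mu_M"] = np.exp(f["a_S"]) * out["mu_D"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["p_H"] = f["a_H"] * out["mu_DG"] / np.maximum(out["mu_D"], 1e-300)
    out["mu_U_2grp"] = out["mu_UG"] + out["mu_UN"]
    out["mu_U_3grp"] = out["mu_U_2grp"] + out["mu_UP"]
    out["mu"] = out["mu_DG"] + out["mu_DN"] + out["mu_U_2grp"]
    return out, valid


def derived_outputs(founders: dict, variant: AssumptionVariant) -> dict:
    """All derived model outputs from founder values within their support.

    Raises ValueError if any derived prevalence falls outside [0, 1]
    (which indicates a support violation in the founders).
    """
    f, scalar = _as_arrays(founders)
    _check_support(f, variant, on_invalid="raise")
    out, valid = _derived(f, variant)
    if not valid.all():
        raise ValueError(
            "derived prevalence outside [0, 1] (e.g. pi_GA or pi_g); "
            "the founder values violate the model support"
        )
    if scalar:
        out = {k: float(v[0]) for k, v in out.items()}
    return out


# ---------------------------------------------------------------------------
# Prior, likelihood, posterior


def _check_support(f: dict, variant: AssumptionVariant, on_invalid="neginf"):
    ok = np.ones(next(iter(f.values())).shape[0], dtype=bool)
    for name in founder_names(variant):
        if name not in f:
            raise KeyError(f"missing founder {name!r}")
        lo, hi = FOUNDER_BOUNDS[name]
        v = f[name]
        if lo is not None:
            ok &= v > lo
        if hi is not None:
            ok &= v < hi
        ok &= np.isfinite(v)
    rho_rest = 1.0 - (f["rho_G"] + f["rho_N"] + f["rho_P"])
    ok &= rho_rest > 0
    # guard exp() overflow for extreme proposals on the unbounded founders
    ok &= (f["log_mu_pop"] < 700.0) & (f["a_S"] < 700.0)
    if on_invalid == "raise" and not ok.all():
        raise ValueError("founder values outside the prior support")
    return ok


def log_prior(founders: dict, variant: AssumptionVariant) -> np.ndarray | float:
    """Joint log prior density on the constrained (founder) scale."""
    f, scalar = _as_arrays(founders)
    ok = _check_support(f, variant)
    n = ok.shape[0]
    lp = np.zeros(n)
    # log(mu_pop) ~ N(0, 1000^2)
    lp += -0.5 * (f["log_mu_pop"] / 1000.0) ** 2 - np.log(1000.0) - 0.5 * np.log(2 * np.pi)
    # rho ~ Dirichlet(1,1,1,1) over four categories
    lp += gammaln(4.0)
    # exp(a_S) ~ N(1, 0.018^2), density on the a_S scale
    with np.errstate(over="ignore"):
        ea = np.exp(np.where(ok, f["a_S"], 0.0))
    lp += -0.5 * ((ea - 1.0) / 0.018) ** 2 - np.log(0.018) - 0.5 * np.log(2 * np.pi) + f["a_S"]
    # uniform founders contribute their normalizing constants
    lp += -np.log(GAMMA4_UPPER)          # gamma4 ~ U(0, 0.15)
    lp += -np.log(A_UN_HI - A_UN_LO)     # a_UN ~ U(log 0.5, log 1.5)
    # U(0,1) founders (incl. pibar_G_free under variant (a)) contribute 0
    lp = np.where(ok, lp, -np.inf)
    return float(lp[0]) if scalar else lp


def _pois_logpmf(y, mu):
    return xlogy(y, mu) - mu - gammaln(y + 1.0)


def _binom_logpmf(y, size, p):
    return (gammaln(size + 1.0) - gammaln(y + 1.0) - gammaln(size - y + 1.0)
            + xlogy(y, p) + xlogy(size - y, 1.0 - p))


def log_likelihood(founders: dict, data: HivObservations,
                   variant: AssumptionVariant, include=None) -> np.ndarray | float:
    """Sum of the log likelihood terms for the active data sources.

    ``include``: iterable of term names (subset of LIKELIHOOD_TERMS);
    None means all.  An empty tuple gives a prior-only model.
    """
    f, scalar = _as_arrays(founders)
    terms = LIKELIHOOD_TERMS if include is None else tuple(include)
    unknown = set(terms) - set(LIKELIHOOD_TERMS)
    if unknown:
        raise ValueError(f"unknown likelihood terms: {sorted(unknown)}")
    ok = _check_support(f, variant)
    out, valid = _derived(f, variant)
    ok &= valid
    n = ok.shape[0]
    ll = np.zeros(n)
    safe = lambda a: np.where(ok, a, 0.5)  # placeholder inside (0,1) for masked rows

    if "ons" in terms:
        ll += _pois_logpmf(data.ypop, np.where(ok, out["mu_pop"], 1.0))
    if "natsal" in terms:
        rho_rest = 1.0 - (f["rho_G"] + f["rho_N"] + f["rho_P"])
        y_rest = data.y_NAT - data.y_G - data.y_N - data.y_P
        ll += (gammaln(data.y_NAT + 1.0)
               - gammaln(data.y_G + 1.0) - gammaln(data.y_N + 1.0)
               - gammaln(data.y_P + 1.0) - gammaln(y_rest + 1.0)
               + xlogy(data.y_G, safe(f["rho_G"])) + xlogy(data.y_N, safe(f["rho_N"]))
               + xlogy(data.y_P, safe(f["rho_P"])) + xlogy(y_rest, safe(rho_rest)))
    if "sophid" in terms:
        ll += _pois_logpmf(data.y_M, np.where(ok, out["mu_M"], 1.0))
    if "handd" in terms:
        ll += _binom_logpmf(data.y_H, data.y_M, safe(out["p_H"]))
    if "gumcad" in terms:
        cascade = [data.g1, data.g2, data.g3, data.g4, data.g5]
        for i, gam in enumerate([f["gamma1"], f["gamma2"], f["gamma3"], f["gamma4"]]):
            ll += _binom_logpmf(cascade[i + 1], cascade[i], safe(gam))
    if "gum_anon" in terms:
        ll += _binom_logpmf(data.g_A, data.g_AN, safe(out["pi_GA"]))
    if "gmshs" in terms:
        ll += _binom_logpmf(data.y_G_GM, data.n_G_GM, safe(f["p_G_GM"]))
        ll += _binom_logpmf(data.y_N_GM, data.n_N_GM, safe(f["p_N_GM"]))

    ll = np.where(ok, ll, -np.inf)
    return float(ll[0]) if scalar else ll


def log_posterior(founders: dict, data: HivObservations,
                  variant: AssumptionVariant, include=None) -> np.ndarray | float:
    """Log prior + log likelihood; -inf outside the support."""
    lp = log_prior(founders, variant)
    ll = log_likelihood(founders, data, variant, include=include)
    with np.errstate(invalid="ignore"):
        total = lp + ll
    if np.ndim(total) == 0:
        return float(total) if np.isfinite(total) else -np.inf
    total = np.where(np.isfinite(lp) & np.isfinite(ll), total, -np.inf)
    return total


def log_posterior_unconstrained(Z: np.ndarray, data: HivObservations,
                                variant: AssumptionVariant, include=None) -> np.ndarray:
    """Posterior density on the unconstrained scale (with Jacobian)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    founders, log_jac = founders_from_unconstrained(Z, variant)
    lp = log_posterior(founders, data, variant, include=include)
    lp = np.atleast_1d(lp)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isfinite(lp), lp + log_jac, -np.inf)
    return out
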