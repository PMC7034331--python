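"""Independent transcription of the HIV model's joint density.

This is a deliberately literal, scalar re-implementation of the priors,
deterministic links and likelihood terms, written directly from the model
description using scipy.stats distribution objects.  It shares no code
with voisyn.hiv.model (which is vectorized and built from gammaln
identities), and serves as a double-implementation oracle: the two must
agree to 1e-8 at any interior point of the support.
"""

import numpy as np
from scipy import stats


def oracle_log_posterior(f: dict, data, variant) -> float:
    """Scalar log prior + log likelihood at one founder point."""
    rho = [f["rho_G"], f["rho_N"], f["rho_P"]]
    rho_rest = 1.0 - sum(rho)

    # ---- priors -------------------------------------------------------
    lp = stats.norm.logpdf(f["log_mu_pop"], loc=0.0, scale=1000.0)
    lp += stats.dirichlet.logpdf(np.array(rho + [rho_rest]), np.ones(4))
    # exp(a_S) ~ N(1, 0.018^2); change of variables to the a_S scale
    lp += stats.norm.logpdf(np.exp(f["a_S"]), loc=1.0, scale=0.018) + f["a_S"]
    for name in ("a_H", "a_delta_G", "a_delta_N", "a_delta_P",
                 "gamma1", "gamma2", "gamma3", "a_OP",
                 "p_G_GM", "p_N_GM", "u_pibar_P"):
        lp += stats.uniform.logpdf(f[name], loc=0.0, scale=1.0)
    lp += stats.uniform.logpdf(f["gamma4"], loc=0.0, scale=0.15)
    lp += stats.uniform.logpdf(f["a_UN"], loc=np.log(0.5),
                               scale=np.log(1.5) - np.log(0.5))
    if variant.free_pibar_G:
        lp += stats.uniform.logpdf(f["pibar_G_free"], loc=0.0, scale=1.0)

    # ---- deterministic links ------------------------------------------
    mu_pop = np.exp(f["log_mu_pop"])
    g1, g2, g3, g4 = f["gamma1"], f["gamma2"], f["gamma3"], f["gamma4"]
    odds = lambda p: p / (1 - p)
    p_UN = 1.0 / (1.0 + np.exp(-(np.log(odds(g4)) + f["a_UN"])))
    pi_UN = g1 * (1 - g2) * p_UN
    a_EX = f["a_OP"] * (0.15 - g4)
    pi_OP = g1 * g2 * (1 - g3) * (g4 + a_EX)
    pi_GD = g1 * g2 * g3 * g4
    pibar_G = f["pibar_G_free"] if variant.free_pibar_G else pi_UN + pi_OP
    pi_GA = (pibar_G + pi_GD) / g1
    or_GM = odds(f["p_N_GM"]) / odds(f["p_G_GM"])
    o_N = odds(pibar_G) * or_GM
    pibar_N = o_N / (1 + o_N)
    pibar_P = f["u_pibar_P"] * pibar_N

    pidelta = {}
    for g, pibar in (("G", pibar_G), ("N", pibar_N), ("P", pibar_P)):
        if g == "G" and variant.gumcad_informs_diagnosed:
            pidelta[g] = (1 - g1) + pi_GD
        else:
            delta = f[f"a_delta_{g}"] * (1 - pibar)
            pi = pibar / (1 - delta)
            pidelta[g] = pi * delta
    mu_D = sum(pidelta[g] * f[f"rho_{g}"] * mu_pop for g in ("G", "N", "P"))
    mu_DG = pidelta["G"] * f["rho_G"] * mu_pop
    mu_M = np.exp(f["a_S"]) * mu_D
    p_H = f["a_H"] * mu_DG / mu_D

    # ---- likelihood ---------------------------------------------------
    ll = stats.poisson.logpmf(data.ypop, mu_pop)
    counts = [data.y_G, data.y_N, data.y_P,
              data.y_NAT - data.y_G - data.y_N - data.y_P]
    ll += stats.multinomial.logpmf(counts, n=data.y_NAT, p=rho + [rho_rest])
    ll += stats.poisson.logpmf(data.y_M, mu_M)
    ll += stats.binom.logpmf(data.y_H, data.y_M, p_H)
    cascade = [data.g1, data.g2, data.g3, data.g4, data.g5]
    for i, gam in enumerate((g1, g2, g3, g4)):
        ll += stats.binom.logpmf(cascade[i + 1], cascade[i], gam)
    ll += stats.binom.logpmf(data.g_A, data.g_AN, pi_GA)
    ll += stats.binom.logpmf(data.y_G_GM, data.n_G_GM, f["p_G_GM"])
    ll += stats.binom.logpmf(data.y_N_GM, data.n_N_GM, f["p_N_GM"])
    return float(lp + ll)
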