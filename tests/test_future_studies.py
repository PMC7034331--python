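import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voisyn import DrawsTable, LossSpec
from voisyn.future_studies import (
    FutureDesign,
    evsi_curve,
    simulate_gmshs,
    simulate_gum_anon,
)


def _synthetic_posterior(K=50_000, seed=0):
    """Stand-in posterior table (synthetic) with the columns the designs need."""
    rng = np.random.default_rng(seed)
    pi_GA = rng.beta(5, 80, K)
    p_G = rng.beta(21, 474, K)
    p_N = rng.beta(21, 433, K)
    alpha = 1e5 * pi_GA + rng.normal(0, 20, K)
    return DrawsTable(pd.DataFrame({
        "pi_GA": pi_GA, "p_G_GM": p_G, "p_N_GM": p_N, "alpha": alpha,
    }))


def test_design_validation():
    with pytest.raises(ValueError):
        FutureDesign("gum_anon", 0)
    with pytest.raises(ValueError):
        FutureDesign("postal_survey", 10)


def test_gum_anon_degenerate_prevalence_gives_zero_statistic():
    t = DrawsTable(pd.DataFrame({"pi_GA": np.zeros(500)}))
    stats_ = simulate_gum_anon(t, 50, seed=1)
    assert np.all(stats_.T == 0.0)


def test_gum_anon_iterated_expectation():
    """mean over draws of T equals the posterior mean of pi_GA."""
    t = _synthetic_posterior()
    stats_ = simulate_gum_anon(t, 30, seed=2)
    pbar = t.column("pi_GA").mean()
    mc_se = np.sqrt(np.var(stats_.T) / t.K)
    assert abs(stats_.T.mean() - pbar) < 3 * mc_se
    assert np.all((stats_.T >= 0) & (stats_.T <= 1))


def test_gum_anon_large_n_approaches_partial_perfect_information():
    from voisyn import evppi, evsi
    t = _synthetic_posterior(30_000)
    loss = LossSpec("scalar_quadratic", ["alpha"])
    ppi = evppi(t, ["pi_GA"], loss, seed=0)
    big = simulate_gum_anon(t, 100_000, seed=3)
    es = evsi(big.attach(t), ["T"], loss, seed=0)
    assert es.value == pytest.approx(ppi.value, rel=0.03)


def test_gmshs_null_odds_ratio():
    """Equal prevalences in both groups give T centred at 1 for large n."""
    rng = np.random.default_rng(4)
    p = rng.beta(30, 600, 20_000)
    t = DrawsTable(pd.DataFrame({"p_G_GM": p, "p_N_GM": p}))
    stats_ = simulate_gmshs(t, 5000, seed=4)
    assert np.median(stats_.T) == pytest.approx(1.0, abs=0.05)


def test_gmshs_smoothing_keeps_statistic_finite():
    """Even when one group gets no participants, T is finite and positive."""
    rng = np.random.default_rng(5)
    t = DrawsTable(pd.DataFrame({
        "p_G_GM": rng.beta(2, 50, 5000), "p_N_GM": rng.beta(2, 50, 5000)}))
    for n in (1, 2, 5):
        stats_ = simulate_gmshs(t, n, seed=5)
        assert np.all(np.isfinite(stats_.T)) and np.all(stats_.T > 0)


def test_gmshs_small_n_distribution_matches_enumeration():
    """Exact enumeration of (N_G, Y_G, Y_N) at n = 10 for one fixed draw."""
    n, p_G, p_N = 10, 0.08, 0.15
    K = 200_000
    t = DrawsTable(pd.DataFrame({"p_G_GM": np.full(K, p_G),
                                 "p_N_GM": np.full(K, p_N)}))
    sim = simulate_gmshs(t, n, seed=6)
    # enumerate: N_G ~ BetaBinomial(n, 493.5, 452.5), then binomial positives
    probs = {}
    for m in range(n + 1):
        pm = stats.betabinom(n, 493.5, 452.5).pmf(m)
        for yg in range(m + 1):
            for yn in range(n - m + 1):
                T = ((yn + 0.5) / (n - m + 1) / (1 - (yn + 0.5) / (n - m + 1))) / \
                    ((yg + 0.5) / (m + 1) / (1 - (yg + 0.5) / (m + 1)))
                pr = pm * stats.binom.pmf(yg, m, p_G) * stats.binom.pmf(yn, n - m, p_N)
                probs[round(T, 12)] = probs.get(round(T, 12), 0.0) + pr
    support = np.array(sorted(probs))
    cdf_exact = np.cumsum([probs[t_] for t_ in support])
    cdf_sim = np.searchsorted(np.sort(sim.T), support * (1 + 1e-9)) / K
    assert np.max(np.abs(cdf_sim - cdf_exact)) < 3.5 / np.sqrt(K)


def test_curve_grid_validation_and_reproducibility():
    t = _synthetic_posterior(5000)
    loss = LossSpec("scalar_quadratic", ["alpha"])
    with pytest.raises(ValueError):
        evsi_curve(t, "gum_anon", [], loss)
    with pytest.raises(ValueError):
        evsi_curve(t, "gum_anon", [10, 10, 20], loss)
    c1 = evsi_curve(t, "gum_anon", [20, 50], loss, seed=9)
    c2 = evsi_curve(t, "gum_anon", [20, 50], loss, seed=9)
    pd.testing.assert_frame_equal(c1, c2)
    assert list(c1.columns) == ["n", "evsi", "se", "residual_loss", "residual_sd"]


def test_curve_uninformative_statistic_is_null():
    """A design observing a constant carries no value at any n."""
    rng = np.random.default_rng(10)
    t = DrawsTable(pd.DataFrame({"pi_GA": np.full(5000, 0.04),
                                 "alpha": rng.normal(size=5000)}))
    c = evsi_curve(t, "gum_anon", [50], LossSpec("scalar_quadratic", ["alpha"]), seed=0)
    assert abs(c["evsi"].iloc[0]) < 3 * max(c["se"].iloc[0], 1e-4)
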