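import numpy as np
import pandas as pd
import pytest

from voisyn import DrawsTable, LossSpec, evpi, evppi, evsi, voi_standard_error
from voisyn.oracles import (
    BetaBinomial,
    LinearSum,
    NormalKnownVar,
    TwoActionGaussian,
)
from voisyn.regression import fit_conditional_mean

SQ = lambda col: LossSpec("scalar_quadratic", [col])


def _normal_table(K=200_000, seed=0):
    rng = np.random.default_rng(seed)
    return DrawsTable(pd.DataFrame({"alpha": rng.normal(size=K)}))


# ---------------------------------------------------------------------------
# EVPI


def test_evpi_zero_when_no_uncertainty():
    t = DrawsTable(pd.DataFrame({"a1": np.zeros(2000), "a2": np.zeros(2000)}))
    est = evpi(t, LossSpec("finite_action", ["a1", "a2"]))
    assert est.value == pytest.approx(0.0, abs=1e-12)


def test_evpi_quadratic_equals_variance():
    t = _normal_table()
    est = evpi(t, SQ("alpha"))
    assert est.value == pytest.approx(1.0, rel=0.02)
    assert est.residual_loss == 0.0


def test_evpi_two_action_matches_gaussian_partial_expectation():
    """EVPI for actions {0, Z} with Z ~ N(0,1) equals 1/sqrt(2*pi)."""
    fx = TwoActionGaussian(m=0.0, sd=1.0)
    t = fx.generate_draws(200_000, seed=3)
    est = evpi(t, fx.loss_spec())
    truth = fx.closed_form_evpi()
    assert truth == pytest.approx(1 / np.sqrt(2 * np.pi))
    assert est.value == pytest.approx(truth, rel=0.02)


def test_evpi_unknown_columns_error():
    with pytest.raises(KeyError):
        evpi(_normal_table(1000), SQ("missing"))


# ---------------------------------------------------------------------------
# EVPPI


def test_evppi_of_output_itself_is_total_variance():
    t = _normal_table(20_000, seed=1).with_columns()
    t = t.with_columns(phi=t.column("alpha"))
    est = evppi(t, ["phi"], SQ("alpha"), seed=0)
    assert est.proportion == pytest.approx(1.0, abs=1e-6)


def test_evppi_irrelevant_parameter_is_null():
    rng = np.random.default_rng(2)
    K = 100_000
    t = DrawsTable(pd.DataFrame({"alpha": rng.normal(size=K),
                                 "phi": rng.normal(size=K)}))
    est = evppi(t, ["phi"], SQ("alpha"), seed=0)
    # no true signal: estimate is overfitting bias (~df/K) plus noise
    assert abs(est.value) < max(2 * est.standard_error, 30 / K)


def test_evppi_linear_sum_conjugate_closed_form():
    fx = LinearSum(sigmas=(1.0, 1.0))
    t = fx.generate_draws(100_000, seed=4)
    est = evppi(t, ["phi1"], fx.loss_spec(), seed=0)
    assert est.value == pytest.approx(1.0, rel=0.05)
    assert est.baseline_loss == pytest.approx(2.0, rel=0.05)


def test_evppi_variance_decomposition_identity():
    """var(fitted) and var(alpha) - mean-squared-residual agree exactly."""
    fx = LinearSum(sigmas=(1.0, 0.5), tau=0.3)
    t = fx.generate_draws(20_000, seed=5)
    est = evppi(t, ["phi1"], fx.loss_spec(), seed=0)
    X, y = t.column("phi1"), t.column("alpha")
    fit = fit_conditional_mean(X, y)
    var_fitted = np.var(fit.fitted, ddof=1)
    assert est.value == pytest.approx(var_fitted, rel=1e-9)


def test_evppi_complete_founder_set_equals_evpi():
    """With a deterministic link, learning all founders = perfect information."""
    fx = LinearSum(sigmas=(1.0, 0.7))
    t = fx.generate_draws(50_000, seed=6)
    full = evppi(t, ["phi1", "phi2"], fx.loss_spec(), seed=0)
    total = evpi(t, fx.loss_spec())
    se = np.hypot(full.standard_error, total.standard_error)
    assert abs(full.value - total.value) <= 3 * se + 0.01 * total.value


def test_evppi_multivariate_d_optimal_independent_components():
    """D-optimal EVPPI reduces to products of variances for independent outputs."""
    rng = np.random.default_rng(7)
    K = 30_000
    phi = rng.normal(size=K)
    a1 = phi + rng.normal(0, 0.5, K)
    a2 = -phi + rng.normal(0, 0.5, K)
    t = DrawsTable(pd.DataFrame({"phi": phi, "a1": a1, "a2": a2}))
    loss = LossSpec("d_optimal", ["a1", "a2"])
    est = evppi(t, ["phi"], loss, seed=0)
    # residuals of the two regressions are independent noise (var 0.25 each)
    assert est.residual_loss == pytest.approx(0.25 * 0.25, rel=0.1)
    assert est.value == pytest.approx(np.linalg.det(np.cov(a1, a2)) - 0.0625, rel=0.15)


def test_evppi_a_optimal_weighted_sum():
    fx = LinearSum(sigmas=(1.0, 1.0))
    t = fx.generate_draws(30_000, seed=8)
    t = t.with_columns(alpha2=t.column("phi2") + 0 * t.column("phi1"))
    loss = LossSpec("a_optimal", ["alpha", "alpha2"], weights=[1.0, 0.0])
    est = evppi(t, ["phi1"], loss, seed=0)
    # weight (1,0): same as scalar EVPPI of alpha
    assert est.value == pytest.approx(1.0, rel=0.08)


def test_evppi_draw_floor_enforced():
    fx = LinearSum()
    t = fx.generate_draws(200, seed=9)
    with pytest.raises(ValueError, match="at least"):
        evppi(t, ["phi1"], fx.loss_spec())
    evppi(t, ["phi1"], fx.loss_spec(), min_draws=100)  # explicit override


# ---------------------------------------------------------------------------
# EVSI


def test_evsi_uninformative_statistic_is_null():
    fx = NormalKnownVar()
    t = fx.generate_draws(20_000, seed=10)
    t = t.with_columns(T=np.full(t.K, 0.123))
    est = evsi(t, ["T"], fx.loss_spec(), seed=0)
    assert est.value == pytest.approx(0.0, abs=1e-10)


def test_evsi_conjugate_normal_preposterior():
    """n = 1 future observation with s = 1 halves the N(0,1) variance."""
    fx = NormalKnownVar(m0=0.0, sd0=1.0, s=1.0)
    t = fx.generate_draws(100_000, seed=11)
    t = fx.simulate_statistic(t, n=1, seed=1100)
    est = evsi(t, ["T"], fx.loss_spec(), seed=0)
    assert est.value == pytest.approx(fx.closed_form_evsi(1), rel=0.05)
    assert fx.closed_form_evsi(1) == pytest.approx(0.5)


def test_evsi_beta_binomial_enumeration():
    """Uniform p, one Bernoulli trial: EVSI = 1/36 by exact enumeration."""
    fx = BetaBinomial(a=1.0, b=1.0)
    t = fx.generate_draws(100_000, seed=12)
    t = fx.simulate_statistic(t, n=1, seed=1200)
    est = evsi(t, ["T"], fx.loss_spec(), seed=0)
    assert est.value == pytest.approx(1 / 36, rel=0.06)


# ---------------------------------------------------------------------------
# Standard errors


def test_standard_error_zero_for_deterministic_response():
    rng = np.random.default_rng(13)
    x = rng.normal(size=2000)
    fit = fit_conditional_mean(x, 3 * x + 1, method="gam")
    se = voi_standard_error(fit, SQ("y"), n_sims=150, seed=0)
    assert se < 1e-8


def test_standard_error_requires_enough_simulations():
    rng = np.random.default_rng(14)
    fit = fit_conditional_mean(rng.normal(size=500), rng.normal(size=500))
    with pytest.raises(ValueError, match="n_sims"):
        voi_standard_error(fit, SQ("y"), n_sims=10)


def test_standard_error_scales_inversely_with_sqrt_k():
    """Quadrupling K roughly halves the SE (checked over 20 replicates)."""
    fx = LinearSum(sigmas=(1.0, 1.0))
    ratios = []
    for rep in range(20):
        t_small = fx.generate_draws(2000, seed=100 + rep)
        t_big = fx.generate_draws(8000, seed=200 + rep)
        e_small = evppi(t_small, ["phi1"], fx.loss_spec(), seed=rep, min_draws=100)
        e_big = evppi(t_big, ["phi1"], fx.loss_spec(), seed=rep, min_draws=100)
        ratios.append(e_small.standard_error / e_big.standard_error)
    assert np.mean(ratios) == pytest.approx(2.0, rel=0.25)


def test_standard_error_deterministic_given_seed():
    fx = LinearSum()
    t = fx.generate_draws(5000, seed=15)
    e1 = evppi(t, ["phi1"], fx.loss_spec(), seed=7, min_draws=100)
    e2 = evppi(t, ["phi1"], fx.loss_spec(), seed=7, min_draws=100)
    assert e1.standard_error == e2.standard_error


def test_negative_estimates_flagged_not_truncated():
    rng = np.random.default_rng(16)
    K = 2000
    t = DrawsTable(pd.DataFrame({"alpha": rng.normal(size=K),
                                 "phi": rng.normal(size=K)}))
    # a_optimal with pure-noise regressions can come out slightly negative
    est = evppi(t, ["phi"], SQ("alpha"), min_draws=100, seed=0)
    assert est.diagnostics["negative_value"] == (est.value < 0)
    assert est.value == est.baseline_loss - est.residual_loss
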