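import numpy as np
import pytest
from hypothesis import given, strategies as st

from voisyn.hiv import london_msm_2012, variant
from voisyn.hiv.data import AssumptionVariant, HivObservations, load_observations
from voisyn.hiv.model import (
    FOUNDER_BOUNDS,
    derived_outputs,
    founder_names,
    founders_from_unconstrained,
    log_likelihood,
    log_posterior,
    log_prior,
    n_unconstrained,
)
from hiv_oracle import oracle_log_posterior


def _random_founders(variant_, n=200, seed=0, scale=1.0):
    """Random points inside the support (rejecting derived-prevalence
    violations such as pi_GA > 1), via the unconstrained transform."""
    rng = np.random.default_rng(seed)
    names = founder_names(variant_)
    collected = {nm: [] for nm in names}
    count = 0
    while count < n:
        Z = rng.normal(0, scale, size=(4 * n, n_unconstrained(variant_)))
        Z[:, 0] = rng.normal(14.5, 0.2, 4 * n)  # log population, plausible range
        if "pibar_G_free" in names:  # keep the free prevalence mostly small
            Z[:, names.index("pibar_G_free")] -= 3.0
        f, _ = founders_from_unconstrained(Z, variant_)
        valid = np.isfinite(log_likelihood(f, london_msm_2012(), variant_, include=()))
        for nm in names:
            collected[nm].append(f[nm][valid])
        count += int(valid.sum())
    return {nm: np.concatenate(collected[nm])[:n] for nm in names}


# ---------------------------------------------------------------------------
# Data container


def test_shipped_dataset_values():
    d = london_msm_2012()
    assert (d.y_G, d.y_N, d.y_P, d.y_NAT) == (7, 38, 10, 824)
    assert (d.y_M, d.y_H) == (8390, 630)
    assert (d.g1, d.g5) == (35121, 855)
    assert (d.g_A, d.g_AN) == (4, 85)
    assert (d.y_G_GM, d.n_G_GM, d.y_N_GM, d.n_N_GM) == (20, 493, 20, 452)


def test_observation_invariants_enforced():
    d = london_msm_2012().to_dict()
    bad = dict(d, g2=d["g1"] + 1)
    with pytest.raises(ValueError, match="cascade"):
        HivObservations(**bad)
    with pytest.raises(ValueError):
        HivObservations(**dict(d, g_A=d["g_AN"] + 1))
    with pytest.raises(ValueError):
        HivObservations(**dict(d, y_G=900))


def test_observations_yaml_roundtrip(tmp_path):
    d = london_msm_2012()
    p = tmp_path / "obs.yaml"
    d.save(p)
    assert load_observations(p) == d


def test_variant_constructors():
    assert variant("base") == AssumptionVariant()
    assert variant("a").free_pibar_G and not variant("a").gumcad_informs_diagnosed
    assert variant("b").gumcad_informs_diagnosed and not variant("b").free_pibar_G
    assert variant("ab").label == "ab"
    with pytest.raises(ValueError):
        variant("c")


# ---------------------------------------------------------------------------
# Deterministic links


@pytest.mark.parametrize("vname", ["base", "b"])
def test_undiagnosed_decomposition_identity(vname):
    """pibar_G = pi_UN + pi_OP holds to machine precision in every draw."""
    v = variant(vname)
    f = _random_founders(v, 500, seed=1)
    out = derived_outputs(f, v)
    np.testing.assert_allclose(out["pibar_G"], out["pi_UN"] + out["pi_OP"],
                               rtol=0, atol=1e-15)


def test_count_additivity_identities():
    v = variant("base")
    out = derived_outputs(_random_founders(v, 500, seed=2), v)
    np.testing.assert_allclose(out["mu_D"], out["mu_DG"] + out["mu_DN"] + out["mu_DP"])
    np.testing.assert_allclose(out["mu"], out["mu_DG"] + out["mu_DN"]
                               + out["mu_UG"] + out["mu_UN"])
    np.testing.assert_allclose(out["mu_U_3grp"], out["mu_U_2grp"] + out["mu_UP"])


def test_zero_diagnosis_fraction_boundary():
    """a_delta_g -> 0 forces delta_g, diagnosed prevalence and mu_Dg to 0."""
    v = variant("base")
    f = {k: np.atleast_1d(v_)[:1] for k, v_ in _random_founders(v, 1, seed=3).items()}
    for g in ("G", "N", "P"):
        f[f"a_delta_{g}"] = np.array([1e-300])
    out = derived_outputs(f, v)
    for g in ("G", "N", "P"):
        assert out[f"delta_{g}"] == pytest.approx(0.0, abs=1e-290)
        assert out[f"mu_D{g}"] == pytest.approx(0.0, abs=1e-280)


def test_null_odds_ratio_identity():
    """Equal GMSHS prevalences give or = 1 and pibar_N = pibar_G."""
    v = variant("base")
    f = _random_founders(v, 50, seed=4)
    f = dict(f, p_N_GM=f["p_G_GM"].copy())
    out = derived_outputs(f, v)
    np.testing.assert_allclose(out["or_GM"], 1.0, rtol=1e-12)
    np.testing.assert_allclose(out["pibar_N"], out["pibar_G"], rtol=1e-12)


def test_variant_a_uses_free_prevalence():
    v = variant("a")
    f = _random_founders(v, 100, seed=5)
    out = derived_outputs(f, v)
    np.testing.assert_array_equal(out["pibar_G"], f["pibar_G_free"])
    assert not np.allclose(out["pibar_G"], out["pi_UN"] + out["pi_OP"])


def test_variant_b_cascade_diagnosed_prevalence():
    v = variant("b")
    f = _random_founders(v, 100, seed=6)
    out = derived_outputs(f, v)
    g1, g2, g3, g4 = f["gamma1"], f["gamma2"], f["gamma3"], f["gamma4"]
    np.testing.assert_allclose(out["pidelta_G"], (1 - g1) + g1 * g2 * g3 * g4)
    # diagnosed-fraction consistency: pi_G = pidelta_G + pibar_G
    np.testing.assert_allclose(out["pi_G"], out["pidelta_G"] + out["pibar_G"])


def test_diagnosed_fraction_constraint_by_construction():
    """1 - delta_g > pibar_g, so every pi_g is a valid prevalence."""
    for vname in ("base", "a", "b"):
        v = variant(vname)
        out = derived_outputs(_random_founders(v, 1000, seed=7), v)
        for g in ("G", "N", "P"):
            assert np.all(1.0 - out[f"delta_{g}"] > out[f"pibar_{g}"])
            assert np.all((out[f"pi_{g}"] > 0) & (out[f"pi_{g}"] < 1))


def test_support_violation_raises():
    v = variant("base")
    f = {k: np.atleast_1d(val)[:1] for k, val in _random_founders(v, 1, seed=8).items()}
    f["gamma4"] = np.array([0.2])  # beyond the 0.15 prior bound
    with pytest.raises(ValueError):
        derived_outputs(f, v)
    assert log_posterior({k: val[0] for k, val in f.items()},
                         london_msm_2012(), v) == -np.inf


@given(st.integers(0, 10_000))
def test_unconstrained_transform_lands_in_support(seed):
    """Any unconstrained point maps to founders inside the prior support."""
    rng = np.random.default_rng(seed)
    v = variant("a")
    z = rng.normal(0, 2, size=(1, n_unconstrained(v)))
    f, log_jac = founders_from_unconstrained(z, v)
    assert np.isfinite(log_jac).all()
    for name in founder_names(v):
        lo, hi = FOUNDER_BOUNDS[name]
        x = f[name][0]
        assert (lo is None or x > lo) and (hi is None or x < hi)
    assert f["rho_G"][0] + f["rho_N"][0] + f["rho_P"][0] < 1.0


# ---------------------------------------------------------------------------
# Posterior density


@pytest.mark.parametrize("vname", ["base", "a", "b"])
def test_log_posterior_matches_literal_transcription(vname):
    """Double-implementation agreement to 1e-8 at random interior points."""
    data = london_msm_2012()
    v = variant(vname)
    f = _random_founders(v, 200, seed=9)
    ours = log_posterior(f, data, v)
    for k in range(0, 200, 1):
        point = {name: float(val[k]) for name, val in f.items()}
        ref = oracle_log_posterior(point, data, v)
        assert ours[k] == pytest.approx(ref, abs=1e-8)


def test_sophid_term_isolated_by_reporting_bias():
    """Moving a_S changes only the SOPHID likelihood term."""
    data = london_msm_2012()
    v = variant("base")
    f = {k: float(val[0]) for k, val in _random_founders(v, 1, seed=10).items()}
    f2 = dict(f, a_S=f["a_S"] + 0.005)
    for term in ("ons", "natsal", "handd", "gumcad", "gum_anon", "gmshs"):
        assert log_likelihood(f, data, v, include=(term,)) == \
            pytest.approx(log_likelihood(f2, data, v, include=(term,)), abs=1e-12)
    assert log_likelihood(f, data, v, include=("sophid",)) != \
        pytest.approx(log_likelihood(f2, data, v, include=("sophid",)), abs=1e-6)
    # the full-likelihood change equals the SOPHID-term change
    d_full = log_likelihood(f2, data, v) - log_likelihood(f, data, v)
    d_sophid = log_likelihood(f2, data, v, include=("sophid",)) - \
        log_likelihood(f, data, v, include=("sophid",))
    assert d_full == pytest.approx(d_sophid, rel=1e-9)


def test_likelihood_term_sum_decomposition():
    data = london_msm_2012()
    v = variant("a")
    f = {k: float(val[0]) for k, val in _random_founders(v, 1, seed=11).items()}
    total = log_likelihood(f, data, v)
    parts = sum(log_likelihood(f, data, v, include=(t,))
                for t in ("ons", "natsal", "sophid", "handd", "gumcad",
                          "gum_anon", "gmshs"))
    assert total == pytest.approx(parts, rel=1e-12)
    with pytest.raises(ValueError, match="unknown likelihood"):
        log_likelihood(f, data, v, include=("sophid", "twitter"))


def test_prior_only_mode_and_jacobian_finite():
    data = london_msm_2012()
    v = variant("base")
    f = {k: float(val[0]) for k, val in _random_founders(v, 1, seed=12).items()}
    assert log_posterior(f, data, v, include=()) == pytest.approx(log_prior(f, v))
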