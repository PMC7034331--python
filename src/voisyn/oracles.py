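"""Conjugate fixtures and brute-force oracles for the VoI estimators.

Each fixture is a small joint model of conditioning quantities phi,
output alpha, and (where meaningful) future data y with sufficient
statistic T(y), for which the EVPPI and EVSI are available in closed
form, by exact enumeration, or by nested Monte Carlo.  They provide an
independent verification path for the regression estimators in
:mod:`voisyn.voi`: the fixtures generate exact joint samples, while the
oracles here never use the regression machinery.

Registry (``FIXTURES``): hyperparameters are chosen so the EVPPI as a
proportion of the baseline loss spans roughly 10%-90%, stressing the
regression backend at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .draws import DrawsTable
from .loss import LossSpec

__all__ = [
    "ConjugateFixture", "NormalKnownVar", "BetaBinomial", "LinearSum",
    "TwoActionGaussian", "FIXTURES", "get_fixture", "generate_draws",
    "nested_mc_evppi", "exact_evsi_enumeration",
]


class ConjugateFixture:
    """Base class: a joint model of (phi, alpha[, T(y)]) with known VoI."""

    name: str = "abstract"
    phi_names: tuple[str, ...] = ()
    alpha_names: tuple[str, ...] = ("alpha",)

    def loss_spec(self) -> LossSpec:
        return LossSpec("scalar_quadratic", list(self.alpha_names))

    # sampling interface -------------------------------------------------

    def sample_phi(self, rng: np.random.Generator, K: int) -> np.ndarray:
        raise NotImplementedError

    def sample_alpha_given_phi(self, rng: np.random.Generator, phi: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def generate_draws(self, K: int, seed: int = 0) -> DrawsTable:
        """Exact joint sample of (phi, alpha); reproducible by seed."""
        if K < 1:
            raise ValueError("K must be >= 1")
        rng = np.random.default_rng(seed)
        phi = self.sample_phi(rng, K)
        alpha = self.sample_alpha_given_phi(rng, phi)
        if alpha.ndim == 1:
            alpha = alpha[:, None]
        df = pd.DataFrame(np.hstack([phi, alpha]),
                          columns=list(self.phi_names) + list(self.alpha_names))
        return DrawsTable(df)

    def simulate_statistic(self, draws: DrawsTable, n: int, seed: int = 0) -> DrawsTable:
        """Attach a column 'T': the statistic of future data of size n, per draw."""
        raise NotImplementedError(f"fixture {self.name} has no future-data design")

    # closed forms -------------------------------------------------------

    def closed_form_evppi(self, phi_names=None) -> float:
        raise NotImplementedError

    def closed_form_evsi(self, n: int) -> float:
        raise NotImplementedError


@dataclass
class NormalKnownVar(ConjugateFixture):
    """alpha = theta ~ N(m0, sd0^2); future y_i ~ N(theta, s^2), T = mean(y)."""

    m0: float = 0.0
    sd0: float = 1.0
    s: float = 1.0
    name: str = "normal_known_var"
    phi_names: tuple[str, ...] = ("theta",)

    def __post_init__(self):
        if self.sd0 <= 0 or self.s <= 0:
            raise ValueError("sd0 and s must be positive")

    def sample_phi(self, rng, K):
        return rng.normal(self.m0, self.sd0, size=(K, 1))

    def sample_alpha_given_phi(self, rng, phi):
        return phi[:, 0]  # alpha IS theta

    def simulate_statistic(self, draws, n, seed=0):
        if n < 1:
            raise ValueError("future sample size n must be >= 1 (EVSI(0) = 0 exactly)")
        rng = np.random.default_rng(seed)
        theta = draws.column("theta")
        T = rng.normal(theta, self.s / np.sqrt(n))
        return draws.with_columns(T=T)

    def closed_form_evppi(self, phi_names=None) -> float:
        return self.sd0**2

    def closed_form_evsi(self, n: int) -> float:
        if n == 0:
            return 0.0
        post_var = 1.0 / (1.0 / self.sd0**2 + n / self.s**2)
        return self.sd0**2 - post_var


@dataclass
class BetaBinomial(ConjugateFixture):
    """alpha = p ~ Beta(a, b); future y ~ Bin(n, p), T = y / n."""

    a: float = 1.0
    b: float = 1.0
    name: str = "beta_binomial"
    phi_names: tuple[str, ...] = ("p",)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta hyperparameters must be positive")

    def sample_phi(self, rng, K):
        return rng.beta(self.a, self.b, size=(K, 1))

    def sample_alpha_given_phi(self, rng, phi):
        return phi[:, 0]

    def simulate_statistic(self, draws, n, seed=0):
        if n < 1:
            raise ValueError("future sample size n must be >= 1 (EVSI(0) = 0 exactly)")
        rng = np.random.default_rng(seed)
        p = draws.column("p")
        T = rng.binomial(n, p) / n
        return draws.with_columns(T=T)

    def closed_form_evppi(self, phi_names=None) -> float:
        return float(stats.beta(self.a, self.b).var())

    def closed_form_evsi(self, n: int) -> float:
        return exact_evsi_enumeration(self, n)


@dataclass
class LinearSum(ConjugateFixture):
    """phi_i ~ N(0, sigma_i^2) independent; alpha = sum_i phi_i + N(0, tau^2).

    EVPPI of any subset S is sum_{i in S} sigma_i^2 exactly.
    """

    sigmas: tuple[float, ...] = (1.0, 1.0)
    tau: float = 0.0
    name: str = "linear_sum"

    def __post_init__(self):
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")
        self.phi_names = tuple(f"phi{i + 1}" for i in range(len(self.sigmas)))

    def sample_phi(self, rng, K):
        return rng.normal(0.0, self.sigmas, size=(K, len(self.sigmas)))

    def sample_alpha_given_phi(self, rng, phi):
        noise = rng.normal(0.0, self.tau, size=phi.shape[0]) if self.tau > 0 else 0.0
        return phi.sum(axis=1) + noise

    def analytic_cov(self) -> np.ndarray:
        """Covariance of (phi_1..phi_p, alpha)."""
        p = len(self.sigmas)
        cov = np.zeros((p + 1, p + 1))
        v = np.asarray(self.sigmas) ** 2
        cov[:p, :p] = np.diag(v)
        cov[:p, p] = cov[p, :p] = v
        cov[p, p] = v.sum() + self.tau**2
        return cov

    def closed_form_evppi(self, phi_names=None) -> float:
        names = list(phi_names) if phi_names is not None else list(self.phi_names)
        idx = [self.phi_names.index(n) for n in names]
        return float(sum(self.sigmas[i] ** 2 for i in idx))

    def conditional_var(self, phi_names) -> float:
        """var(alpha | the named components) — constant in the Gaussian case."""
        return self.closed_form_evppi(self.phi_names) + self.tau**2 - self.closed_form_evppi(phi_names)


@dataclass
class TwoActionGaussian(ConjugateFixture):
    """Two actions: loss alpha1 = 0 and alpha2 ~ N(m, sd^2); phi = alpha2.

    EVPI = min(0, m) - E[min(0, alpha2)] with
    E[min(0, X)] = m * Phi(-m/sd) - sd * phi(m/sd).
    """

    m: float = 0.0
    sd: float = 1.0
    name: str = "two_action_gaussian"
    phi_names: tuple[str, ...] = ("alpha2_phi",)
    alpha_names: tuple[str, ...] = ("alpha1", "alpha2")

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def loss_spec(self) -> LossSpec:
        return LossSpec("finite_action", list(self.alpha_names))

    def sample_phi(self, rng, K):
        return rng.normal(self.m, self.sd, size=(K, 1))

    def sample_alpha_given_phi(self, rng, phi):
        return np.column_stack([np.zeros(phi.shape[0]), phi[:, 0]])

    def closed_form_evpi(self) -> float:
        z = self.m / self.sd
        e_min = self.m * stats.norm.cdf(-z) - self.sd * stats.norm.pdf(z)
        return min(0.0, self.m) - e_min

    def closed_form_evppi(self, phi_names=None) -> float:
        # phi determines alpha exactly, so partial = perfect information
        return self.closed_form_evpi()


#: Fixture registry: EVPPI proportions of the baseline loss span ~10%-90%.
FIXTURES: dict[str, ConjugateFixture] = {
    "normal_known_var": NormalKnownVar(m0=0.0, sd0=1.0, s=1.0),
    "beta_binomial": BetaBinomial(a=2.0, b=8.0),
    "linear_sum": LinearSum(sigmas=(1.0, 1.0)),          # EVPPI(phi1) = 50%
    "linear_sum_weak": LinearSum(sigmas=(0.35, 1.0)),    # EVPPI(phi1) ~ 11%
    "linear_sum_strong": LinearSum(sigmas=(3.0, 1.0)),   # EVPPI(phi1) = 90%
    "two_action_gaussian": TwoActionGaussian(m=0.0, sd=1.0),
}


def get_fixture(name: str) -> ConjugateFixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}") from None


def generate_draws(fixture: ConjugateFixture | str, K: int, seed: int = 0) -> DrawsTable:
    """Exact joint samples of (phi, alpha) under the fixture."""
    if isinstance(fixture, str):
        fixture = get_fixture(fixture)
    return fixture.generate_draws(K, seed=seed)


# ---------------------------------------------------------------------------
# Oracles


def nested_mc_evppi(fixture: ConjugateFixture | str, phi_names=None,
                    K_outer: int = 2000, K_inner: int = 2000, seed: int = 0) -> float:
    """Two-loop Monte Carlo estimate of the EVPPI — a test oracle only.

    Outer loop draws phi; inner loop draws alpha | phi and evaluates the
    expected loss under the optimal decision given phi.  Expensive by
    design; never used by the estimators it checks.
    """
    if isinstance(fixture, str):
        fixture = get_fixture(fixture)
    if phi_names is not None and list(phi_names) != list(fixture.phi_names):
        if not isinstance(fixture, LinearSum):
            raise ValueError(f"fixture {fixture.name} only supports the full phi set")
    rng = np.random.default_rng(seed)
    loss = fixture.loss_spec()

    if isinstance(fixture, LinearSum) and phi_names is not None \
            and list(phi_names) != list(fixture.phi_names):
        # condition on a subset: alpha | phi_S ~ N(sum phi_S, remaining var)
        names = list(phi_names)
        idx = [fixture.phi_names.index(n) for n in names]
        rest = [i for i in range(len(fixture.sigmas)) if i not in idx]
        phi = fixture.sample_phi(rng, K_outer)
        resid_sd = np.sqrt(sum(fixture.sigmas[i] ** 2 for i in rest) + fixture.tau**2)
        inner_vars = np.empty(K_outer)
        marginal = np.empty(K_outer)
        for k in range(K_outer):
            mean_k = phi[k, idx].sum()
            inner = rng.normal(mean_k, resid_sd, size=K_inner)
            inner_vars[k] = inner.var(ddof=1)
            marginal[k] = inner[0]
        return float(np.var(marginal, ddof=1) - inner_vars.mean())

    phi = fixture.sample_phi(rng, K_outer)
    if loss.kind == "finite_action":
        # alpha | phi is deterministic for the registered finite-action fixture
        inner_loss = np.empty(K_outer)
        marginal = np.empty((K_outer, len(fixture.alpha_names)))
        for k in range(K_outer):
            inner = fixture.sample_alpha_given_phi(rng, np.repeat(phi[k:k + 1], K_inner, axis=0))
            inner_loss[k] = inner.mean(axis=0).min()
            marginal[k] = inner[0]
        base = marginal.mean(axis=0).min()
        return float(base - inner_loss.mean())

    inner_vars = np.empty(K_outer)
    marginal = np.empty(K_outer)
    for k in range(K_outer):
        inner = fixture.sample_alpha_given_phi(rng, np.repeat(phi[k:k + 1], K_inner, axis=0))
        inner = np.asarray(inner, dtype=float).ravel()
        if inner.size == 1:  # alpha deterministic given phi
            inner_vars[k] = 0.0
            marginal[k] = inner[0]
        else:
            inner_vars[k] = inner.var(ddof=1)
            marginal[k] = inner[0]
    return float(np.var(marginal, ddof=1) - inner_vars.mean())


def exact_evsi_enumeration(fixture: ConjugateFixture | str, n: int) -> float:
    """EVSI by exact enumeration (binomial) or the conjugate normal formula."""
    if isinstance(fixture, str):
        fixture = get_fixture(fixture)
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return 0.0
    if isinstance(fixture, NormalKnownVar):
        return fixture.closed_form_evsi(n)
    if isinstance(fixture, BetaBinomial):
        a, b = fixture.a, fixture.b
        prior_var = stats.beta(a, b).var()
        y = np.arange(n + 1)
        log_pmf = (stats.betabinom(n, a, b).logpmf(y))
        post_var = stats.beta(a + y, b + n - y).var()
        return float(prior_var - np.exp(log_pmf) @ post_var)
    raise ValueError(
        f"no exact EVSI oracle for fixture {fixture.name}; "
        "supported: normal_known_var, beta_binomial"
    )
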