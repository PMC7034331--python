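"""Posterior-predictive simulation of future studies and their statistics.

For EVSI the information in a future dataset y must be reduced to a
low-dimensional sufficient statistic T(y).  Two candidate designs are
supported, mirroring the surveillance sources that inform undiagnosed
HIV prevalence:

``gum_anon``
    A further anonymous seroprevalence survey of n previously undiagnosed
    GUM-clinic attenders: y ~ Binomial(n, pi_GA) per posterior draw, with
    T(y) = y / n, the empirical prevalence.

``gmshs``
    A further venue-based survey of n previously undiagnosed MSM.  The
    number attending GUM clinics is N_G ~ Binomial(n, q) with the venue
    GMSM fraction q resampled per draw from its Jeffreys posterior given
    the observed 493 / 945 split; positives are Y_G ~ Binomial(N_G, p_G)
    and Y_N ~ Binomial(n - N_G, p_N).  T(y) is the plug-in odds ratio
    built from Jeffreys-smoothed proportions (y + 0.5) / (N + 1), which
    keeps T finite when a denominator is empty.

Each entry of an EVSI curve re-simulates the design independently with a
seed derived from (seed, n), so curves are reproducible and statistically
independent across sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import DrawsTable
from .loss import LossSpec
from .voi import evsi

__all__ = ["FutureDesign", "PredictiveStatistics", "simulate_gum_anon",
           "simulate_gmshs", "simulate_design", "evsi_curve"]

DESIGN_SOURCES = ("gum_anon", "gmshs")

#: Observed GMSHS venue split (GMSM, NGMSM) behind the Jeffreys posterior for q.
GMSHS_SPLIT = (493, 452)


@dataclass(frozen=True)
class FutureDesign:
    """A candidate future study: data source and sample size."""

    source: str
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in DESIGN_SOURCES:
            raise ValueError(f"source must be one of {DESIGN_SOURCES}")
        if self.n < 1:
            raise ValueError("future sample size n must be >= 1 (EVSI(0) = 0 exactly)")


@dataclass
class PredictiveStatistics:
    """Per-draw sufficient statistics T(y) of a simulated future study."""

    T: np.ndarray = field(repr=False)
    design: FutureDesign
    counts: dict = field(default_factory=dict, repr=False)

    def attach(self, draws: DrawsTable, column: str = "T") -> DrawsTable:
        return draws.with_columns(**{column: self.T})


def _rng_for(seed: int, n: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(n))))


def simulate_gum_anon(draws: DrawsTable, n: int, seed: int = 0) -> PredictiveStatistics:
    """Future GUM Anon survey: T = y/n with y ~ Binomial(n, pi_GA) per draw."""
    design = FutureDesign("gum_anon", n, seed)
    rng = _rng_for(seed, n)
    pi_GA = draws.column("pi_GA")
    y = rng.binomial(n, pi_GA)
    return PredictiveStatistics(T=y / n, design=design, counts={"y": y})


def simulate_gmshs(draws: DrawsTable, n: int, seed: int = 0,
                   split: tuple[int, int] = GMSHS_SPLIT) -> PredictiveStatistics:
    """Future GMSHS survey: T = smoothed odds(p_N-hat) / odds(p_G-hat)."""
    design = FutureDesign("gmshs", n, seed)
    rng = _rng_for(seed, n)
    p_G = draws.column("p_G_GM")
    p_N = draws.column("p_N_GM")
    K = draws.K
    q = rng.beta(split[0] + 0.5, split[1] + 0.5, size=K)
    N_G = rng.binomial(n, q)
    N_N = n - N_G
    Y_G = rng.binomial(N_G, p_G)
    Y_N = rng.binomial(N_N, p_N)
    phat_G = (Y_G + 0.5) / (N_G + 1.0)
    phat_N = (Y_N + 0.5) / (N_N + 1.0)
    T = (phat_N / (1.0 - phat_N)) / (phat_G / (1.0 - phat_G))
    return PredictiveStatistics(
        T=T, design=design,
        counts={"N_G": N_G, "Y_G": Y_G, "Y_N": Y_N},
    )


def simulate_design(draws: DrawsTable, source: str, n: int, seed: int = 0) -> PredictiveStatistics:
    if source == "gum_anon":
        return simulate_gum_anon(draws, n, seed=seed)
    if source == "gmshs":
        return simulate_gmshs(draws, n, seed=seed)
    raise ValueError(f"unknown design source {source!r}; choose from {DESIGN_SOURCES}")


def evsi_curve(draws: DrawsTable, design_source: str, n_grid, loss: LossSpec,
               method: str = "gam", settings: dict | None = None,
               seed: int = 0, n_se_sims: int = 200, n_reps: int = 1) -> pd.DataFrame:
    """EVSI across a grid of future sample sizes.

    ``n_reps`` independent simulate -> regress -> estimate cycles per n,
    averaged.  The posterior draws are common to every n, so replicate
    averaging targets exactly the per-n simulation noise that would
    otherwise jitter the shape of the curve (and any argmax taken on
    it).  Columns: ``n``, ``evsi``, ``se``, ``residual_loss`` (the
    expected loss — for quadratic loss, the expected variance —
    remaining after collecting the data) and ``residual_sd`` (its square
    root, for scalar quadratic loss).
    """
    n_grid = [int(n) for n in n_grid]
    if len(n_grid) == 0:
        raise ValueError("n_grid is empty")
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for n in n_grid:
        values, ses, residuals = [], [], []
        for rep in range(n_reps):
            stats = simulate_design(draws, design_source, n,
                                    seed=seed + 1_000_003 * rep)
            with_T = stats.attach(draws)
            est = evsi(with_T, ["T"], loss, method=method, settings=settings,
                       seed=seed, n_se_sims=n_se_sims, min_draws=min(draws.K, 1000))
            values.append(est.value)
            ses.append(est.standard_error)
            residuals.append(est.residual_loss)
        rows.append({
            "n": n,
            "evsi": float(np.mean(values)),
            "se": float(np.sqrt(np.mean(np.square(ses)) / n_reps)),
            "residual_loss": float(np.mean(residuals)),
            "residual_sd": float(np.sqrt(np.mean(residuals)))
            if loss.kind == "scalar_quadratic" else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["baseline_loss"] = float(rows[0]["evsi"] + rows[0]["residual_loss"]) \
        if loss.kind in ("scalar_quadratic",) else None
    out.attrs["design_source"] = design_source
    out.attrs["loss_kind"] = loss.kind
    return out
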