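"""Expected net benefit of sampling: monetize EVSI and subtract costs.

The decision-maker states a willingness-to-pay lambda for precision —
either per unit of variance reduction (``linear_variance``,
b = lambda * (v0 - v_y)) or per halving of the variance (``halving``,
b = lambda * log2(v0 / v_y)) — and a sampling cost that is linear in the
number of participants.  The expected net benefit of sampling at size n
is E[b(y)] - c(n); its argmax over the design grid is the optimal sample
size.

Monte Carlo noise in a per-n EVSI curve would jitter the argmax, so the
coarse EVSI curve is first made monotone by isotonic regression
(anchored at EVSI(0) = 0) and then interpolated onto the dense grid with
a monotone cubic (PCHIP).  The raw coarse-grid argmax is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

__all__ = ["BenefitSpec", "CostSpec", "EnbsCurve", "expected_benefit", "enbs_curve"]


@dataclass(frozen=True)
class BenefitSpec:
    """Willingness-to-pay for precision.

    kind ``linear_variance``: lam is currency per unit of variance
    reduction.  kind ``halving``: lam is currency per halving of the
    variance.
    """

    kind: str = "linear_variance"
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_variance", "halving"):
            raise ValueError("kind must be 'linear_variance' or 'halving'")
        if self.lam < 0:
            raise ValueError("willingness-to-pay lam must be nonnegative")


@dataclass(frozen=True)
class CostSpec:
    """Sampling cost: fixed_cost + unit_cost * n."""

    unit_cost: float = 0.0
    fixed_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_cost < 0 or self.fixed_cost < 0:
            raise ValueError("costs must be nonnegative")

    def at(self, n) -> np.ndarray:
        return self.fixed_cost + self.unit_cost * np.asarray(n, dtype=float)


@dataclass
class EnbsCurve:
    """Expected benefit, cost and net benefit across sample sizes."""

    table: pd.DataFrame = field(repr=False)
    n_star: int
    n_star_raw: int
    benefit: BenefitSpec
    cost: CostSpec

    def to_json_dict(self) -> dict:
        return {
            "n_star": self.n_star,
            "n_star_raw": self.n_star_raw,
            "benefit_kind": self.benefit.kind,
            "lambda": self.benefit.lam,
            "unit_cost": self.cost.unit_cost,
            "fixed_cost": self.cost.fixed_cost,
            "max_net_benefit": float(self.table["net_benefit"].max()),
        }


def expected_benefit(v0: float, residual: float, spec: BenefitSpec) -> float:
    """Monetary value of reducing the expected loss from v0 to residual."""
    if v0 <= 0:
        raise ValueError("baseline variance v0 must be positive")
    # a tiny negative EVSI estimate means residual marginally above v0
    residual = float(np.clip(residual, None, v0))
    if spec.kind == "linear_variance":
        return spec.lam * (v0 - residual)
    if residual <= 0:
        raise ValueError("halving benefit undefined for residual variance <= 0")
    return spec.lam * float(np.log2(v0 / residual))


def enbs_curve(evsi_table: pd.DataFrame, benefit: BenefitSpec, cost: CostSpec,
               n_grid=None, baseline: float | None = None) -> EnbsCurve:
    """Net-benefit curve and optimal sample size from an EVSI table.

    ``evsi_table`` is the output of :func:`voisyn.future_studies.evsi_curve`
    (columns n, evsi, residual_loss).  ``n_grid`` is the dense evaluation
    grid (default: every integer from 1 to max(n) of the table).
    """
    if len(evsi_table) == 0:
        raise ValueError("EVSI table is empty")
    n_coarse = evsi_table["n"].to_numpy(dtype=float)
    ev = evsi_table["evsi"].to_numpy(dtype=float)
    if baseline is None:
        baseline = evsi_table.attrs.get("baseline_loss")
    if baseline is None:
        baseline = float((evsi_table["evsi"] + evsi_table["residual_loss"]).mean())

    # monotone smoothing anchored at EVSI(0) = 0, capped at the baseline
    iso = IsotonicRegression(y_min=0.0, y_max=baseline, increasing=True)
    ev_smooth = iso.fit_transform(np.concatenate([[0.0], n_coarse]),
                                  np.concatenate([[0.0], ev]))
    if n_grid is None:
        n_grid = np.arange(1, int(n_coarse.max()) + 1)
    n_grid = np.asarray(n_grid, dtype=int)
    interp = PchipInterpolator(np.concatenate([[0.0], n_coarse]), ev_smooth)
    ev_dense = np.clip(interp(n_grid.astype(float)), 0.0, baseline)

    ben = np.array([expected_benefit(baseline, baseline - e, benefit) for e in ev_dense])
    c = cost.at(n_grid)
    net = ben - c
    table = pd.DataFrame({"n": n_grid, "expected_benefit": ben, "cost": c,
                          "net_benefit": net})
    n_star = int(n_grid[int(np.argmax(net))])  # first index on ties

    ben_raw = np.array([expected_benefit(baseline, baseline - e, benefit)
                        for e in np.clip(ev, 0.0, baseline)])
    net_raw = ben_raw - cost.at(n_coarse)
    n_star_raw = int(n_coarse[int(np.argmax(net_raw))])
    return EnbsCurve(table=table, n_star=n_star, n_star_raw=n_star_raw,
                     benefit=benefit, cost=cost)
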