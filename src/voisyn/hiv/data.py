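"""Surveillance observations and assumption variants for the HIV model.

The model synthesizes six data sources on HIV among men who have sex with
men (MSM) in London, 2012:

* ONS: the male population count (Poisson observation of mu_pop).
* NATSAL: a survey classifying men as GUM-clinic-attending MSM (GMSM),
  non-attending MSM (NGMSM), previous MSM (PMSM) or neither
  (multinomial observation of the subgroup proportions rho).
* SOPHID: the register count of prevalent diagnosed HIV in MSM.
* HANDD: new HIV diagnoses made in GUM clinics, a lower bound on the
  diagnosed-and-attending fraction.
* GUMCAD: the GUM-clinic testing cascade (visitors, not previously
  diagnosed, offered a test, accepted, diagnosed).
* GUM Anon: an anonymous seroprevalence survey of previously undiagnosed
  clinic attenders.
* GMSHS: a venue-based survey giving undiagnosed prevalence among GMSM
  and NGMSM, used through the odds ratio between the two groups.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict

import yaml

__all__ = ["HivObservations", "AssumptionVariant", "load_observations",
           "london_msm_2012", "variant"]

_COUNT_FIELDS = [
    "ypop", "y_G", "y_N", "y_P", "y_NAT", "y_M", "y_H",
    "g1", "g2", "g3", "g4", "g5", "g_A", "g_AN",
    "y_G_GM", "n_G_GM", "y_N_GM", "n_N_GM",
]


@dataclass(frozen=True)
class HivObservations:
    """Observed counts from the six surveillance/survey sources."""

    ypop: int       # ONS male population count
    y_G: int        # NATSAL: GMSM
    y_N: int        # NATSAL: NGMSM
    y_P: int        # NATSAL: PMSM
    y_NAT: int      # NATSAL denominator
    y_M: int        # SOPHID: prevalent diagnosed MSM
    y_H: int        # HANDD: new GUM-clinic diagnoses
    g1: int         # GUMCAD: clinic visitors
    g2: int         # GUMCAD: not previously diagnosed
    g3: int         # GUMCAD: offered an HIV test
    g4: int         # GUMCAD: accepted the test
    g5: int         # GUMCAD: diagnosed
    g_A: int        # GUM Anon: positive
    g_AN: int       # GUM Anon: tested
    y_G_GM: int     # GMSHS: positive among GMSM
    n_G_GM: int     # GMSHS: GMSM tested
    y_N_GM: int     # GMSHS: positive among NGMSM
    n_N_GM: int     # GMSHS: NGMSM tested

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if not (self.g1 >= self.g2 >= self.g3 >= self.g4 >= self.g5):
            raise ValueError("GUMCAD cascade must be nonincreasing: g1 >= ... >= g5")
        if self.y_G + self.y_N + self.y_P > self.y_NAT:
            raise ValueError("NATSAL subgroup counts exceed the survey denominator")
        if self.g_A > self.g_AN:
            raise ValueError("GUM Anon positives exceed the number tested")
        if self.y_G_GM > self.n_G_GM or self.y_N_GM > self.n_N_GM:
            raise ValueError("GMSHS positives exceed denominators")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class AssumptionVariant:
    """Structural-assumption toggles (independent of each other).

    ``undiagnosed_source``: how undiagnosed GMSM prevalence is built —
    ``"gumcad_priors"`` (base case: the unoffered + opt-out decomposition
    of the GUMCAD cascade with its strong priors) or ``"gum_anon_only"``
    (variant (a): a free U(0,1) parameter, informed only through the GUM
    Anon likelihood; GUMCAD still informs the cascade probabilities).

    ``gumcad_informs_diagnosed``: variant (b) — diagnosed GMSM prevalence
    is set directly from the cascade as (1 - gamma1) + gamma1 g2 g3 g4.
    """

    undiagnosed_source: str = "gumcad_priors"
    gumcad_informs_diagnosed: bool = False

    def __post_init__(self) -> None:
        if self.undiagnosed_source not in ("gumcad_priors", "gum_anon_only"):
            raise ValueError(
                "undiagnosed_source must be 'gumcad_priors' or 'gum_anon_only'"
            )

    @property
    def free_pibar_G(self) -> bool:
        return self.undiagnosed_source == "gum_anon_only"

    @property
    def label(self) -> str:
        if self.free_pibar_G and self.gumcad_informs_diagnosed:
            return "ab"
        if self.free_pibar_G:
            return "a"
        if self.gumcad_informs_diagnosed:
            return "b"
        return "base"


def variant(name: str) -> AssumptionVariant:
    """Shorthand constructor: 'base', 'a', 'b' or 'ab'."""
    name = name.lower()
    table = {
        "base": AssumptionVariant(),
        "a": AssumptionVariant(undiagnosed_source="gum_anon_only"),
        "b": AssumptionVariant(gumcad_informs_diagnosed=True),
        "ab": AssumptionVariant(undiagnosed_source="gum_anon_only",
                                gumcad_informs_diagnosed=True),
    }
    if name not in table:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(table)}")
    return table[name]


def load_observations(path) -> HivObservations:
    """Read observations from a YAML/JSON mapping with HivObservations field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return HivObservations(**{k: int(v) for k, v in raw.items()})


def london_msm_2012() -> HivObservations:
    """The London 2012 MSM dataset shipped with the package."""
    ref = importlib.resources.files("voisyn.hiv") / "data" / "london_msm_2012.yaml"
    raw = yaml.safe_load(ref.read_text())
    return HivObservations(**{k: int(v) for k, v in raw.items()})
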