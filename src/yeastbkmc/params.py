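"""Model parameters.

All rates are per minute; sizes are dimensionless "physiological size" units
(1 size unit ~ 61.4 fL when compared against volume measurements).  Defaults
are the published wild-type parameterization: every Boolean switch has
propensity 1/min except Cln2 (10/min, an unstable protein slaved to SBF),
growth rate mu = 0.007/min (mass-doubling time ~99 min, glucose), a
lognormal 30-min multi-step delay for the mitotic activations, and lognormal
distributions for the birth-assigned critical size S0 and the mother's
division fraction f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .state import VARIABLES

#: propensity-constant attribute per Boolean variable, in canonical order
PROPENSITY_NAMES: tuple[str, ...] = (
    "p_Cdh1",
    "p_SBF",
    "p_Cln2",
    "p_Clb5",
    "p_Clb2G",
    "p_Clb2M",
    "p_Cdc20",
)


@dataclass(frozen=True)
class Parameters:
    """Rate constants and stochastic-distribution settings.

    Attributes use the published config names one-to-one (``p_G1``,
    ``p_Cdh1`` ... ``f_CV``, ``mu``).
    """

    p_G1: float = 1.0
    p_Cdh1: float = 1.0
    p_SBF: float = 1.0
    p_Cln2: float = 10.0
    p_Clb5: float = 1.0
    p_Clb2G: float = 1.0
    p_Clb2M: float = 1.0
    p_Cdc20: float = 1.0
    mu: float = 0.007
    t_M_mean: float = 30.0
    t_M_CV: float = 0.30
    S0_mean: float = 0.4
    S0_CV: float = 0.05
    f_mean: float = 0.58
    f_CV: float = 0.05

    def __post_init__(self) -> None:
        for name in PROPENSITY_NAMES + ("p_G1", "t_M_mean", "S0_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        for name in ("t_M_CV", "S0_CV", "f_CV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.f_mean < 1.0:
            raise ValueError("f_mean must lie in (0, 1)")

    @property
    def propensity_vector(self) -> tuple[float, ...]:
        """Per-variable switching rates, in the canonical variable order."""
        return tuple(getattr(self, name) for name in PROPENSITY_NAMES)

    @property
    def mass_doubling_time(self) -> float:
        """ln 2 / mu, in minutes (inf when mu = 0)."""
        return math.log(2) / self.mu if self.mu > 0 else math.inf

    def with_mass_doubling_time(self, mdt: float) -> "Parameters":
        """Copy with mu set from a mass-doubling time in minutes."""
        if mdt <= 0:
            raise ValueError("mass-doubling time must be positive")
        return replace(self, mu=math.log(2) / mdt)

    def replace(self, **changes: float) -> "Parameters":
        unknown = set(changes) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


assert len(PROPENSITY_NAMES) == len(VARIABLES)
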