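"""Closed-form flux-force relationships.

The net rate of an enzyme-catalysed reaction partitions into a forward flux
J+ and a reverse flux J-, with ln(J+/J-) = -dG'/RT.  The three functions
here express the ratio, the reverse share of the total flux, and the
flux-force efficacy (net over total flux) as functions of the reaction
Gibbs energy change.  All inputs are kJ/mol; all outputs are fractions
(never percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ThermoConstants",
    "DrivingForce",
    "forward_reverse_ratio",
    "reverse_flux_fraction",
    "flux_force_efficacy",
]

#: |dg|/RT beyond which exponentials are evaluated asymptotically.
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature used throughout one analysis.

    Defaults give RT ~ 2.479 kJ/mol (298.15 K), the standard-condition
    convention.
    """

    gas_constant_r: float = 8.314e-3  # kJ / (mol K)
    temperature_k: float = 298.15
    rt: float = field(init=False)

    def __post_init__(self) -> None:
        rt = self.gas_constant_r * self.temperature_k
        if not (rt > 0 and math.isfinite(rt)):
            raise ValueError(f"RT must be a positive finite number, got {rt}")
        object.__setattr__(self, "rt", rt)


#: Module-wide default constants (298.15 K).
DEFAULT_CONSTANTS = ThermoConstants()


@dataclass(frozen=True)
class DrivingForce:
    """A reaction driving force in kJ/mol, equal to -dG' by definition."""

    value: float

    @classmethod
    def from_dg_prime(cls, dg_prime: float) -> "DrivingForce":
        return cls(-dg_prime)

    @property
    def dg_prime(self) -> float:
        return -self.value


def _check_finite(dg_prime: float) -> float:
    dg = float(dg_prime)
    if not math.isfinite(dg):
        raise ValueError(f"dg_prime must be finite, got {dg_prime!r}")
    return dg


def forward_reverse_ratio(
    dg_prime: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Ratio J+/J- of forward to reverse flux, exp(-dg'/RT).

    Strictly decreasing in ``dg_prime``; equals 1 at equilibrium.
    """
    dg = _check_finite(dg_prime)
    z = -dg / constants.rt
    if z > _EXP_CLAMP:
        return math.inf
    return math.exp(z)


def reverse_flux_fraction(
    dg_prime: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Share J-/(J+ + J-) of the total flux running in reverse.

    Equals 1/(1 + exp(-dg'/RT)); 0.5 at equilibrium, -> 0 for strongly
    forward-driven reactions.
    """
    dg = _check_finite(dg_prime)
    z = -dg / constants.rt
    if z > _EXP_CLAMP:
        return 0.0
    if z < -_EXP_CLAMP:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def flux_force_efficacy(
    dg_prime: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Net flux over total flux, (J+ - J-)/(J+ + J-) = tanh(-dg'/(2 RT)).

    Lies in (-1, 1); negative when the reaction runs net backwards
    (``dg_prime > 0``).
    """
    dg = _check_finite(dg_prime)
    return math.tanh(-dg / (2.0 * constants.rt))
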