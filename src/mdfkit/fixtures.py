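"""Deterministic synthetic pathways with known closed-form optima.

Linear chains with fixed terminal concentrations admit an analytic MDF
(when no intermediate bound binds), which serves as an independent oracle
for the LP solver.  ``random_instance`` produces small seeded instances for
property and grid-oracle testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConstraintError
from .model import ConcentrationConstraints, PathwayModel, Reaction
from .thermo import DEFAULT_CONSTANTS, ThermoConstants

__all__ = [
    "ChainSpec",
    "make_chain",
    "chain_constraints",
    "chain_mdf_closed_form",
    "random_instance",
]


@dataclass(frozen=True)
class ChainSpec:
    """A linear chain C0 -> C1 -> ... -> Cn with unit molecularities.

    ``dg0`` lists each step's standard energy (kJ/mol); terminal compound
    concentrations are fixed, intermediates range over
    (intermediate_lower, intermediate_upper).
    """

    dg0: tuple[float, ...]
    c_start: float = 1e-3
    c_end: float = 1e-3
    intermediate_lower: float = 1e-12
    intermediate_upper: float = 1e3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dg0) < 1:
            raise ValueError("chain needs at least one reaction")
        for c in (self.c_start, self.c_end):
            if not (c > 0 and math.isfinite(c)):
                raise ValueError(f"terminal concentration {c} not positive finite")
        if not (0 < self.intermediate_lower <= self.intermediate_upper):
            raise ValueError("invalid intermediate bounds")

    @property
    def n_reactions(self) -> int:
        return len(self.dg0)


def make_chain(spec: ChainSpec, name: str = "chain") -> PathwayModel:
    """Build the chain pathway C0 <=> C1 <=> ... with deterministic ids."""
    pw = PathwayModel(name=name, metadata={"fixture": "chain", "seed": spec.seed})
    for i, g in enumerate(spec.dg0):
        pw.add_reaction(
            Reaction.from_formula(f"R{i + 1}", f"C{i} <=> C{i + 1}", dg0_prime=g)
        )
    return pw


def chain_constraints(spec: ChainSpec) -> ConcentrationConstraints:
    """Terminals fixed, intermediates within the spec's wide bounds."""
    n = spec.n_reactions
    cons = ConcentrationConstraints(
        default_lower=spec.intermediate_lower,
        default_upper=spec.intermediate_upper,
    )
    cons.fix("C0", spec.c_start)
    cons.fix(f"C{n}", spec.c_end)
    return cons


def chain_mdf_closed_form(
    spec: ChainSpec, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Analytic MDF for an interior-optimum chain.

    With terminals fixed and all intermediate bounds slack, every step
    carries the same driving force, giving

        MDF = -(sum(dg0) + RT (ln c_end - ln c_start)) / n.

    The implied optimal intermediate log-concentrations are checked against
    the bounds; a binding intermediate invalidates the formula and raises
    :class:`ConstraintError` with a diagnostic.
    """
    rt = constants.rt
    n = spec.n_reactions
    b = -(sum(spec.dg0) + rt * (math.log(spec.c_end) - math.log(spec.c_start))) / n
    # equal driving forces determine x recursively: x_j = x_{j-1} - (g_j + B)/RT
    x = math.log(spec.c_start)
    lo = math.log(spec.intermediate_lower)
    hi = math.log(spec.intermediate_upper)
    for j, g in enumerate(spec.dg0[:-1]):
        x = x - (g + b) / rt
        if not (lo + 1e-9 < x < hi - 1e-9):
            raise ConstraintError(
                f"closed form invalid: intermediate C{j + 1} optimum "
                f"exp({x:.3f}) M hits its bounds "
                f"[{spec.intermediate_lower}, {spec.intermediate_upper}]"
            )
    return b


def random_instance(
    n_compounds: int = 4,
    n_reactions: int = 3,
    seed: int = 0,
) -> PathwayModel:
    """Seeded random sparse pathway: molecularities in {1, 2}, dg0 in
    [-30, +10] kJ/mol.  Small by construction (<= 5 x 5)."""
    if not (1 <= n_reactions <= 5):
        raise ValueError("n_reactions must be in 1..5")
    if not (2 <= n_compounds <= 5):
        raise ValueError("n_compounds must be in 2..5")
    rng = np.random.default_rng(seed)
    pw = PathwayModel(
        name=f"random-{seed}", metadata={"fixture": "random", "seed": seed}
    )
    from .model import Compound

    cids = [f"M{i}" for i in range(n_compounds)]
    for cid in cids:
        pw.add_compound(Compound(cid))
    for j in range(n_reactions):
        n_side = rng.integers(1, min(3, n_compounds))
        subs = rng.choice(n_compounds, size=n_side, replace=False)
        remaining = [i for i in range(n_compounds) if i not in subs]
        prods = rng.choice(
            remaining, size=int(rng.integers(1, min(3, len(remaining) + 1))),
            replace=False,
        )
        stoich = {cids[i]: -float(rng.integers(1, 3)) for i in subs}
        stoich.update({cids[i]: float(rng.integers(1, 3)) for i in prods})
        pw.add_reaction(
            Reaction(
                id=f"R{j + 1}",
                stoichiometry=stoich,
                dg0_prime=float(rng.uniform(-30.0, 10.0)),
            )
        )
    return pw
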