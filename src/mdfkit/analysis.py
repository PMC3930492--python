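"""Pathway-level studies built on the solver.

pH sweeps over tabulated standard energies, declarative ATP-yield
accounting, MDF-vs-yield Pareto fronts, and a relative enzyme-demand
report derived from flux-force efficacies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .lp import MDFResult, solve_mdf
from .model import ConcentrationConstraints, PathwayModel
from .thermo import DEFAULT_CONSTANTS, ThermoConstants, flux_force_efficacy

__all__ = [
    "PhSweepResult",
    "PathwayComparison",
    "ph_sweep",
    "atp_yield",
    "pareto_front",
    "enzyme_demand_report",
    "compare_pathways",
    "DEFAULT_PO_RULES",
]

#: ATP produced per reduced carrier in oxidative phosphorylation
#: (P/O ratio 1.5 for NAD(P)H and ferredoxin pairs, 1.0 for quinols).
DEFAULT_PO_RULES: dict[str, float] = {
    "NADH": 1.5,
    "NADPH": 1.5,
    "Fd_pair": 1.5,
    "quinol": 1.0,
}


@dataclass(frozen=True)
class PhSweepPoint:
    ph: float
    mdf: float
    bottlenecks: tuple[str, ...]


@dataclass
class PhSweepResult:
    points: list[PhSweepPoint]

    def __iter__(self):
        return iter(self.points)

    def to_rows(self) -> list[tuple[float, float, str]]:
        return [(p.ph, p.mdf, ";".join(p.bottlenecks)) for p in self.points]


def ph_sweep(
    pathway: PathwayModel,
    constraints: ConcentrationConstraints | None,
    ph_values: Sequence[float],
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    tie_break: bool = False,
) -> PhSweepResult:
    """Re-solve the MDF LP at each pH with energies interpolated from the
    per-reaction dg0_by_ph tables.  No extrapolation outside a table."""
    phs = [float(p) for p in ph_values]
    if any(b <= a for a, b in zip(phs, phs[1:])):
        raise ValueError("pH grid must be strictly increasing")
    points = []
    for ph in phs:
        result = solve_mdf(
            pathway.with_dg0_at_ph(ph), constraints, constants, tie_break=tie_break
        )
        points.append(
            PhSweepPoint(
                ph=ph, mdf=result.mdf, bottlenecks=tuple(result.bottlenecks())
            )
        )
    return PhSweepResult(points)


def atp_yield(
    atp_accounting: Mapping | None,
    po_rules: Mapping[str, float] | None = None,
) -> float:
    """ATP per pathway turn from substrate-level phosphorylation plus
    redox carriers converted at the configured P/O ratios."""
    rules = dict(DEFAULT_PO_RULES if po_rules is None else po_rules)
    if not atp_accounting:
        return 0.0
    total = float(atp_accounting.get("substrate_level_atp", 0.0))
    for carrier, count in (atp_accounting.get("carriers") or {}).items():
        if carrier not in rules:
            raise ConfigurationError(
                f"unknown redox carrier {carrier!r}; known: {sorted(rules)}"
            )
        total += float(count) * rules[carrier]
    return total


def pareto_front(points: Sequence[tuple[float, float]]) -> list[bool]:
    """2-D maximization dominance flags; ties are non-dominating."""
    pts = [(float(a), float(b)) for a, b in points]
    if any(not (math.isfinite(a) and math.isfinite(b)) for a, b in pts):
        raise ValueError("pareto_front requires finite values")
    flags = []
    for i, (a, b) in enumerate(pts):
        dominated = any(
            (c >= a and d >= b) and (c > a or d > b)
            for j, (c, d) in enumerate(pts)
            if j != i
        )
        flags.append(not dominated)
    return flags


@dataclass(frozen=True)
class PathwayComparison:
    id: str
    mdf: float
    atp_yield: float
    on_pareto_front: bool


def compare_pathways(
    pathways: Sequence[PathwayModel],
    constraints: ConcentrationConstraints | None = None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    po_rules: Mapping[str, float] | None = None,
) -> list[PathwayComparison]:
    """MDF and ATP yield per pathway, flagged by Pareto dominance."""
    entries = []
    for pw in pathways:
        result = solve_mdf(pw, constraints, constants)
        entries.append((pw.name or f"pathway{len(entries)}", result.mdf,
                        atp_yield(pw.atp_accounting, po_rules)))
    flags = pareto_front([(m, y) for _, m, y in entries])
    return [
        PathwayComparison(pid, m, y, flag)
        for (pid, m, y), flag in zip(entries, flags)
    ]


def enzyme_demand_report(
    result: MDFResult, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> dict[str, float]:
    """Fold-excess enzyme per reaction versus an irreversible enzyme at the
    same net flux: 1/efficacy at the optimal dG'.  Reactions at or beyond
    equilibrium get an infinite factor (with a warning)."""
    if result.solver_status != "optimal" or result.drg_prime_opt is None:
        raise ValueError("enzyme_demand_report requires an optimal MDFResult")
    report: dict[str, float] = {}
    for rid, dg in zip(result.reaction_ids, result.drg_prime_opt):
        eff = flux_force_efficacy(float(dg), constants)
        if eff <= 0:
            warnings.warn(
                f"reaction {rid!r} has non-positive efficacy at the optimum; "
                "enzyme demand is unbounded"
            )
            report[rid] = math.inf
        else:
            report[rid] = 1.0 / eff
    return report
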