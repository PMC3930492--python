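"""Pathway data model.

Compounds, reactions with actual molecularities, the stoichiometric matrix
(rows = compounds, columns = reactions), the standard-energy vector, and
concentration constraints.  Concentrations are molar in every public
interface; natural-log values are internal to the solver.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ConstraintError, FormulaParseError
from .thermo import DEFAULT_CONSTANTS, ThermoConstants

__all__ = [
    "Compound",
    "RatioConstraint",
    "Reaction",
    "PathwayModel",
    "ConcentrationConstraints",
    "parse_reaction_formula",
    "format_reaction_formula",
    "build_matrices",
    "compute_drg_prime",
    "default_constraints",
]

_ARROW = "<=>"
_TOKEN_RE = re.compile(r"^(?:(\d+(?:\.\d+)?|\.\d+)\s+)?([A-Za-z_][\w\-+'\[\]]*)$")


def parse_reaction_formula(text: str) -> dict[str, float]:
    """Parse ``"2 A + B <=> C"`` into ``{"A": -2.0, "B": -1.0, "C": 1.0}``.

    Omitted coefficients mean 1.  Left-hand (substrate) ids get negative
    coefficients, right-hand (product) ids positive.  Raises
    :class:`FormulaParseError` for malformed tokens, duplicate ids on one
    side, or explicit zero coefficients.
    """
    if _ARROW not in text:
        raise FormulaParseError(f"missing '{_ARROW}' arrow in formula {text!r}")
    left, _, right = text.partition(_ARROW)
    stoich: dict[str, float] = {}
    for side_text, sign in ((left, -1.0), (right, +1.0)):
        seen: set[str] = set()
        offset = 0 if sign < 0 else len(left) + len(_ARROW)
        for term in side_text.split("+"):
            stripped = term.strip()
            position = offset + text[offset:].find(stripped) if stripped else offset
            if not stripped:
                raise FormulaParseError(
                    f"empty term in formula {text!r}", position=position
                )
            m = _TOKEN_RE.match(stripped)
            if m is None:
                raise FormulaParseError(
                    f"malformed term {stripped!r} in formula {text!r}",
                    position=position,
                )
            coef = float(m.group(1)) if m.group(1) else 1.0
            cid = m.group(2)
            if coef == 0:
                raise FormulaParseError(
                    f"zero coefficient for {cid!r} in formula {text!r}",
                    position=position,
                )
            if cid in seen:
                raise FormulaParseError(
                    f"duplicate compound {cid!r} on one side of {text!r}",
                    position=position,
                )
            seen.add(cid)
            stoich[cid] = stoich.get(cid, 0.0) + sign * coef
    # a compound on both sides may cancel; a zero net coefficient is invalid
    zeros = [cid for cid, c in stoich.items() if c == 0]
    if zeros:
        raise FormulaParseError(
            f"compound(s) {zeros} cancel to zero net coefficient in {text!r}"
        )
    return stoich


def _format_coef(coef: float) -> str:
    mag = abs(coef)
    if mag == 1:
        return ""
    if mag == int(mag):
        return f"{int(mag)} "
    return f"{mag:g} "


def format_reaction_formula(stoichiometry: Mapping[str, float]) -> str:
    """Inverse of :func:`parse_reaction_formula` on canonical formulas."""
    subs = [f"{_format_coef(c)}{cid}" for cid, c in stoichiometry.items() if c < 0]
    prods = [f"{_format_coef(c)}{cid}" for cid, c in stoichiometry.items() if c > 0]
    return f"{' + '.join(subs)} {_ARROW} {' + '.join(prods)}"


@dataclass
class Compound:
    """A metabolite.  Constraint metadata lives in ConcentrationConstraints."""

    id: str
    name: str = ""
    is_cofactor: bool = False


@dataclass(frozen=True)
class RatioConstraint:
    """Fixed concentration ratio numerator/denominator (e.g. ATP/ADP = 10)."""

    numerator: str
    denominator: str
    ratio: float

    def __post_init__(self) -> None:
        if not (self.ratio > 0 and math.isfinite(self.ratio)):
            raise ConstraintError(
                f"ratio {self.numerator}/{self.denominator} must be positive, "
                f"got {self.ratio}"
            )


@dataclass
class Reaction:
    """One pathway step: stoichiometry (actual molecularities, net-flux
    direction forward) and its standard transformed Gibbs energy in kJ/mol.

    ``dg0_by_ph`` optionally tabulates dg0_prime against pH as (pH, kJ/mol)
    pairs for sweep analyses.
    """

    id: str
    stoichiometry: dict[str, float]
    dg0_prime: float | None = None
    name: str = ""
    dg0_by_ph: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not any(c < 0 for c in self.stoichiometry.values()) or not any(
            c > 0 for c in self.stoichiometry.values()
        ):
            raise ConfigurationError(
                f"reaction {self.id!r} needs at least one substrate and one product"
            )
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ConfigurationError(f"reaction {self.id!r} has a zero coefficient")
        if self.dg0_by_ph is not None:
            self.dg0_by_ph = sorted((float(p), float(g)) for p, g in self.dg0_by_ph)

    @classmethod
    def from_formula(
        cls,
        id: str,
        formula: str,
        dg0_prime: float | None = None,
        name: str = "",
        dg0_by_ph: list[tuple[float, float]] | None = None,
    ) -> "Reaction":
        return cls(id, parse_reaction_formula(formula), dg0_prime, name, dg0_by_ph)

    @property
    def formula(self) -> str:
        return format_reaction_formula(self.stoichiometry)

    def dg0_at_ph(self, ph: float) -> float:
        """Linear interpolation of the dg0_by_ph table; no extrapolation."""
        if not self.dg0_by_ph:
            raise ConfigurationError(f"reaction {self.id!r} has no dg0_by_ph table")
        phs = [p for p, _ in self.dg0_by_ph]
        if ph < phs[0] or ph > phs[-1]:
            raise ConfigurationError(
                f"pH {ph} outside dg0_by_ph table range [{phs[0]}, {phs[-1]}] "
                f"for reaction {self.id!r}"
            )
        return float(np.interp(ph, phs, [g for _, g in self.dg0_by_ph]))


class PathwayModel:
    """Ordered reactions plus a compound registry.

    Compounds referenced by a reaction are auto-registered on insertion, so
    every stoichiometry key always resolves.  ``atp_accounting`` is an
    optional declarative stanza for yield analyses:
    ``{"substrate_level_atp": float, "carriers": {name: count}}``.
    """

    def __init__(
        self,
        name: str = "",
        metadata: dict | None = None,
        atp_accounting: dict | None = None,
    ):
        self.name = name
        self.metadata: dict = dict(metadata or {})
        self.atp_accounting = atp_accounting
        self._compounds: dict[str, Compound] = {}
        self.reactions: list[Reaction] = []

    # -- registry ---------------------------------------------------------
    def add_compound(self, compound: Compound) -> Compound:
        if compound.id in self._compounds:
            raise ConfigurationError(f"compound {compound.id!r} registered twice")
        self._compounds[compound.id] = compound
        return compound

    def add_reaction(self, reaction: Reaction) -> Reaction:
        if any(r.id == reaction.id for r in self.reactions):
            raise ConfigurationError(f"reaction {reaction.id!r} registered twice")
        for cid in reaction.stoichiometry:
            if cid not in self._compounds:
                self._compounds[cid] = Compound(cid)
        self.reactions.append(reaction)
        return reaction

    @property
    def compounds(self) -> dict[str, Compound]:
        return self._compounds

    @property
    def compound_ids(self) -> list[str]:
        return list(self._compounds)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def copy(self) -> "PathwayModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def with_dg0_at_ph(self, ph: float) -> "PathwayModel":
        """Copy with each reaction's dg0_prime interpolated from its table."""
        out = self.copy()
        for rxn in out.reactions:
            rxn.dg0_prime = rxn.dg0_at_ph(ph)
        return out


def build_matrices(pathway: PathwayModel) -> tuple[np.ndarray, np.ndarray]:
    """Stoichiometric matrix S (compounds x reactions) and energy vector G0.

    Row/column order follows registration order.  Raises
    :class:`ConfigurationError` for an empty pathway or a reaction with no
    dg0_prime.
    """
    if not pathway.reactions:
        raise ConfigurationError("pathway has no reactions")
    cids = pathway.compound_ids
    index = {cid: i for i, cid in enumerate(cids)}
    S = np.zeros((len(cids), len(pathway.reactions)))
    G0 = np.zeros(len(pathway.reactions))
    for j, rxn in enumerate(pathway.reactions):
        if rxn.dg0_prime is None:
            raise ConfigurationError(f"reaction {rxn.id!r} has no dg0_prime")
        G0[j] = rxn.dg0_prime
        for cid, coef in rxn.stoichiometry.items():
            S[index[cid], j] = coef
    return S, G0


def compute_drg_prime(
    G0: np.ndarray,
    S: np.ndarray,
    x: np.ndarray,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """dG' = G0 + RT * S^T x for a log-concentration vector x (ln molar)."""
    G0 = np.asarray(G0, dtype=float)
    S = np.asarray(S, dtype=float)
    x = np.asarray(x, dtype=float)
    if S.shape != (x.shape[0], G0.shape[0]):
        raise ValueError(
            f"dimension mismatch: S {S.shape}, x {x.shape}, G0 {G0.shape}"
        )
    return G0 + constants.rt * (S.T @ x)


class ConcentrationConstraints:
    """Concentration bounds, fixed values, and ratio constraints (molar).

    Per-compound overrides win over the defaults; a fixed value is encoded
    as an equal lower/upper pair.  Ratio constraints pin only the log
    difference of the two members, not their absolute level.
    """

    def __init__(
        self,
        default_lower: float = 1e-6,
        default_upper: float = 1e-2,
        bounds: Mapping[str, tuple[float | None, float | None]] | None = None,
        fixed: Mapping[str, float] | None = None,
        ratios: Iterable[RatioConstraint] | None = None,
    ):
        self.default_lower = float(default_lower)
        self.default_upper = float(default_upper)
        self.bounds: dict[str, tuple[float | None, float | None]] = dict(bounds or {})
        self.fixed: dict[str, float] = dict(fixed or {})
        self.ratios: list[RatioConstraint] = list(ratios or [])

    def copy(self) -> "ConcentrationConstraints":
        return ConcentrationConstraints(
            self.default_lower,
            self.default_upper,
            dict(self.bounds),
            dict(self.fixed),
            list(self.ratios),
        )

    # -- editing ----------------------------------------------------------
    def set_bound(
        self, compound_id: str, lower: float | None = None, upper: float | None = None
    ) -> None:
        lo, hi = self.bounds.get(compound_id, (None, None))
        if lower is not None:
            lo = float(lower)
        if upper is not None:
            hi = float(upper)
        self.bounds[compound_id] = (lo, hi)

    def fix(self, compound_id: str, value: float) -> None:
        self.fixed[compound_id] = float(value)

    def add_ratio(self, numerator: str, denominator: str, ratio: float) -> None:
        self.ratios.append(RatioConstraint(numerator, denominator, ratio))

    # -- resolution -------------------------------------------------------
    def bounds_for(self, compound_id: str) -> tuple[float, float]:
        """Effective (lower, upper) molar bounds for one compound."""
        if compound_id in self.fixed:
            v = self.fixed[compound_id]
            return (v, v)
        lo, hi = self.bounds.get(compound_id, (None, None))
        return (
            self.default_lower if lo is None else lo,
            self.default_upper if hi is None else hi,
        )

    def restrict(self, compound_ids: Sequence[str]) -> "ConcentrationConstraints":
        """Drop fixed/ratio entries that reference absent compounds.

        Shipped cofactor defaults list many compounds; only those present in
        the pathway at hand apply.
        """
        present = set(compound_ids)
        return ConcentrationConstraints(
            self.default_lower,
            self.default_upper,
            {cid: b for cid, b in self.bounds.items() if cid in present},
            {cid: v for cid, v in self.fixed.items() if cid in present},
            [
                r
                for r in self.ratios
                if r.numerator in present and r.denominator in present
            ],
        )

    def validate(self, compound_ids: Sequence[str]) -> None:
        """Raise :class:`ConstraintError` on any inconsistency."""
        if not (0 < self.default_lower <= self.default_upper):
            raise ConstraintError(
                f"default bounds invalid: ({self.default_lower}, {self.default_upper})"
            )
        for cid in compound_ids:
            lo, hi = self.bounds_for(cid)
            if not (0 < lo <= hi):
                raise ConstraintError(
                    f"compound {cid!r}: invalid bounds ({lo}, {hi})"
                )
        for cid, v in self.fixed.items():
            if not (v > 0 and math.isfinite(v)):
                raise ConstraintError(f"compound {cid!r}: fixed value {v} invalid")
        present = set(compound_ids)
        ratio_members: set[str] = set()
        for r in self.ratios:
            for cid in (r.numerator, r.denominator):
                if cid not in present:
                    raise ConstraintError(
                        f"ratio constraint references unknown compound {cid!r}"
                    )
                if cid in self.fixed:
                    raise ConstraintError(
                        f"compound {cid!r} is both fixed and ratio-constrained"
                    )
            ratio_members.update((r.numerator, r.denominator))

    def log_bounds(
        self, compound_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(ln lower, ln upper) arrays in registration order."""
        lo = np.empty(len(compound_ids))
        hi = np.empty(len(compound_ids))
        for i, cid in enumerate(compound_ids):
            l, h = self.bounds_for(cid)
            lo[i], hi[i] = math.log(l), math.log(h)
        return lo, hi


#: Cofactor table reproducing physiological defaults: fixed concentrations
#: (molar) and conserved concentration ratios.
DEFAULT_FIXED = {
    "pi": 1e-2,  # orthophosphate
    "ppi": 1e-3,  # pyrophosphate
    "coa": 1e-3,
    "co2": 1e-5,  # CO2(aq), ambient
}
DEFAULT_RATIOS = [
    ("atp", "adp", 10.0),
    ("adp", "amp", 1.0),
    ("nadh", "nad", 0.1),
    ("nadph", "nadp", 10.0),
    ("fd_red", "fd_ox", 1.0),
]


def default_constraints() -> ConcentrationConstraints:
    """Physiological defaults: 1 uM - 10 mM range plus the cofactor table."""
    return ConcentrationConstraints(
        default_lower=1e-6,
        default_upper=1e-2,
        fixed=dict(DEFAULT_FIXED),
        ratios=[RatioConstraint(n, d, r) for n, d, r in DEFAULT_RATIOS],
    )
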