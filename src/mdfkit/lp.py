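"""Max-min Driving Force linear program and its dual.

Primal, over log-concentrations x and a free scalar B:

    maximize  B
    s.t.      -G0 - RT * S^T x >= B          (one row per reaction)
              ln(Cmin) <= x <= ln(Cmax)      (fixed values: equal bounds)
              x_num - x_den = ln(ratio)      (cofactor ratio constraints)

The optimal B is the MDF; the pathway is thermodynamically feasible iff
MDF > 0.  Dual variables: w (per reaction, sum to 1), u_max / u_min (per
compound, unitless — the marginal MDF gain is shadow_price * RT * ln(fold)
for a bound relaxation and -w_j * delta for a dG0 perturbation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import ConstraintError, SolverError
from .model import (
    ConcentrationConstraints,
    PathwayModel,
    build_matrices,
    compute_drg_prime,
    default_constraints,
)
from .thermo import DEFAULT_CONSTANTS, ThermoConstants, flux_force_efficacy

__all__ = [
    "MDFResult",
    "solve_mdf",
    "extract_shadow_prices",
    "solve_dual_explicit",
    "sensitivity_check",
    "SensitivityCheck",
    "brute_force_mdf",
]

_ACTIVE_TOL = 1e-6


@dataclass
class MDFResult:
    """Solution of the MDF program for one pathway.

    ``mdf`` is the optimal B in kJ/mol.  ``x_opt`` holds one optimal
    log-concentration profile (the primal optimum need not be unique).
    Shadow prices follow the conventions in the module docstring.
    """

    mdf: float
    solver_status: Literal["optimal", "infeasible_constraints", "numerical_failure"]
    compound_ids: list[str]
    reaction_ids: list[str]
    x_opt: np.ndarray | None = None
    drg_prime_opt: np.ndarray | None = None
    efficacy_opt: np.ndarray | None = None
    reaction_shadow_prices: np.ndarray | None = None  # w
    u_max: np.ndarray | None = None
    u_min: np.ndarray | None = None
    metabolite_shadow_prices: np.ndarray | None = None
    dual_objective: float | None = None
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        """Thermodynamic feasibility verdict: MDF strictly positive."""
        return self.solver_status == "optimal" and self.mdf > 0

    @property
    def concentrations(self) -> dict[str, float]:
        if self.x_opt is None:
            return {}
        return {cid: float(np.exp(v)) for cid, v in zip(self.compound_ids, self.x_opt)}

    def bottlenecks(self, tol: float = _ACTIVE_TOL) -> list[str]:
        """Reaction ids with positive shadow price (they limit the MDF)."""
        if self.reaction_shadow_prices is None:
            return []
        return [
            rid
            for rid, w in zip(self.reaction_ids, self.reaction_shadow_prices)
            if w > tol
        ]

    def limiting_metabolites(self, tol: float = _ACTIVE_TOL) -> list[str]:
        if self.metabolite_shadow_prices is None:
            return []
        return [
            cid
            for cid, u in zip(self.compound_ids, self.metabolite_shadow_prices)
            if u > tol
        ]


def _ratio_equalities(
    constraints: ConcentrationConstraints, compound_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Rows E, rhs ln(r) encoding x_num - x_den = ln(ratio)."""
    idx = {cid: i for i, cid in enumerate(compound_ids)}
    E = np.zeros((len(constraints.ratios), len(compound_ids)))
    rhs = np.zeros(len(constraints.ratios))
    for k, rc in enumerate(constraints.ratios):
        E[k, idx[rc.numerator]] = 1.0
        E[k, idx[rc.denominator]] = -1.0
        rhs[k] = np.log(rc.ratio)
    return E, rhs


def extract_shadow_prices(
    scipy_result,
    S: np.ndarray,
    rt: float,
    n_compounds: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map LP-backend marginals to (w, u_max, u_min, metabolite prices).

    HiGHS reports marginals for the minimization form; signs are flipped so
    all shadow prices are nonnegative gains per unit relaxation.  u vectors
    are divided by RT so that a bound relaxation by a factor f yields
    u * RT * ln(f), matching the reaction prices' scale.
    """
    marg_ineq = getattr(scipy_result.ineqlin, "marginals", None)
    if marg_ineq is None:  # pragma: no cover - HiGHS always provides duals
        raise SolverError("backend returned no dual values")
    w = np.maximum(-np.asarray(marg_ineq, dtype=float), 0.0)
    u_max = np.maximum(
        -np.asarray(scipy_result.upper.marginals[:n_compounds], dtype=float) / rt, 0.0
    )
    u_min = np.maximum(
        np.asarray(scipy_result.lower.marginals[:n_compounds], dtype=float) / rt, 0.0
    )
    met = np.maximum(np.abs(u_max), np.abs(u_min))
    return w, u_max, u_min, met


def solve_mdf(
    pathway: PathwayModel,
    constraints: ConcentrationConstraints | None = None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    tie_break: bool = False,
) -> MDFResult:
    """Solve the MDF LP; return optimum, one optimal profile, and duals.

    ``tie_break=True`` re-optimizes the (possibly non-unique) concentration
    profile by maximizing the sum of driving forces at B fixed to the MDF.
    Raises :class:`ConstraintError` before solving when bounds are
    inconsistent.  An MDF <= 0 is a scientific verdict, not an error.
    """
    if constraints is None:
        constraints = default_constraints()
    S, G0 = build_matrices(pathway)
    cids = pathway.compound_ids
    cons = constraints.restrict(cids)
    cons.validate(cids)

    rt = constants.rt
    n_c, n_r = S.shape
    lb, ub = cons.log_bounds(cids)
    E, eq_rhs = _ratio_equalities(cons, cids)

    # variables: [x (n_c), B]; maximize B
    c = np.zeros(n_c + 1)
    c[-1] = -1.0
    A_ub = np.hstack([rt * S.T, np.ones((n_r, 1))])
    b_ub = -G0
    A_eq = b_eq = None
    if len(E):
        A_eq = np.hstack([E, np.zeros((len(E), 1))])
        b_eq = eq_rhs
    var_bounds = list(zip(lb, ub)) + [(None, None)]

    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds,
        method="highs",
    )
    if not res.success:
        status = "infeasible_constraints" if res.status == 2 else "numerical_failure"
        return MDFResult(
            mdf=float("nan"),
            solver_status=status,
            compound_ids=list(cids),
            reaction_ids=pathway.reaction_ids,
            diagnostics={"backend_status": res.status, "message": res.message},
        )

    mdf = float(-res.fun)
    try:
        w, u_max, u_min, met = extract_shadow_prices(res, S, rt, n_c)
        nu = (
            -np.asarray(res.eqlin.marginals, dtype=float) / rt
            if A_eq is not None
            else np.zeros(0)
        )
    except SolverError:
        w, u_max, u_min, nu = solve_dual_explicit(S, G0, lb, ub, E, eq_rhs, rt)
        met = np.maximum(np.abs(u_max), np.abs(u_min))

    dual_obj = float(
        -w @ G0 + rt * (u_max @ ub - u_min @ lb) + (rt * nu @ eq_rhs if len(E) else 0.0)
    )

    x = np.asarray(res.x[:n_c], dtype=float)
    drg = compute_drg_prime(G0, S, x, constants)

    if tie_break:
        x2 = _tie_break_profile(S, G0, lb, ub, E, eq_rhs, rt, mdf)
        if x2 is not None:
            x = x2
            drg = compute_drg_prime(G0, S, x, constants)

    # degeneracy heuristic: more active constraints than free dims + 1
    n_free = int(np.sum(ub - lb > 1e-12)) - len(E)
    active = (
        int(np.sum(-drg <= mdf + _ACTIVE_TOL))
        + int(np.sum(x <= lb + 1e-9))
        + int(np.sum(x >= ub - 1e-9))
    )
    efficacy = np.array([flux_force_efficacy(g, constants) for g in drg])

    return MDFResult(
        mdf=mdf,
        solver_status="optimal",
        compound_ids=list(cids),
        reaction_ids=pathway.reaction_ids,
        x_opt=x,
        drg_prime_opt=drg,
        efficacy_opt=efficacy,
        reaction_shadow_prices=w,
        u_max=u_max,
        u_min=u_min,
        metabolite_shadow_prices=met,
        dual_objective=dual_obj,
        degenerate=active > n_free + 1,
        diagnostics={
            "backend": "scipy-highs",
            "n_compounds": n_c,
            "n_reactions": n_r,
            "eq_duals": nu,
        },
    )


def _tie_break_profile(S, G0, lb, ub, E, eq_rhs, rt, mdf) -> np.ndarray | None:
    """Among B-optimal profiles, maximize the total driving force."""
    n_c, n_r = S.shape
    c = rt * S.sum(axis=1)  # minimize sum(G0 + RT S^T x) over x
    A_ub = rt * S.T
    b_ub = -G0 - (mdf - 1e-9)
    A_eq = E if len(E) else None
    b_eq = eq_rhs if len(E) else None
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=list(zip(lb, ub)), method="highs",
    )
    return np.asarray(res.x, dtype=float) if res.success else None


def solve_dual_explicit(
    S: np.ndarray,
    G0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    E: np.ndarray,
    eq_rhs: np.ndarray,
    rt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Solve the dual LP directly (fallback when backend duals are missing).

        minimize  -w.G0 + RT (u_max.ln Cmax - u_min.ln Cmin + nu.ln r)
        s.t.      sum(w) = 1;  u_max - u_min + E^T nu = -S w
                  w, u_max, u_min >= 0;  nu free
    """
    n_c, n_r = S.shape
    n_e = len(E)
    # variables: [w (n_r), u_max (n_c), u_min (n_c), nu (n_e)]
    n_v = n_r + 2 * n_c + n_e
    c = np.concatenate([-G0, rt * ub, -rt * lb, rt * eq_rhs])
    A_eq = np.zeros((1 + n_c, n_v))
    b_eq = np.zeros(1 + n_c)
    A_eq[0, :n_r] = 1.0
    b_eq[0] = 1.0
    A_eq[1:, :n_r] = S
    A_eq[1:, n_r : n_r + n_c] = np.eye(n_c)
    A_eq[1:, n_r + n_c : n_r + 2 * n_c] = -np.eye(n_c)
    if n_e:
        A_eq[1:, n_r + 2 * n_c :] = E.T
    bounds = [(0, None)] * (n_r + 2 * n_c) + [(None, None)] * n_e
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"explicit dual LP failed: {res.message}")
    w = res.x[:n_r]
    u_max = res.x[n_r : n_r + n_c]
    u_min = res.x[n_r + n_c : n_r + 2 * n_c]
    nu = res.x[n_r + 2 * n_c :]
    return w, u_max, u_min, nu


@dataclass(frozen=True)
class SensitivityCheck:
    """Shadow-price prediction vs. a fresh re-solve after a perturbation."""

    predicted_change: float
    recomputed_change: float

    @property
    def discrepancy(self) -> float:
        return abs(self.predicted_change - self.recomputed_change)


def sensitivity_check(
    pathway: PathwayModel,
    constraints: ConcentrationConstraints,
    result: MDFResult,
    *,
    reaction: str | None = None,
    delta_dg0: float | None = None,
    compound: str | None = None,
    bound: Literal["upper", "lower"] | None = None,
    fold: float | None = None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> SensitivityCheck:
    """Compare a shadow-price MDF prediction against an actual re-solve.

    Reaction perturbation (``reaction`` + ``delta_dg0``): predicted change
    is ``-w_j * delta``.  Bound perturbation (``compound`` + ``bound`` +
    ``fold``): predicted change is ``price * RT * ln(fold)`` for the upper
    bound and ``-price * RT * ln(fold)`` for the lower bound, where price is
    the corresponding u entry.  Disagreement is reported, never raised.
    """
    if result.solver_status != "optimal":
        raise SolverError("sensitivity_check requires an optimal base result")
    pw = pathway.copy()
    cons = constraints.copy()
    if reaction is not None:
        if delta_dg0 is None:
            raise ValueError("delta_dg0 required with reaction=")
        j = result.reaction_ids.index(reaction)
        predicted = -float(result.reaction_shadow_prices[j]) * delta_dg0
        for rxn in pw.reactions:
            if rxn.id == reaction:
                rxn.dg0_prime = rxn.dg0_prime + delta_dg0
    elif compound is not None:
        if bound not in ("upper", "lower") or fold is None or fold <= 0:
            raise ValueError("compound= requires bound='upper'|'lower' and fold>0")
        i = result.compound_ids.index(compound)
        lo, hi = cons.bounds_for(compound)
        if compound in cons.fixed:
            raise ConstraintError(f"cannot perturb bound of fixed compound {compound!r}")
        if bound == "upper":
            predicted = float(result.u_max[i]) * constants.rt * np.log(fold)
            cons.set_bound(compound, upper=hi * fold)
        else:
            predicted = -float(result.u_min[i]) * constants.rt * np.log(fold)
            cons.set_bound(compound, lower=lo * fold)
    else:
        raise ValueError("specify either reaction= or compound=")

    new = solve_mdf(pw, cons, constants)
    if new.solver_status != "optimal":
        raise SolverError(f"perturbed re-solve failed: {new.solver_status}")
    return SensitivityCheck(
        predicted_change=predicted, recomputed_change=new.mdf - result.mdf
    )


def _free_variable_layout(
    cons: ConcentrationConstraints, cids: Sequence[str]
) -> tuple[list[int], np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int, float]]]:
    """Collapse ratio groups by substitution and split fixed vs free vars.

    Returns (free indices, lb, ub, x0 with fixed values filled,
    ties [(member, representative, log-offset)]).
    """
    idx = {cid: i for i, cid in enumerate(cids)}
    lb, ub = cons.log_bounds(cids)
    # union ratio members into components rooted at a representative
    parent = {i: i for i in range(len(cids))}
    offset = {i: 0.0 for i in range(len(cids))}  # x_i = x_root + offset[i]

    def find(i):
        if parent[i] == i:
            return i, 0.0
        root, off = find(parent[i])
        parent[i], offset[i] = root, offset[i] + off
        return root, offset[i]

    for rc in cons.ratios:
        ni, di = idx[rc.numerator], idx[rc.denominator]
        rn, on = find(ni)
        rd, od = find(di)
        if rn == rd:
            continue  # consistent chain assumed; validated upstream
        # x_num = x_den + ln r  =>  x_rn + on' relation
        parent[rn] = rd
        offset[rn] = od + np.log(rc.ratio) - on
    ties: list[tuple[int, int, float]] = []
    eff_lb = lb.copy()
    eff_ub = ub.copy()
    for i in range(len(cids)):
        r, off = find(i)
        if r != i:
            ties.append((i, r, off))
            eff_lb[r] = max(eff_lb[r], lb[i] - off)
            eff_ub[r] = min(eff_ub[r], ub[i] - off)
    roots = sorted(set(find(i)[0] for i in range(len(cids))))
    for r in roots:
        if eff_lb[r] > eff_ub[r] + 1e-12:
            raise ConstraintError(
                f"ratio constraints incompatible with bounds around {cids[r]!r}"
            )
    x0 = np.full(len(cids), np.nan)
    free = []
    for r in roots:
        if eff_ub[r] - eff_lb[r] <= 1e-12:
            x0[r] = eff_lb[r]
        else:
            free.append(r)
    return free, eff_lb, eff_ub, x0, ties


def brute_force_mdf(
    pathway: PathwayModel,
    constraints: ConcentrationConstraints | None = None,
    resolution: int = 21,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    max_free: int = 4,
) -> float:
    """Grid-search oracle: max over a lattice of the min driving force.

    Exhaustively evaluates ``resolution`` points per free log-concentration
    (after substituting fixed values and ratio ties).  The result is a lower
    bound on the LP optimum, within grid-spacing * RT * (max molecularity
    row sum) of it.  Refuses more than ``max_free`` free variables.
    """
    if constraints is None:
        constraints = default_constraints()
    S, G0 = build_matrices(pathway)
    cids = pathway.compound_ids
    cons = constraints.restrict(cids)
    cons.validate(cids)
    free, lb, ub, x0, ties = _free_variable_layout(cons, cids)
    if len(free) > max_free:
        raise ValueError(
            f"{len(free)} free variables exceed brute-force limit {max_free}"
        )
    rt = constants.rt
    if free:
        axes = [np.linspace(lb[i], ub[i], resolution) for i in free]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)  # (P, n_free)
    else:
        pts = np.zeros((1, 0))
    X = np.tile(x0, (len(pts), 1))
    for k, i in enumerate(free):
        X[:, i] = pts[:, k]
    for member, root, off in ties:
        X[:, member] = X[:, root] + off
    # driving forces for every grid point: -(G0 + RT X S)
    D = -(G0[None, :] + rt * (X @ S))
    return float(np.max(np.min(D, axis=1)))
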