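import math

import numpy as np
import pytest

from mdfkit import (
    ChainSpec,
    ConcentrationConstraints,
    ConstraintError,
    PathwayModel,
    Reaction,
    brute_force_mdf,
    build_matrices,
    chain_constraints,
    chain_mdf_closed_form,
    make_chain,
    random_instance,
    sensitivity_check,
    solve_mdf,
)
from mdfkit.lp import solve_dual_explicit, _ratio_equalities
from mdfkit.thermo import ThermoConstants

RT = ThermoConstants().rt
TOL = 1e-6


def single_reaction(dg0: float, formula: str = "A <=> B") -> PathwayModel:
    pw = PathwayModel(name="single")
    pw.add_reaction(Reaction.from_formula("R1", formula, dg0_prime=dg0))
    return pw


class TestSolveMdf:
    def test_single_reaction_default_bounds(self):
        # bound A at Cmax, B at Cmin: MDF = RT ln(1e4)
        res = solve_mdf(single_reaction(0.0), ConcentrationConstraints())
        assert res.mdf == pytest.approx(RT * math.log(1e4), abs=TOL)
        assert res.mdf == pytest.approx(22.8, abs=0.1)
        assert res.feasible

    def test_symmetric_chain_interior_optimum(self, symmetric_4chain):
        spec, pw, cons = symmetric_4chain
        res = solve_mdf(pw, cons)
        assert res.mdf == pytest.approx(4.0, abs=TOL)
        np.testing.assert_allclose(-res.drg_prime_opt, [4.0] * 4, atol=1e-6)

    def test_infeasible_pathway_negative_mdf(self):
        res = solve_mdf(single_reaction(50.0), ConcentrationConstraints())
        assert res.solver_status == "optimal"
        assert res.mdf == pytest.approx(RT * math.log(1e4) - 50.0, abs=TOL)
        assert res.mdf == pytest.approx(-27.2, abs=0.1)
        assert not res.feasible

    def test_inconsistent_bounds_raise_before_solve(self):
        cons = ConcentrationConstraints()
        cons.set_bound("A", lower=1.0, upper=1e-6)
        with pytest.raises(ConstraintError):
            solve_mdf(single_reaction(0.0), cons)

    def test_ratio_incompatible_with_bounds_is_infeasible_status(self):
        cons = ConcentrationConstraints()
        cons.set_bound("A", lower=1e-3, upper=1e-2)
        cons.set_bound("B", lower=1e-6, upper=1e-5)
        cons.add_ratio("A", "B", 1.0)  # forces [A]=[B], ranges disjoint
        res = solve_mdf(single_reaction(0.0), cons)
        assert res.solver_status == "infeasible_constraints"
        assert math.isnan(res.mdf)

    def test_ratio_constraint_pins_log_difference(self):
        cons = ConcentrationConstraints()
        cons.add_ratio("atp", "adp", 10.0)
        pw = single_reaction(0.0, "atp <=> adp")
        res = solve_mdf(pw, cons)
        conc = res.concentrations
        assert conc["atp"] / conc["adp"] == pytest.approx(10.0, rel=1e-6)
        # driving force fully determined by the ratio
        assert res.mdf == pytest.approx(RT * math.log(10.0), abs=TOL)

    def test_mdf_invariant_to_registration_order(self):
        defs = [("Ra", "A <=> B", -3.0), ("Rb", "B <=> C", -1.0),
                ("Rc", "C <=> D", -6.0)]
        results = []
        for order in (defs, list(reversed(defs))):
            pw = PathwayModel()
            for rid, f, g in order:
                pw.add_reaction(Reaction.from_formula(rid, f, g))
            results.append(solve_mdf(pw, ConcentrationConstraints()))
        a, b = results
        assert a.mdf == pytest.approx(b.mdf, abs=TOL)
        for rid in a.reaction_ids:
            ja, jb = a.reaction_ids.index(rid), b.reaction_ids.index(rid)
            assert a.drg_prime_opt[ja] == pytest.approx(
                b.drg_prime_opt[jb], abs=1e-6
            )

    def test_tie_break_profile_keeps_mdf(self):
        # slack geometry: 2 reactions, huge total drop -> non-unique optimum
        pw = PathwayModel()
        pw.add_reaction(Reaction.from_formula("R1", "A <=> B", dg0_prime=-40.0))
        pw.add_reaction(Reaction.from_formula("R2", "B <=> C", dg0_prime=-40.0))
        plain = solve_mdf(pw, ConcentrationConstraints())
        tied = solve_mdf(pw, ConcentrationConstraints(), tie_break=True)
        assert tied.mdf == pytest.approx(plain.mdf, abs=TOL)
        assert np.sum(-tied.drg_prime_opt) >= np.sum(-plain.drg_prime_opt) - 1e-9


class TestShadowPrices:
    def test_symmetric_chain_quarters(self, symmetric_4chain):
        _, pw, cons = symmetric_4chain
        res = solve_mdf(pw, cons)
        np.testing.assert_allclose(
            res.reaction_shadow_prices, [0.25] * 4, atol=1e-8
        )

    def test_slack_reaction_has_zero_price(self):
        pw = PathwayModel()
        pw.add_reaction(Reaction.from_formula("R1", "A <=> B", dg0_prime=0.0))
        pw.add_reaction(Reaction.from_formula("R2", "B <=> C", dg0_prime=-60.0))
        res = solve_mdf(pw, ConcentrationConstraints())
        j = res.reaction_ids.index("R2")
        assert res.reaction_shadow_prices[j] == pytest.approx(0.0, abs=1e-8)

    def test_interior_compound_zero_price(self, two_chain_bound_limited):
        pw, cons = two_chain_bound_limited
        res = solve_mdf(pw, cons)
        i = res.compound_ids.index("C1")
        assert res.metabolite_shadow_prices[i] == pytest.approx(0.0, abs=1e-8)

    def test_bound_limited_two_chain_half_prices(self, two_chain_bound_limited):
        pw, cons = two_chain_bound_limited
        res = solve_mdf(pw, cons)
        np.testing.assert_allclose(
            res.reaction_shadow_prices, [0.5, 0.5], atol=1e-8
        )
        a = res.compound_ids.index("C0")
        c = res.compound_ids.index("C2")
        assert res.u_max[a] == pytest.approx(0.5, abs=1e-8)
        assert res.u_min[c] == pytest.approx(0.5, abs=1e-8)

    def test_explicit_dual_matches_backend(self, symmetric_4chain):
        _, pw, cons = symmetric_4chain
        res = solve_mdf(pw, cons)
        S, G0 = build_matrices(pw)
        rcons = cons.restrict(pw.compound_ids)
        lb, ub = rcons.log_bounds(pw.compound_ids)
        E, rhs = _ratio_equalities(rcons, pw.compound_ids)
        w, umax, umin, _ = solve_dual_explicit(S, G0, lb, ub, E, rhs, RT)
        np.testing.assert_allclose(w, res.reaction_shadow_prices, atol=1e-7)
        np.testing.assert_allclose(umax, res.u_max, atol=1e-7)
        np.testing.assert_allclose(umin, res.u_min, atol=1e-7)


class TestDualityProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_strong_duality_and_stationarity(self, seed):
        pw = random_instance(n_compounds=4, n_reactions=3, seed=seed)
        res = solve_mdf(pw, ConcentrationConstraints())
        assert res.solver_status == "optimal"
        assert abs(res.mdf - res.dual_objective) < 1e-6
        w = res.reaction_shadow_prices
        assert abs(w.sum() - 1.0) < 1e-8
        assert (w >= -1e-10).all()
        assert (res.u_max >= -1e-10).all() and (res.u_min >= -1e-10).all()
        # dual stationarity: u_max - u_min = -S w (no ratio groups here)
        S, _ = build_matrices(pw)
        np.testing.assert_allclose(
            res.u_max - res.u_min, -(S @ w), atol=1e-7
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_complementary_slackness(self, seed):
        pw = random_instance(n_compounds=4, n_reactions=4, seed=seed + 100)
        cons = ConcentrationConstraints()
        res = solve_mdf(pw, cons)
        lb, ub = cons.restrict(pw.compound_ids).log_bounds(pw.compound_ids)
        for j, wj in enumerate(res.reaction_shadow_prices):
            if wj > 1e-6:
                assert -res.drg_prime_opt[j] == pytest.approx(res.mdf, abs=1e-6)
        for i in range(len(res.compound_ids)):
            if res.u_max[i] > 1e-6:
                assert res.x_opt[i] == pytest.approx(ub[i], abs=1e-6)
            if res.u_min[i] > 1e-6:
                assert res.x_opt[i] == pytest.approx(lb[i], abs=1e-6)

    @pytest.mark.parametrize("seed", range(15))
    def test_monotonicity_under_bound_widening(self, seed):
        pw = random_instance(n_compounds=4, n_reactions=3, seed=seed + 300)
        base = solve_mdf(pw, ConcentrationConstraints())
        wide = ConcentrationConstraints(default_lower=1e-7, default_upper=1e-1)
        assert solve_mdf(pw, wide).mdf >= base.mdf - 1e-9

    @pytest.mark.parametrize("seed", range(15))
    def test_monotonicity_under_energy_relaxation(self, seed):
        pw = random_instance(n_compounds=4, n_reactions=3, seed=seed + 400)
        base = solve_mdf(pw, ConcentrationConstraints())
        rng = np.random.default_rng(seed)
        relaxed = pw.copy()
        j = int(rng.integers(len(relaxed.reactions)))
        relaxed.reactions[j].dg0_prime -= float(rng.uniform(0, 10))
        assert solve_mdf(relaxed, ConcentrationConstraints()).mdf >= base.mdf - 1e-9


class TestSensitivity:
    def test_quarter_price_times_four(self, symmetric_4chain):
        _, pw, cons = symmetric_4chain
        res = solve_mdf(pw, cons)
        check = sensitivity_check(pw, cons, res, reaction="R2", delta_dg0=-4.0)
        assert check.predicted_change == pytest.approx(1.0, abs=1e-8)
        assert check.recomputed_change == pytest.approx(1.0, abs=1e-6)

    def test_tenfold_upper_bound_raise(self, two_chain_bound_limited):
        pw, cons = two_chain_bound_limited
        res = solve_mdf(pw, cons)
        check = sensitivity_check(
            pw, cons, res, compound="C0", bound="upper", fold=10.0
        )
        assert check.predicted_change == pytest.approx(0.5 * RT * math.log(10), abs=1e-8)
        assert check.discrepancy < 1e-6

    def test_zero_price_predicts_zero(self):
        pw = PathwayModel()
        pw.add_reaction(Reaction.from_formula("R1", "A <=> B", dg0_prime=0.0))
        pw.add_reaction(Reaction.from_formula("R2", "B <=> C", dg0_prime=-60.0))
        cons = ConcentrationConstraints()
        res = solve_mdf(pw, cons)
        check = sensitivity_check(pw, cons, res, reaction="R2", delta_dg0=-0.5)
        assert check.predicted_change == 0.0
        assert check.recomputed_change == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_finite_difference_on_chains(self, seed):
        rng = np.random.default_rng(seed)
        spec = ChainSpec(
            dg0=tuple(rng.uniform(-8, -2, size=4)),
            c_start=1e-3,
            c_end=1e-3,
            intermediate_lower=1e-14,
            intermediate_upper=1e6,
        )
        pw, cons = make_chain(spec), chain_constraints(spec)
        res = solve_mdf(pw, cons)
        rid = f"R{int(rng.integers(1, 5))}"
        delta = float(rng.uniform(-0.01, 0.01))
        check = sensitivity_check(pw, cons, res, reaction=rid, delta_dg0=delta)
        assert check.discrepancy < 1e-6


class TestBruteForceOracle:
    def test_all_fixed_no_free_variables(self):
        cons = ConcentrationConstraints()
        cons.fix("A", 1e-3)
        cons.fix("B", 1e-4)
        pw = single_reaction(-5.0)
        expected = -(-5.0 + RT * (math.log(1e-4) - math.log(1e-3)))
        assert brute_force_mdf(pw, cons) == pytest.approx(expected, abs=1e-12)
        assert solve_mdf(pw, cons).mdf == pytest.approx(expected, abs=TOL)

    def test_chain_fine_grid_converges(self, symmetric_4chain):
        _, pw, cons = symmetric_4chain
        assert brute_force_mdf(pw, cons, resolution=81) == pytest.approx(
            4.0, abs=0.05
        )

    def test_refuses_too_many_free_variables(self):
        pw = random_instance(n_compounds=5, n_reactions=3, seed=1)
        with pytest.raises(ValueError):
            brute_force_mdf(pw, ConcentrationConstraints(), max_free=4)

    def test_ratio_substitution(self):
        cons = ConcentrationConstraints()
        cons.add_ratio("atp", "adp", 10.0)
        pw = single_reaction(0.0, "atp <=> adp")
        # one free variable after substitution; the ratio fixes the MDF
        assert brute_force_mdf(pw, cons, resolution=11) == pytest.approx(
            RT * math.log(10.0), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_agreement_on_random_instances(self, seed):
        pw = random_instance(n_compounds=3, n_reactions=3, seed=seed + 1000)
        cons = ConcentrationConstraints()
        lp = solve_mdf(pw, cons).mdf
        resolution = 33
        bf = brute_force_mdf(pw, cons, resolution=resolution)
        S, _ = build_matrices(pw)
        spacing = math.log(1e4) / (resolution - 1)
        bound = spacing * RT * float(np.abs(S).sum(axis=0).max())
        assert bf <= lp + 1e-9
        assert lp - bf <= bound


class TestClosedFormOracle:
    @pytest.mark.parametrize("seed", range(100))
    def test_chain_closed_form_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        spec = ChainSpec(
            dg0=tuple(rng.uniform(-10, 5, size=n)),
            c_start=float(rng.uniform(1e-4, 1e-2)),
            c_end=float(rng.uniform(1e-4, 1e-2)),
            intermediate_lower=1e-14,
            intermediate_upper=1e6,
            seed=seed,
        )
        try:
            expected = chain_mdf_closed_form(spec)
        except ConstraintError:
            pytest.skip("geometry guard rejected this spec")
        res = solve_mdf(make_chain(spec), chain_constraints(spec))
        assert res.mdf == pytest.approx(expected, abs=1e-6)
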