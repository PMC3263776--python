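import itertools

import networkx as nx
import numpy as np
import pytest

import endurosim.fba as F
from endurosim.fba import (
    NetworkError,
    Reaction,
    build_system,
    check_elemental_balance,
    parse_equation,
    sample_flux_space,
    solve_fba,
)


def rxn(rid, eq):
    stoich, rev = parse_equation(rid, eq)
    return Reaction(rid, stoich, rev)


def enumerate_vertices_optimum(system, objective_id):
    """Brute-force LP oracle: enumerate basic feasible solutions.

    Fixes (n - rank S) fluxes at bound combinations, solves the equalities
    for the rest, keeps feasible points, and returns the best objective.
    """
    S = system.S
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    j_obj = system.column(objective_id)
    best = None
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < rank:
            continue
        for bounds_choice in itertools.product(*[
                (system.lower[j], system.upper[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(bounds_choice)
            sol, res, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < system.lower - 1e-9) or np.any(v > system.upper + 1e-9):
                continue
            if best is None or v[j_obj] > best:
                best = v[j_obj]
    return best


class TestParsing:
    def test_balance_row_sign_convention(self):
        """Producing reactions enter positive, consuming negative, weighted
        by stoichiometry: a production V1 balanced against V2 + 2 V3."""
        reactions = [rxn("R1", " --> X"), rxn("R2", "X --> "), rxn("R3", "2 X --> ")]
        system = build_system(reactions, objective="R1")
        np.testing.assert_array_equal(system.S, [[1.0, -1.0, -2.0]])

    def test_duplicate_ids_rejected(self):
        r = rxn("R1", "a_c --> b_c")
        with pytest.raises(NetworkError, match="duplicate"):
            build_system([r, r])

    def test_unknown_bound_rejected(self):
        with pytest.raises(NetworkError, match="unknown"):
            build_system([rxn("R1", "a_c --> b_c")], bounds={"NOPE": (0, 1)})

    def test_empty_bounds_leave_system_well_formed(self):
        system = build_system([rxn("R1", "a_c --> b_c")])
        assert system.S.shape == (2, 1)

    def test_missing_arrow_rejected(self):
        with pytest.raises(NetworkError, match="arrow"):
            parse_equation("BAD", "a_c + b_c")


class TestElementalBalance:
    def test_hexokinase_balances_carbon_and_phosphate(self):
        r = rxn("HEX1", "glc__D_c + atp_c --> g6p_c + adp_c")
        res = check_elemental_balance(r)
        assert res["C"] == 0 and res["P"] == 0 and res["N"] == 0

    def test_corrupted_coefficient_flips_residual_sign(self):
        plus = rxn("BAD", "glc__D_c + atp_c --> 2 g6p_c + adp_c")
        minus = rxn("BAD2", "2 glc__D_c + atp_c --> g6p_c + adp_c")
        assert check_elemental_balance(plus)["C"] > 0
        assert check_elemental_balance(minus)["C"] < 0

    def test_exchange_reactions_exempt(self):
        assert check_elemental_balance(rxn("EX_glc", "glc__D_e <->"))["exempt"]

    def test_unknown_metabolite_reported_unchecked(self):
        res = check_elemental_balance(rxn("R", "mystery_c --> co2_c"))
        assert res["unchecked"] and res["missing"] == "mystery"

    def test_packaged_brain_network_is_balanced(self):
        formulas = F.load_formulas()
        for r in F.load_brain_network():
            res = check_elemental_balance(r, formulas)
            if res.get("exempt") or res.get("unchecked"):
                continue
            assert all(abs(v) < 1e-9 for v in res.values()), (r.id, res)


def toy_networks():
    """Small bounded networks (<= 6 reactions) for the LP-vs-oracle check."""
    chain = [rxn("SRC", " --> a_c"), rxn("CONV", "a_c --> b_c"), rxn("SNK", "b_c --> ")]
    branch = [
        rxn("SRC", " --> a_c"),
        rxn("HI", "a_c --> 2 b_c"),
        rxn("LO", "a_c --> b_c"),
        rxn("SNK", "b_c --> "),
    ]
    loop = [
        rxn("SRC", " --> a_c"),
        rxn("FWD", "a_c <-> b_c"),
        rxn("ALT", "a_c --> c_c"),
        rxn("BACK", "c_c <-> b_c"),
        rxn("SNK", "b_c --> "),
    ]
    return [
        (chain, {"SRC": (0.0, 1.0), "CONV": (0.0, 10.0), "SNK": (0.0, 10.0)}, "SNK"),
        (branch, {"SRC": (0.0, 1.0), "HI": (0.0, 0.3), "LO": (0.0, 10.0), "SNK": (0.0, 10.0)}, "SNK"),
        (loop, {"SRC": (0.0, 2.0), "FWD": (-1.0, 0.5), "ALT": (0.0, 10.0),
                "BACK": (-3.0, 3.0), "SNK": (0.0, 10.0)}, "SNK"),
    ]


class TestLinearProgramming:
    @pytest.mark.parametrize("case", range(3))
    def test_optimum_equals_vertex_enumeration(self, case):
        reactions, bounds, obj = toy_networks()[case]
        system = build_system(reactions, bounds, objective=obj)
        result = solve_fba(system, "maximize")
        oracle = enumerate_vertices_optimum(system, obj)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(oracle, abs=1e-9)

    def test_unproduced_substrate_forces_zero(self):
        reactions = [rxn("EAT", "ghost_c --> b_c"), rxn("SNK", "b_c --> ")]
        system = build_system(reactions, objective="SNK")
        result = solve_fba(system)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_reported_not_silent(self):
        reactions = [rxn("SRC", " --> a_c"), rxn("SNK", "a_c --> ")]
        system = build_system(reactions, {"SRC": (1.0, 1.0), "SNK": (0.0, 0.5)}, objective="SNK")
        assert solve_fba(system).status == "infeasible"

    def test_steady_state_residual_tiny(self):
        reactions, bounds, obj = toy_networks()[1]
        system = build_system(reactions, bounds, objective=obj)
        result = solve_fba(system)
        v = result.fluxes.to_numpy()
        assert np.max(np.abs(system.S @ v)) < 1e-8

    def test_flux_ranges_bracket_the_solution(self):
        reactions, bounds, obj = toy_networks()[2]
        system = build_system(reactions, bounds, objective=obj)
        result = solve_fba(system, compute_ranges=True)
        for rid in system.reaction_ids:
            lo, hi = result.ranges.loc[rid, "min"], result.ranges.loc[rid, "max"]
            assert lo - 1e-7 <= result[rid] <= hi + 1e-7


class TestSampler:
    def test_every_sample_feasible(self):
        reactions, bounds, obj = toy_networks()[1]
        system = build_system(reactions, bounds, objective=obj)
        samples = sample_flux_space(system, 200, seed=11, box=10.0)
        assert len(samples) == 200
        V = samples.to_numpy()
        assert np.max(np.abs(system.S @ V.T)) < 1e-8
        assert (V >= system.lower - 1e-9).all() and (V <= system.upper + 1e-9).all()

    def test_segment_mean_approaches_midpoint(self):
        # v1 = v2 in [0, 1]: a 1-simplex; the uniform mean is 1/2
        reactions = [rxn("IN", " --> x_c"), rxn("OUT", "x_c --> ")]
        system = build_system(reactions, {"IN": (0.0, 1.0), "OUT": (0.0, 1.0)}, objective="OUT")
        n = 400
        samples = sample_flux_space(system, n, seed=5)
        se = 1.0 / np.sqrt(12 * n)
        assert abs(samples["IN"].mean() - 0.5) < 3 * se

    def test_same_seed_identical_samples(self):
        reactions, bounds, obj = toy_networks()[0]
        system = build_system(reactions, bounds, objective=obj)
        a = sample_flux_space(system, 50, seed=3)
        b = sample_flux_space(system, 50, seed=3)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestBrainScenarios:
    def test_rest_matches_oxygen_glucose_stoichiometry(self):
        result, report = F.brain_scenario("rest")
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(9.28, rel=0.02)
        assert abs(result["G6PDH2r"]) < 1e-9  # no pentose phosphate flux
        assert report["closure_residual"] == pytest.approx(0.0, abs=1e-9)

    def test_exercise_synthesizes_palmitate(self):
        result, report = F.brain_scenario("exercise")
        assert result.status == "optimal"
        assert result["EX_hdca"] == pytest.approx(0.14, rel=0.10)
        assert result["G6PDH2r"] > 0.5  # PPP activated for NADPH
        # carbon in = CO2 out + 16 x palmitate
        assert report["carbon_in"] == pytest.approx(0.8 * 6 + 0.53 * 3)
        assert abs(report["closure_residual"]) / report["carbon_in"] < 0.01

    def test_objective_homogeneity_in_glucose(self):
        """Scaling glucose (with O2 at 6x) scales the ATP optimum linearly."""
        reactions = F.load_brain_network()
        def optimum(glc):
            bounds = {"EX_glc": (-glc, -glc), "EX_lac": (0.0, 0.0),
                      "EX_o2": (-6 * glc, -6 * glc), "EX_co2": (0.0, 1e4),
                      "EX_hdca": (0.0, 0.0), "EX_ala": (0.0, 0.0)}
            return solve_fba(build_system(reactions, bounds, objective="ATPS4m")).objective_value
        assert optimum(0.8) == pytest.approx(2 * optimum(0.4), rel=1e-9)

    def test_relaxing_uptake_cannot_decrease_optimum(self):
        reactions = F.load_brain_network()
        base_bounds = {"EX_glc": (-0.4, -0.4), "EX_lac": (0.0, 0.0),
                       "EX_o2": (-2.4, -2.4), "EX_co2": (0.0, 1e4),
                       "EX_hdca": (0.0, 0.0), "EX_ala": (0.0, 0.0)}
        base = solve_fba(build_system(reactions, base_bounds, objective="ATPS4m")).objective_value
        relaxed_bounds = dict(base_bounds, EX_o2=(-3.0, 0.0), EX_glc=(-0.4, 0.0))
        relaxed = solve_fba(build_system(reactions, relaxed_bounds, objective="ATPS4m")).objective_value
        assert relaxed >= base - 1e-9


class TestInterchange:
    def test_graph_export_round_trip(self, tmp_path):
        reactions, bounds, obj = toy_networks()[0]
        system = build_system(reactions, bounds, objective=obj)
        result = solve_fba(system)
        path = tmp_path / "net.graphml"
        g = F.export_graph(system, result, path)
        assert g.number_of_nodes() == len(system.metabolites) + len(system.reactions)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.nodes["SNK"]["flux"] == pytest.approx(result["SNK"])

    def test_zero_flux_reactions_flagged(self):
        reactions, bounds, obj = toy_networks()[1]
        bounds = dict(bounds, HI=(0.0, 0.0))
        system = build_system(reactions, bounds, objective=obj)
        g = F.export_graph(system, solve_fba(system))
        assert g.nodes["HI"]["zero_flux"]

    def test_sbml_round_trip(self, tmp_path):
        pytest.importorskip("libsbml")
        reactions = F.load_brain_network()
        path = tmp_path / "brain.xml"
        F.write_sbml(reactions, path)
        back = {r.id: r for r in F.read_sbml(path)}
        assert set(back) == {r.id for r in reactions}
        for r in reactions:
            assert back[r.id].stoichiometry == pytest.approx(r.stoichiometry)
            assert back[r.id].reversible == r.reversible


class TestIndependentSolverCrossCheck:
    def test_rest_optimum_agrees_with_cobrapy(self):
        """The same network and bounds solved by an independent
        constraint-based-modelling stack give the same ATP optimum."""
        cobra = pytest.importorskip("cobra")
        reactions = F.load_brain_network()
        model = cobra.Model("brain")
        mets = {}
        for r in reactions:
            rx = cobra.Reaction(r.id)
            rx.lower_bound = -1000.0 if r.reversible else 0.0
            rx.upper_bound = 1000.0
            model.add_reactions([rx])
            rx.add_metabolites(
                {mets.setdefault(k, cobra.Metabolite(k)): v for k, v in r.stoichiometry.items()})
        u = F.BRAIN_UPTAKES["rest"]
        model.reactions.EX_glc.bounds = (-u["glc"], -u["glc"])
        model.reactions.EX_lac.bounds = (0.0, 0.0)
        model.reactions.EX_o2.bounds = (-u["o2"], -u["o2"])
        model.reactions.EX_co2.bounds = (0.0, 1000.0)
        model.reactions.EX_hdca.bounds = (0.0, 0.0)
        model.reactions.EX_ala.bounds = (0.0, 0.0)
        model.objective = "ATPS4m"
        independent = model.optimize()
        ours, _ = F.brain_scenario("rest")
        assert independent.status == "optimal"
        assert ours.objective_value == pytest.approx(independent.objective_value, abs=1e-6)
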