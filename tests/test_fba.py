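import itertools

import numpy as np
import pytest

from oenoflux.constraints import PhaseConstraintSet
from oenoflux.fba import (
    InfeasibleModelError,
    estimate_ngam,
    fva_linear_combination,
    ngam_sensitivity,
    solve_fba,
    solve_fva,
)
from oenoflux.network import MetabolicNetwork, Metabolite, Reaction, stoichiometric_matrix


def brute_force_lp(network, objective_id, sense="max"):
    """Vertex-enumeration oracle for small bounded LPs over
    {S v = 0, lb <= v <= ub}: pin every size-d subset of coordinates to a
    bound and solve the equality system for the rest."""
    S = stoichiometric_matrix(network)
    lb, ub = network.bounds()
    m = len(network.reactions)
    rank = np.linalg.matrix_rank(S)
    d = m - rank
    j_obj = network.reaction_index(objective_id)
    best = None
    for pinned in itertools.combinations(range(m), d):
        free = [j for j in range(m) if j not in pinned]
        A_free = S[:, free]
        if np.linalg.matrix_rank(A_free) < len(free):
            continue
        for values in itertools.product(*[(lb[j], ub[j]) for j in pinned]):
            rhs = -S[:, pinned] @ np.array(values)
            sol, residuals, _, _ = np.linalg.lstsq(A_free, rhs, rcond=None)
            v = np.zeros(m)
            v[list(pinned)] = values
            v[free] = sol
            if np.abs(S @ v).max() > 1e-8:
                continue
            if (v < lb - 1e-8).any() or (v > ub + 1e-8).any():
                continue
            value = v[j_obj]
            if best is None:
                best = value
            elif sense == "max":
                best = max(best, value)
            else:
                best = min(best, value)
    return best


def branched_network():
    """A -> B via cheap/rich routes with different yields (<=6 reactions)."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("IN", {"A": 1}, 0, 4, "exchange"),
        Reaction("R1", {"A": -1, "B": 1}, 0, 3),
        Reaction("R2", {"A": -2, "B": 3}, 0, 1),
        Reaction("OUT", {"B": -1}, 0, 10, "exchange"),
    ]
    return MetabolicNetwork(mets, rxns, objective_id="OUT")


class TestSolveFBA:
    def test_chain_bottleneck(self, chain_network):
        sol = solve_fba(chain_network)
        assert sol.solver_status == "optimal"
        assert sol.objective_value == pytest.approx(5.0)

    def test_closed_system_zero(self, chain_network):
        chain_network.set_bounds("EX_A", 0.0, 0.0)
        sol = solve_fba(chain_network)
        assert sol.objective_value == pytest.approx(0.0)

    def test_steady_state_residual(self, chain_network):
        sol = solve_fba(chain_network)
        assert sol.residual <= 1e-6

    def test_matches_vertex_oracle(self):
        net = branched_network()
        sol = solve_fba(net)
        oracle = brute_force_lp(net, "OUT", "max")
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_toys_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mets = [Metabolite(f"M{i}") for i in range(2)]
        rxns = [
            Reaction("IN", {"M0": 1}, 0, float(rng.integers(1, 5)), "exchange"),
            Reaction("Ra", {"M0": -1, "M1": 1}, 0, float(rng.integers(1, 5))),
            Reaction("Rb", {"M0": -1, "M1": 2}, 0, float(rng.integers(1, 4))),
            Reaction("Rc", {"M1": -1, "M0": 1}, 0, float(rng.integers(1, 3))),
            Reaction("OUT", {"M1": -1}, 0, float(rng.integers(2, 8)), "exchange"),
        ]
        net = MetabolicNetwork(mets, rxns, objective_id="OUT")
        sol = solve_fba(net)
        oracle = brute_force_lp(net, "OUT", "max")
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_infeasible_reported(self, chain_network):
        chain_network.set_bounds("EX_B", 3.0, 10.0)
        chain_network.set_bounds("EX_A", 0.0, 0.0)
        sol = solve_fba(chain_network)
        assert sol.solver_status == "infeasible"
        assert sol.fluxes == {}


class TestSolveFVA:
    def test_fixed_reaction(self, chain_network):
        chain_network.set_bounds("R1", 2.0, 2.0)
        chain_network.set_bounds("EX_A", -5.0, 0.0)
        ranges = solve_fva(chain_network, ["R1"])
        assert ranges["R1"] == pytest.approx((2.0, 2.0))

    def test_chain_span(self, chain_network):
        ranges = solve_fva(chain_network, ["R1"])
        assert ranges["R1"] == pytest.approx((0.0, 5.0))

    def test_matches_per_reaction_oracle(self):
        net = branched_network()
        ranges = solve_fva(net)
        for rid in net.reaction_ids:
            lo = brute_force_lp(net, rid, "min")
            hi = brute_force_lp(net, rid, "max")
            assert ranges[rid][0] == pytest.approx(lo, abs=1e-8)
            assert ranges[rid][1] == pytest.approx(hi, abs=1e-8)


class TestLinearCombination:
    def test_single_reaction_reduces_to_fva(self, chain_network):
        lo, hi = fva_linear_combination(chain_network, ["R1"], [1.0])
        assert (lo, hi) == pytest.approx(solve_fva(chain_network, ["R1"])["R1"])

    def test_structurally_equal_pair_cancels(self, chain_network):
        # T_A and R1 carry identical flux in every solution
        lo, hi = fva_linear_combination(chain_network, ["T_A", "R1"], [1.0, -1.0])
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_matches_auxiliary_variable_oracle(self):
        net = branched_network()
        lo, hi = fva_linear_combination(net, ["R1", "R2"], [1.0, 2.0])
        # oracle: add an explicit summing pseudo-metabolite + free reaction
        aux = net.copy()
        aux.add_metabolite(Metabolite("SUM"))
        aux.reaction("R1").stoichiometry["SUM"] = 1.0
        aux.reaction("R2").stoichiometry["SUM"] = 2.0
        aux.add_reaction(Reaction("DRAIN", {"SUM": -1.0}, -1000, 1000))
        ranges = solve_fva(aux, ["DRAIN"])
        assert (lo, hi) == pytest.approx(ranges["DRAIN"], abs=1e-8)


class TestNGAM:
    def test_grid_covers_zero_and_four(self, closure_results):
        res = closure_results[0.0]["ngam"][0]
        assert res.grid == (0.0, 4.0, 0.01)

    def test_boundary_optimum_zero(self, closure_results):
        """If mu_exp equals the NGAM=0 prediction, the estimate is 0."""
        res = closure_results[0.0]
        net, cs = res["models"][0], res["constraints"][0]
        scan = estimate_ngam(net, cs, res["rate_sets"][0].mu).scan
        mu0 = scan[0][1]  # predicted mu at the smallest feasible NGAM
        est = estimate_ngam(net, cs, mu0)
        assert est.ngam == pytest.approx(scan[0][0])

    def test_recovers_true_ngam(self, closure_results):
        for level, res in closure_results.items():
            for i, ng in enumerate(res["ngam"]):
                truth = res["truth"].phase(i + 1)
                assert abs(ng.ngam - truth.ngam) <= 0.01 + 1e-9

    def test_deterministic(self, closure_results):
        res = closure_results[0.0]
        a = estimate_ngam(res["models"][0], res["constraints"][0],
                          res["rate_sets"][0].mu)
        b = estimate_ngam(res["models"][0], res["constraints"][0],
                          res["rate_sets"][0].mu)
        assert a.ngam == b.ngam
        assert a.scan == b.scan

    def test_all_infeasible_raises(self, reduced_model):
        cs = PhaseConstraintSet(
            phase_id=1,
            fixed_fluxes={"EX_glc": 0.0, "EX_fru": 0.0, "EX_mal": 0.0,
                          "EX_cit": 0.0, "EX_man": 5.0},
            tolerance=0.0,
        )
        with pytest.raises(InfeasibleModelError):
            estimate_ngam(reduced_model, cs, 0.02)


class TestSensitivity:
    def test_zero_perturbation_self_check(self, closure_results):
        res = closure_results[0.0]
        rep = ngam_sensitivity(
            res["models"][0], res["constraints"][0], res["rate_sets"][0].mu,
            perturbation=0.0, coarse_step=0.05, grid_step=0.01,
        )
        for rid, (plus, minus, change) in rep.per_rate.items():
            assert plus == pytest.approx(rep.baseline_ngam)
            assert minus == pytest.approx(rep.baseline_ngam)
            assert change == pytest.approx(0.0, abs=1e-9)

    def test_irrelevant_constraint_no_change(self, reduced_model):
        """A rate with no route to ATP or biomass leaves NGAM untouched."""
        net = reduced_model.copy()
        net.add_metabolite(Metabolite("inert_e", compartment="e"))
        net.add_metabolite(Metabolite("inert_c", compartment="c"))
        net.add_reaction(
            Reaction("EX_inert", {"inert_e": -1}, -1000, 1000, "exchange")
        )
        net.add_reaction(
            Reaction("INERTt", {"inert_e": -1, "inert_c": 1}, 0, 1000, "transport")
        )
        net.add_reaction(
            Reaction("DM_inert", {"inert_c": -1}, 0, 1000, "demand")
        )
        cs = PhaseConstraintSet(
            phase_id=1,
            fixed_fluxes={"EX_glc": -1.0, "EX_inert": -0.5},
            tolerance=0.01,
        )
        base = estimate_ngam(net, cs, 0.005, grid_step=0.05)
        rep = ngam_sensitivity(net, cs, 0.005, grid_step=0.05)
        plus, minus, change = rep.per_rate["EX_inert"]
        assert change == pytest.approx(0.0, abs=1e-9)
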