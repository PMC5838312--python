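import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oenoflux.constraints import PhaseConstraintSet
from oenoflux.extended import (
    accumulation_reaction_id,
    apply_experimental_constraints,
    build_extended_model,
    demand_reaction_id,
    fva_accumulation,
    restrict_extended_solution,
    sink_reaction_id,
    split_into_phase_models,
)
from oenoflux.fba import InfeasibleModelError, LinearModel, solve_fba
from oenoflux.network import MetabolicNetwork, Metabolite, Reaction
from oenoflux.reduced_model import ACCUMULATION_COMPOUNDS


def toy_base():
    """3 metabolites, 4 reactions; C is the accumulating species."""
    mets = [Metabolite("A"), Metabolite("B"), Metabolite("C")]
    rxns = [
        Reaction("IN", {"A": 1}, 0, 10, "exchange"),
        Reaction("AB", {"A": -1, "B": 1}, 0, 10),
        Reaction("BC", {"B": -1, "C": 1}, 0, 10),
        Reaction("OUT", {"C": -1}, 0, 10, "exchange"),
    ]
    return MetabolicNetwork(mets, rxns, objective_id="OUT", name="toy")


class TestBuild:
    def test_dimension_law_reduced_model(self, reduced_model):
        ext = build_extended_model(reduced_model, 3)
        m = len(reduced_model.reactions)
        n = len(reduced_model.metabolites)
        assert ext.Z.shape == (3 * n, 3 * m + 2 * 6)

    def test_single_phase_degenerate(self, reduced_model):
        ext = build_extended_model(reduced_model, 1)
        assert ext.Z.shape == (
            len(reduced_model.metabolites),
            len(reduced_model.reactions),
        )
        assert ext.accumulation == []

    def test_toy_hand_built_oracle(self):
        base = toy_base()
        ext = build_extended_model(base, 2, compounds={"c": "C"})
        Z = ext.Z
        assert Z.shape == (6, 9)
        S = np.array([
            [1, -1, 0, 0],
            [0, 1, -1, 0],
            [0, 0, 1, -1],
        ], dtype=float)
        # block diagonal in two copies of S
        assert np.array_equal(Z[:3, :4], S)
        assert np.array_equal(Z[3:, 4:8], S)
        assert np.array_equal(Z[:3, 4:8], np.zeros((3, 4)))
        assert np.array_equal(Z[3:, :4], np.zeros((3, 4)))
        # accumulation column: -1 on C phase 1, +1 on C phase 2
        col = Z[:, 8]
        expected = np.zeros(6)
        expected[2] = -1.0
        expected[5] = 1.0
        assert np.array_equal(col, expected)

    def test_missing_compound_named(self, reduced_model):
        with pytest.raises(KeyError, match="unobtainium"):
            build_extended_model(
                reduced_model, 3, compounds={"unobtainium": "nope_c"}
            )

    @settings(max_examples=20, deadline=None)
    @given(
        n_phases=st.integers(min_value=1, max_value=4),
        n_compounds=st.integers(min_value=0, max_value=2),
        n_chain=st.integers(min_value=3, max_value=6),
    )
    def test_dimension_law_property(self, n_phases, n_compounds, n_chain):
        mets = [Metabolite(f"M{i}") for i in range(n_chain)]
        rxns = [Reaction("IN", {"M0": 1}, 0, 10, "exchange")]
        rxns += [
            Reaction(f"R{i}", {f"M{i}": -1, f"M{i+1}": 1}, 0, 10)
            for i in range(n_chain - 1)
        ]
        rxns.append(
            Reaction("OUT", {f"M{n_chain-1}": -1}, 0, 10, "exchange")
        )
        base = MetabolicNetwork(mets, rxns, objective_id="OUT")
        compounds = {f"c{i}": f"M{i}" for i in range(n_compounds)}
        ext = build_extended_model(base, n_phases, compounds=compounds)
        m = len(base.reactions)
        assert ext.Z.shape[1] == n_phases * m + (n_phases - 1) * n_compounds


class TestConstraintsAndFVA:
    def test_all_zero_constraints_feasible(self, reduced_model):
        ext = build_extended_model(reduced_model, 3)
        css = [
            PhaseConstraintSet(phase_id=p, fixed_fluxes={"EX_glc": 0.0},
                               tolerance=0.0)
            for p in (1, 2, 3)
        ]
        constrained = apply_experimental_constraints(ext, css)
        spans = fva_accumulation(constrained)
        assert all(lo >= 0 for lo, hi in spans.spans.values())

    def test_contradictory_rate_reports_infeasibility(self, reduced_model):
        ext = build_extended_model(reduced_model, 3)
        # force mannitol production with every substrate shut off
        css = [
            PhaseConstraintSet(
                phase_id=p,
                fixed_fluxes={
                    "EX_glc": 0.0, "EX_fru": 0.0, "EX_mal": 0.0,
                    "EX_cit": 0.0, "EX_man": 5.0,
                },
                tolerance=0.0,
            )
            for p in (1, 2, 3)
        ]
        with pytest.raises(InfeasibleModelError, match="relaxable"):
            apply_experimental_constraints(ext, css)

    def test_noiseless_constraints_feasible(self, closure_results):
        # the session fixture already applied the generator's constraints
        for level, res in closure_results.items():
            assert len(res["spans"].spans) == 12

    def test_span_contains_witness(self, closure_results):
        for level, res in closure_results.items():
            truth = res["truth"]
            for acc_id, (lo, hi) in res["spans"].spans.items():
                compound, p = _parse_acc(acc_id)
                w = truth.phase(p).accumulation_out[compound]
                assert lo - 1e-6 <= w <= hi + 1e-6

    def test_never_produced_compound_zero_span(self):
        base = toy_base()
        ext = build_extended_model(base, 2, compounds={"c": "C"})
        css = [
            PhaseConstraintSet(phase_id=p, fixed_fluxes={"IN": 0.0},
                               tolerance=0.0)
            for p in (1, 2)
        ]
        constrained = apply_experimental_constraints(ext, css)
        spans = fva_accumulation(constrained)
        lo, hi = spans[accumulation_reaction_id("c", 1)]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_unconstrained_toy_span_hits_cap(self):
        base = toy_base()
        ext = build_extended_model(base, 2, compounds={"c": "C"})
        constrained = apply_experimental_constraints(
            ext, [PhaseConstraintSet(phase_id=p) for p in (1, 2)],
            check_feasible=False,
        )
        spans = fva_accumulation(constrained)
        _, hi = spans[accumulation_reaction_id("c", 1)]
        assert hi == pytest.approx(10.0)  # capped by the IN bound

    def test_spans_shrink_with_tighter_tolerance(self, closure_results,
                                                 reduced_model):
        res = closure_results[0.0]
        ext = build_extended_model(reduced_model, 3)
        widths = {}
        for tol in (0.05, 0.0):
            css = [
                PhaseConstraintSet(
                    phase_id=cs.phase_id,
                    fixed_fluxes=dict(cs.fixed_fluxes),
                    biomass=cs.biomass,
                    tolerance=tol,
                )
                for cs in res["constraints"]
            ]
            spans = fva_accumulation(apply_experimental_constraints(ext, css))
            widths[tol] = {
                rid: hi - lo for rid, (lo, hi) in spans.spans.items()
            }
        for rid in widths[0.0]:
            assert widths[0.0][rid] <= widths[0.05][rid] + 1e-9


class TestSplit:
    def test_phase_two_gains_twelve_reactions(self, closure_results,
                                              reduced_model):
        models = closure_results[0.0]["models"]
        m = len(reduced_model.reactions)
        assert len(models[0].reactions) == m + 6  # demands only
        assert len(models[1].reactions) == m + 12  # sinks + demands
        assert len(models[2].reactions) == m + 6  # sinks only

    def test_zero_bounds_block_accumulation(self):
        base = toy_base()
        ext = build_extended_model(base, 2, compounds={"c": "C"})
        from oenoflux.extended import AccumulationBounds

        bounds = AccumulationBounds(
            {accumulation_reaction_id("c", 1): (0.0, 0.0)}
        )
        models = split_into_phase_models(ext, bounds)
        assert models[0].reaction(demand_reaction_id("c")).upper_bound == 0.0
        assert models[1].reaction(sink_reaction_id("c")).upper_bound == 0.0

    def test_restriction_of_extended_solution_feasible(self, closure_results,
                                                       reduced_model):
        """A feasible extended vector restricts to feasible phase vectors."""
        res = closure_results[0.0]
        truth = res["truth"]
        for p in (1, 2, 3):
            net = res["models"][p - 1]
            ph = truth.phase(p)
            v = dict(ph.fluxes)
            # witness demand/sink names match the split model's
            lb, ub = net.bounds()
            x = np.array([v.get(rid, 0.0) for rid in net.reaction_ids])
            from oenoflux.network import stoichiometric_matrix

            S = stoichiometric_matrix(net)
            assert np.abs(S @ x).max() < 1e-6
            assert (x >= lb - 1e-6).all() and (x <= ub + 1e-6).all()

    def test_accumulation_conservation_same_variable(self, closure_results):
        """Outflow of phase k equals inflow of phase k+1 bit-exactly."""
        for level, res in closure_results.items():
            truth = res["truth"]
            for p in (1, 2):
                out = truth.phase(p).accumulation_out
                inflow = truth.phase(p + 1).accumulation_in
                for compound in ACCUMULATION_COMPOUNDS:
                    assert out[compound] == inflow[compound]


def _parse_acc(acc_id):
    # ACC_<compound>_p<k>p<k+1>
    body = acc_id[len("ACC_"):]
    name, phases = body.rsplit("_", 1)
    return name, int(phases[1])
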