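import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oenoflux.network import (
    MetabolicNetwork,
    Metabolite,
    NetworkFormatError,
    NetworkValidationError,
    Reaction,
    carbon_imbalances,
    read_network,
    stoichiometric_matrix,
    validate_network,
    write_network,
)
from oenoflux.fba import solve_fba
from oenoflux.reduced_model import build_reduced_oeni_model, load_reduced_oeni_model


def minimal_network():
    return MetabolicNetwork(
        [Metabolite("A"), Metabolite("B")],
        [Reaction("R1", {"A": -1, "B": 1}, 0, 1000)],
        objective_id="R1",
        name="minimal",
    )


class TestReadWrite:
    def test_json_minimal_irreversible_defaults(self, tmp_path):
        doc = {
            "name": "m",
            "objective": "R1",
            "metabolites": [{"id": "A"}, {"id": "B"}],
            "reactions": [
                {"id": "R1", "stoichiometry": {"A": -1, "B": 1},
                 "reversible": False}
            ],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        net = read_network(str(path), format="json")
        assert len(net.metabolites) == 2
        assert len(net.reactions) == 1
        assert net.reaction("R1").lower_bound == 0.0
        assert net.reaction("R1").upper_bound == 1000.0

    def test_json_reversible_defaults(self, tmp_path):
        doc = {
            "metabolites": [{"id": "A"}, {"id": "B"}],
            "reactions": [{"id": "R1", "stoichiometry": {"A": -1, "B": 1}}],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        net = read_network(str(path), format="json")
        assert net.reaction("R1").lower_bound == -1000.0

    def test_json_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"metabolites": [,]}')
        with pytest.raises(NetworkFormatError):
            read_network(str(path), format="json")

    def test_dangling_metabolite_names_offender(self, tmp_path):
        doc = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "R1", "stoichiometry": {"A": -1, "X": 1}}],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(NetworkValidationError, match="X"):
            read_network(str(path), format="json")

    def test_tsv_dangling_metabolite(self, tmp_path):
        d = tmp_path / "net"
        d.mkdir()
        (d / "metabolites.tsv").write_text(
            "id\tname\tcompartment\tformula\tphase_tag\nA\t\tc\t\t\n"
        )
        (d / "reactions.tsv").write_text(
            "id\tname\tlower_bound\tupper_bound\tsubsystem\trole_tags\tobjective\n"
            "R1\t\t0.0\t1000.0\t\t\t0\n"
        )
        (d / "stoichiometry.tsv").write_text(
            "reaction\tmetabolite\tcoefficient\nR1\tA\t-1\nR1\tX\t1\n"
        )
        with pytest.raises(NetworkValidationError, match="X"):
            read_network(str(d), format="tsv")

    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_round_trip_minimal(self, tmp_path, fmt):
        net = minimal_network()
        path = str(tmp_path / ("m.json" if fmt == "json" else "mdir"))
        write_network(net, path, format=fmt)
        again = read_network(path, format=fmt)
        assert again.structurally_equal(net)

    def test_round_trip_unicode_names(self, tmp_path):
        net = minimal_network()
        net.metabolite("A").name = "α-D-glucose → β"
        path = str(tmp_path / "m.json")
        write_network(net, path, format="json")
        assert read_network(path).metabolite("A").name == "α-D-glucose → β"

    @pytest.mark.parametrize("fmt", ["json", "tsv", "sbml"])
    def test_round_trip_reduced_model_preserves_tags(self, tmp_path, fmt):
        if fmt == "sbml":
            pytest.importorskip("libsbml")
        net = load_reduced_oeni_model()
        path = str(tmp_path / ("model." + fmt if fmt != "tsv" else "modeldir"))
        write_network(net, path, format=fmt)
        again = read_network(path, format=fmt)
        assert again.structurally_equal(net)
        assert {r.id for r in again.reactions_with_tag("atp_producer_pkp")} == {
            "ACK", "PYK", "PGK"
        }

    def test_unwritable_path_raises(self, tmp_path):
        with pytest.raises(OSError):
            write_network(minimal_network(), str(tmp_path / "no" / "dir" / "x.json"))


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        S = stoichiometric_matrix(minimal_network())
        assert S.shape == (2, 1)
        assert list(S[:, 0]) == [-1.0, 1.0]

    def test_coefficients(self):
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("B"), Metabolite("C")],
            [Reaction("R", {"A": -1, "B": -1, "C": 2}, 0, 1000)],
        )
        S = stoichiometric_matrix(net)
        assert list(S[:, 0]) == [-1.0, -1.0, 2.0]

    def test_reduced_model_shape(self, reduced_model):
        S = stoichiometric_matrix(reduced_model)
        assert S.shape == (
            len(reduced_model.metabolites),
            len(reduced_model.reactions),
        )

    def test_exchange_columns_have_one_nonzero(self, reduced_model):
        S = stoichiometric_matrix(reduced_model)
        for rxn in reduced_model.exchange_reactions():
            col = S[:, reduced_model.reaction_index(rxn.id)]
            assert np.count_nonzero(col) == 1


class TestValidation:
    def test_valid_minimal_is_clean(self):
        assert validate_network(minimal_network()) == []

    def test_duplicate_reaction_id(self):
        net = minimal_network()
        net.reactions.append(net.reactions[0].copy())
        findings = validate_network(net)
        assert any(f.code == "duplicate-reaction" for f in findings)

    def test_bound_order_error(self):
        net = minimal_network()
        net.reactions[0].lower_bound = 5
        net.reactions[0].upper_bound = 1
        findings = validate_network(net)
        assert any(f.code == "bound-order" for f in findings)

    def test_exchange_arity(self):
        net = minimal_network()
        net.reactions[0].subsystem = "exchange"
        findings = validate_network(net)
        assert any(f.code == "exchange-arity" for f in findings)


class TestReducedModel:
    def test_expected_subsystems_present(self, reduced_model):
        assert {
            "phosphoketolase", "MLF", "citrate_degradation",
            "fructose_reduction", "ATPase", "NGAM",
        } <= reduced_model.subsystems()

    def test_mlf_consumes_malate_produces_lactate(self, reduced_model):
        mlf = reduced_model.reactions_in_subsystem("MLF")
        assert any(
            r.stoichiometry.get("mal_c", 0) < 0
            and r.stoichiometry.get("llac_c", 0) > 0
            for r in mlf
        )

    def test_pkp_atp_producers_exact(self, reduced_model):
        ids = {r.id for r in reduced_model.reactions_with_tag("atp_producer_pkp")}
        assert ids == {"ACK", "PYK", "PGK"}

    def test_closed_exchanges_zero_flux(self, reduced_model):
        net = reduced_model.copy()
        for r in net.exchange_reactions():
            r.lower_bound = r.upper_bound = 0.0
        sol = solve_fba(net)
        assert sol.solver_status == "optimal"
        assert abs(sol.objective_value) < 1e-9
        assert max(abs(v) for v in sol.fluxes.values()) < 1e-6

    def test_no_internal_dead_ends(self, reduced_model):
        produced, consumed = set(), set()
        for rxn in reduced_model.reactions:
            for met, coeff in rxn.stoichiometry.items():
                if reduced_model.metabolite(met).compartment == "e":
                    continue
                (produced if coeff > 0 else consumed).add(met)
                if rxn.lower_bound < 0:  # reversible: both directions
                    (consumed if coeff > 0 else produced).add(met)
        internal = {
            m.id for m in reduced_model.metabolites if m.compartment != "e"
        }
        assert internal <= produced
        assert internal <= consumed

    def test_carbon_balanced(self, reduced_model):
        assert carbon_imbalances(reduced_model) == {}

    def test_packaged_json_matches_builder(self, reduced_model):
        assert reduced_model.structurally_equal(build_reduced_oeni_model())


@settings(max_examples=25, deadline=None)
@given(
    n_extra=st.integers(min_value=0, max_value=5),
    lb=st.sampled_from([-1000.0, 0.0]),
)
def test_json_round_trip_property(tmp_path_factory, n_extra, lb):
    mets = [Metabolite(f"M{i}") for i in range(n_extra + 2)]
    rxns = [
        Reaction(
            f"R{i}",
            {f"M{i}": -1.0, f"M{i+1}": 1.0},
            lb,
            1000.0,
            subsystem="core",
            role_tags={"sink"} if i == 0 else set(),
        )
        for i in range(n_extra + 1)
    ]
    net = MetabolicNetwork(mets, rxns, objective_id="R0")
    path = tmp_path_factory.mktemp("rt") / "net.json"
    write_network(net, str(path), format="json")
    assert read_network(str(path)).structurally_equal(net)
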