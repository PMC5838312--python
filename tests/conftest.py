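import numpy as np
import pytest

from oenoflux.constraints import PhaseConstraintSet
from oenoflux.extended import (
    apply_experimental_constraints,
    build_extended_model,
    fva_accumulation,
    split_into_phase_models,
)
from oenoflux.fba import estimate_ngam
from oenoflux.network import MetabolicNetwork, Metabolite, Reaction
from oenoflux.rates import estimate_rates
from oenoflux.reduced_model import (
    PRODUCT_EXCHANGES,
    SUBSTRATE_EXCHANGES,
    load_reduced_oeni_model,
)
from oenoflux.synth import MEASURED_COMPOUNDS, default_config, simulate_culture

EXCHANGE_BY_NAME = {**SUBSTRATE_EXCHANGES, **PRODUCT_EXCHANGES}


@pytest.fixture(scope="session")
def reduced_model():
    return load_reduced_oeni_model()


@pytest.fixture(scope="session")
def gen_config():
    return default_config()


def make_chain_network():
    """A_ex -> A -> B -> B_ex with uptake capacity 5."""
    mets = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("B_e", compartment="e"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -5, 0, "exchange"),
        Reaction("T_A", {"A_e": -1, "A": 1}, 0, 1000, "transport"),
        Reaction("R1", {"A": -1, "B": 1}, 0, 1000, "core"),
        Reaction("T_B", {"B": -1, "B_e": 1}, 0, 1000, "transport"),
        Reaction("EX_B", {"B_e": -1}, 0, 1000, "exchange"),
    ]
    return MetabolicNetwork(mets, rxns, objective_id="EX_B", name="chain")


def make_diamond_network():
    net = make_chain_network()
    net.add_reaction(Reaction("R2", {"A": -1, "B": 1}, 0, 1000, "core"))
    return net


@pytest.fixture
def chain_network():
    return make_chain_network()


@pytest.fixture
def diamond_network():
    return make_diamond_network()


def closure_for_level(ethanol, config, base, ext):
    """Run the generator -> rates -> extended -> NGAM loop for one level."""
    tc, truth = simulate_culture(config, ethanol, noise_cv=0.0)
    rate_sets = estimate_rates(tc)
    css = [
        PhaseConstraintSet(
            phase_id=rs.phase_id,
            fixed_fluxes={
                EXCHANGE_BY_NAME[n]: rs.q[n] for n in MEASURED_COMPOUNDS
            },
            biomass=rs.mu,
            tolerance=0.0,
        )
        for rs in rate_sets[:3]
    ]
    cext = apply_experimental_constraints(ext, css)
    spans = fva_accumulation(cext)
    models = split_into_phase_models(cext, spans)
    ngam_results = [
        estimate_ngam(models[i], css[i], rate_sets[i].mu) for i in range(3)
    ]
    return {
        "timecourse": tc,
        "truth": truth,
        "rate_sets": rate_sets,
        "constraints": css,
        "spans": spans,
        "models": models,
        "ngam": ngam_results,
    }


@pytest.fixture(scope="session")
def closure_results(gen_config, reduced_model):
    """Noiseless end-to-end closure for all five ethanol levels (shared)."""
    ext = build_extended_model(reduced_model, 3)
    return {
        e: closure_for_level(e, gen_config, reduced_model, ext)
        for e in gen_config.ethanol_levels
    }
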