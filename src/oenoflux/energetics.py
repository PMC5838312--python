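"""ATP, NAD(P)H and proton bookkeeping over a solved flux distribution.

Accounting is done twice: once from ``role_tags`` (the declared enzyme
routes) and once directly from the stoichiometry.  The stoichiometric audit
is authoritative — at steady state production equals consumption for every
tracked species — and the tag-based route sums must agree with it; a
mismatch points at an incomplete tagging of the model and raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .fba import FluxDistribution, fva_linear_combination
from .network import MetabolicNetwork

AUDIT_TOL = 1e-6

#: species ids used by the packaged models
ATP = "atp_c"
NADH = "nadh_c"
NADPH = "nadph_c"
H_CYT = "h_c"
H_EXT = "h_e"


class AccountingConfigError(ValueError):
    """The network lacks the role tags / species needed for a report."""


@dataclass
class SpeciesBalance:
    production: float
    consumption: float

    @property
    def net(self) -> float:
        return self.production - self.consumption


@dataclass
class EnergeticsReport:
    r_atp_f0f1: float
    r_atp_pkp: float
    per_reaction: Dict[str, float]  # signed ATP contribution by reaction
    consumers: Dict[str, float]  # ATP consumption by reaction (positive)
    ngam_flux: float
    non_unique: bool = False

    @property
    def r_atp_total(self) -> float:
        return self.r_atp_f0f1 + self.r_atp_pkp

    @property
    def fraction_f0f1(self) -> float:
        total = self.r_atp_total
        return self.r_atp_f0f1 / total if total > 0 else float("nan")


@dataclass
class RedoxReport:
    nadh_production: Dict[str, float]  # per tagged enzyme
    nadph_production: Dict[str, float]
    nadh_total: float
    nadph_total: float
    regeneration_share: float  # NAD(P)+ regenerated by polyol formation
    non_unique: bool = False

    @property
    def nadph_plus_nadh_total(self) -> float:
        return self.nadh_total + self.nadph_total


@dataclass
class ProtonReport:
    protons_in_f0f1: float
    protons_out_mlf_lactate: float
    protons_consumed_diacetyl: float
    membrane_fluxes: Dict[str, float]  # signed h_e production per reaction
    cytosol_fluxes: Dict[str, float]  # signed h_c production per reaction

    def fraction_of_f0f1(self, amount: float) -> float:
        if self.protons_in_f0f1 <= 0:
            return float("nan")
        return amount / self.protons_in_f0f1

    @property
    def fraction_mlf_lactate(self) -> float:
        return self.fraction_of_f0f1(self.protons_out_mlf_lactate)

    @property
    def fraction_diacetyl(self) -> float:
        return self.fraction_of_f0f1(self.protons_consumed_diacetyl)


# ---------------------------------------------------------------------------
# stoichiometric audits
# ---------------------------------------------------------------------------

def species_contributions(
    flux: FluxDistribution, network: MetabolicNetwork, species: str
) -> Dict[str, float]:
    """Signed production rate of ``species`` per reaction (coeff · flux)."""
    out: Dict[str, float] = {}
    for rxn in network.reactions:
        coeff = rxn.stoichiometry.get(species)
        if coeff is None:
            continue
        v = flux.fluxes.get(rxn.id, 0.0)
        contribution = coeff * v
        if contribution != 0.0:
            out[rxn.id] = contribution
    return out


def species_balance(
    flux: FluxDistribution, network: MetabolicNetwork, species: str
) -> SpeciesBalance:
    contrib = species_contributions(flux, network, species)
    production = sum(c for c in contrib.values() if c > 0)
    consumption = -sum(c for c in contrib.values() if c < 0)
    return SpeciesBalance(production, consumption)


def audit_balances(
    flux: FluxDistribution,
    network: MetabolicNetwork,
    species: Sequence[str] = (ATP, NADH, NADPH, H_CYT),
    tol: float = AUDIT_TOL,
) -> Dict[str, SpeciesBalance]:
    """Assert production == consumption for every tracked species."""
    balances = {}
    for sp in species:
        if not network.has_metabolite(sp):
            continue
        bal = species_balance(flux, network, sp)
        if abs(bal.net) > tol:
            raise AssertionError(
                f"{sp} balance violated: production {bal.production:.6g} "
                f"vs consumption {bal.consumption:.6g}"
            )
        balances[sp] = bal
    return balances


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def atp_accounting(
    flux: FluxDistribution,
    network: MetabolicNetwork,
    ngam_id: str = "NGAM",
    atp_id: str = ATP,
    uniqueness_network: Optional[MetabolicNetwork] = None,
) -> EnergeticsReport:
    """ATP production split into the F0F1 and substrate-level routes.

    With ``uniqueness_network`` (a bound-constrained model), the report is
    flagged non-unique when FVA shows the route sums admit alternate
    optima beyond the audit tolerance.
    """
    pkp_rxns = network.reactions_with_tag("atp_producer_pkp")
    f0f1_rxns = network.reactions_with_tag("atp_producer_f0f1")
    if not pkp_rxns or not f0f1_rxns:
        raise AccountingConfigError(
            "network lacks atp_producer_pkp / atp_producer_f0f1 role tags"
        )
    contrib = species_contributions(flux, network, atp_id)
    audit_balances(flux, network, species=(atp_id,))
    r_pkp = sum(max(contrib.get(r.id, 0.0), 0.0) for r in pkp_rxns)
    r_f0f1 = sum(max(contrib.get(r.id, 0.0), 0.0) for r in f0f1_rxns)
    tagged_total = r_pkp + r_f0f1
    total_production = sum(c for c in contrib.values() if c > 0)
    if tagged_total - total_production < -AUDIT_TOL * max(1.0, total_production):
        untagged = [
            rid for rid, c in contrib.items()
            if c > AUDIT_TOL
            and not ({"atp_producer_pkp", "atp_producer_f0f1"}
                     & network.reaction(rid).role_tags)
        ]
        raise AccountingConfigError(
            f"untagged ATP-producing reactions: {sorted(untagged)}"
        )
    consumers = {rid: -c for rid, c in contrib.items() if c < 0}
    non_unique = False
    if uniqueness_network is not None:
        ids = [r.id for r in pkp_rxns + f0f1_rxns]
        coeffs = [r.stoichiometry[atp_id] for r in pkp_rxns + f0f1_rxns]
        lo, hi = fva_linear_combination(uniqueness_network, ids, coeffs)
        non_unique = (hi - lo) > AUDIT_TOL
    return EnergeticsReport(
        r_atp_f0f1=r_f0f1,
        r_atp_pkp=r_pkp,
        per_reaction=contrib,
        consumers=consumers,
        ngam_flux=flux.fluxes.get(ngam_id, 0.0),
        non_unique=non_unique,
    )


def redox_accounting(
    flux: FluxDistribution,
    network: MetabolicNetwork,
    nadh_id: str = NADH,
    nadph_id: str = NADPH,
    polyol_reaction_ids: Sequence[str] = ("MANDH", "ERYS"),
    uniqueness_network: Optional[MetabolicNetwork] = None,
) -> RedoxReport:
    """Per-enzyme NAD(P)H production and the polyol regeneration share."""
    nadh_rxns = network.reactions_with_tag("nadh_producer")
    nadph_rxns = network.reactions_with_tag("nadph_producer")
    if not nadh_rxns or not nadph_rxns:
        raise AccountingConfigError(
            "network lacks nadh_producer / nadph_producer role tags"
        )
    nadh_contrib = species_contributions(flux, network, nadh_id)
    nadph_contrib = species_contributions(flux, network, nadph_id)
    audit_balances(flux, network, species=(nadh_id, nadph_id))
    nadh_prod = {
        r.id: max(nadh_contrib.get(r.id, 0.0), 0.0) for r in nadh_rxns
    }
    nadph_prod = {
        r.id: max(nadph_contrib.get(r.id, 0.0), 0.0) for r in nadph_rxns
    }
    # terminal reoxidation = pooled NAD(P)H consumption per reaction, so a
    # transhydrogenase (NADPH -> NADH, pooled change zero) does not count
    pooled: Dict[str, float] = {}
    for contrib in (nadh_contrib, nadph_contrib):
        for rid, c in contrib.items():
            pooled[rid] = pooled.get(rid, 0.0) + c
    total_reox = -sum(c for c in pooled.values() if c < 0)
    polyol_reox = sum(
        -min(pooled.get(rid, 0.0), 0.0)
        for rid in polyol_reaction_ids
        if network.has_reaction(rid)
    )
    share = polyol_reox / total_reox if total_reox > 0 else float("nan")
    non_unique = False
    if uniqueness_network is not None:
        for rxns, species in ((nadh_rxns, nadh_id), (nadph_rxns, nadph_id)):
            ids = [r.id for r in rxns]
            coeffs = [r.stoichiometry[species] for r in rxns]
            lo, hi = fva_linear_combination(uniqueness_network, ids, coeffs)
            if (hi - lo) > AUDIT_TOL:
                non_unique = True
    return RedoxReport(
        nadh_production=nadh_prod,
        nadph_production=nadph_prod,
        nadh_total=sum(nadh_prod.values()),
        nadph_total=sum(nadph_prod.values()),
        regeneration_share=share,
        non_unique=non_unique,
    )


def proton_accounting(
    flux: FluxDistribution,
    network: MetabolicNetwork,
    h_cyt_id: str = H_CYT,
    h_ext_id: str = H_EXT,
    mlf_subsystem: str = "MLF",
    lactate_symport_id: str = "LLACt",
    diacetyl_route_ids: Sequence[str] = ("ALS", "DIAS"),
) -> ProtonReport:
    """Proton balance: F0F1 influx vs the MLF/L-lactate and diacetyl routes."""
    if not (network.has_metabolite(h_cyt_id) and network.has_metabolite(h_ext_id)):
        raise AccountingConfigError(
            "explicit proton species required in both compartments"
        )
    ext = species_contributions(flux, network, h_ext_id)
    cyt = species_contributions(flux, network, h_cyt_id)
    audit_balances(flux, network, species=(h_cyt_id,))
    f0f1 = network.reactions_with_tag("atp_producer_f0f1")
    protons_in = sum(-min(ext.get(r.id, 0.0), 0.0) for r in f0f1)
    mlf_consumed = sum(
        -min(cyt.get(r.id, 0.0), 0.0)
        for r in network.reactions_in_subsystem(mlf_subsystem)
    )
    symport_out = 0.0
    if network.has_reaction(lactate_symport_id):
        symport_out = -min(cyt.get(lactate_symport_id, 0.0), 0.0)
    diacetyl = sum(
        -min(cyt.get(rid, 0.0), 0.0)
        for rid in diacetyl_route_ids
        if network.has_reaction(rid)
    )
    return ProtonReport(
        protons_in_f0f1=protons_in,
        protons_out_mlf_lactate=mlf_consumed + symport_out,
        protons_consumed_diacetyl=diacetyl,
        membrane_fluxes=ext,
        cytosol_fluxes=cyt,
    )
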