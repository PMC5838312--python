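"""Multi-phase stacked stoichiometric system with inter-phase accumulation.

The extended model block-stacks one copy of the base network per growth
phase (metabolite and reaction ids suffixed ``__p<k>``) and couples
consecutive phases through irreversible accumulation reactions, one per
accumulating compound, that move one unit of the phase-k cytosolic species
to its phase-(k+1) twin.  The stacked matrix ``Z`` therefore has shape
``(n_phases·n) x (n_phases·m + (n_phases-1)·c)`` for ``c`` compounds.

After experimental rates are imposed per phase, FVA over the accumulation
columns yields the admissible carry-over spans, and the system is split
back into per-phase models in which carried material enters as a sink
(phases II, III) and leaves as a demand (phases I, II).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .constraints import PhaseConstraintSet
from .fba import FVARange, InfeasibleModelError, LinearModel, solve_fva
from .network import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    stoichiometric_matrix,
)
from .reduced_model import ACCUMULATION_COMPOUNDS, NGAM_ID

DEFAULT_NGAM_RANGE = (0.0, 4.0)


@dataclass
class AccumulationReaction:
    """Carry-over of one compound from ``from_phase`` to ``from_phase + 1``."""

    compound: str
    metabolite_id: str  # cytosolic id in the base network
    from_phase: int
    reaction_id: str

    @property
    def to_phase(self) -> int:
        return self.from_phase + 1


@dataclass
class ExtendedModel:
    base: MetabolicNetwork
    n_phases: int
    compounds: Dict[str, str]  # name -> base cytosolic metabolite id
    accumulation: List[AccumulationReaction]
    network: MetabolicNetwork

    @property
    def Z(self) -> np.ndarray:
        return stoichiometric_matrix(self.network)

    def phase_reaction_id(self, phase: int, base_reaction_id: str) -> str:
        return f"{base_reaction_id}__p{phase}"

    def accumulation_ids(self) -> List[str]:
        return [a.reaction_id for a in self.accumulation]

    def expected_columns(self) -> int:
        m = len(self.base.reactions)
        c = len(self.compounds)
        return self.n_phases * m + (self.n_phases - 1) * c


@dataclass
class AccumulationBounds:
    """FVA spans (min, max) per accumulation reaction id."""

    spans: Dict[str, Tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.spans[rxn_id]


def accumulation_reaction_id(compound: str, from_phase: int) -> str:
    return f"ACC_{compound}_p{from_phase}p{from_phase + 1}"


def build_extended_model(
    base: MetabolicNetwork,
    n_phases: int = 3,
    compounds: Optional[Mapping[str, str]] = None,
) -> ExtendedModel:
    """Stack ``n_phases`` copies of ``base`` joined by accumulation columns.

    ``compounds`` maps compound name to its cytosolic metabolite id in
    ``base`` (defaults to the packaged six).  With ``n_phases == 1`` the
    result is the base system with no accumulation reactions.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    compounds = dict(compounds) if compounds is not None else dict(ACCUMULATION_COMPOUNDS)
    for name, mid in compounds.items():
        if not base.has_metabolite(mid):
            raise KeyError(
                f"accumulation compound {name!r}: metabolite {mid!r} absent from base network"
            )
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    for p in range(1, n_phases + 1):
        for m in base.metabolites:
            mets.append(
                Metabolite(
                    id=f"{m.id}__p{p}",
                    name=m.name,
                    compartment=m.compartment,
                    formula=m.formula,
                    phase_tag=p,
                )
            )
        for r in base.reactions:
            rxns.append(
                Reaction(
                    id=f"{r.id}__p{p}",
                    stoichiometry={
                        f"{k}__p{p}": v for k, v in r.stoichiometry.items()
                    },
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    subsystem=r.subsystem,
                    role_tags=set(r.role_tags),
                    name=r.name,
                )
            )
    accumulation: List[AccumulationReaction] = []
    for name, mid in compounds.items():
        for p in range(1, n_phases):
            rid = accumulation_reaction_id(name, p)
            rxns.append(
                Reaction(
                    id=rid,
                    stoichiometry={f"{mid}__p{p}": -1.0, f"{mid}__p{p + 1}": 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    subsystem="accumulation",
                    role_tags={"accumulation"},
                    name=f"{name} carry-over phase {p} to {p + 1}",
                )
            )
            accumulation.append(
                AccumulationReaction(
                    compound=name,
                    metabolite_id=mid,
                    from_phase=p,
                    reaction_id=rid,
                )
            )
    network = MetabolicNetwork(
        mets, rxns, objective_id=None, name=f"{base.name}__extended{n_phases}"
    )
    ext = ExtendedModel(
        base=base,
        n_phases=n_phases,
        compounds=compounds,
        accumulation=accumulation,
        network=network,
    )
    assert len(network.reactions) == ext.expected_columns()
    return ext


def apply_experimental_constraints(
    ext: ExtendedModel,
    per_phase: Sequence[PhaseConstraintSet],
    ngam_range: Tuple[float, float] = DEFAULT_NGAM_RANGE,
    ngam_id: str = NGAM_ID,
    biomass_id: Optional[str] = None,
    check_feasible: bool = True,
) -> ExtendedModel:
    """Impose per-phase measured rates on a copy of the extended system.

    Each fixed flux is bounded to ``value ± tolerance·|value|`` in its phase
    block; biomass likewise when given.  The per-phase maintenance flux is
    bounded to ``ngam_range`` unless the constraint set pins it.  On
    infeasibility, a best-effort list of constraints whose individual
    relaxation restores feasibility is reported.
    """
    if len(per_phase) != ext.n_phases:
        raise ValueError(
            f"expected {ext.n_phases} constraint sets, got {len(per_phase)}"
        )
    biomass_id = biomass_id or ext.base.objective_id
    net = ext.network.copy()
    applied: List[Tuple[str, float, float]] = []
    for cs in per_phase:
        p = cs.phase_id
        if not 1 <= p <= ext.n_phases:
            raise ValueError(f"phase_id {p} outside 1..{ext.n_phases}")
        for rid, value in cs.fixed_fluxes.items():
            ext_id = ext.phase_reaction_id(p, rid)
            if not net.has_reaction(ext_id):
                raise KeyError(f"no reaction {rid!r} in phase {p} block")
            lo, hi = cs.interval(value)
            net.set_bounds(ext_id, lo, hi)
            applied.append((ext_id, lo, hi))
        for rid, (lo, hi) in cs.range_bounds.items():
            ext_id = ext.phase_reaction_id(p, rid)
            net.set_bounds(ext_id, lo, hi)
            applied.append((ext_id, lo, hi))
        if cs.biomass is not None and biomass_id is not None:
            lo, hi = cs.interval(cs.biomass)
            ext_id = ext.phase_reaction_id(p, biomass_id)
            net.set_bounds(ext_id, max(lo, 0.0), hi)
            applied.append((ext_id, max(lo, 0.0), hi))
        ngam_ext = ext.phase_reaction_id(p, ngam_id)
        if net.has_reaction(ngam_ext):
            if cs.ngam is not None:
                net.set_bounds(ngam_ext, cs.ngam, cs.ngam)
            else:
                net.set_bounds(ngam_ext, *ngam_range)
    constrained = ExtendedModel(
        base=ext.base,
        n_phases=ext.n_phases,
        compounds=dict(ext.compounds),
        accumulation=list(ext.accumulation),
        network=net,
    )
    if check_feasible:
        lp = LinearModel(net)
        status, _, _ = lp.solve({net.reactions[0].id: 0.0}, sense="min")
        if status == "infeasible":
            culprits = _diagnose_infeasibility(net, applied)
            raise InfeasibleModelError(
                "extended model infeasible under experimental constraints; "
                f"individually-relaxable constraints: {culprits or 'none found'}"
            )
    return constrained


def _diagnose_infeasibility(
    net: MetabolicNetwork, applied: List[Tuple[str, float, float]]
) -> List[str]:
    culprits = []
    for rid, _, _ in applied:
        probe = net.copy()
        probe.set_bounds(rid, -1000.0, 1000.0)
        lp = LinearModel(probe)
        status, _, _ = lp.solve({rid: 0.0}, sense="min")
        if status == "optimal":
            culprits.append(rid)
    return culprits


def fva_accumulation(ext: ExtendedModel) -> AccumulationBounds:
    """Min/max feasible flux of every accumulation reaction (FVA)."""
    ids = ext.accumulation_ids()
    fva: FVARange = solve_fva(ext.network, ids)
    spans = {}
    for rid in ids:
        lo, hi = fva[rid]
        spans[rid] = (max(lo, 0.0), max(hi, 0.0))  # clip solver noise
    return AccumulationBounds(spans)


def sink_reaction_id(compound: str) -> str:
    return f"SINK_{compound}"


def demand_reaction_id(compound: str) -> str:
    return f"DM_{compound}"


def split_into_phase_models(
    ext: ExtendedModel,
    bounds: AccumulationBounds,
) -> List[MetabolicNetwork]:
    """Decompose the extended system into per-phase networks (S' matrices).

    Phase k receives a sink (inflow bounded by the (k-1)->k span) for every
    compound when k > 1, and a demand (outflow bounded by the k->(k+1)
    span) when k < n_phases.  Everything else is the base network.
    """
    models: List[MetabolicNetwork] = []
    by_phase: Dict[int, Dict[str, AccumulationReaction]] = {}
    for acc in ext.accumulation:
        by_phase.setdefault(acc.from_phase, {})[acc.compound] = acc
    for p in range(1, ext.n_phases + 1):
        net = ext.base.copy(name=f"{ext.base.name}__phase{p}")
        if p > 1:
            for compound, acc in by_phase.get(p - 1, {}).items():
                lo, hi = bounds[acc.reaction_id]
                net.add_reaction(
                    Reaction(
                        id=sink_reaction_id(compound),
                        stoichiometry={acc.metabolite_id: 1.0},
                        lower_bound=lo,
                        upper_bound=hi,
                        subsystem="accumulation",
                        role_tags={"sink", "accumulation"},
                        name=f"{compound} accumulated in phase {p - 1}",
                    )
                )
        if p < ext.n_phases:
            for compound, acc in by_phase.get(p, {}).items():
                lo, hi = bounds[acc.reaction_id]
                net.add_reaction(
                    Reaction(
                        id=demand_reaction_id(compound),
                        stoichiometry={acc.metabolite_id: -1.0},
                        lower_bound=lo,
                        upper_bound=hi,
                        subsystem="accumulation",
                        role_tags={"demand", "accumulation"},
                        name=f"{compound} accumulating for phase {p + 1}",
                    )
                )
        models.append(net)
    return models


def restrict_extended_solution(
    ext: ExtendedModel, fluxes: Mapping[str, float], phase: int
) -> Dict[str, float]:
    """Project an extended flux vector onto one phase's split model ids."""
    out: Dict[str, float] = {}
    suffix = f"__p{phase}"
    for rid, v in fluxes.items():
        if rid.endswith(suffix):
            out[rid[: -len(suffix)]] = v
    for acc in ext.accumulation:
        v = fluxes.get(acc.reaction_id, 0.0)
        if acc.from_phase == phase:
            out[demand_reaction_id(acc.compound)] = v
        elif acc.to_phase == phase:
            out[sink_reaction_id(acc.compound)] = v
    return out
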