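"""Data model and I/O for constraint-based metabolic networks.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions from which the stoichiometric matrix ``S`` (metabolites x
reactions) is derived.  Three interchange formats are supported:

* canonical JSON (the package's native format, carries every field),
* a three-file TSV layout (``metabolites.tsv``, ``reactions.tsv``,
  ``stoichiometry.tsv`` inside one directory),
* SBML Level 3 with the ``fbc`` package (requires ``python-libsbml``;
  subsystem and role tags travel in reaction notes).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

DEFAULT_BOUND = 1000.0

#: tokens accepted in Reaction.role_tags
KNOWN_ROLE_TAGS = {
    "atp_producer_pkp",
    "atp_producer_f0f1",
    "nadh_producer",
    "nadph_producer",
    "proton_extruder",
    "proton_importer",
    "sink",
    "demand",
    "accumulation",
}


class NetworkFormatError(ValueError):
    """Raised when a model file cannot be parsed under the named format."""


class NetworkValidationError(ValueError):
    """Raised when a parsed model violates structural invariants."""


@dataclass
class Metabolite:
    """One chemical species in one compartment.

    ``phase_tag`` is only populated inside extended multi-phase models,
    never in base networks.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    phase_tag: Optional[int] = None

    def carbon_count(self) -> Optional[int]:
        """Number of carbon atoms parsed from ``formula`` (None if unknown)."""
        if not self.formula:
            return None
        return _element_count(self.formula, "C")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    Stoichiometry maps metabolite id to a signed coefficient; negative
    means consumed.  Bounds are in mmol·gDCW⁻¹·h⁻¹ (h⁻¹ for biomass).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    role_tags: Set[str] = field(default_factory=set)
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            role_tags=set(self.role_tags),
            name=self.name,
        )


@dataclass
class Finding:
    """A validation finding; ``level`` is 'error' or 'warning'."""

    level: str
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.code}: {self.message}"


class MetabolicNetwork:
    """Ordered metabolites + reactions with a designated objective reaction."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: Optional[str] = None,
        name: str = "",
    ) -> None:
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective_id = objective_id
        self.name = name
        self._reindex()

    # -- indexing helpers -------------------------------------------------
    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def reactions_in_subsystem(self, subsystem: str) -> List[Reaction]:
        return [r for r in self.reactions if r.subsystem == subsystem]

    def reactions_with_tag(self, tag: str) -> List[Reaction]:
        return [r for r in self.reactions if tag in r.role_tags]

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.subsystem == "exchange"]

    def subsystems(self) -> Set[str]:
        return {r.subsystem for r in self.reactions if r.subsystem}

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise NetworkValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise NetworkValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                )
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    def copy(self, name: Optional[str] = None) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=[
                Metabolite(m.id, m.name, m.compartment, m.formula, m.phase_tag)
                for m in self.metabolites
            ],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            name=self.name if name is None else name,
        )

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reaction(rxn_id)
        if lower > upper:
            raise NetworkValidationError(
                f"lower bound {lower} > upper bound {upper} for {rxn_id!r}"
            )
        rxn.lower_bound = lower
        rxn.upper_bound = upper

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def structurally_equal(self, other: "MetabolicNetwork") -> bool:
        """Id-, stoichiometry- and bound-level equality (order preserved)."""
        if self.metabolite_ids != other.metabolite_ids:
            return False
        if self.reaction_ids != other.reaction_ids:
            return False
        if self.objective_id != other.objective_id:
            return False
        for a, b in zip(self.reactions, other.reactions):
            if not math.isclose(a.lower_bound, b.lower_bound, abs_tol=1e-9):
                return False
            if not math.isclose(a.upper_bound, b.upper_bound, abs_tol=1e-9):
                return False
            if set(a.stoichiometry) != set(b.stoichiometry):
                return False
            for k, v in a.stoichiometry.items():
                if not math.isclose(v, b.stoichiometry[k], abs_tol=1e-9):
                    return False
            if a.subsystem != b.subsystem or a.role_tags != b.role_tags:
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicNetwork {self.name!r}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------

def stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense S matrix (n metabolites x m reactions).

    Entry ``(i, j)`` is the coefficient of metabolite ``i`` in reaction
    ``j``; rows follow ``network.metabolites``, columns
    ``network.reactions``.
    """
    n, m = len(network.metabolites), len(network.reactions)
    S = np.zeros((n, m))
    for j, rxn in enumerate(network.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[network.metabolite_index(met_id), j] = coeff
    return S


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(network: MetabolicNetwork) -> List[Finding]:
    """Return findings for violated invariants; empty list means valid."""
    findings: List[Finding] = []
    seen_m: Set[str] = set()
    for met in network.metabolites:
        if met.id in seen_m:
            findings.append(Finding("error", "duplicate-metabolite", met.id))
        seen_m.add(met.id)
    seen_r: Set[str] = set()
    used_mets: Set[str] = set()
    for rxn in network.reactions:
        if rxn.id in seen_r:
            findings.append(Finding("error", "duplicate-reaction", rxn.id))
        seen_r.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                Finding(
                    "error",
                    "bound-order",
                    f"{rxn.id}: lower bound {rxn.lower_bound} > upper bound {rxn.upper_bound}",
                )
            )
        dangling = [m for m in rxn.stoichiometry if m not in seen_m_all(network)]
        for met_id in dangling:
            findings.append(
                Finding(
                    "error",
                    "dangling-metabolite",
                    f"{rxn.id} references undeclared metabolite {met_id!r}",
                )
            )
        used_mets.update(rxn.stoichiometry)
        if rxn.subsystem == "exchange" and len(rxn.stoichiometry) != 1:
            findings.append(
                Finding(
                    "error",
                    "exchange-arity",
                    f"exchange reaction {rxn.id} touches {len(rxn.stoichiometry)} metabolites",
                )
            )
        unknown_tags = rxn.role_tags - KNOWN_ROLE_TAGS
        if unknown_tags:
            findings.append(
                Finding(
                    "warning",
                    "unknown-role-tag",
                    f"{rxn.id}: {sorted(unknown_tags)}",
                )
            )
    if network.objective_id is not None and network.objective_id not in seen_r:
        findings.append(
            Finding("error", "missing-objective", str(network.objective_id))
        )
    for met in network.metabolites:
        if met.id not in used_mets:
            findings.append(Finding("warning", "orphan-metabolite", met.id))
    return findings


def seen_m_all(network: MetabolicNetwork) -> Set[str]:
    return set(network._met_index)


def require_valid(network: MetabolicNetwork) -> None:
    errors = [f for f in validate_network(network) if f.level == "error"]
    if errors:
        raise NetworkValidationError(
            "invalid network: " + "; ".join(str(f) for f in errors)
        )


# ---------------------------------------------------------------------------
# element bookkeeping
# ---------------------------------------------------------------------------

def _element_count(formula: str, element: str) -> int:
    count = 0
    i = 0
    while i < len(formula):
        ch = formula[i]
        if ch.isupper():
            sym = ch
            i += 1
            while i < len(formula) and formula[i].islower():
                sym += formula[i]
                i += 1
            digits = ""
            while i < len(formula) and formula[i].isdigit():
                digits += formula[i]
                i += 1
            if sym == element:
                count += int(digits) if digits else 1
        else:
            i += 1
    return count


def carbon_imbalances(
    network: MetabolicNetwork, skip: Sequence[str] = ()
) -> Dict[str, float]:
    """Net carbon per reaction, excluding exchanges, biomass and ``skip``.

    A nonzero value flags a carbon-unbalanced internal reaction.  Reactions
    touching a metabolite without a formula are skipped.
    """
    out: Dict[str, float] = {}
    for rxn in network.reactions:
        if rxn.subsystem in ("exchange", "biomass") or rxn.id in skip:
            continue
        if rxn.id == network.objective_id:
            continue
        total = 0.0
        known = True
        for met_id, coeff in rxn.stoichiometry.items():
            c = network.metabolite(met_id).carbon_count()
            if c is None:
                known = False
                break
            total += coeff * c
        if known and abs(total) > 1e-9:
            out[rxn.id] = total
    return out


# ---------------------------------------------------------------------------
# JSON format
# ---------------------------------------------------------------------------

def _network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "name": network.name,
        "objective": network.objective_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"phase_tag": m.phase_tag} if m.phase_tag is not None else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "role_tags": sorted(r.role_tags),
            }
            for r in network.reactions
        ],
    }


def _network_from_dict(data: dict, source: str = "<json>") -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                phase_tag=m.get("phase_tag"),
            )
            for m in data["metabolites"]
        ]
        rxns = []
        for r in data["reactions"]:
            stoich = {k: float(v) for k, v in r["stoichiometry"].items()}
            reversible = bool(r.get("reversible", True))
            lb = r.get("lower_bound")
            ub = r.get("upper_bound")
            if lb is None:
                lb = -DEFAULT_BOUND if reversible else 0.0
            if ub is None:
                ub = DEFAULT_BOUND
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoichiometry=stoich,
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    subsystem=r.get("subsystem", ""),
                    role_tags=set(r.get("role_tags", [])),
                    name=r.get("name", ""),
                )
            )
    except (KeyError, TypeError) as exc:
        raise NetworkFormatError(f"{source}: malformed model document ({exc})") from exc
    net = MetabolicNetwork(
        mets, rxns, objective_id=data.get("objective"), name=data.get("name", "")
    )
    errors = [f for f in validate_network(net) if f.level == "error"]
    if errors:
        raise NetworkValidationError(
            f"{source}: " + "; ".join(str(f) for f in errors)
        )
    return net


# ---------------------------------------------------------------------------
# TSV format (directory with metabolites.tsv / reactions.tsv / stoichiometry.tsv)
# ---------------------------------------------------------------------------

def _write_tsv(network: MetabolicNetwork, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metabolites.tsv"), "w", encoding="utf-8") as fh:
        fh.write("id\tname\tcompartment\tformula\tphase_tag\n")
        for m in network.metabolites:
            fh.write(
                f"{m.id}\t{m.name}\t{m.compartment}\t{m.formula or ''}\t"
                f"{'' if m.phase_tag is None else m.phase_tag}\n"
            )
    with open(os.path.join(path, "reactions.tsv"), "w", encoding="utf-8") as fh:
        fh.write("id\tname\tlower_bound\tupper_bound\tsubsystem\trole_tags\tobjective\n")
        for r in network.reactions:
            fh.write(
                f"{r.id}\t{r.name}\t{r.lower_bound!r}\t{r.upper_bound!r}\t"
                f"{r.subsystem}\t{','.join(sorted(r.role_tags))}\t"
                f"{1 if r.id == network.objective_id else 0}\n"
            )
    with open(os.path.join(path, "stoichiometry.tsv"), "w", encoding="utf-8") as fh:
        fh.write("reaction\tmetabolite\tcoefficient\n")
        for r in network.reactions:
            for met_id, coeff in r.stoichiometry.items():
                fh.write(f"{r.id}\t{met_id}\t{coeff!r}\n")


def _read_tsv_table(path: str) -> List[Dict[str, str]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise NetworkFormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise NetworkFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        rows.append(dict(zip(header, cells)))
    return rows


def _read_tsv(path: str) -> MetabolicNetwork:
    if not os.path.isdir(path):
        raise NetworkFormatError(f"{path}: TSV layout expects a directory")
    mets = [
        {
            "id": row["id"],
            "name": row.get("name", ""),
            "compartment": row.get("compartment", "c"),
            "formula": row.get("formula") or None,
            "phase_tag": int(row["phase_tag"]) if row.get("phase_tag") else None,
        }
        for row in _read_tsv_table(os.path.join(path, "metabolites.tsv"))
    ]
    stoich: Dict[str, Dict[str, float]] = {}
    for row in _read_tsv_table(os.path.join(path, "stoichiometry.tsv")):
        stoich.setdefault(row["reaction"], {})[row["metabolite"]] = float(
            row["coefficient"]
        )
    rxns = []
    objective = None
    for row in _read_tsv_table(os.path.join(path, "reactions.tsv")):
        rxns.append(
            {
                "id": row["id"],
                "name": row.get("name", ""),
                "stoichiometry": stoich.get(row["id"], {}),
                "lower_bound": float(row["lower_bound"]),
                "upper_bound": float(row["upper_bound"]),
                "subsystem": row.get("subsystem", ""),
                "role_tags": [t for t in row.get("role_tags", "").split(",") if t],
            }
        )
        if row.get("objective") == "1":
            objective = row["id"]
    return _network_from_dict(
        {"name": os.path.basename(path.rstrip("/")), "objective": objective,
         "metabolites": mets, "reactions": rxns},
        source=path,
    )


# ---------------------------------------------------------------------------
# SBML format (optional dependency)
# ---------------------------------------------------------------------------

_NOTE_KEYS = ("subsystem", "role_tags", "phase_tag")


def _write_sbml(network: MetabolicNetwork, path: str) -> None:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise NetworkFormatError(
            "SBML support requires the python-libsbml package"
        ) from exc

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sbml_id(network.name) or "model")
    model.setName(network.name)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = sorted({m.compartment for m in network.metabolites})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId("M_" + m.id)
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)
        if m.phase_tag is not None:
            _set_notes(sp, {"phase_tag": str(m.phase_tag)})

    # flux bound parameters
    def _bound_param(value: float) -> str:
        pid = "B_" + repr(value).replace("-", "m").replace(".", "p")
        if model.getParameter(pid) is None:
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId("R_" + r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for met_id, coeff in r.stoichiometry.items():
            if coeff < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies("M_" + met_id)
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(r.lower_bound))
        rplug.setUpperFluxBound(_bound_param(r.upper_bound))
        notes = {}
        if r.subsystem:
            notes["subsystem"] = r.subsystem
        if r.role_tags:
            notes["role_tags"] = ",".join(sorted(r.role_tags))
        if notes:
            _set_notes(rx, notes)

    if network.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + network.objective_id)
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, path)


def _set_notes(node, mapping: Mapping[str, str]) -> None:
    import libsbml

    body = "".join(f"<p>{k}: {v}</p>" for k, v in mapping.items())
    xhtml = (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )
    node.setNotes(libsbml.XMLNode.convertStringToXMLNode(
        f'<notes>{xhtml}</notes>'))


def _get_notes(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if not node.isSetNotes():
        return out
    text = node.getNotesString()
    for chunk in text.split("<p>")[1:]:
        body = chunk.split("</p>")[0]
        if ":" in body:
            key, val = body.split(":", 1)
            if key.strip() in _NOTE_KEYS:
                out[key.strip()] = val.strip()
    return out


def _sbml_id(raw: str) -> str:
    return "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in raw)


def _read_sbml(path: str) -> MetabolicNetwork:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise NetworkFormatError(
            "SBML support requires the python-libsbml package"
        ) from exc

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise NetworkFormatError(
            f"{path}:{err.getLine()}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkFormatError(f"{path}: no model element")

    def strip_prefix(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    mets = []
    for sp in model.getListOfSpecies():
        notes = _get_notes(sp)
        fplug = sp.getPlugin("fbc")
        formula = None
        if fplug is not None and fplug.isSetChemicalFormula():
            formula = fplug.getChemicalFormula()
        mets.append(
            {
                "id": strip_prefix(sp.getId(), "M_"),
                "name": sp.getName(),
                "compartment": sp.getCompartment(),
                "formula": formula,
                "phase_tag": int(notes["phase_tag"]) if "phase_tag" in notes else None,
            }
        )

    objective = None
    mplug = model.getPlugin("fbc")
    if mplug is not None and mplug.getActiveObjective() is not None:
        active = mplug.getActiveObjective()
        if active.getNumFluxObjectives() > 0:
            objective = strip_prefix(
                active.getFluxObjective(0).getReaction(), "R_"
            )

    rxns = []
    for rx in model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for ref in rx.getListOfReactants():
            stoich[strip_prefix(ref.getSpecies(), "M_")] = (
                stoich.get(strip_prefix(ref.getSpecies(), "M_"), 0.0)
                - ref.getStoichiometry()
            )
        for ref in rx.getListOfProducts():
            stoich[strip_prefix(ref.getSpecies(), "M_")] = (
                stoich.get(strip_prefix(ref.getSpecies(), "M_"), 0.0)
                + ref.getStoichiometry()
            )
        rplug = rx.getPlugin("fbc")
        lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
        ub = DEFAULT_BOUND
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = model.getParameter(rplug.getLowerFluxBound())
                if p is not None:
                    lb = p.getValue()
            if rplug.isSetUpperFluxBound():
                p = model.getParameter(rplug.getUpperFluxBound())
                if p is not None:
                    ub = p.getValue()
        notes = _get_notes(rx)
        rxns.append(
            {
                "id": strip_prefix(rx.getId(), "R_"),
                "name": rx.getName(),
                "stoichiometry": stoich,
                "lower_bound": lb,
                "upper_bound": ub,
                "subsystem": notes.get("subsystem", ""),
                "role_tags": [
                    t for t in notes.get("role_tags", "").split(",") if t
                ],
            }
        )
    return _network_from_dict(
        {
            "name": model.getName() or model.getId(),
            "objective": objective,
            "metabolites": mets,
            "reactions": rxns,
        },
        source=path,
    )


# ---------------------------------------------------------------------------
# public I/O entry points
# ---------------------------------------------------------------------------

_FORMATS = ("json", "tsv", "sbml")


def read_network(path: str, format: str = "json") -> MetabolicNetwork:
    """Read and validate a network from ``path`` in the named format."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "json":
        try:
            with open(path, encoding="utf-8") as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkFormatError(f"{path}:{exc.lineno}: {exc.msg}") from exc
        return _network_from_dict(data, source=path)
    if format == "tsv":
        return _read_tsv(path)
    return _read_sbml(path)


def write_network(network: MetabolicNetwork, path: str, format: str = "json") -> None:
    """Write ``network`` so that ``read_network`` round-trips structurally."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    require_valid(network)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_network_to_dict(network), fh, indent=1, ensure_ascii=False)
            fh.write("\n")
    elif format == "tsv":
        _write_tsv(network, path)
    else:
        _write_sbml(network, path)
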