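"""Data model for genome-scale metabolic networks.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (rows =
metabolites, columns = reactions), flux bounds ``lb``/``ub`` (mmol gDW^-1
h^-1; the biomass pseudo-reaction in h^-1), gene-protein-reaction (GPR)
boolean rules, and an objective reaction (typically the biomass objective
function, BOF).  Models are read from a versioned canonical JSON format or
imported from SBML Level 3 with the FBC package.

Conventions
-----------
* Exchange reactions (single-metabolite boundary reactions) use negative
  flux for uptake and positive flux for secretion.
* Gene knockouts close reactions (bounds set to 0) rather than deleting
  them, so reaction indices stay comparable across mutants.
* GPR strings use ``and`` / ``or`` (case-insensitive) with parentheses;
  ``and`` binds tighter than ``or``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

JSON_SCHEMA_VERSION = 1


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate id, bad bounds...)."""


class ModelParseError(ValueError):
    """A model file cannot be parsed into the canonical form."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRRule:
    """Boolean AND/OR tree over gene ids.

    ``node`` is one of ``("gene", id)``, ``("and", children)``,
    ``("or", children)`` or ``None`` for the empty rule (orphan reaction).
    An empty rule always evaluates True: orphan reactions are never disabled
    by gene knockouts.
    """

    node: Optional[tuple] = None

    def is_empty(self) -> bool:
        return self.node is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(n):
            if n is None:
                return
            kind = n[0]
            if kind == "gene":
                out.add(n[1])
            else:
                for c in n[1]:
                    walk(c)

        walk(self.node)
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str]) -> bool:
        """True iff the reaction remains catalysable after the knockout."""
        ko = set(knocked_out)

        def walk(n) -> bool:
            if n is None:
                return True
            kind = n[0]
            if kind == "gene":
                return n[1] not in ko
            if kind == "and":
                return all(walk(c) for c in n[1])
            return any(walk(c) for c in n[1])

        return walk(self.node)

    def to_string(self) -> str:
        def walk(n, parent=None) -> str:
            if n is None:
                return ""
            kind = n[0]
            if kind == "gene":
                return n[1]
            sep = f" {kind} "
            s = sep.join(walk(c, kind) for c in n[1])
            # parenthesise an OR nested under an AND ('and' binds tighter)
            if parent == "and" and kind == "or":
                return f"({s})"
            return s

        return walk(self.node)

    @staticmethod
    def parse(text: str) -> "GPRRule":
        return parse_gpr(text)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string; grammar: OR-list of AND-lists of atoms.

    ``and`` binds tighter than ``or``; both are case-insensitive.
    """
    if text is None or not text.strip():
        return GPRRule(None)
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return ("or", tuple(children))

    def parse_and():
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return ("and", tuple(children))

    def parse_atom():
        tok = peek()
        if tok is None:
            raise ModelParseError(f"GPR ended unexpectedly: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelParseError(f"unbalanced parenthesis in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return ("gene", take())

    node = parse_or()
    if pos != len(tokens):
        raise ModelParseError(f"trailing tokens in GPR: {text!r}")
    return GPRRule(node)


def evaluate_gpr(rule: GPRRule, knocked_out: Iterable[str]) -> bool:
    """AND = all children, OR = any child, leaf = gene not knocked out."""
    return rule.evaluate(knocked_out)


# ---------------------------------------------------------------------------
# Metabolites, reactions, model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None
    carbon: Optional[float] = None  # tracked carbon units, for balance checks

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment tag must be non-empty")


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GPRRule = field(default_factory=GPRRule)
    subsystem: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(
                f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")
        object.__setattr__(self, "lower_bound", float(self.lower_bound))
        object.__setattr__(self, "upper_bound", float(self.upper_bound))
        object.__setattr__(self, "stoichiometry",
                           {k: float(v) for k, v in self.stoichiometry.items()})

    @property
    def is_exchange(self) -> bool:
        """Single-metabolite boundary reaction (exchange, demand or sink)."""
        return len(self.stoichiometry) == 1

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


@dataclass(frozen=True)
class MetabolicModel:
    model_id: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    genes: Mapping[str, str]           # gene id -> gene name
    objective_reaction: str

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "genes", dict(self.genes))
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for kind, ids in (("metabolite", met_ids), ("reaction", rxn_ids),
                          ("gene", list(self.genes))):
            seen = set()
            for i in ids:
                if i in seen:
                    raise ModelValidationError(f"duplicate {kind} id {i!r}")
                seen.add(i)
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}")
            undeclared = r.gpr.genes() - gene_set
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses undeclared genes {sorted(undeclared)}")
        if self.objective_reaction not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model")

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def reaction_index(self, rxn_id: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rxn_id:
                return i
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    # -- LP ingredients ---------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with shape (|metabolites|, |reactions|)."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                data.append(float(coeff))
        return sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)))

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- derived models ---------------------------------------------------
    def with_reactions(self, new_reactions: Iterable[Reaction],
                       objective: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=self.metabolites,
            reactions=tuple(new_reactions),
            genes=self.genes,
            objective_reaction=objective or self.objective_reaction)

    def set_bounds(self, rxn_id: str, lb: float, ub: float) -> "MetabolicModel":
        return set_reaction_bounds(self, rxn_id, lb, ub)

    def set_objective(self, rxn_id: str) -> "MetabolicModel":
        if rxn_id not in set(self.reaction_ids):
            raise ModelValidationError(f"unknown reaction {rxn_id!r}")
        return MetabolicModel(self.model_id, self.metabolites, self.reactions,
                              self.genes, rxn_id)

    def knock_out_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicModel":
        """Close the listed reactions (bounds set to 0)."""
        targets = set(rxn_ids)
        unknown = targets - set(self.reaction_ids)
        if unknown:
            raise ModelValidationError(f"unknown reactions {sorted(unknown)}")
        new = [replace(r, lower_bound=0.0, upper_bound=0.0)
               if r.id in targets else r for r in self.reactions]
        return self.with_reactions(new)


def set_reaction_bounds(model: MetabolicModel, rxn_id: str,
                        lb: float, ub: float) -> MetabolicModel:
    """Derived model with one reaction's bounds replaced."""
    if lb > ub:
        raise ModelValidationError(
            f"reaction {rxn_id!r}: lower bound {lb} exceeds upper bound {ub}")
    idx = model.reaction_index(rxn_id)  # raises KeyError if unknown
    new = list(model.reactions)
    new[idx] = replace(new[idx], lower_bound=float(lb), upper_bound=float(ub))
    return model.with_reactions(new)


def apply_gene_knockout(model: MetabolicModel,
                        genes: Iterable[str]) -> MetabolicModel:
    """Close every reaction whose GPR evaluates False under the knockout.

    Orphan reactions (empty GPR) are never affected.  The input model is not
    mutated; a derived model is returned.
    """
    ko = set(genes)
    unknown = ko - set(model.genes)
    if unknown:
        raise ModelValidationError(f"unknown genes {sorted(unknown)}")
    closed = [r.id for r in model.reactions
              if not r.gpr.is_empty() and not r.gpr.evaluate(ko)]
    if not closed:
        return model
    return model.knock_out_reactions(closed)


# ---------------------------------------------------------------------------
# Canonical JSON I/O
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "model_id": model.model_id,
        "metabolites": [
            {k: v for k, v in {
                "id": m.id, "name": m.name, "compartment": m.compartment,
                "formula": m.formula, "charge": m.charge, "carbon": m.carbon,
            }.items() if v is not None}
            for m in model.metabolites],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
             "lb": r.lower_bound, "ub": r.upper_bound,
             "gpr": r.gpr.to_string(), "subsystem": r.subsystem}
            for r in model.reactions],
        "genes": [{"id": g, "name": n} for g, n in model.genes.items()],
        "objective": model.objective_reaction,
    }


def model_from_dict(doc: dict) -> MetabolicModel:
    try:
        mets = []
        for m in doc["metabolites"]:
            mets.append(Metabolite(
                id=m["id"], name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"), charge=m.get("charge"),
                carbon=m.get("carbon")))
        rxns = []
        for r in doc["reactions"]:
            rxns.append(Reaction(
                id=r["id"], name=r.get("name", ""),
                stoichiometry={k: float(v)
                               for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lb"]), upper_bound=float(r["ub"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", "")))
        genes = {g["id"]: g.get("name", "") for g in doc.get("genes", [])}
        return MetabolicModel(
            model_id=doc.get("model_id", "model"),
            metabolites=mets, reactions=rxns, genes=genes,
            objective_reaction=doc["objective"])
    except KeyError as exc:
        raise ModelParseError(f"missing required field {exc.args[0]!r}") from exc


def write_model_json(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelParseError("top level of a model file must be an object")
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# SBML Level 3 / FBC import
# ---------------------------------------------------------------------------

# SBML SIds must start with a letter or underscore; the conventional
# namespace prefixes (R_/M_/G_) are added on export and stripped on import.
def _strip_sid(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def import_sbml_fbc(path) -> MetabolicModel:
    """Import an SBML L3 model with the FBC package (bounds, GPRs, objective)."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorLog().toString()
        raise ModelParseError(f"SBML parse failure in {path}: {err}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelParseError(f"{path}: FBC package not used")

    params = {p.getId(): p.getValue()
              for p in (sbml_model.getParameter(i)
                        for i in range(sbml_model.getNumParameters()))}

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        fbc_sp = sp.getPlugin("fbc")
        formula = fbc_sp.getChemicalFormula() if fbc_sp is not None and \
            fbc_sp.isSetChemicalFormula() else None
        charge = fbc_sp.getCharge() if fbc_sp is not None and \
            fbc_sp.isSetCharge() else None
        mets.append(Metabolite(id=_strip_sid(sp.getId(), "M_"),
                               name=sp.getName(),
                               compartment=sp.getCompartment() or "c",
                               formula=formula, charge=charge))
    met_ids = {m.id for m in mets}

    genes = {}
    for i in range(fbc.getNumGeneProducts()):
        gp = fbc.getGeneProduct(i)
        gid = _strip_sid(gp.getId(), "G_")
        genes[gid] = gp.getName() or gp.getLabel() or gid

    def assoc_to_node(assoc):
        if assoc is None:
            return None
        if assoc.isGeneProductRef():
            return ("gene", _strip_sid(assoc.getGeneProduct(), "G_"))
        kids = tuple(assoc_to_node(assoc.getAssociation(i))
                     for i in range(assoc.getNumAssociations()))
        if assoc.isFbcAnd():
            return ("and", kids)
        if assoc.isFbcOr():
            return ("or", kids)
        raise ModelParseError("unknown gene association node type")

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        fbc_rx = rx.getPlugin("fbc")
        if fbc_rx is None or not (fbc_rx.isSetLowerFluxBound()
                                  and fbc_rx.isSetUpperFluxBound()):
            raise ModelParseError(
                f"reaction {rx.getId()!r}: missing FBC flux bounds")
        lb = params[fbc_rx.getLowerFluxBound()]
        ub = params[fbc_rx.getUpperFluxBound()]
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            sid = _strip_sid(sr.getSpecies(), "M_")
            if sid in met_ids:
                stoich[sid] = stoich.get(sid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            sid = _strip_sid(sr.getSpecies(), "M_")
            if sid in met_ids:
                stoich[sid] = stoich.get(sid, 0.0) + sr.getStoichiometry()
        gpa = fbc_rx.getGeneProductAssociation()
        try:
            node = assoc_to_node(gpa.getAssociation()) if gpa is not None else None
        except ModelParseError as exc:
            raise ModelParseError(
                f"reaction {rx.getId()!r}: unparseable gene association") from exc
        rxns.append(Reaction(id=_strip_sid(rx.getId(), "R_"),
                             name=rx.getName(),
                             stoichiometry=stoich, lower_bound=lb,
                             upper_bound=ub, gpr=GPRRule(node)))

    objective = None
    active = fbc.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective = _strip_sid(active.getFluxObjective(0).getReaction(), "R_")
    if objective is None:
        raise ModelParseError(f"{path}: no active objective")

    return MetabolicModel(model_id=sbml_model.getId() or "sbml_model",
                          metabolites=mets, reactions=rxns, genes=genes,
                          objective_reaction=objective)


def export_sbml_fbc(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3 + FBC v2 (used for round-trip testing)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.model_id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    comps = sorted({m.compartment for m in model.metabolites})
    for cid in comps:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(f"M_{m.id}")
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        fbc_sp = sp.getPlugin("fbc")
        if m.formula is not None:
            fbc_sp.setChemicalFormula(m.formula)
        if m.charge is not None:
            fbc_sp.setCharge(int(m.charge))

    for g, name in model.genes.items():
        gp = fbc.createGeneProduct()
        gp.setId(f"G_{g}")
        gp.setName(name)
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def build_assoc(parent, node):
        if node[0] == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(f"G_{node[1]}")
        elif node[0] == "and":
            grp = parent.createAnd()
            for c in node[1]:
                build_assoc(grp, c)
        else:
            grp = parent.createOr()
            for c in node[1]:
                build_assoc(grp, c)

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(f"R_{r.id}")
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met, coeff in r.stoichiometry.items():
            if coeff < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coeff)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coeff)
            sr.setSpecies(f"M_{met}")
            sr.setConstant(True)
        fbc_rx = rx.getPlugin("fbc")
        fbc_rx.setLowerFluxBound(bound_param(r.lower_bound))
        fbc_rx.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty():
            gpa = fbc_rx.createGeneProductAssociation()
            build_assoc(gpa, r.gpr.node)

    obj = fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(f"R_{model.objective_reaction}")
    fo.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Structural checks used by fixtures and the generator
# ---------------------------------------------------------------------------

def carbon_imbalances(model: MetabolicModel, tol: float = 1e-9) -> dict[str, float]:
    """Signed carbon-unit imbalance per non-exchange reaction.

    Uses each metabolite's ``carbon`` annotation; reactions touching any
    unannotated metabolite are skipped.  Exchange/demand/sink reactions
    (single-metabolite) are boundary flows and excluded by definition.
    """
    carbon = {m.id: m.carbon for m in model.metabolites}
    bad = {}
    for r in model.reactions:
        if r.is_exchange:
            continue
        if any(carbon[m] is None for m in r.stoichiometry):
            continue
        total = sum(coeff * carbon[m] for m, coeff in r.stoichiometry.items())
        if not math.isclose(total, 0.0, abs_tol=tol):
            bad[r.id] = total
    return bad


def models_structurally_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    return model_to_dict(a) == model_to_dict(b)
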