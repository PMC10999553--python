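"""Model readers/writers (COBRA-JSON, SBML L3 + FBC) and tabular inputs.

COBRA-JSON is handled directly (it is plain JSON with a fixed key set);
SBML goes through libSBML with the FBC package for bounds, objectives and
gene-product associations.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from .gpr import parse_gpr
from .model import (
    DEFAULT_BOUND,
    MediaCondition,
    Metabolite,
    MetabolicModel,
    Reaction,
    infer_reaction_class,
)

__all__ = [
    "load_model",
    "write_model",
    "load_json_model",
    "write_json_model",
    "load_sbml_model",
    "write_sbml_model",
    "read_media_tsv",
]


def load_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load a model, inferring the dialect from the suffix if not given."""
    path = Path(path)
    if dialect is None:
        dialect = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    if dialect == "cobra-json":
        return load_json_model(path)
    if dialect == "sbml":
        return load_sbml_model(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    if dialect == "cobra-json":
        write_json_model(model, path)
    elif dialect == "sbml":
        write_sbml_model(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# COBRA-JSON
# ---------------------------------------------------------------------------

def load_json_model(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    model = MetabolicModel(name=doc.get("id", Path(path).stem))
    for m in doc.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=m.get("formula") or "",
                charge=m.get("charge"),
                compartment=m.get("compartment", ""),
                annotation=m.get("annotation", {}) or {},
            )
        )
    declared_genes = {g["id"] for g in doc.get("genes", [])}
    model.genes |= declared_genes
    objective_id = None
    objective_coef = 0.0
    for r in doc.get("reactions", []):
        gpr = parse_gpr(r.get("gene_reaction_rule", ""))
        unregistered = gpr.genes() - declared_genes
        if unregistered:
            warnings.warn(
                f"reaction {r['id']}: GPR genes {sorted(unregistered)} absent from the "
                "gene list; auto-registering",
                stacklevel=2,
            )
        coef = float(r.get("objective_coefficient", 0) or 0)
        is_objective = coef != 0
        if is_objective and (objective_id is None or coef > objective_coef):
            objective_id, objective_coef = r["id"], coef
        rxn_class = infer_reaction_class(
            r["id"],
            r.get("metabolites", {}),
            explicit=(r.get("annotation", {}) or {}).get("reaction_class")
            or r.get("reaction_class"),
            objective=is_objective,
        )
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=gpr,
                subsystem=r.get("subsystem", "") or "",
                reaction_class=rxn_class,
                annotation=r.get("annotation", {}) or {},
            )
        )
    if objective_id is None:
        raise ValueError(f"{path}: no reaction carries a nonzero objective_coefficient")
    model.objective_id = objective_id
    model.validate()
    return model


def write_json_model(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "id": model.name,
        "version": "1",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
                "annotation": m.annotation,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
                "annotation": {**r.annotation, "reaction_class": r.reaction_class},
            }
            for r in model.reactions.values()
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def _sbml_safe(sid: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _gpr_to_fbc(node, fbc_assoc_parent):
    """Recursively build an FBC association tree from a GPR tree."""
    from .gpr import GPRLeaf, GPRNode

    if isinstance(node, GPRLeaf):
        ref = fbc_assoc_parent.createGeneProductRef()
        ref.setGeneProduct(_sbml_safe("G_" + node.gene))
    elif isinstance(node, GPRNode):
        sub = (
            fbc_assoc_parent.createAnd()
            if node.op == "and"
            else fbc_assoc_parent.createOr()
        )
        for child in node.children:
            _gpr_to_fbc(child, sub)


def write_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_safe(model.name or "model"))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = {m.compartment or "c" for m in model.metabolites.values()}
    for comp in sorted(compartments):
        c = sbml_model.createCompartment()
        c.setId(_sbml_safe(comp))
        c.setConstant(True)

    met_sid = {}
    for m in model.metabolites.values():
        s = sbml_model.createSpecies()
        sid = _sbml_safe("M_" + m.id)
        met_sid[m.id] = sid
        s.setId(sid)
        s.setName(m.name or m.id)
        s.setCompartment(_sbml_safe(m.compartment or "c"))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        if m.formula:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_safe("G_" + g))
        gp.setLabel(g)

    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = _sbml_safe(f"b_{len(bound_params)}")
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions.values():
        rx = sbml_model.createReaction()
        rid = _sbml_safe("R_" + r.id)
        rx.setId(rid)
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met, coef in r.stoichiometry.items():
            if coef < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(met_sid[met])
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            _gpr_to_fbc(r.gpr.root, assoc)
        # stash class/subsystem where COBRA tools expect notes
        notes = (
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            f"<p>SUBSYSTEM: {r.subsystem}</p><p>CLASS: {r.reaction_class}</p></body>"
        )
        rx.setNotes(notes)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    if model.objective_id is not None:
        fo = objective.createFluxObjective()
        fo.setReaction(_sbml_safe("R_" + model.objective_id))
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, str(path))


def _fbc_to_gpr_string(assoc) -> str:
    import libsbml

    if assoc is None:
        return ""

    def walk(node):
        if node.isGeneProductRef():
            gid = node.getGeneProduct()
            return gid[2:] if gid.startswith("G_") else gid
        parts = [walk(node.getAssociation(i)) for i in range(node.getNumAssociations())]
        joiner = " and " if node.isFbcAnd() else " or "
        return "(" + joiner.join(parts) + ")"

    return walk(assoc.getAssociation())


def load_sbml_model(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise IOError(f"{path}: libSBML reported errors: "
                      f"{doc.getErrorLog().toString()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise IOError(f"{path}: no SBML model element")
    mplug = sbml_model.getPlugin("fbc")
    model = MetabolicModel(name=sbml_model.getId())

    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        splug = s.getPlugin("fbc")
        mid = s.getId()
        if mid.startswith("M_"):
            mid = mid[2:]
        charge = None
        formula = ""
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                id=mid,
                name=s.getName() or mid,
                formula=formula,
                charge=charge,
                compartment=s.getCompartment(),
            )
        )

    gene_label = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            gene_label[gp.getId()] = label
            model.genes.add(label)

    objective_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            rid = obj.getFluxObjective(0).getReaction()
            objective_id = rid[2:] if rid.startswith("R_") else rid

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()
        if rid.startswith("R_"):
            rid = rid[2:]
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            mid = sr.getSpecies()
            mid = mid[2:] if mid.startswith("M_") else mid
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            mid = sr.getSpecies()
            mid = mid[2:] if mid.startswith("M_") else mid
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr_text = ""
        if rplug is not None:
            lb_param = sbml_model.getParameter(rplug.getLowerFluxBound())
            ub_param = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lb_param is not None:
                lb = lb_param.getValue()
            if ub_param is not None:
                ub = ub_param.getValue()
            raw = _fbc_to_gpr_string(rplug.getGeneProductAssociation())
            # rewrite FBC gene-product ids back to labels
            for gid, label in gene_label.items():
                stripped = gid[2:] if gid.startswith("G_") else gid
                raw = raw.replace(stripped, label) if stripped != label else raw
            gpr_text = raw
        subsystem, explicit_class = "", None
        if rx.isSetNotes():
            notes = rx.getNotesString()
            for line in notes.splitlines():
                if "SUBSYSTEM:" in line:
                    subsystem = line.split("SUBSYSTEM:", 1)[1].split("<")[0].strip()
                if "CLASS:" in line:
                    explicit_class = line.split("CLASS:", 1)[1].split("<")[0].strip()
        model.add_reaction(
            Reaction(
                id=rid,
                name=rx.getName() or rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(gpr_text),
                subsystem=subsystem,
                reaction_class=infer_reaction_class(
                    rid, stoich, explicit=explicit_class, objective=(rid == objective_id)
                ),
            )
        )

    if objective_id is None:
        raise ValueError(f"{path}: SBML file declares no active flux objective")
    model.objective_id = objective_id
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_media_tsv(path: str | Path, label: str = "custom") -> MediaCondition:
    """Read a two-column media TSV (exchange_id, uptake_rate); '#' comments."""
    uptakes: dict[str, float] = {}
    with open(path) as fh:
        header_seen = False
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed media line {raw!r}")
            if not header_seen:
                header_seen = True
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header row
            uptakes[parts[0]] = float(parts[1])
    return MediaCondition(uptakes=uptakes, label=label)
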