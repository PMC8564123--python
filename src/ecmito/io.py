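"""Readers and writers for the toolkit JSON dialect and SBML Level 3 + fbc.

JSON is the canonical format: it carries every field of the in-memory model
losslessly (kcat pairs, pseudo flags, compartment kinds, protein records).
SBML output is Level 3 Version 1 with the fbc v2 package for charges,
formulas and flux bounds; toolkit-specific fields ride in structured notes
(`key: json-value` paragraphs) so a round-trip through SBML is also lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml

from .model_core import (
    Compartment,
    FormatError,
    Metabolite,
    Model,
    ProteinRecord,
    Reaction,
    ReferenceError_,
    ValidationError,
    validate_model,
)

JSON_SCHEMA_VERSION = "1"
_BIG = 1000.0


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "compartments": [
            {"id": c.id, "name": c.name, "kind": c.kind}
            for c in model.compartments.values()
        ],
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "charge": m.charge,
                "formula": m.formula,
                "is_pseudo": m.is_pseudo,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "enzymes": [[p, k] for p, k in r.enzymes],
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
                "is_transport": r.is_transport,
                "is_biomass": r.is_biomass,
                "annotations": r.annotations,
            }
            for r in model.reactions.values()
        ],
        "proteins": [
            {
                "id": p.id,
                "sequence": p.sequence,
                "mw": p.mw,
                "compartment": p.compartment,
                "presequence_length": p.presequence_length,
                "tm_segments": [[s, e] for s, e in p.tm_segments],
                "cysteine_motif": p.cysteine_motif,
                "is_carrier": p.is_carrier,
                "abundance": p.abundance,
                "annotations": p.annotations,
            }
            for p in model.proteins.values()
        ],
        "annotations": model.annotations,
    }


def model_from_dict(data: dict) -> Model:
    try:
        model = Model(id=data.get("id", "model"), annotations=data.get("annotations", {}))
        for c in data["compartments"]:
            model.add_compartment(Compartment(id=c["id"], name=c.get("name", ""), kind=c["kind"]))
        for m in data["metabolites"]:
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m["compartment"],
                    charge=m.get("charge"),
                    formula=m.get("formula"),
                    is_pseudo=m.get("is_pseudo", False),
                )
            )
        for p in data.get("proteins", []):
            model.add_protein(
                ProteinRecord(
                    id=p["id"],
                    sequence=p.get("sequence", ""),
                    mw=p.get("mw", 0.0),
                    compartment=p.get("compartment", "cytosol"),
                    presequence_length=p.get("presequence_length", 0),
                    tm_segments=[tuple(seg) for seg in p.get("tm_segments", [])],
                    cysteine_motif=p.get("cysteine_motif"),
                    is_carrier=p.get("is_carrier", False),
                    abundance=p.get("abundance"),
                    annotations=p.get("annotations", {}),
                )
            )
        for r in data["reactions"]:
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", _BIG)),
                    enzymes=[(e[0], float(e[1])) for e in r.get("enzymes", [])],
                    subsystem=r.get("subsystem", ""),
                    is_exchange=r.get("is_exchange", False),
                    is_transport=r.get("is_transport", False),
                    is_biomass=r.get("is_biomass", False),
                    annotations=r.get("annotations", {}),
                )
            )
    except ReferenceError_:
        raise
    except KeyError as exc:
        raise FormatError(f"missing required field {exc} in model JSON") from exc
    return model


# ---------------------------------------------------------------------------
# SBML via libsbml
# ---------------------------------------------------------------------------

def _notes_from_pairs(pairs: dict) -> str:
    body = "".join(
        f"<p>{key}: {json.dumps(value)}</p>" for key, value in pairs.items()
    )
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )


def _pairs_from_notes(node) -> dict:
    out: dict = {}
    if node is None:
        return out
    text = libsbml.XMLNode.convertXMLNodeToString(node)
    import re

    for match in re.finditer(r"<p>\s*([^:<]+):\s*(.*?)</p>", text, re.S):
        key = match.group(1).strip()
        raw = match.group(2).strip()
        # libsbml escapes quotes inside notes text
        raw = raw.replace("&quot;", '"').replace("&amp;", "&").replace("&lt;", "<").replace("&gt;", ">")
        try:
            out[key] = json.loads(raw)
        except json.JSONDecodeError:
            out[key] = raw
    return out


def write_sbml(model: Model, path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)
    if model.annotations:
        sbml_model.setNotes(_notes_from_pairs({"annotations": model.annotations}))

    for comp in model.compartments.values():
        c = sbml_model.createCompartment()
        c.setId(comp.id)
        c.setName(comp.name)
        c.setConstant(True)
        c.setNotes(_notes_from_pairs({"kind": comp.kind}))

    for met in model.metabolites.values():
        s = sbml_model.createSpecies()
        s.setId(met.id)
        s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula:
            splug.setChemicalFormula(met.formula)
        notes = {"is_pseudo": met.is_pseudo, "has_charge": met.charge is not None}
        s.setNotes(_notes_from_pairs(notes))

    bounds_seen: dict = {}

    def _bound_param(value: float) -> str:
        key = repr(value)
        if key not in bounds_seen:
            pid = f"bnd_{len(bounds_seen)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[key] = pid
        return bounds_seen[key]

    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        for mid, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = r.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = r.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(mid)
            ref.setConstant(True)
        notes = {
            "enzymes": [[p, k] for p, k in rxn.enzymes],
            "subsystem": rxn.subsystem,
            "is_exchange": rxn.is_exchange,
            "is_transport": rxn.is_transport,
            "is_biomass": rxn.is_biomass,
            "annotations": rxn.annotations,
        }
        r.setNotes(_notes_from_pairs(notes))

    if model.proteins:
        # protein records have no SBML home; carried in the model notes
        payload = model_to_dict(model)["proteins"]
        notes = _pairs_from_notes(sbml_model.getNotes())
        notes["annotations"] = model.annotations
        notes["proteins"] = payload
        sbml_model.setNotes(_notes_from_pairs(notes))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path) -> Model:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"SBML parse failure: {err.getMessage() if err else 'unknown error'}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML file contains no model")

    model_notes = _pairs_from_notes(sbml_model.getNotes())
    model = Model(id=sbml_model.getId() or "model", annotations=model_notes.get("annotations", {}))

    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        notes = _pairs_from_notes(c.getNotes())
        model.add_compartment(
            Compartment(id=c.getId(), name=c.getName(), kind=notes.get("kind", "cytosol"))
        )
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        splug = s.getPlugin("fbc")
        notes = _pairs_from_notes(s.getNotes())
        charge = None
        if splug is not None and splug.isSetCharge() and notes.get("has_charge", True):
            charge = splug.getCharge()
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                id=s.getId(),
                name=s.getName(),
                compartment=s.getCompartment(),
                charge=charge,
                formula=formula or None,
                is_pseudo=bool(notes.get("is_pseudo", False)),
            )
        )
    for p in model_notes.get("proteins", []):
        model.add_protein(
            ProteinRecord(
                id=p["id"],
                sequence=p.get("sequence", ""),
                mw=p.get("mw", 0.0),
                compartment=p.get("compartment", "cytosol"),
                presequence_length=p.get("presequence_length", 0),
                tm_segments=[tuple(seg) for seg in p.get("tm_segments", [])],
                cysteine_motif=p.get("cysteine_motif"),
                is_carrier=p.get("is_carrier", False),
                abundance=p.get("abundance"),
                annotations=p.get("annotations", {}),
            )
        )
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rplug = r.getPlugin("fbc")
        notes = _pairs_from_notes(r.getNotes())
        stoich: dict = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb, ub = -_BIG, _BIG
        if rplug is not None:
            lb_par = sbml_model.getParameter(rplug.getLowerFluxBound())
            ub_par = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lb_par is not None:
                lb = lb_par.getValue()
            if ub_par is not None:
                ub = ub_par.getValue()
        model.add_reaction(
            Reaction(
                id=r.getId(),
                name=r.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                enzymes=[(e[0], float(e[1])) for e in notes.get("enzymes", [])],
                subsystem=notes.get("subsystem", "") or "",
                is_exchange=bool(notes.get("is_exchange", False)),
                is_transport=bool(notes.get("is_transport", False)),
                is_biomass=bool(notes.get("is_biomass", False)),
                annotations=notes.get("annotations", {}),
            )
        )
    return model


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_model(path, format: str = None) -> Model:
    """Read a model from ``path`` (``json`` or ``sbml``; inferred from suffix)."""
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid JSON: {path} ({exc})") from exc
        return model_from_dict(data)
    if fmt == "sbml":
        return read_sbml(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_model(model: Model, path, format: str = None) -> None:
    """Write ``model`` to ``path``; validates structure before touching the file."""
    violations = validate_model(model)
    if violations:
        raise ValidationError(
            "refusing to write invalid model: " + "; ".join(violations[:5])
        )
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json")
    if fmt == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=False))
    elif fmt == "sbml":
        write_sbml(model, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
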