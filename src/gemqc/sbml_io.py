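"""Read and write reconstructions in two SBML dialects.

Supported dialects:

``fbc3``
    SBML Level 3 Version 1 with the Flux Balance Constraints (fbc v2)
    package: bounds as global parameters, GPRs as
    ``geneProductAssociation`` trees, an active objective.
``cobra_l2``
    SBML Level 2 Version 4 in the COBRA Toolbox convention: bounds as
    ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters, GPRs as
    ``GENE_ASSOCIATION:`` notes lines, objective via
    ``OBJECTIVE_COEFFICIENT``.
``reconstruction_only``
    Level 3 + fbc gene products but no objective and no explicit bounds;
    bounds are inferred from the ``reversible`` flag on read.

MIRIAM-style annotations (controlled-vocabulary CVTerms with
identifiers.org / ``urn:miriam`` URIs) are parsed for PubMed references
on reactions and database cross-references on species and gene products.
Parsing the older COBRA ``Notes``-field annotations is opt-in via
``notes_fallback``.

Unbounded fluxes are serialized as +/-1000 (the de-facto cap); on read,
any bound at or beyond the cap is restored to a true infinity.
"""

from __future__ import annotations

import math
import os
import re
from typing import Iterable

import libsbml
import pandas as pd

from .errors import CapabilityError, FormatError, ModelValidationError
from .model import (
    DEFAULT_FLUX_CAP,
    GPR_EMPTY,
    Gene,
    GeneAssociation,
    GprAnd,
    GprLeaf,
    GprOr,
    Metabolite,
    Model,
    Reaction,
    parse_gpr,
)

DIALECTS = ("fbc3", "cobra_l2", "reconstruction_only")

_FBC_URI_RE = re.compile(r"fbc/version\d+$")


# ---------------------------------------------------------------------------
# annotation helpers
# ---------------------------------------------------------------------------

def _resource_to_ref(uri: str) -> tuple[str, str] | None:
    """Split a MIRIAM resource URI into a (database, accession) pair."""
    uri = uri.strip()
    if uri.startswith("urn:miriam:"):
        rest = uri[len("urn:miriam:"):]
        db, _, acc = rest.partition(":")
        if db and acc:
            return (db.lower(), acc)
    m = re.match(r"https?://(?:www\.)?identifiers\.org/(.+)$", uri)
    if m:
        rest = m.group(1)
        if "/" in rest:
            db, _, acc = rest.partition("/")
            # new-style identifiers.org may embed the prefix in the accession
            if ":" in acc and not acc.startswith("CHEBI:"):
                maybe_db, _, maybe_acc = acc.partition(":")
                if maybe_db.lower() == db.lower():
                    acc = maybe_acc
            return (db.lower(), acc)
        if ":" in rest:
            db, _, acc = rest.partition(":")
            return (db.lower(), acc)
    return None


def _collect_refs(sbase: libsbml.SBase) -> list[tuple[str, str]]:
    refs: list[tuple[str, str]] = []
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for j in range(term.getNumResources()):
            ref = _resource_to_ref(term.getResourceURI(j))
            if ref is not None:
                refs.append(ref)
    return refs


def _set_refs(sbase: libsbml.SBase, refs: Iterable[tuple[str, str]],
              qualifier: int = libsbml.BQB_IS) -> None:
    refs = list(refs)
    if not refs:
        return
    if not sbase.isSetMetaId():
        sbase.setMetaId(f"meta_{sbase.getId()}")
    term = libsbml.CVTerm()
    term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
    term.setBiologicalQualifierType(qualifier)
    for db, acc in refs:
        term.addResource(f"http://identifiers.org/{db}/{acc}")
    sbase.addCVTerm(term)


_NOTES_KV = re.compile(r"^\s*([A-Za-z_ ]+?)\s*:\s*(.*?)\s*$")


def _parse_notes(sbase: libsbml.SBase) -> dict[str, str]:
    """Extract ``KEY: value`` pairs from a COBRA-style notes body."""
    if not sbase.isSetNotes():
        return {}
    text = sbase.getNotesString()
    # strip XML tags, keep line structure from <p>/<html:p> elements
    text = re.sub(r"</(?:\w+:)?p>", "\n", text)
    text = re.sub(r"<[^>]+>", "", text)
    out: dict[str, str] = {}
    for line in text.splitlines():
        m = _NOTES_KV.match(line)
        if m:
            out[m.group(1).strip().upper().replace(" ", "_")] = m.group(2)
    return out


# ---------------------------------------------------------------------------
# GPR conversion (fbc association tree <-> gemqc tree)
# ---------------------------------------------------------------------------

def _from_fbc_association(assoc: libsbml.FbcAssociation) -> GeneAssociation:
    if assoc is None:
        return GPR_EMPTY
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        gp = assoc.getGeneProduct()
        return GprLeaf(gp)
    if code == libsbml.SBML_FBC_AND:
        kids = [_from_fbc_association(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())]
        return kids[0] if len(kids) == 1 else GprAnd(kids)
    if code == libsbml.SBML_FBC_OR:
        kids = [_from_fbc_association(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())]
        return kids[0] if len(kids) == 1 else GprOr(kids)
    raise FormatError(f"unsupported fbc association element (type code {code})")


def _to_fbc_association(gpr: GeneAssociation, parent) -> None:
    if isinstance(gpr, GprLeaf):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gpr.gene_id)
    elif isinstance(gpr, GprAnd):
        node = parent.createAnd()
        for child in gpr.children:
            _to_fbc_association(child, node)
    elif isinstance(gpr, GprOr):
        node = parent.createOr()
        for child in gpr.children:
            _to_fbc_association(child, node)
    else:  # pragma: no cover - EMPTY handled by caller
        raise ValueError("cannot serialize EMPTY association")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def detect_dialect(doc: libsbml.SBMLDocument) -> str:
    model = doc.getModel()
    if doc.getLevel() == 2:
        return "cobra_l2"
    fbc = model.getPlugin("fbc") if model is not None else None
    if fbc is not None:
        active = fbc.getActiveObjective()
        if active is not None or fbc.getNumObjectives() > 0:
            return "fbc3"
        return "reconstruction_only"
    return "reconstruction_only"


def _restore_inf(value: float, cap: float | None) -> float:
    if cap is None:
        return value
    if value >= cap:
        return math.inf
    if value <= -cap:
        return -math.inf
    return value


def read_model(path: str, dialect: str | None = None, *,
               cap: float | None = DEFAULT_FLUX_CAP,
               notes_fallback: bool = False) -> Model:
    """Parse an SBML file into a :class:`~gemqc.model.Model`.

    Parameters
    ----------
    path:
        SBML file to read.
    dialect:
        Force a dialect; auto-detected from the document when omitted.
    cap:
        Bounds with ``|b| >= cap`` are restored to true infinities
        (pass ``None`` to keep serialized values verbatim).
    notes_fallback:
        Also mine COBRA-style ``Notes`` fields for annotations when
        controlled-vocabulary terms are absent.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise FormatError(
                f"SBML parse error in {path} (line {err.getLine()}): "
                f"{err.getMessage().strip()}"
            )
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path}: document contains no <model> element")
    if dialect is None:
        dialect = detect_dialect(doc)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")

    model = Model(id=sm.getId() or "model", name=sm.getName() or "",
                  dialect=dialect)

    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    boundary: set[str] = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        name = sp.getName() or sp.getId()
        model.add_metabolite(Metabolite(
            id=sp.getId(),
            name=name,
            compartment_id=sp.getCompartment() or "",
            external_refs=_collect_refs(sp),
            is_biomass="biomass" in name.lower() or "biomass" in sp.getId().lower(),
        ))

    fbc = sm.getPlugin("fbc")
    if dialect == "fbc3" and fbc is None:
        raise FormatError(f"{path}: fbc dialect requested but no fbc package present")

    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            model.add_gene(Gene(
                id=gp.getLabel() or gp.getId(),
                standard_name=gp.getName() or "",
                external_refs=_collect_refs(gp),
            ))
    gp_id_to_label = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gp_id_to_label[gp.getId()] = gp.getLabel() or gp.getId()

    def relabel(gpr: GeneAssociation) -> GeneAssociation:
        if isinstance(gpr, GprLeaf):
            return GprLeaf(gp_id_to_label.get(gpr.gene_id, gpr.gene_id))
        if isinstance(gpr, (GprAnd, GprOr)):
            return type(gpr)([relabel(c) for c in gpr.children])
        return gpr

    # fbc v1 encodes bounds as a listOfFluxBounds instead of per-reaction
    # parameter references; collect them up front.
    v1_bounds: dict[str, list[float]] = {}
    if fbc is not None and hasattr(fbc, "getNumFluxBounds"):
        for i in range(fbc.getNumFluxBounds()):
            fb = fbc.getFluxBound(i)
            entry = v1_bounds.setdefault(fb.getReaction(), [-math.inf, math.inf])
            op = fb.getOperation()
            if op in ("greaterEqual", "equal"):
                entry[0] = fb.getValue()
            if op in ("lessEqual", "equal"):
                entry[1] = fb.getValue()

    objective_id = None
    if fbc is not None:
        active = fbc.getActiveObjective()
        if active is None and fbc.getNumObjectives() > 0:
            active = fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            flux_obj = active.getFluxObjective(0)
            objective_id = flux_obj.getReaction()
            model.objective_sense = (
                "minimize" if active.getType() == libsbml.OBJECTIVE_TYPE_MINIMIZE
                else "maximize"
            )

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        if rid in v1_bounds:
            lb, ub = v1_bounds[rid]
        else:
            lb, ub = _read_bounds(sr, sm, dialect, rid)
        lb, ub = _restore_inf(lb, cap), _restore_inf(ub, cap)

        gpr: GeneAssociation = GPR_EMPTY
        rfbc = sr.getPlugin("fbc")
        if rfbc is not None and hasattr(rfbc, "isSetGeneProductAssociation") \
                and rfbc.isSetGeneProductAssociation():
            gpa = rfbc.getGeneProductAssociation()
            gpr = relabel(_from_fbc_association(gpa.getAssociation()))
        else:
            # both dialects may carry the textual grammar in a notes field
            notes = _parse_notes(sr)
            gene_text = notes.get("GENE_ASSOCIATION", "")
            if gene_text:
                gpr = parse_gpr(gene_text)

        pubmed = [acc for db, acc in _collect_refs(sr) if db == "pubmed"]
        if not pubmed and notes_fallback:
            notes = _parse_notes(sr)
            auth = notes.get("AUTHORS", "") + " " + notes.get("REFERENCES", "")
            pubmed = re.findall(r"PMID:\s*(\d+)", auth)

        model.add_reaction(Reaction(
            id=rid,
            name=sr.getName() or rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            pubmed_refs=pubmed,
            is_exchange=len(stoich) == 1,
        ))

        if dialect == "cobra_l2" and objective_id is None:
            if _objective_coefficient(sr) not in (0.0, None):
                objective_id = rid

    # genes referenced only in notes-style GPRs (cobra_l2)
    for rxn in model.reactions.values():
        for g in sorted(rxn.gpr.genes()):
            if g not in model.genes:
                model.add_gene(Gene(id=g))

    if objective_id is not None:
        model.objective_reaction_id = objective_id
    model.validate()
    return model


def _objective_coefficient(sr) -> float | None:
    kl = sr.getKineticLaw()
    if kl is None:
        return None
    p = kl.getParameter("OBJECTIVE_COEFFICIENT")
    return p.getValue() if p is not None else None


def _read_bounds(sr, sm, dialect: str, rid: str) -> tuple[float, float]:
    rfbc = sr.getPlugin("fbc")
    if rfbc is not None and rfbc.isSetLowerFluxBound() and rfbc.isSetUpperFluxBound():
        plb = sm.getParameter(rfbc.getLowerFluxBound())
        pub = sm.getParameter(rfbc.getUpperFluxBound())
        if plb is None or pub is None:
            raise FormatError(f"reaction {rid!r}: flux bound parameter missing")
        return plb.getValue(), pub.getValue()
    kl = sr.getKineticLaw()
    if kl is not None:
        plb = kl.getParameter("LOWER_BOUND")
        pub = kl.getParameter("UPPER_BOUND")
        if plb is not None and pub is not None:
            return plb.getValue(), pub.getValue()
    if dialect == "reconstruction_only":
        # GENRE files carry no explicit bounds; infer from reversibility
        return (-math.inf, math.inf) if sr.getReversible() else (0.0, math.inf)
    if dialect == "cobra_l2" and sr.isSetReversible():
        return (-math.inf, math.inf) if sr.getReversible() else (0.0, math.inf)
    raise FormatError(f"reaction {rid!r}: no flux bounds found and none inferable")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _cap_bound(value: float, cap: float) -> float:
    if math.isinf(value):
        return math.copysign(cap, value)
    return value


def _sanitize(sid: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "g_" + out
    return out


def write_model(model: Model, path: str, dialect: str = "fbc3", *,
                cap: float = DEFAULT_FLUX_CAP) -> None:
    """Serialize ``model`` to ``path`` in the requested dialect.

    The model is validated first; nothing is written if an invariant
    fails or the dialect cannot represent a feature.
    """
    model.validate()
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "reconstruction_only" and model.objective_reaction_id is not None:
        raise CapabilityError(
            "reconstruction_only dialect cannot carry an objective "
            f"(model sets {model.objective_reaction_id!r})"
        )
    if dialect == "cobra_l2" and model.objective_sense == "minimize":
        raise CapabilityError(
            "cobra_l2 dialect encodes objectives by coefficient only; "
            "a minimization sense cannot be represented"
        )
    if dialect == "cobra_l2":
        doc = _write_l2(model, cap)
    else:
        doc = _write_l3(model, cap, with_objective=(dialect == "fbc3"),
                        with_bounds=(dialect == "fbc3"))
    ok = libsbml.writeSBMLToFile(doc, path)
    if not ok:  # pragma: no cover - filesystem failure
        raise IOError(f"could not write SBML to {path}")


def _write_l3(model: Model, cap: float, *, with_objective: bool,
              with_bounds: bool) -> libsbml.SBMLDocument:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    sm.setName(model.name or model.id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)

    for cid, cname in (model.compartments or {"c": "cytoplasm"}).items():
        comp = sm.createCompartment()
        comp.setId(_sanitize(cid))
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sanitize(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize(met.compartment_id or
                                    next(iter(model.compartments or {"c": "c"}))))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        _set_refs(sp, met.external_refs)

    gene_sid: dict[str, str] = {}
    for gene in model.genes.values():
        gp = fbc.createGeneProduct()
        sid = "G_" + _sanitize(gene.id)
        gene_sid[gene.id] = sid
        gp.setId(sid)
        gp.setLabel(gene.id)
        if gene.standard_name:
            gp.setName(gene.standard_name)
        _set_refs(gp, gene.external_refs)

    def rename(gpr: GeneAssociation) -> GeneAssociation:
        if isinstance(gpr, GprLeaf):
            return GprLeaf(gene_sid[gpr.gene_id])
        if isinstance(gpr, (GprAnd, GprOr)):
            return type(gpr)([rename(c) for c in gpr.children])
        return gpr

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        value = _cap_bound(value, cap)
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sanitize(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sanitize(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        if with_bounds:
            rfbc = sr.getPlugin("fbc")
            rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
            rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty():
            rfbc = sr.getPlugin("fbc")
            gpa = rfbc.createGeneProductAssociation()
            _to_fbc_association(rename(rxn.gpr), gpa)
        if rxn.pubmed_refs:
            _set_refs(sr, [("pubmed", p) for p in rxn.pubmed_refs],
                      qualifier=libsbml.BQB_IS_DESCRIBED_BY)

    if with_objective and model.objective_reaction_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("minimize" if model.objective_sense == "minimize" else "maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sanitize(model.objective_reaction_id))
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")
    return doc


def _write_l2(model: Model, cap: float) -> libsbml.SBMLDocument:
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    sm.setName(model.name or model.id)

    for cid, cname in (model.compartments or {"c": "cytoplasm"}).items():
        comp = sm.createCompartment()
        comp.setId(_sanitize(cid))
        comp.setName(cname)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sanitize(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize(met.compartment_id or
                                    next(iter(model.compartments or {"c": "c"}))))
        sp.setBoundaryCondition(False)
        _set_refs(sp, met.external_refs)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sanitize(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sanitize(met_id))
            ref.setStoichiometry(abs(coef))
        if not rxn.gpr.is_empty():
            notes = (
                "<body xmlns=\"http://www.w3.org/1999/xhtml\">"
                f"<p>GENE_ASSOCIATION: {rxn.gpr.to_string()}</p>"
                "</body>"
            )
            sr.setNotes(notes)
        kl = sr.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, pval in (
            ("LOWER_BOUND", _cap_bound(rxn.lower_bound, cap)),
            ("UPPER_BOUND", _cap_bound(rxn.upper_bound, cap)),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT",
             1.0 if rxn.id == model.objective_reaction_id else 0.0),
        ):
            p = kl.createParameter()
            p.setId(pname)
            p.setValue(pval)
        if rxn.pubmed_refs:
            _set_refs(sr, [("pubmed", p) for p in rxn.pubmed_refs],
                      qualifier=libsbml.BQB_IS_DESCRIBED_BY)
    return doc


# ---------------------------------------------------------------------------
# annotation audit
# ---------------------------------------------------------------------------

def annotation_coverage(model: Model) -> tuple[float, pd.DataFrame]:
    """Fraction of reactions carrying at least one PubMed reference.

    Returns the fraction in ``[0, 1]`` together with a per-reaction table
    (columns ``reaction_id``, ``n_pubmed_refs``).  An empty model yields
    a fraction of ``0.0``.
    """
    rows = [(rxn.id, len(rxn.pubmed_refs)) for rxn in model.reactions.values()]
    table = pd.DataFrame(rows, columns=["reaction_id", "n_pubmed_refs"])
    if not rows:
        return 0.0, table
    n_annotated = int((table["n_pubmed_refs"] > 0).sum())
    return n_annotated / len(rows), table
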