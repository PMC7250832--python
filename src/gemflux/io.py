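"""Reading and writing models and their companion inputs.

Canonical tabular dialect
-------------------------
Models travel as two tab-separated sheets.

``reactions.tsv`` columns::

    id  name  formula  gpr  subsystem  lower_bound  upper_bound  confidence  kind  objective  tags

* ``formula`` is a reaction string such as ``"a[c] + 2 b[c] -> c[p]"``;
  ``<=>`` (or ``<->``) marks a reversible reaction.  One-sided strings
  (``"a[e] ->"``) are used for boundary pseudo-reactions.
* blank bounds default to (0, 1000) for ``->`` and (-1000, 1000) for
  ``<=>`` in mmol·gDW⁻¹·h⁻¹ (the standard COBRA convention).
* ``objective`` optionally names the objective this reaction carries
  (e.g. ``biomass_aerobic``); ``tags`` is a semicolon list, with ``ngam``
  marking the non-growth ATP maintenance reaction.

``metabolites.tsv`` columns::

    id  name  compartment  formula  charge

SBML import/export uses SBML Level 3 with the ``fbc`` package (flux
bounds as parameters, GPRs as gene-product associations, named
objectives).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Tuple

import pandas as pd
import yaml

from .core import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    format_gpr,
    gpr_genes,
    parse_gpr,
)

__all__ = [
    "MediumSpec",
    "ExpressionProfile",
    "parse_reaction_formula",
    "format_reaction_formula",
    "parse_chemical_formula",
    "format_chemical_formula",
    "read_model_tables",
    "write_model_tables",
    "read_sbml",
    "write_sbml",
    "read_medium",
    "write_medium",
    "read_expression_table",
    "write_expression_table",
    "read_hit_table",
]

DEFAULT_UB = 1000.0
DEFAULT_REVERSIBLE_LB = -1000.0

REACTION_COLUMNS = ["id", "name", "formula", "gpr", "subsystem", "lower_bound",
                    "upper_bound", "confidence", "kind", "objective", "tags"]
METABOLITE_COLUMNS = ["id", "name", "compartment", "formula", "charge"]


# ---------------------------------------------------------------------------
# Media and expression containers
# ---------------------------------------------------------------------------

@dataclass
class MediumSpec:
    """An in-silico medium: bounds on exchange reactions.

    ``bounds`` maps exchange reaction ids to (lb, ub) in mmol·gDW⁻¹·h⁻¹;
    negative lower bounds permit uptake.  Exchanges not listed default to
    secretion only (lb = 0).  ``carbon_source`` / ``nitrogen_source``
    identify which exchanges play those roles so that source screening
    can remove them from the background.  ``ngam`` optionally overrides
    the model's maintenance ATP flux (e.g. 0.92 aerobic vs 0.15
    anaerobic).
    """

    name: str
    bounds: dict = field(default_factory=dict)
    aerobic: bool = True
    carbon_source: Optional[str] = None
    nitrogen_source: Optional[str] = None
    ngam: Optional[float] = None
    o2_exchange: str = "EX_o2_e"

    def __post_init__(self):
        if not self.aerobic:
            lb, ub = self.bounds.get(self.o2_exchange, (0.0, DEFAULT_UB))
            # anoxic medium: no oxygen entry
            self.bounds[self.o2_exchange] = (0.0, ub)

    def with_bound(self, rid: str, lb: float, ub: float = DEFAULT_UB) -> "MediumSpec":
        new = MediumSpec(self.name, dict(self.bounds), self.aerobic,
                         self.carbon_source, self.nitrogen_source, self.ngam,
                         self.o2_exchange)
        new.bounds[rid] = (lb, ub)
        return new

    def without(self, rid) -> "MediumSpec":
        rids = {rid} if isinstance(rid, str) else set(rid)
        new = MediumSpec(self.name,
                         {k: v for k, v in self.bounds.items() if k not in rids},
                         self.aerobic, self.carbon_source, self.nitrogen_source,
                         self.ngam, self.o2_exchange)
        return new


@dataclass
class ExpressionProfile:
    """Gene expression for one growth condition, in FPKM.

    Genes absent from the table carry *no data* — they are excluded from
    quantile computation and never cause a reaction to be flagged as
    unexpressed.
    """

    condition: str
    fpkm: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {g: v for g, v in self.fpkm.items() if v < 0}
        if bad:
            raise ValueError(f"negative FPKM values: {bad}")

    def get(self, gene: str) -> Optional[float]:
        return self.fpkm.get(gene)

    def values(self):
        return list(self.fpkm.values())


# ---------------------------------------------------------------------------
# Formula strings
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d+\.\d+|\d*)")


def parse_chemical_formula(text: str) -> Optional[dict]:
    """Parse ``"C4H6O3"`` into ``{"C": 4, "H": 6, "O": 3}`` (None if blank)."""
    text = (text or "").strip()
    if not text:
        return None
    pos = 0
    formula: dict = {}
    for m in _ELEMENT.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse chemical formula {text!r}")
        count = float(m.group(2)) if m.group(2) else 1.0
        formula[m.group(1)] = formula.get(m.group(1), 0.0) + count
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse chemical formula {text!r}")
    return formula


def format_chemical_formula(formula: Optional[Mapping[str, float]]) -> str:
    if not formula:
        return ""
    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))
    # Hill-like order: C, H, then alphabetical
    keys = sorted(formula, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{fmt(formula[e])}" for e in keys if formula[e])


_ARROWS = ("<=>", "<->", "->")


def parse_reaction_formula(text: str) -> Tuple[dict, bool]:
    """Parse a reaction string into (stoichiometry, reversible).

    ``"a[c] + 2 b[c] -> c[p]"`` yields ``({"a[c]": -1, "b[c]": -2,
    "c[p]": 1}, False)``; ``<=>``/``<->`` mark reversibility.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ValueError(f"reaction formula lacks an arrow: {text!r}")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in reaction formula: {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ValueError(f"reaction formula has no net stoichiometry: {text!r}")
    return stoich, arrow in ("<=>", "<->")


def format_reaction_formula(stoichiometry: Mapping[str, float],
                            reversible: bool) -> str:
    def fmt(mid: str, coeff: float) -> str:
        c = abs(coeff)
        return mid if c == 1 else f"{int(c) if c.is_integer() else c} {mid}"

    subs = [fmt(m, c) for m, c in stoichiometry.items() if c < 0]
    prods = [fmt(m, c) for m, c in stoichiometry.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


# ---------------------------------------------------------------------------
# Tabular model sheets
# ---------------------------------------------------------------------------

def write_model_tables(model: MetabolicModel, reaction_sheet, metabolite_sheet) -> None:
    rrows = []
    for r in model.reactions:
        obj_names = sorted(n for n, rid in model.objectives.items() if rid == r.id)
        tags = []
        if model.ngam_reaction_id == r.id:
            tags.append("ngam")
        rrows.append({
            "id": r.id,
            "name": r.name,
            "formula": format_reaction_formula(r.stoichiometry, r.reversible),
            "gpr": format_gpr(r.gpr),
            "subsystem": r.subsystem,
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "confidence": "" if r.confidence is None else r.confidence,
            "kind": r.kind,
            "objective": ";".join(obj_names),
            "tags": ";".join(tags),
        })
    pd.DataFrame(rrows, columns=REACTION_COLUMNS).to_csv(
        reaction_sheet, sep="\t", index=False)

    mrows = [{
        "id": m.id,
        "name": m.name,
        "compartment": m.compartment,
        "formula": format_chemical_formula(m.formula),
        "charge": "" if m.charge is None else m.charge,
    } for m in model.metabolites]
    pd.DataFrame(mrows, columns=METABOLITE_COLUMNS).to_csv(
        metabolite_sheet, sep="\t", index=False)


def read_model_tables(reaction_sheet, metabolite_sheet,
                      model_id: Optional[str] = None) -> MetabolicModel:
    """Load a model from the canonical TSV sheets.

    Raises ``ModelValidationError`` naming the offending row for
    unparseable formulas, duplicate ids or GPRs citing unknown genes.
    """
    mdf = pd.read_csv(metabolite_sheet, sep="\t", dtype=str).fillna("")
    rdf = pd.read_csv(reaction_sheet, sep="\t", dtype=str).fillna("")
    if rdf.empty:
        raise ModelValidationError(f"no reactions in {reaction_sheet}")

    metabolites = []
    for i, row in mdf.iterrows():
        try:
            formula = parse_chemical_formula(row.get("formula", ""))
            charge = int(float(row["charge"])) if str(row.get("charge", "")).strip() else None
            metabolites.append(Metabolite(
                id=row["id"], name=row.get("name", ""),
                compartment=row.get("compartment", "c") or "c",
                formula=formula, charge=charge))
        except (ValueError, KeyError) as exc:
            raise ModelValidationError(
                f"{metabolite_sheet} row {i + 2}: {exc}") from exc

    reactions = []
    objectives: dict = {}
    ngam_id = None
    for i, row in rdf.iterrows():
        try:
            stoich, reversible = parse_reaction_formula(row["formula"])
            lb_s, ub_s = str(row.get("lower_bound", "")).strip(), str(row.get("upper_bound", "")).strip()
            lb = float(lb_s) if lb_s else (DEFAULT_REVERSIBLE_LB if reversible else 0.0)
            ub = float(ub_s) if ub_s else DEFAULT_UB
            conf_s = str(row.get("confidence", "")).strip()
            confidence = int(float(conf_s)) if conf_s else None
            gpr = parse_gpr(row.get("gpr", ""))
            kind = (row.get("kind", "") or "internal").strip()
            reactions.append(Reaction(
                id=row["id"], name=row.get("name", ""), stoichiometry=stoich,
                lower_bound=lb, upper_bound=ub, gpr=gpr,
                subsystem=row.get("subsystem", ""), confidence=confidence,
                kind=kind))
            for obj_name in str(row.get("objective", "")).split(";"):
                if obj_name.strip():
                    objectives[obj_name.strip()] = row["id"]
            if "ngam" in str(row.get("tags", "")).split(";"):
                ngam_id = row["id"]
        except ModelValidationError:
            raise
        except (ValueError, KeyError) as exc:
            raise ModelValidationError(
                f"{reaction_sheet} row {i + 2}: {exc}") from exc

    genes = sorted(set().union(frozenset(), *(r.genes for r in reactions)))
    model = MetabolicModel(
        id=model_id or Path(str(reaction_sheet)).stem,
        metabolites=metabolites, reactions=reactions, genes=genes,
        objectives=objectives, ngam_reaction_id=ngam_id)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    out = _SID_BAD.sub("__", raw)
    return out if re.match(r"[A-Za-z_]", out) else "_" + out


def _unsid(sid: str) -> str:
    # compartment suffix encoding: met[c] <-> met__c__ (round-trips [] safely)
    return sid.replace("__", "[", 1).replace("__", "]", 1) if "__" in sid else sid


def _met_sid(mid: str) -> str:
    m = re.match(r"^(.*)\[([a-z])\]$", mid)
    if m:
        return "M_" + _sid(m.group(1)) + "_" + m.group(2)
    return "M_" + _sid(mid)


def write_sbml(model: MetabolicModel, path) -> None:
    """Serialize a model to SBML Level 3 Version 1 with the fbc package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites} or {"c"}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    met_sids = {}
    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sid = _met_sid(m.id)
        met_sids[m.id] = sid
        sp.setId(sid)
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if m.formula is not None:
            splug.setChemicalFormula(format_chemical_formula(m.formula))
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    for g in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sid(g))
        gp.setLabel(g)

    bound_params = {}

    def bound_param(value: float) -> str:
        key = float(value)
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(key)
            p.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId("R_" + _sid(r.id))
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met_sids[mid])
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            gpr_str = format_gpr(r.gpr)
            for g in gpr_genes(r.gpr):
                gpr_str = re.sub(rf"(?<![\w]){re.escape(g)}(?![\w])",
                                 "G_" + _sid(g), gpr_str)
            gpa.setAssociation(gpr_str, True, False)  # match by id, no auto-add
        notes = [f"KIND: {r.kind}"]
        if r.subsystem:
            notes.append(f"SUBSYSTEM: {r.subsystem}")
        if r.confidence is not None:
            notes.append(f"CONFIDENCE: {r.confidence}")
        rx.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            + "".join(f"<p>{n}</p>" for n in notes) + "</body>")

    objective_names = sorted(model.objectives) or []
    for name in objective_names:
        obj = mplug.createObjective()
        obj.setId(_sid(name))
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sid(model.objectives[name]))
        fo.setCoefficient(1.0)
    if objective_names:
        active = "biomass_aerobic" if "biomass_aerobic" in objective_names \
            else objective_names[0]
        mplug.setActiveObjectiveId(_sid(active))

    model_notes = []
    if model.ngam_reaction_id:
        model_notes.append(f"NGAM: {model.ngam_reaction_id}")
    if model_notes:
        sbml_model.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            + "".join(f"<p>{n}</p>" for n in model_notes) + "</body>")

    libsbml.writeSBMLToFile(doc, str(path))


def _notes_dict(node) -> dict:
    notes = {}
    if node.isSetNotes():
        text = node.getNotesString()
        for m in re.finditer(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", text):
            notes[m.group(1)] = m.group(2)
    return notes


def read_sbml(path, default_lb: float = DEFAULT_REVERSIBLE_LB,
              default_ub: float = DEFAULT_UB) -> MetabolicModel:
    """Load an SBML L3+fbc model.

    Reactions lacking explicit flux bounds get defaults (reversible:
    ±1000, irreversible: 0..1000) — a warning is emitted since bounds are
    semantically part of the model.
    """
    import warnings

    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse errors in {path}: "
            f"{doc.getErrorLog().toString()}")
    sbml_model = doc.getModel()
    mplug = sbml_model.getPlugin("fbc")

    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    met_ids = {}
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp = sp.getCompartment() or "c"
        raw = sp.getId()
        base = raw[2:] if raw.startswith("M_") else raw
        if base.endswith("_" + comp):
            base = base[: -(len(comp) + 1)]
        mid = f"{base}[{comp}]"
        met_ids[raw] = mid
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_chemical_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(Metabolite(id=mid, name=sp.getName() or mid,
                                      compartment=comp, formula=formula,
                                      charge=charge))

    params = {}
    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        params[p.getId()] = p.getValue()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        raw = rx.getId()
        rid = raw[2:] if raw.startswith("R_") else raw
        stoich = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[met_ids[ref.getSpecies()]] = \
                stoich.get(met_ids[ref.getSpecies()], 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[met_ids[ref.getSpecies()]] = \
                stoich.get(met_ids[ref.getSpecies()], 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = ub = None
        gpr = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr_str = _association_to_string(gpa.getAssociation(), gene_labels)
                gpr = parse_gpr(gpr_str)
        if lb is None or ub is None:
            warnings.warn(
                f"reaction {rid}: no explicit flux bounds in SBML, applying "
                f"defaults", stacklevel=2)
            lb = default_lb if rx.getReversible() else 0.0
            ub = default_ub
        notes = _notes_dict(rx)
        conf = notes.get("CONFIDENCE")
        reactions.append(Reaction(
            id=rid, name=rx.getName() or rid, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            subsystem=notes.get("SUBSYSTEM", ""),
            confidence=int(conf) if conf else None,
            kind=notes.get("KIND", "internal")))

    objectives = {}
    if mplug is not None:
        for i in range(mplug.getNumObjectives()):
            obj = mplug.getObjective(i)
            if obj.getNumFluxObjectives() == 1:
                fo_rid = obj.getFluxObjective(0).getReaction()
                objectives[obj.getId()] = fo_rid[2:] if fo_rid.startswith("R_") else fo_rid

    model_notes = _notes_dict(sbml_model)
    genes = sorted(set().union(frozenset(), *(r.genes for r in reactions)))
    model = MetabolicModel(
        id=sbml_model.getId() or Path(str(path)).stem,
        metabolites=metabolites, reactions=reactions, genes=genes,
        objectives=objectives,
        ngam_reaction_id=model_notes.get("NGAM") or None)
    model.validate()
    return model


def _association_to_string(assoc, gene_labels: dict) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return gene_labels.get(assoc.getGeneProduct(), assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        return "(" + " and ".join(
            _association_to_string(assoc.getAssociation(i), gene_labels)
            for i in range(assoc.getNumAssociations())) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        return "(" + " or ".join(
            _association_to_string(assoc.getAssociation(i), gene_labels)
            for i in range(assoc.getNumAssociations())) + ")"
    raise ModelValidationError(f"unsupported GPR association node: {assoc}")


# ---------------------------------------------------------------------------
# Media, expression tables, ortholog hit tables
# ---------------------------------------------------------------------------

def read_medium(path) -> MediumSpec:
    """Read a medium config from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    bounds = {rid: (float(b[0]), float(b[1]))
              for rid, b in data.get("bounds", {}).items()}
    return MediumSpec(
        name=data.get("name", Path(str(path)).stem),
        bounds=bounds,
        aerobic=bool(data.get("aerobic", True)),
        carbon_source=data.get("carbon_source"),
        nitrogen_source=data.get("nitrogen_source"),
        ngam=data.get("ngam"),
        o2_exchange=data.get("o2_exchange", "EX_o2_e"),
    )


def write_medium(medium: MediumSpec, path) -> None:
    data = {
        "name": medium.name,
        "aerobic": medium.aerobic,
        "bounds": {rid: [lb, ub] for rid, (lb, ub) in sorted(medium.bounds.items())},
        "carbon_source": medium.carbon_source,
        "nitrogen_source": medium.nitrogen_source,
        "ngam": medium.ngam,
        "o2_exchange": medium.o2_exchange,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_expression_table(path, condition: Optional[str] = None) -> ExpressionProfile:
    """Read a two-column TSV of gene_id and FPKM."""
    df = pd.read_csv(path, sep="\t")
    gene_col, fpkm_col = df.columns[0], df.columns[1]
    fpkm = {str(g): float(v) for g, v in zip(df[gene_col], df[fpkm_col])
            if pd.notna(v)}
    return ExpressionProfile(condition or Path(str(path)).stem, fpkm)


def write_expression_table(profile: ExpressionProfile, path) -> None:
    pd.DataFrame(
        {"gene_id": list(profile.fpkm), "fpkm": list(profile.fpkm.values())}
    ).to_csv(path, sep="\t", index=False)


HIT_TABLE_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                     "gapopen", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore", "qcovs", "scovs"]


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-like hit table (TSV).

    Accepts either a headered table or a headerless 14-column one in the
    canonical order (standard outfmt 6 plus qcovs/scovs).
    """
    probe = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    has_header = str(probe.iloc[0, 0]).strip() == "qseqid"
    if has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=HIT_TABLE_COLUMNS[: probe.shape[1]])
    required = {"qseqid", "sseqid", "pident", "evalue", "qcovs", "scovs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} lacks columns: {sorted(missing)}")
    return df
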