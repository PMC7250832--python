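"""In-memory representation of a constraint-based metabolic model.

A model is a set of metabolites (with compartment, elemental formula and
charge), reactions (stoichiometry over metabolite ids, flux bounds in
mmol·gDW⁻¹·h⁻¹, a boolean gene-protein-reaction rule and a structural
kind) and genes.  The stoichiometric matrix S is assembled with one row
per metabolite and one column per reaction, so the steady-state
constraint reads S·v = 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BalanceReport",
    "GprGene",
    "GprAnd",
    "GprOr",
    "Gpr",
    "parse_gpr",
    "format_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "build_stoichiometric_matrix",
    "check_mass_balance",
    "ModelValidationError",
    "REACTION_KINDS",
]

COMPARTMENTS = ("c", "p", "e")
REACTION_KINDS = ("internal", "exchange", "sink", "demand", "biomass")

#: kinds exempt from elemental balance checks — they move mass across the
#: system boundary (or, for biomass, consume precursors in gDW units).
BOUNDARY_KINDS = ("exchange", "sink", "demand", "biomass")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR boolean rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprGene:
    gene: str

    def __str__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class GprAnd:
    children: tuple

    def __str__(self) -> str:
        return " and ".join(_paren(c) for c in self.children)


@dataclass(frozen=True)
class GprOr:
    children: tuple

    def __str__(self) -> str:
        return " or ".join(_paren(c) for c in self.children)


#: A GPR expression: a tree of GprGene/GprAnd/GprOr nodes, or ``None`` for
#: an orphan (spontaneous) reaction with no gene requirement.
Gpr = Optional[object]


def _paren(node) -> str:
    if isinstance(node, (GprAnd, GprOr)):
        return f"({node})"
    return str(node)


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> Gpr:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a rule tree.

    ``and``/``or`` are case-insensitive; an empty or blank string denotes an
    orphan reaction.  Gene tokens are any non-whitespace run without
    parentheses (locus tags such as ``SGRAN_2644`` included).
    """
    tokens = _GPR_TOKEN.findall(text or "")
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprOr(tuple(terms))

    def parse_and():
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else GprAnd(tuple(terms))

    def parse_atom():
        tok = peek()
        if tok is None:
            raise ModelValidationError(f"truncated GPR expression: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ModelValidationError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelValidationError(f"malformed GPR expression: {text!r}")
        return GprGene(take())

    expr = parse_or()
    if pos != len(tokens):
        raise ModelValidationError(f"trailing tokens in GPR: {text!r}")
    return expr


def format_gpr(gpr: Gpr) -> str:
    """Canonical string form of a GPR tree ('' for orphan reactions)."""
    return "" if gpr is None else str(gpr)


def gpr_genes(gpr: Gpr) -> frozenset:
    """The set of gene ids appearing as leaves of a GPR tree."""
    if gpr is None:
        return frozenset()
    if isinstance(gpr, GprGene):
        return frozenset((gpr.gene,))
    return frozenset().union(*(gpr_genes(c) for c in gpr.children))


def evaluate_gpr(gpr: Gpr, deleted) -> bool:
    """Evaluate a GPR rule under a set of deleted genes.

    ``GENE(g)`` is false iff ``g`` is deleted; AND is conjunction, OR is
    disjunction.  The empty (orphan) expression is always true: no gene
    deletion can switch off a spontaneous reaction.
    """
    if gpr is None:
        return True
    if isinstance(gpr, GprGene):
        return gpr.gene not in deleted
    if isinstance(gpr, GprAnd):
        return all(evaluate_gpr(c, deleted) for c in gpr.children)
    if isinstance(gpr, GprOr):
        return any(evaluate_gpr(c, deleted) for c in gpr.children)
    raise TypeError(f"not a GPR node: {gpr!r}")


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

_MET_COMPARTMENT = re.compile(r"\[([a-z])\]$")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    Ids carry a compartment suffix, e.g. ``akg[c]``; compartments follow
    the convention c = cytosol, p = periplasm, e = extracellular space.
    ``formula`` maps element symbols to counts (may be None when the
    composition is unknown, e.g. biomass or lumped species).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[Mapping[str, float]] = None
    charge: Optional[int] = None

    def validate(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}")
        m = _MET_COMPARTMENT.search(self.id)
        if m and m.group(1) != self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id}: id tag [{m.group(1)}] does not match "
                f"compartment {self.compartment!r}")


@dataclass(frozen=True)
class Reaction:
    """A (pseudo-)reaction: signed stoichiometry plus flux bounds and a GPR.

    Bounds are in mmol·gDW⁻¹·h⁻¹ (the biomass reaction's flux is the
    specific growth rate in h⁻¹).  Reversibility is encoded purely by
    ``lower_bound < 0``.  ``kind`` distinguishes internal chemistry from
    the boundary pseudo-reactions (exchange / sink / demand) and biomass.
    """

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Gpr = None
    subsystem: str = ""
    confidence: Optional[int] = None
    kind: str = "internal"

    def validate(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")
        n = len(self.stoichiometry)
        if self.kind in ("exchange", "sink", "demand") and n != 1:
            raise ModelValidationError(
                f"reaction {self.id}: {self.kind} reactions touch exactly one "
                f"metabolite (got {n})")
        if self.kind == "internal" and n < 2:
            raise ModelValidationError(
                f"reaction {self.id}: internal reactions need >= 2 metabolites")
        if self.confidence is not None and self.confidence not in (1, 2, 3, 4):
            raise ModelValidationError(
                f"reaction {self.id}: confidence must be in 1..4")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)

    @property
    def genes(self) -> frozenset:
        return gpr_genes(self.gpr)


# ---------------------------------------------------------------------------
# The model container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    #: named objectives, e.g. {"biomass_aerobic": "BIOMASS", ...}
    objectives: dict = field(default_factory=dict)
    ngam_reaction_id: Optional[str] = None

    # -- indexing -----------------------------------------------------------
    def metabolite_index(self) -> dict:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def set_reaction(self, reaction: Reaction) -> None:
        idx = self.reaction_index()[reaction.id]
        self.reactions[idx] = reaction

    def exchanges(self) -> Iterator[Reaction]:
        return (r for r in self.reactions if r.kind == "exchange")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=list(self.genes),
            objectives=dict(self.objectives),
            ngam_reaction_id=self.ngam_reaction_id,
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError."""
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known_mets = set(met_ids)
        known_genes = set(self.genes)
        for m in self.metabolites:
            m.validate()
        for r in self.reactions:
            r.validate()
            missing = set(r.stoichiometry) - known_mets
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id} references unknown metabolites: "
                    f"{sorted(missing)}")
            orphan_genes = r.genes - known_genes
            if orphan_genes:
                raise ModelValidationError(
                    f"reaction {r.id}: GPR references undeclared genes: "
                    f"{sorted(orphan_genes)}")
        for name, rid in self.objectives.items():
            if rid not in set(rxn_ids):
                raise ModelValidationError(
                    f"objective {name!r} names unknown reaction {rid!r}")
        if self.ngam_reaction_id is not None and \
                self.ngam_reaction_id not in set(rxn_ids):
            raise ModelValidationError(
                f"NGAM reaction {self.ngam_reaction_id!r} not in model")


# ---------------------------------------------------------------------------
# Matrix assembly and balance checking
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel, dense: bool = False):
    """Assemble S with rows = metabolites, columns = reactions.

    ``S[m, r]`` is the signed coefficient of metabolite ``m`` in reaction
    ``r``; column order follows ``model.reactions``.
    """
    midx = model.metabolite_index()
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            rows.append(midx[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.coo_matrix(
        (vals, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    ).tocsr()
    return S.toarray() if dense else S


@dataclass
class BalanceReport:
    """Classification of every reaction by elemental balance.

    Each reaction id appears in exactly one of the four lists; boundary
    pseudo-reactions (exchange/sink/demand/biomass) are exempt, and
    internal reactions touching any metabolite without a formula are
    'unknown-formula'.  ``imbalances`` maps imbalanced reaction ids to the
    per-element net excess (products minus substrates).
    """

    balanced: list = field(default_factory=list)
    imbalanced: list = field(default_factory=list)
    exempt: list = field(default_factory=list)
    unknown_formula: list = field(default_factory=list)
    imbalances: dict = field(default_factory=dict)

    @property
    def n_imbalanced(self) -> int:
        return len(self.imbalanced)


def check_mass_balance(model: MetabolicModel, tol: float = 1e-6) -> BalanceReport:
    """Per-element balance check of every internal reaction."""
    formulas = {m.id: m.formula for m in model.metabolites}
    report = BalanceReport()
    for r in model.reactions:
        if r.kind in BOUNDARY_KINDS:
            report.exempt.append(r.id)
            continue
        if any(formulas[mid] is None for mid in r.stoichiometry):
            report.unknown_formula.append(r.id)
            continue
        net: dict = {}
        for mid, coeff in r.stoichiometry.items():
            for element, count in formulas[mid].items():
                net[element] = net.get(element, 0.0) + coeff * count
        net = {e: v for e, v in net.items() if abs(v) > tol}
        if net:
            report.imbalanced.append(r.id)
            report.imbalances[r.id] = net
        else:
            report.balanced.append(r.id)
    return report
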