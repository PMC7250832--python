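"""Reconstruction utilities: ortholog filtering, draft projection and
merging, genome-derived biomass coefficients, and uptake-rate estimation
from concentration time courses.

These implement the standard first steps of a genome-scale
reconstruction: orthologs between the target genome and well-curated
donor models are called by reciprocal best BLASTP hits; donor reactions
whose GPRs remain satisfiable after rewriting onto the target's genes
are projected into a draft; biomass stoichiometric coefficients for
amino acids, dNTPs and NTPs are computed from the proteome and genome
sequences; and substrate uptake rates (mmol·gDW⁻¹·h⁻¹) are estimated by
regressing concentration against cumulative biomass-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GprAnd,
    GprGene,
    GprOr,
    MetabolicModel,
    Metabolite,
    Reaction,
    format_gpr,
)
from .fba import GROWTH_TOLERANCE, solve_fba

__all__ = [
    "filter_rbh",
    "gpr_curation_filter",
    "project_and_merge",
    "BiomassComposition",
    "biomass_coefficients",
    "UptakeEstimate",
    "estimate_uptake_rate",
    "report_biomass_gaps",
    "DEFAULT_MASS_FRACTIONS",
    "AA_RESIDUE_MASS",
    "DNTP_RESIDUE_MASS",
    "NTP_RESIDUE_MASS",
]


# ---------------------------------------------------------------------------
# Ortholog filtering
# ---------------------------------------------------------------------------

def _best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: lowest e-value, ties by bitscore then identity."""
    df = df.copy()
    if "bitscore" not in df.columns:
        df["bitscore"] = 0.0
    df = df.sort_values(["qseqid", "evalue", "bitscore", "pident"],
                        ascending=[True, True, False, False],
                        kind="mergesort")
    return df.drop_duplicates("qseqid", keep="first")


def _passes(row, min_identity, min_coverage, max_evalue, both_coverage) -> bool:
    cov_ok = row["qcovs"] >= min_coverage and (
        not both_coverage or row["scovs"] >= min_coverage)
    if not both_coverage:
        cov_ok = row["qcovs"] >= min_coverage
    return (row["pident"] >= min_identity and cov_ok
            and row["evalue"] < max_evalue)


def filter_rbh(forward_hits: pd.DataFrame, reverse_hits: pd.DataFrame,
               min_identity: float = 40.0, min_coverage: float = 80.0,
               max_evalue: float = 1e-20,
               both_coverage: bool = True) -> list:
    """Reciprocal-best-hit ortholog pairs passing alignment thresholds.

    A pair (q, s) is kept iff s is q's best forward hit, q is s's best
    reverse hit, and both directional hits satisfy identity >=
    ``min_identity`` %, coverage >= ``min_coverage`` % (on both query
    and subject by default; query-only with ``both_coverage=False``) and
    e-value < ``max_evalue``.  Returns sorted (query, subject) pairs.
    """
    fwd = _best_hits(forward_hits)
    rev = _best_hits(reverse_hits)
    rev_best = {row["qseqid"]: row for _, row in rev.iterrows()}
    pairs = []
    for _, frow in fwd.iterrows():
        q, s = frow["qseqid"], frow["sseqid"]
        rrow = rev_best.get(s)
        if rrow is None or rrow["sseqid"] != q:
            continue
        if _passes(frow, min_identity, min_coverage, max_evalue, both_coverage) \
                and _passes(rrow, min_identity, min_coverage, max_evalue,
                            both_coverage):
            pairs.append((q, s))
    return sorted(pairs)


def gpr_curation_filter(candidates: pd.DataFrame,
                        min_identity: float = 30.0,
                        min_coverage: float = 70.0,
                        max_evalue: float = 1e-5) -> pd.DataFrame:
    """Filter candidate gene-reaction assignments on alignment quality.

    Acceptance requires e-value < ``max_evalue``, identity strictly
    higher than ``min_identity`` % and coverage of *both* proteins
    strictly higher than ``min_coverage`` % (boundary values are
    rejected).  Expects columns pident, qcovs, scovs, evalue.
    """
    keep = ((candidates["evalue"] < max_evalue)
            & (candidates["pident"] > min_identity)
            & (candidates["qcovs"] > min_coverage)
            & (candidates["scovs"] > min_coverage))
    return candidates[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Draft projection and merge
# ---------------------------------------------------------------------------

class _Unsat:
    """Sentinel: a GPR branch that no target gene combination satisfies."""


_UNSAT = _Unsat()


def _rewrite_gpr(gpr, gene_map: Mapping[str, str]):
    """Rewrite a donor GPR over target genes; unmapped genes are treated
    as deleted (an AND missing a mandatory subunit fails, an OR simply
    drops the unmapped isozyme)."""
    if gpr is None:
        return None
    if isinstance(gpr, GprGene):
        return GprGene(gene_map[gpr.gene]) if gpr.gene in gene_map else _UNSAT
    children = [_rewrite_gpr(c, gene_map) for c in gpr.children]
    if isinstance(gpr, GprAnd):
        if any(c is _UNSAT for c in children):
            return _UNSAT
        return children[0] if len(children) == 1 else GprAnd(tuple(children))
    kept = [c for c in children if c is not _UNSAT]
    if not kept:
        return _UNSAT
    return kept[0] if len(kept) == 1 else GprOr(tuple(kept))


def project_and_merge(donor_models: Sequence[MetabolicModel],
                      ortholog_maps: Sequence[Mapping[str, str]],
                      donor_labels: Optional[Sequence[str]] = None
                      ) -> Tuple[MetabolicModel, dict]:
    """Project donor reactions through ortholog maps and merge the drafts.

    A donor reaction enters the draft iff its GPR, rewritten onto target
    genes, is still satisfiable (orphan reactions always are).
    Reactions appearing in several donors are merged once; a provenance
    map records, per reaction, which donors contributed it ('both' when
    more than one).  Identical ids with conflicting stoichiometry raise
    an error listing both definitions.
    """
    if len(donor_models) != len(ortholog_maps):
        raise ValueError("one ortholog map per donor model is required")
    if donor_labels is None:
        donor_labels = [m.id for m in donor_models]

    reactions: dict = {}
    metabolites: dict = {}
    provenance: dict = {}
    for donor, gene_map, label in zip(donor_models, ortholog_maps, donor_labels):
        for r in donor.reactions:
            new_gpr = _rewrite_gpr(r.gpr, gene_map)
            if new_gpr is _UNSAT:
                continue
            projected = Reaction(
                id=r.id, name=r.name, stoichiometry=dict(r.stoichiometry),
                lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                gpr=new_gpr, subsystem=r.subsystem,
                confidence=r.confidence, kind=r.kind)
            if r.id in reactions:
                old = reactions[r.id]
                if dict(old.stoichiometry) != dict(projected.stoichiometry):
                    raise ValueError(
                        f"reaction {r.id}: conflicting stoichiometry across "
                        f"donors: {dict(old.stoichiometry)} vs "
                        f"{dict(projected.stoichiometry)}")
                # keep the first donor's definition; widen the GPR by OR-ing
                # distinct rewritten rules
                if format_gpr(old.gpr) != format_gpr(projected.gpr) and \
                        projected.gpr is not None and old.gpr is not None:
                    reactions[r.id] = Reaction(
                        id=old.id, name=old.name,
                        stoichiometry=dict(old.stoichiometry),
                        lower_bound=old.lower_bound, upper_bound=old.upper_bound,
                        gpr=GprOr((old.gpr, projected.gpr)),
                        subsystem=old.subsystem, confidence=old.confidence,
                        kind=old.kind)
                provenance[r.id] = "both"
            else:
                reactions[r.id] = projected
                provenance[r.id] = label
            for mid in r.stoichiometry:
                if mid not in metabolites:
                    metabolites[mid] = donor.get_metabolite(mid)

    genes = sorted(set().union(
        frozenset(), *(r.genes for r in reactions.values())))
    draft = MetabolicModel(
        id="draft",
        metabolites=list(metabolites.values()),
        reactions=list(reactions.values()),
        genes=genes)
    draft.validate()
    return draft, provenance


# ---------------------------------------------------------------------------
# Biomass coefficients from genomic information
# ---------------------------------------------------------------------------

# average residue masses, g/mol (monomer minus water: peptide /
# phosphodiester condensation) so that mass closure is exact
AA_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
DNTP_RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
NTP_RESIDUE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}

#: macromolecular mass fractions, g·gDW⁻¹ (standard Gram-negative values;
#: no experimental composition is available for the modelled strain)
DEFAULT_MASS_FRACTIONS = {
    "protein": 0.55,
    "rna": 0.17,
    "dna": 0.03,
    "lipid": 0.12,
    "murein": 0.03,
    "ions": 0.01,
    "soluble_pool": 0.09,
}

# lumped pseudo-monomers for the non-sequence-derived classes: nominal
# molar masses (g/mol) chosen so the lumped coefficient closes the class
# mass exactly
_LUMPED_MONOMER_MASS = {
    "lipid_pool": 700.0,
    "sphinganine": 301.51,
    "murein_unit": 1000.0,
    "ion_pool": 100.0,
    "soluble_pool": 300.0,
}
#: share of the lipid fraction carried by the sphingolipid precursor
#: sphinganine (sphingolipids replace LPS in the modelled cell envelope)
SPHINGANINE_LIPID_SHARE = 0.10


@dataclass
class BiomassComposition:
    """Genome-derived biomass stoichiometry.

    ``coefficients`` maps each macromolecular class to monomer
    coefficients in mmol·gDW⁻¹; within each class the coefficients are
    scaled so that Σ coeff × residue mass equals the class mass fraction
    × 1000 mg·gDW⁻¹.  ``gam`` is the growth-associated ATP maintenance
    (mmol ATP·gDW⁻¹); ``ngam`` the non-growth maintenance flux.
    """

    mass_fractions: dict
    coefficients: dict  # class -> {monomer -> mmol/gDW}
    gam: float
    ngam: float

    def class_mass(self, cls: str) -> float:
        masses = {"protein": AA_RESIDUE_MASS, "dna": DNTP_RESIDUE_MASS,
                  "rna": NTP_RESIDUE_MASS}.get(cls, _LUMPED_MONOMER_MASS)
        return sum(coeff * masses[mon]
                   for mon, coeff in self.coefficients[cls].items())

    def total_mass(self) -> float:
        """Σ over classes of Σ coeff × residue mass, in mg·gDW⁻¹."""
        return sum(self.class_mass(cls) for cls in self.coefficients)


def _scaled_coefficients(counts: Mapping[str, float], masses: Mapping[str, float],
                         fraction: float) -> dict:
    total = sum(counts.get(k, 0.0) * masses[k] for k in masses)
    if total <= 0:
        raise ValueError("no monomer counts to scale")
    # coeff_i = fraction (g/gDW) * 1000 (mg/g) * x_i / Σ x_j m_j
    return {k: fraction * 1000.0 * counts.get(k, 0.0) / total for k in masses}


def biomass_coefficients(proteome_fasta, genome_fasta,
                         mass_fractions: Optional[Mapping[str, float]] = None,
                         gam: float = 40.0, ngam: float = 0.92,
                         rna_weights: Optional[Mapping[str, float]] = None
                         ) -> BiomassComposition:
    """Biomass monomer coefficients from proteome and genome FASTA.

    Amino-acid coefficients are proportional to residue frequencies
    across the whole proteome, scaled to the protein mass fraction;
    dNTP coefficients come from the genome base composition counted on
    both strands (so A=T and G=C); NTP coefficients use the
    coding-strand composition as a transcript proxy, optionally weighted
    per record by ``rna_weights`` (e.g. FPKM).  Mass fractions must sum
    to 1 ± 0.01.
    """
    from Bio import SeqIO

    fractions = dict(DEFAULT_MASS_FRACTIONS if mass_fractions is None
                     else mass_fractions)
    total_fraction = sum(fractions.values())
    if abs(total_fraction - 1.0) > 0.01:
        raise ValueError(
            f"mass fractions sum to {total_fraction:.4f}, not 1 +/- 0.01")

    aa_counts: dict = {aa: 0.0 for aa in AA_RESIDUE_MASS}
    n_prot = 0
    for rec in SeqIO.parse(str(proteome_fasta), "fasta"):
        n_prot += 1
        for ch in str(rec.seq).upper().rstrip("*"):
            if ch in aa_counts:
                aa_counts[ch] += 1.0
    if n_prot == 0:
        raise ValueError(f"no sequences in proteome FASTA {proteome_fasta}")

    dnt_counts = {b: 0.0 for b in "ACGT"}
    rnt_counts = {b: 0.0 for b in "ACGU"}
    n_dna = 0
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for rec in SeqIO.parse(str(genome_fasta), "fasta"):
        n_dna += 1
        w = 1.0 if rna_weights is None else float(rna_weights.get(rec.id, 0.0))
        for ch in str(rec.seq).upper():
            if ch in complement:
                dnt_counts[ch] += 1.0
                dnt_counts[complement[ch]] += 1.0  # both strands
                rnt_counts["U" if ch == "T" else ch] += w  # coding strand
    if n_dna == 0:
        raise ValueError(f"no sequences in genome FASTA {genome_fasta}")

    coefficients = {
        "protein": _scaled_coefficients(aa_counts, AA_RESIDUE_MASS,
                                        fractions["protein"]),
        "dna": _scaled_coefficients(dnt_counts, DNTP_RESIDUE_MASS,
                                    fractions["dna"]),
        "rna": _scaled_coefficients(rnt_counts, NTP_RESIDUE_MASS,
                                    fractions["rna"]),
        "lipid": _scaled_coefficients(
            {"sphinganine": SPHINGANINE_LIPID_SHARE / _LUMPED_MONOMER_MASS["sphinganine"],
             "lipid_pool": (1 - SPHINGANINE_LIPID_SHARE) / _LUMPED_MONOMER_MASS["lipid_pool"]},
            {k: _LUMPED_MONOMER_MASS[k] for k in ("sphinganine", "lipid_pool")},
            fractions["lipid"]),
        "murein": {"murein_unit": fractions["murein"] * 1000.0
                   / _LUMPED_MONOMER_MASS["murein_unit"]},
        "ions": {"ion_pool": fractions["ions"] * 1000.0
                 / _LUMPED_MONOMER_MASS["ion_pool"]},
        "soluble_pool": {"soluble_pool": fractions["soluble_pool"] * 1000.0
                         / _LUMPED_MONOMER_MASS["soluble_pool"]},
    }
    return BiomassComposition(fractions, coefficients, gam, ngam)


def biomass_reaction_row(composition: BiomassComposition,
                         metabolite_ids: Mapping[str, str],
                         rid: str = "BIOMASS",
                         objective: str = "biomass_aerobic") -> dict:
    """Emit a model-sheet-compatible biomass reaction row.

    ``metabolite_ids`` maps monomer keys (one-letter amino acids, dNTP/NTP
    letters prefixed 'd'/'r', lumped pool names, and 'atp'/'adp'/'pi'/'h2o')
    to model metabolite ids; monomers without a mapping are skipped.
    """
    from .io import format_reaction_formula

    stoich: dict = {}

    def add(key: str, coeff: float) -> None:
        mid = metabolite_ids.get(key)
        if mid is not None and coeff:
            stoich[mid] = stoich.get(mid, 0.0) - coeff

    for aa, coeff in composition.coefficients["protein"].items():
        add(aa, coeff)
    for b, coeff in composition.coefficients["dna"].items():
        add("d" + b, coeff)
    for b, coeff in composition.coefficients["rna"].items():
        add("r" + b, coeff)
    for cls in ("lipid", "murein", "ions", "soluble_pool"):
        for mon, coeff in composition.coefficients[cls].items():
            add(mon, coeff)
    add("atp", composition.gam)
    add("h2o", composition.gam)
    for key in ("adp", "pi"):
        mid = metabolite_ids.get(key)
        if mid is not None:
            stoich[mid] = stoich.get(mid, 0.0) + composition.gam
    return {
        "id": rid, "name": "biomass (genome-derived coefficients)",
        "formula": format_reaction_formula(stoich, False),
        "gpr": "", "subsystem": "Biomass", "lower_bound": 0.0,
        "upper_bound": 1000.0, "confidence": "", "kind": "biomass",
        "objective": objective, "tags": "",
    }


# ---------------------------------------------------------------------------
# Uptake-rate estimation from time courses
# ---------------------------------------------------------------------------

@dataclass
class UptakeEstimate:
    substrate: str
    rate: float  # mmol·gDW⁻¹·h⁻¹, negative = uptake
    standard_error: float
    fit_window: tuple  # (t_start, t_end) in h
    n_points: int


def estimate_uptake_rate(concentration_timecourse, biomass_timecourse,
                         substrate: str = "substrate",
                         window: Optional[tuple] = None) -> UptakeEstimate:
    """Specific uptake rate from batch concentration and biomass series.

    For a constant specific rate q, dC/dt = q·X(t), so C(t) is linear in
    the cumulative biomass-time integral ∫₀ᵗ X dτ with slope q.  The
    integral is computed by the trapezoidal rule on the biomass series
    (interpolated onto the concentration time points) and q is the
    ordinary least-squares slope, with its regression standard error.
    Concentrations in mM and biomass in gDW·L⁻¹ give q in
    mmol·gDW⁻¹·h⁻¹ (negative for consumption).
    """
    tc = np.asarray(concentration_timecourse, dtype=float)
    tb = np.asarray(biomass_timecourse, dtype=float)
    if tc.ndim != 2 or tc.shape[1] != 2 or tb.ndim != 2 or tb.shape[1] != 2:
        raise ValueError("time courses must be (t, value) pairs")
    if window is not None:
        mask = (tc[:, 0] >= window[0]) & (tc[:, 0] <= window[1])
        tc = tc[mask]
    if len(tc) < 3:
        raise ValueError("need at least 3 time points in the fit window")
    t = tc[:, 0]
    X = np.interp(t, tb[:, 0], tb[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * (X[1:] + X[:-1]))])
    if np.allclose(cum, 0.0):
        raise ValueError("biomass series is zero; uptake rate undefined")
    fit = stats.linregress(cum, tc[:, 1])
    stderr = float(fit.stderr)
    if not np.isfinite(stderr):  # degenerate (e.g. perfectly constant) series
        stderr = 0.0
    return UptakeEstimate(substrate, float(fit.slope), stderr,
                          (float(t[0]), float(t[-1])), len(t))


# ---------------------------------------------------------------------------
# Biomass producibility (gap) report
# ---------------------------------------------------------------------------

def report_biomass_gaps(model: MetabolicModel, medium,
                        objective_name: str = "biomass_aerobic",
                        min_flux: float = GROWTH_TOLERANCE) -> dict:
    """Which biomass precursors the network cannot produce on a medium.

    For every substrate of the biomass reaction, a temporary demand
    (maximize its drain) checks producibility; the report maps
    precursor metabolite id → maximal production flux.  Gap filling
    itself is a curation task; this only locates the holes.

    Caveat: currency metabolites whose moiety is returned on the
    biomass product side (ATP hydrolysed to ADP + Pi) cannot carry a
    *net* drain and show up with zero flux here even in a gapless
    network; interpret those entries as "conserved couple", not a gap.
    """
    biomass = model.get_reaction(
        model.objectives.get(objective_name, objective_name))
    report = {}
    for mid, coeff in biomass.stoichiometry.items():
        if coeff >= 0:
            continue
        probe = model.copy()
        dm_id = f"DM__probe__{mid}"
        probe.reactions = list(probe.reactions) + [Reaction(
            id=dm_id, stoichiometry={mid: -1.0}, lower_bound=0.0,
            upper_bound=1000.0, kind="demand", name=f"probe demand {mid}")]
        sol = solve_fba(probe, medium, dm_id, pfba=False)
        report[mid] = sol.objective_value if sol.optimal else 0.0
    return {mid: flux for mid, flux in report.items()}
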