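"""Synthetic data generators: a toy metabolic network, expression
profiles and batch time courses.

The toy network is a deliberately small stand-in for the central carbon
and energy metabolism of an aerobic/facultatively-anaerobic degrader
bacterium: substrate funnels (a 3-hydroxybutyrate-like C4 acid, a
C10 dicarboxylate funneled by beta-oxidation, a C10 tetralin-like
aromatic whose dioxygenase consumes O2, lactate, glucose without a
transporter, and a glutamate-like C+N amino acid) feed a lumped
TCA cycle with a glyoxylate-shunt bypass (gene ``aceA_toy``),
oxidative phosphorylation with an O2 and a nitrate branch (nitrate in,
nitrite out — the anaerobic electron sink), ammonium assimilation, an
optional PHB storage branch, NGAM and separate aerobic/anaerobic
biomass reactions.

Chemistry is pseudo-elemental: formulas carry C, N, O plus bookkeeping
elements H (redox pairs), P (phosphate) and A (adenosine), with exact
integer stoichiometry, so elemental-balance checks are meaningful
without real biochemistry.  Substrate funnel yields (acetyl units,
redox pairs and ATP activation cost per molecule) are parameters, and
substrate formulas are derived from them, so every parameterization is
balanced by construction.  Default yields make the fatty-acid-like
substrates better per-carbon sources than lactate, and make tetralin
catabolism oxygen-hungry — the qualitative contrasts the analyses
exercise; no quantitative agreement with any real organism is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction, parse_gpr
from .dfba import DfbaConfig, DfbaTrajectory, run_dfba
from .io import ExpressionProfile, MediumSpec

__all__ = [
    "ToyNetworkSpec",
    "SyntheticExpressionSpec",
    "make_toy_model",
    "toy_minimal_medium",
    "make_expression_profiles",
    "make_batch_timecourse",
    "NGAM_AEROBIC",
    "NGAM_ANAEROBIC",
]

#: non-growth ATP maintenance defaults, mmol·gDW⁻¹·h⁻¹ (oxic / anoxic)
NGAM_AEROBIC = 0.92
NGAM_ANAEROBIC = 0.15


@dataclass
class ToyNetworkSpec:
    include_glyoxylate_shunt: bool = True
    include_nitrate_respiration: bool = True
    include_phb_branch: bool = True
    #: number of OR-isozyme GPRs (0-2): the 3-HB ligase pair, then the
    #: terminal-oxidase pair
    n_isozyme_pairs: int = 2
    seed: int = 0
    #: per-substrate funnel yields: acetyl units, redox pairs, ATP
    #: activation cost per molecule of substrate
    funnel_yields: dict = field(default_factory=lambda: {
        "hb3": {"acetyl": 2, "redox": 1, "atp": 0},
        "seb": {"acetyl": 5, "redox": 3, "atp": 1},
    })

    def validate(self) -> None:
        if not 0 <= self.n_isozyme_pairs <= 2:
            raise ValueError("n_isozyme_pairs must be 0, 1 or 2")
        for name, y in self.funnel_yields.items():
            if y["acetyl"] < 1 or y["redox"] < 0 or y["atp"] < 0:
                raise ValueError(f"invalid funnel yields for {name}: {y}")


def _met(mid, name, formula, compartment):
    return Metabolite(id=mid, name=name, compartment=compartment,
                      formula=formula)


def make_toy_model(spec: Optional[ToyNetworkSpec] = None) -> MetabolicModel:
    """Build the toy network (deterministic given the spec)."""
    spec = spec or ToyNetworkSpec()
    spec.validate()

    mets = []
    rxns = []

    def add_species(base, name, formula, compartments=("c",)):
        for comp in compartments:
            mets.append(_met(f"{base}[{comp}]", name, formula, comp))

    # substrate formulas derived from funnel yields: C = 2*acetyl,
    # H = 2*acetyl + 2*redox -> funnels balance for any parameterization
    hb3_y = spec.funnel_yields["hb3"]
    seb_y = spec.funnel_yields["seb"]
    add_species("hb3", "3-hydroxybutyrate-like substrate",
                {"C": 2 * hb3_y["acetyl"], "H": 2 * hb3_y["acetyl"] + 2 * hb3_y["redox"]},
                ("e", "c"))
    add_species("seb", "C10 dicarboxylate (sebacate-like)",
                {"C": 2 * seb_y["acetyl"], "H": 2 * seb_y["acetyl"] + 2 * seb_y["redox"]},
                ("e", "c"))
    add_species("ttl", "tetralin-like bicyclic substrate",
                {"C": 10, "H": 12}, ("e", "c"))
    add_species("dcd", "ring-fission dioate intermediate",
                {"C": 10, "H": 6}, ("c",))
    add_species("lac", "lactate", {"C": 3, "H": 4}, ("e", "c"))
    add_species("glc", "glucose (no transporter)", {"C": 6, "H": 6}, ("e", "c"))
    add_species("glu", "glutamate-like C+N source", {"C": 5, "H": 7, "N": 1},
                ("e", "c"))
    add_species("pyr", "pyruvate", {"C": 3, "H": 2}, ("c",))
    add_species("acu", "acetyl unit", {"C": 2, "H": 2}, ("c",))
    add_species("rh", "redox pair (NADH-equivalent)", {"H": 2}, ("c",))
    add_species("co2", "carbon dioxide (pseudo)", {"C": 1}, ("c", "e"))
    add_species("o2", "dioxygen", {"O": 2}, ("e", "c"))
    add_species("h2o", "water", {"H": 2, "O": 1}, ("c", "e"))
    add_species("nh3", "ammonium (as NH3)", {"N": 1, "H": 3}, ("e", "c"))
    add_species("pi", "phosphate token", {"P": 1}, ("e", "c"))
    add_species("atp", "ATP token", {"A": 1, "P": 1}, ("c",))
    add_species("adp", "ADP token", {"A": 1}, ("c",))
    add_species("g6p", "gluconeogenic sugar-phosphate",
                {"C": 4, "H": 4, "P": 1}, ("c",))
    add_species("prec", "nitrogenous biomass precursor",
                {"C": 2, "H": 5, "N": 1}, ("c",))
    if spec.include_nitrate_respiration:
        add_species("no3", "nitrate", {"N": 1, "O": 3}, ("e", "c"))
        add_species("no2", "nitrite", {"N": 1, "O": 2}, ("c", "e"))
    if spec.include_phb_branch:
        add_species("phb", "PHB monomer equivalent", {"C": 4, "H": 6}, ("c",))

    def rxn(rid, formula_terms, gpr="", kind="internal", lb=0.0, ub=1000.0,
            name="", subsystem="", confidence=None):
        rxns.append(Reaction(
            id=rid, name=name or rid, stoichiometry=dict(formula_terms),
            lower_bound=lb, upper_bound=ub, gpr=parse_gpr(gpr),
            subsystem=subsystem, confidence=confidence, kind=kind))

    # exchanges (flux > 0 secretes, < 0 takes up; media open the uptakes)
    ex_species = ["hb3", "seb", "ttl", "lac", "glc", "glu", "o2", "co2",
                  "h2o", "nh3", "pi"]
    if spec.include_nitrate_respiration:
        ex_species += ["no3", "no2"]
    for base in ex_species:
        rxn(f"EX_{base}_e", {f"{base}[e]": -1.0}, kind="exchange",
            lb=0.0, ub=1000.0, subsystem="Exchange")

    # transports; reversible passive steps are orphan (spontaneous)
    transports = {
        "hb3": "", "seb": "", "lac": "", "glu": "", "o2": "", "co2": "",
        "h2o": "", "nh3": "", "pi": "",
        "ttl": "thnM_toy",
    }
    if spec.include_nitrate_respiration:
        transports["no3"] = "narK_toy"
        transports["no2"] = ""
    for base, gpr in sorted(transports.items()):
        rxn(f"T_{base}", {f"{base}[e]": -1.0, f"{base}[c]": 1.0}, gpr=gpr,
            lb=-1000.0, ub=1000.0, subsystem="Transport")
    # note: no glucose transporter — glc[e] is exchangeable but unreachable

    iso1 = "hbcL1_toy or hbcL2_toy" if spec.n_isozyme_pairs >= 1 else "hbcL1_toy"
    iso2 = "cyoA_toy or cydA_toy" if spec.n_isozyme_pairs >= 2 else "cyoA_toy"

    def funnel_terms(base, y):
        terms = {f"{base}[c]": -1.0, "acu[c]": float(y["acetyl"])}
        if y["redox"]:
            terms["rh[c]"] = float(y["redox"])
        if y["atp"]:
            terms["atp[c]"] = -float(y["atp"])
            terms["adp[c]"] = float(y["atp"])
            terms["pi[c]"] = float(y["atp"])
        return terms

    rxn("HB3CL", funnel_terms("hb3", hb3_y), gpr=iso1,
        name="3-HB activation and cleavage", subsystem="Fatty acid catabolism",
        confidence=3)
    rxn("SEBOX", funnel_terms("seb", seb_y), gpr="fadD_toy",
        name="dicarboxylate beta-oxidation (lumped)",
        subsystem="Fatty acid catabolism", confidence=3)
    rxn("TTL1", {"ttl[c]": -1.0, "o2[c]": -2.0, "rh[c]": -1.0,
                 "dcd[c]": 1.0, "h2o[c]": 4.0},
        gpr="thnA1_toy and thnA2_toy",
        name="tetralin dioxygenase + ring fission (lumped)",
        subsystem="Aromatic catabolism", confidence=4)
    rxn("TTL2", {"dcd[c]": -1.0, "rh[c]": -2.0, "acu[c]": 5.0},
        gpr="thnD_toy", name="dioate beta-oxidation (lumped)",
        subsystem="Aromatic catabolism", confidence=3)
    rxn("RHX", {"rh[c]": -1.0, "o2[c]": -0.5, "h2o[c]": 1.0},
        gpr="thnN_toy", name="uncoupled oxidase (redundant)",
        subsystem="Aromatic catabolism", confidence=2)
    rxn("LACDH", {"lac[c]": -1.0, "pyr[c]": 1.0, "rh[c]": 1.0},
        gpr="lldD_toy", name="lactate dehydrogenase",
        subsystem="Central metabolism", confidence=3)
    rxn("GLCF", {"glc[c]": -1.0, "pyr[c]": 2.0, "rh[c]": 1.0},
        gpr="glk_toy", name="glycolysis (lumped)",
        subsystem="Central metabolism", confidence=2)
    rxn("GLUDC", {"glu[c]": -1.0, "acu[c]": 1.0, "pyr[c]": 1.0,
                  "nh3[c]": 1.0},
        gpr="gudB_toy", name="glutamate deamination",
        subsystem="Amino acid catabolism", confidence=2)
    rxn("PDH", {"pyr[c]": -1.0, "acu[c]": 1.0, "co2[c]": 1.0},
        gpr="aceE_toy", name="pyruvate dehydrogenase",
        subsystem="Central metabolism", confidence=3)
    rxn("TCA", {"acu[c]": -1.0, "co2[c]": 2.0, "rh[c]": 1.0},
        gpr="icd_toy", name="TCA cycle (lumped oxidation)",
        subsystem="Central metabolism", confidence=3)
    if spec.include_glyoxylate_shunt:
        rxn("GLYOX", {"acu[c]": -2.0, "atp[c]": -1.0, "g6p[c]": 1.0,
                      "adp[c]": 1.0},
            gpr="aceA_toy", name="glyoxylate shunt + gluconeogenesis (lumped)",
            subsystem="Central metabolism", confidence=4)
    rxn("PPS", {"pyr[c]": -2.0, "atp[c]": -2.0, "g6p[c]": 1.0,
                "co2[c]": 2.0, "adp[c]": 2.0, "pi[c]": 1.0},
        gpr="ppsA_toy", name="gluconeogenesis from pyruvate (lumped)",
        subsystem="Central metabolism", confidence=3)
    rxn("OXPHO2", {"rh[c]": -1.0, "o2[c]": -0.5, "adp[c]": -2.0,
                   "pi[c]": -2.0, "h2o[c]": 1.0, "atp[c]": 2.0},
        gpr=iso2, name="oxidative phosphorylation (O2)",
        subsystem="Energy metabolism", confidence=3)
    if spec.include_nitrate_respiration:
        rxn("NAR", {"rh[c]": -1.0, "no3[c]": -1.0, "adp[c]": -1.0,
                    "pi[c]": -1.0, "no2[c]": 1.0, "h2o[c]": 1.0,
                    "atp[c]": 1.0},
            gpr="narG_toy", name="respiratory nitrate reductase",
            subsystem="Energy metabolism", confidence=3)
    rxn("ASSIM", {"acu[c]": -1.0, "nh3[c]": -1.0, "prec[c]": 1.0},
        gpr="gltB_toy", name="nitrogen assimilation (lumped)",
        subsystem="Biosynthesis", confidence=3)
    if spec.include_phb_branch:
        rxn("PHBS", {"acu[c]": -2.0, "rh[c]": -1.0, "phb[c]": 1.0},
            gpr="phaC_toy", name="PHB synthesis (lumped)",
            subsystem="Storage", confidence=3)
        rxn("DM_phb", {"phb[c]": -1.0}, kind="demand", lb=0.0, ub=1000.0,
            name="PHB demand", subsystem="Storage")
    # the maintenance flux value is pinned per medium (0.92 oxic / 0.15
    # anoxic); the bare model leaves it free so v = 0 stays feasible
    rxn("NGAM", {"atp[c]": -1.0, "adp[c]": 1.0, "pi[c]": 1.0},
        lb=0.0, ub=1000.0,
        name="non-growth ATP maintenance", subsystem="Energy metabolism")
    rxn("BIOMASS_AERO", {"prec[c]": -1.0, "g6p[c]": -0.5, "atp[c]": -10.0,
                         "adp[c]": 10.0, "pi[c]": 10.5},
        kind="biomass", name="biomass, oxic", subsystem="Biomass")
    rxn("BIOMASS_ANA", {"prec[c]": -1.0, "g6p[c]": -0.5, "atp[c]": -8.0,
                        "adp[c]": 8.0, "pi[c]": 8.5},
        kind="biomass", name="biomass, anoxic", subsystem="Biomass")

    genes = sorted(set().union(frozenset(), *(r.genes for r in rxns)))
    model = MetabolicModel(
        id=f"toy_gem_seed{spec.seed}",
        metabolites=mets, reactions=rxns, genes=genes,
        objectives={"biomass_aerobic": "BIOMASS_AERO",
                    "biomass_anaerobic": "BIOMASS_ANA"},
        ngam_reaction_id="NGAM")
    model.validate()
    return model


def toy_minimal_medium(carbon: str = "EX_hb3_e", aerobic: bool = True,
                       carbon_uptake: float = -10.0,
                       nutrient_uptake: float = -30.0) -> MediumSpec:
    """Minimal medium for the toy model, paper-style bound scheme.

    Nutrients (ammonium, phosphate, water, and O2 when oxic or nitrate
    when anoxic) are open to −30 mmol·gDW⁻¹·h⁻¹; the carbon source
    uptake is set separately; every other exchange is secretion-only.
    NGAM defaults to 0.92 (oxic) or 0.15 (anoxic).
    """
    bounds = {
        "EX_nh3_e": (nutrient_uptake, 1000.0),
        "EX_pi_e": (nutrient_uptake, 1000.0),
        "EX_h2o_e": (nutrient_uptake, 1000.0),
    }
    if aerobic:
        bounds["EX_o2_e"] = (nutrient_uptake, 1000.0)
    else:
        bounds["EX_no3_e"] = (nutrient_uptake, 1000.0)
    bounds[carbon] = (carbon_uptake, 1000.0)
    return MediumSpec(
        name=("oxic" if aerobic else "anoxic") + f" minimal + {carbon}",
        bounds=bounds, aerobic=aerobic, carbon_source=carbon,
        nitrogen_source="EX_nh3_e",
        ngam=NGAM_AEROBIC if aerobic else NGAM_ANAEROBIC)


# ---------------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpressionSpec:
    """Log-normal FPKM baseline with per-condition 'off' gene sets.

    ~30% of expressed genes sit exactly at a detection-floor value (the
    30th percentile of the log-normal draw), emulating an RNA-seq
    quantification floor; 'off' genes are drawn strictly below half the
    floor.  Consequently the first quartile of the profile equals the
    floor whenever fewer than a quarter of the genes are off, so the
    strict below-first-quartile cut-off flags exactly the off genes —
    and flags nothing when the off set is empty.
    """

    log_mean: float = 4.0
    log_sd: float = 1.0
    off_genes: dict = field(default_factory=dict)  # condition -> set of genes
    seed: int = 0
    floor_quantile: float = 0.30


def make_expression_profiles(model: MetabolicModel,
                             spec: Optional[SyntheticExpressionSpec] = None
                             ) -> dict:
    """One ExpressionProfile per condition in the spec (seeded)."""
    spec = spec or SyntheticExpressionSpec(off_genes={"baseline": set()})
    genes = list(model.genes)
    n = len(genes)
    profiles = {}
    for k, (condition, off) in enumerate(sorted(spec.off_genes.items())):
        off = set(off)
        unknown = off - set(genes)
        if unknown:
            raise ValueError(f"off genes not in model: {sorted(unknown)}")
        if len(off) >= 0.25 * n:
            raise ValueError(
                f"condition {condition!r}: {len(off)} off genes is too many "
                f"for a first-quartile cut-off over {n} genes")
        rng = np.random.default_rng((spec.seed, k))
        base = rng.lognormal(spec.log_mean, spec.log_sd, size=n)
        floor = float(np.quantile(base, spec.floor_quantile))
        values = np.maximum(base, floor)
        fpkm = dict(zip(genes, values))
        for g in off:
            fpkm[g] = float(rng.uniform(0.01, 0.5) * floor)
        profiles[condition] = ExpressionProfile(condition, fpkm)
    return profiles


# ---------------------------------------------------------------------------
# Batch time courses
# ---------------------------------------------------------------------------

def make_batch_timecourse(model: MetabolicModel, config: DfbaConfig,
                          noise_sd: float = 0.0, seed: int = 0,
                          sample_every: int = 1):
    """Forward-simulate a batch by dFBA and emit noisy measurements.

    Returns ``(concentration_timecourses, biomass_timecourse, trajectory)``
    where the concentration series (one (t, C) array per tracked
    exchange) carry additive Gaussian noise of standard deviation
    ``noise_sd`` (in mM; 0 for noise-free), clipped at zero, and the
    biomass series is noise-free.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    traj = run_dfba(model, config)
    idx = np.arange(0, len(traj.times), sample_every)
    t = np.asarray(traj.times)[idx]
    X = np.asarray(traj.biomass)[idx]
    biomass_tc = np.column_stack([t, X])
    conc_tcs = {}
    for rid in config.initial_concentrations:
        c = np.asarray(traj.concentration_series(rid))[idx]
        noisy = c + rng.normal(0.0, noise_sd, size=len(c)) if noise_sd else c
        conc_tcs[rid] = np.column_stack([t, np.maximum(noisy, 0.0)])
    return conc_tcs, biomass_tc, traj
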