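"""Ortholog filtering, draft merging, biomass coefficients, uptake rates."""

import numpy as np
import pandas as pd
import pytest

from gemflux.core import MetabolicModel, Metabolite, Reaction, format_gpr, parse_gpr
from gemflux.dfba import DfbaConfig
from gemflux.reconstruction import (
    AA_RESIDUE_MASS,
    biomass_coefficients,
    estimate_uptake_rate,
    filter_rbh,
    gpr_curation_filter,
    project_and_merge,
    report_biomass_gaps,
)
from gemflux.synth import make_batch_timecourse, make_toy_model, toy_minimal_medium


def _hit(q, s, pident, evalue, qcovs=90, scovs=90, bitscore=100.0):
    return {"qseqid": q, "sseqid": s, "pident": pident, "evalue": evalue,
            "qcovs": qcovs, "scovs": scovs, "bitscore": bitscore}


# ---------------------------------------------------------------------------
# RBH
# ---------------------------------------------------------------------------

def test_rbh_thresholds_and_reciprocity():
    fwd = pd.DataFrame([
        _hit("q1", "s1", 45, 1e-30, qcovs=85),        # passes everything
        _hit("q2", "s2", 39, 1e-40),                   # identity fails
        _hit("q3", "s3", 50, 1e-25),                   # best fwd, not best rev
    ])
    rev = pd.DataFrame([
        _hit("s1", "q1", 45, 1e-30, qcovs=85),
        _hit("s2", "q2", 39, 1e-40),
        _hit("s3", "q9", 60, 1e-60),                   # s3 prefers q9
    ])
    assert filter_rbh(fwd, rev) == [("q1", "s1")]


def test_rbh_best_hit_selection_by_evalue():
    fwd = pd.DataFrame([
        _hit("q1", "sBad", 80, 1e-10),
        _hit("q1", "sGood", 70, 1e-50),  # lower e-value wins despite identity
    ])
    rev = pd.DataFrame([_hit("sGood", "q1", 70, 1e-50)])
    assert filter_rbh(fwd, rev) == [("q1", "sGood")]


def test_rbh_idempotent_and_order_invariant():
    fwd = pd.DataFrame([_hit("q1", "s1", 45, 1e-30),
                        _hit("q2", "s2", 55, 1e-45)])
    rev = pd.DataFrame([_hit("s2", "q2", 55, 1e-45),
                        _hit("s1", "q1", 45, 1e-30)])
    once = filter_rbh(fwd, rev)
    shuffled = filter_rbh(fwd.iloc[::-1].reset_index(drop=True), rev)
    assert once == shuffled == [("q1", "s1"), ("q2", "s2")]


def test_rbh_coverage_on_both_proteins_switchable():
    fwd = pd.DataFrame([_hit("q1", "s1", 45, 1e-30, qcovs=85, scovs=60)])
    rev = pd.DataFrame([_hit("s1", "q1", 45, 1e-30, qcovs=85, scovs=60)])
    assert filter_rbh(fwd, rev) == []  # subject coverage fails
    assert filter_rbh(fwd, rev, both_coverage=False) == [("q1", "s1")]


# ---------------------------------------------------------------------------
# GPR curation filter
# ---------------------------------------------------------------------------

def test_curation_filter_thresholds_are_strict():
    rows = pd.DataFrame([
        _hit("g1", "ref1", 35, 1e-10, qcovs=75, scovs=80),  # accepted
        _hit("g2", "ref2", 35, 1e-10, qcovs=75, scovs=60),  # subject cov fails
        _hit("g3", "ref3", 30, 1e-10, qcovs=75, scovs=80),  # 30% exactly: out
        _hit("g4", "ref4", 35, 1e-5, qcovs=75, scovs=80),   # e-value not <
    ])
    accepted = gpr_curation_filter(rows)
    assert list(accepted["qseqid"]) == ["g1"]
    # idempotent
    assert gpr_curation_filter(accepted).equals(accepted)


# ---------------------------------------------------------------------------
# Draft projection / merge
# ---------------------------------------------------------------------------

def _donor(rid_range, shared, gene_prefix):
    mets = [Metabolite(id=f"m{i}[c]") for i in range(4)]
    rxns = []
    genes = []
    for k in rid_range:
        g = f"{gene_prefix}_{k}"
        genes.append(g)
        rxns.append(Reaction(id=f"r{k}", gpr=parse_gpr(g),
                             stoichiometry={"m0[c]": -1.0,
                                            f"m{1 + k % 3}[c]": 1.0}))
    for rid, g in shared:
        genes.append(g)
        rxns.append(Reaction(id=rid, gpr=parse_gpr(g),
                             stoichiometry={"m1[c]": -1.0, "m2[c]": 1.0}))
    model = MetabolicModel(id=gene_prefix, metabolites=mets, reactions=rxns,
                           genes=sorted(set(genes)))
    model.validate()
    return model


def test_two_donor_merge_is_the_set_union():
    """Donors of 5 and 4 reactions sharing 2 ids merge into a 7-reaction
    draft, with shared reactions tagged 'both'."""
    d1 = _donor(range(3), [("shA", "dA_x"), ("shB", "dA_y")], "dA")
    d2 = _donor(range(3, 5), [("shA", "dB_x"), ("shB", "dB_y")], "dB")
    omap1 = {g: f"T_{g}" for g in d1.genes}
    omap2 = {g: f"T_{g}" for g in d2.genes}
    draft, provenance = project_and_merge([d1, d2], [omap1, omap2],
                                          ["donor-A", "donor-B"])
    assert len(draft.reactions) == 7
    assert provenance["shA"] == "both" and provenance["shB"] == "both"
    assert provenance["r0"] == "donor-A" and provenance["r4"] == "donor-B"


def test_reaction_without_ortholog_is_excluded():
    d1 = _donor(range(3), [], "dA")
    omap = {g: f"T_{g}" for g in d1.genes if g != "dA_1"}
    draft, _ = project_and_merge([d1], [omap])
    assert {r.id for r in draft.reactions} == {"r0", "r2"}


def test_and_with_missing_subunit_fails_or_survives():
    mets = [Metabolite(id="m0[c]"), Metabolite(id="m1[c]")]
    rxns = [
        Reaction(id="needs_both", gpr=parse_gpr("gA and gB"),
                 stoichiometry={"m0[c]": -1.0, "m1[c]": 1.0}),
        Reaction(id="either", gpr=parse_gpr("gA or gB"),
                 stoichiometry={"m0[c]": -1.0, "m1[c]": 2.0}),
        Reaction(id="spont", gpr=None,
                 stoichiometry={"m0[c]": -1.0, "m1[c]": 3.0}),
    ]
    donor = MetabolicModel(id="d", metabolites=mets, reactions=rxns,
                           genes=["gA", "gB"])
    draft, _ = project_and_merge([donor], [{"gA": "tA"}])
    ids = {r.id for r in draft.reactions}
    assert ids == {"either", "spont"}  # the AND complex lost a subunit
    assert format_gpr(draft.get_reaction("either").gpr) == "tA"


def test_merge_order_invariance_and_conflict_detection():
    d1 = _donor(range(2), [("sh", "dA_s")], "dA")
    d2 = _donor(range(2, 4), [("sh", "dB_s")], "dB")
    maps = [{g: f"T_{g}" for g in d.genes} for d in (d1, d2)]
    ab, _ = project_and_merge([d1, d2], maps, ["A", "B"])
    ba, _ = project_and_merge([d2, d1], maps[::-1], ["B", "A"])
    assert {r.id for r in ab.reactions} == {r.id for r in ba.reactions}
    for rid in (r.id for r in ab.reactions):
        assert dict(ab.get_reaction(rid).stoichiometry) == \
            dict(ba.get_reaction(rid).stoichiometry)
    # conflicting stoichiometry for a shared id is an error
    d3 = _donor(range(2, 4), [], "dB")
    d3.reactions.append(Reaction(id="sh", gpr=parse_gpr("dB_s"),
                                 stoichiometry={"m1[c]": -2.0, "m2[c]": 1.0}))
    d3.genes = sorted(set(d3.genes + ["dB_s"]))
    with pytest.raises(ValueError, match="conflicting stoichiometry"):
        project_and_merge([d1, d3], [maps[0], {g: f"T_{g}" for g in d3.genes}])


# ---------------------------------------------------------------------------
# Biomass coefficients
# ---------------------------------------------------------------------------

def test_polyalanine_takes_whole_protein_fraction(tmp_path):
    (tmp_path / "p.faa").write_text(">p\nAAAAAAAA\n")
    (tmp_path / "g.fna").write_text(">c\nATGC\n")
    comp = biomass_coefficients(tmp_path / "p.faa", tmp_path / "g.fna")
    protein = comp.coefficients["protein"]
    assert protein["A"] == pytest.approx(
        0.55 * 1000.0 / AA_RESIDUE_MASS["A"])
    assert all(v == 0 for aa, v in protein.items() if aa != "A")


def test_two_protein_coefficients_match_hand_arithmetic(tmp_path):
    (tmp_path / "p.faa").write_text(">p1\nAAAA\n>p2\nGGLL\n")
    (tmp_path / "g.fna").write_text(">c\nATGCATGC\n")
    comp = biomass_coefficients(tmp_path / "p.faa", tmp_path / "g.fna")
    counts = {"A": 4, "G": 2, "L": 2}
    denom = sum(c * AA_RESIDUE_MASS[aa] for aa, c in counts.items())
    for aa, count in counts.items():
        assert comp.coefficients["protein"][aa] == pytest.approx(
            0.55 * 1000.0 * count / denom)


def test_balanced_gc_genome_gives_equal_dntps(tmp_path):
    (tmp_path / "p.faa").write_text(">p\nMA\n")
    (tmp_path / "g.fna").write_text(">c\nATGCATGCAT\n")  # both strands counted
    comp = biomass_coefficients(tmp_path / "p.faa", tmp_path / "g.fna")
    dntps = list(comp.coefficients["dna"].values())
    # both-strand counting forces A=T and G=C regardless of the strand read
    assert comp.coefficients["dna"]["A"] == pytest.approx(
        comp.coefficients["dna"]["T"])
    assert comp.coefficients["dna"]["G"] == pytest.approx(
        comp.coefficients["dna"]["C"])


def test_mass_closure_within_one_percent(tmp_path):
    (tmp_path / "p.faa").write_text(">p1\nMKVLAAGGWT\n>p2\nPPQRSTYYED\n")
    (tmp_path / "g.fna").write_text(">c\n" + "ATGGCATTACCGGTA" * 3 + "\n")
    comp = biomass_coefficients(tmp_path / "p.faa", tmp_path / "g.fna")
    assert comp.total_mass() == pytest.approx(1000.0, rel=0.01)
    assert sum(comp.mass_fractions.values()) == pytest.approx(1.0, abs=0.01)


def test_bad_inputs_raise(tmp_path):
    (tmp_path / "empty.faa").write_text("")
    (tmp_path / "g.fna").write_text(">c\nATGC\n")
    with pytest.raises(ValueError, match="no sequences"):
        biomass_coefficients(tmp_path / "empty.faa", tmp_path / "g.fna")
    (tmp_path / "p.faa").write_text(">p\nMA\n")
    with pytest.raises(ValueError, match="mass fractions"):
        biomass_coefficients(tmp_path / "p.faa", tmp_path / "g.fna",
                             mass_fractions={"protein": 0.5, "rna": 0.2,
                                             "dna": 0.1, "lipid": 0.1,
                                             "murein": 0.02, "ions": 0.01,
                                             "soluble_pool": 0.02})


# ---------------------------------------------------------------------------
# Uptake-rate estimation
# ---------------------------------------------------------------------------

def _noisefree_batch(toy_model, q=2.0, n=40):
    medium = toy_minimal_medium(carbon="EX_hb3_e")
    medium.ngam = 0.0
    config = DfbaConfig(initial_biomass=0.01,
                        initial_concentrations={"EX_hb3_e": 40.0},
                        fixed_uptake_bounds={"EX_hb3_e": -q},
                        medium=medium, timestep=0.1, n_steps=n,
                        objective_name="biomass_aerobic")
    return make_batch_timecourse(toy_model, config, noise_sd=0.0, seed=0)


def test_noise_free_recovery_is_nearly_exact(toy_model):
    conc, biomass, _ = _noisefree_batch(toy_model)
    est = estimate_uptake_rate(conc["EX_hb3_e"], biomass, "3hb")
    assert est.rate == pytest.approx(-2.0, rel=1e-3)


def test_constant_concentration_gives_zero_rate():
    t = np.linspace(0, 5, 8)
    conc = np.column_stack([t, np.full_like(t, 12.0)])
    biomass = np.column_stack([t, 0.1 * np.exp(0.2 * t)])
    est = estimate_uptake_rate(conc, biomass)
    assert est.rate == pytest.approx(0.0, abs=1e-12)
    assert est.standard_error >= 0


def test_noisy_recovery_within_three_se(toy_model):
    """20 noisy replicates (sigma = 2% of C0): each estimate is within
    3 standard errors of the configured rate."""
    medium = toy_minimal_medium(carbon="EX_hb3_e")
    medium.ngam = 0.0
    config = DfbaConfig(initial_biomass=0.01,
                        initial_concentrations={"EX_hb3_e": 40.0},
                        fixed_uptake_bounds={"EX_hb3_e": -2.0},
                        medium=medium, timestep=0.1, n_steps=40,
                        objective_name="biomass_aerobic")
    hits = 0
    for rep in range(20):
        conc, biomass, _ = make_batch_timecourse(
            toy_model, config, noise_sd=0.02 * 40.0, seed=100 + rep)
        est = estimate_uptake_rate(conc["EX_hb3_e"], biomass, "3hb")
        if abs(est.rate - (-2.0)) <= 3 * est.standard_error:
            hits += 1
    assert hits >= 19  # 3 sigma: essentially all replicates


def test_too_few_points_raise():
    t = np.array([0.0, 1.0])
    with pytest.raises(ValueError, match="3 time points"):
        estimate_uptake_rate(np.column_stack([t, [5.0, 4.0]]),
                             np.column_stack([t, [0.1, 0.2]]))


def test_biomass_gap_report_finds_producible_precursors(toy_model):
    gaps = report_biomass_gaps(toy_model, toy_minimal_medium())
    assert gaps["prec[c]"] > 1e-6
    assert gaps["g6p[c]"] > 1e-6
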