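"""GIMME condition models, expression mapping, ACHR sampling, flux ratios."""

import numpy as np
import pytest

from gemflux.core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_stoichiometric_matrix,
    parse_gpr,
)
from gemflux.expression import (
    ConditionModel,
    build_condition_model,
    conditional_essentiality,
    flux_ratio_map,
    fpkm_threshold,
    reaction_expression,
    sample_flux_space,
)
from gemflux.fba import effective_bounds, gene_deletion_screen, solve_fba
from gemflux.io import ExpressionProfile
from gemflux.synth import toy_minimal_medium


# ---------------------------------------------------------------------------
# Thresholds and reaction-level expression
# ---------------------------------------------------------------------------

def test_first_quartile_linear_interpolation():
    profile = ExpressionProfile("x", {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
    assert fpkm_threshold(profile) == pytest.approx(1.75)


def test_threshold_of_constant_profile_is_the_constant():
    profile = ExpressionProfile("x", {g: 7.5 for g in "abcde"})
    assert fpkm_threshold(profile) == pytest.approx(7.5)


def test_threshold_monotone_in_quantile():
    rng = np.random.default_rng(3)
    profile = ExpressionProfile(
        "x", {f"g{i}": float(v) for i, v in
              enumerate(rng.lognormal(3, 1, size=50))})
    cuts = [fpkm_threshold(profile, q) for q in (0.15, 0.2, 0.25, 0.3, 0.35)]
    assert cuts == sorted(cuts)


def test_threshold_needs_enough_genes():
    with pytest.raises(ValueError, match="at least 4"):
        fpkm_threshold(ExpressionProfile("x", {"a": 1.0, "b": 2.0}))


@pytest.mark.parametrize("gpr, fpkm, expected", [
    ("g1 and g2", {"g1": 10.0, "g2": 2.0}, 2.0),   # scarcest subunit limits
    ("g1 or g2", {"g1": 10.0, "g2": 2.0}, 10.0),   # isozymes add capacity
    ("g1 and g2", {"g1": 10.0}, 10.0),             # no data is neutral
    ("g1 or g2", {"g2": 2.0}, 2.0),
    ("g1 and g2", {}, None),
    ("", {"g1": 10.0}, None),                      # orphan: no data ever
])
def test_reaction_expression_conventions(gpr, fpkm, expected):
    profile = ExpressionProfile("x", fpkm)
    assert reaction_expression(parse_gpr(gpr), profile) == expected


# ---------------------------------------------------------------------------
# Condition models
# ---------------------------------------------------------------------------

def _profile_for(model, off=(), value_on=100.0, value_off=0.1):
    fpkm = {g: value_on for g in model.genes}
    # a block at a common floor keeps Q1 below the expressed genes
    for g in list(model.genes)[:max(6, len(model.genes) // 3)]:
        fpkm[g] = min(fpkm[g], 50.0)
    for g in off:
        fpkm[g] = value_off
    return ExpressionProfile("cond", fpkm)


def test_all_expressed_profile_changes_nothing(toy_model, aerobic_hb3):
    profile = _profile_for(toy_model, off=())
    cond = build_condition_model(toy_model, profile, aerobic_hb3)
    assert cond.flagged_reactions == set()
    assert cond.removed_reactions == set()
    parent = solve_fba(toy_model, aerobic_hb3, pfba=False).objective_value
    reduced = solve_fba(cond.to_model(), aerobic_hb3, pfba=False).objective_value
    assert reduced == pytest.approx(parent)


def test_flux_reroutes_through_expressed_path(toy_model):
    """Two gluconeogenic routes exist on lactate (glyoxylate shunt vs the
    pyruvate route); silencing one forces all flux through the other,
    matching what enumerating the two routings predicts."""
    medium = toy_minimal_medium(carbon="EX_lac_e")
    cond = build_condition_model(
        toy_model, _profile_for(toy_model, off=("aceA_toy",)), medium)
    assert "GLYOX" in cond.removed_reactions
    sol = solve_fba(cond.to_model(), medium)
    assert sol.fluxes["GLYOX"] == pytest.approx(0.0, abs=1e-9)
    assert sol.fluxes["PPS"] > 1e-6
    # and the mirror condition routes the other way
    cond2 = build_condition_model(
        toy_model, _profile_for(toy_model, off=("ppsA_toy",)), medium)
    sol2 = solve_fba(cond2.to_model(), medium)
    assert sol2.fluxes["PPS"] == pytest.approx(0.0, abs=1e-9)
    assert sol2.fluxes["GLYOX"] > 1e-6


def test_condition_model_attains_required_fraction(toy_model):
    medium = toy_minimal_medium(carbon="EX_lac_e")
    parent = solve_fba(toy_model, medium, pfba=False).objective_value
    for off in [(), ("aceA_toy",), ("ppsA_toy", "glk_toy")]:
        cond = build_condition_model(
            toy_model, _profile_for(toy_model, off=off), medium,
            required_objective_fraction=0.9)
        reduced = solve_fba(cond.to_model(), medium, pfba=False).objective_value
        assert reduced >= 0.9 * parent - 1e-6


def test_flagged_set_monotone_in_quantile(toy_model):
    medium = toy_minimal_medium(carbon="EX_hb3_e")
    profile = _profile_for(toy_model, off=("glk_toy", "thnN_toy"))
    flagged = []
    for q in (0.1, 0.25, 0.4):
        cond = build_condition_model(toy_model, profile, medium, quantile=q)
        flagged.append(cond.flagged_reactions)
    assert flagged[0] <= flagged[1] <= flagged[2]


def test_removed_must_be_subset_of_flagged(toy_model):
    with pytest.raises(ValueError, match="subset"):
        ConditionModel(toy_model, "x", 1.0, flagged_reactions={"TCA"},
                       removed_reactions={"PPS"},
                       required_objective_fraction=0.9)


def test_isocitrate_lyase_essential_only_in_condition_model(toy_model):
    """On lactate the glyoxylate-shunt gene has a redundant partner route
    in the parent model, but once transcriptomics silences that route the
    gene becomes conditionally essential."""
    medium = toy_minimal_medium(carbon="EX_lac_e")
    parent_res = {r.gene_id: r.essential for r in gene_deletion_screen(
        toy_model, medium, genes=["aceA_toy"])}
    assert parent_res["aceA_toy"] is False
    cond = build_condition_model(
        toy_model, _profile_for(toy_model, off=("ppsA_toy",)), medium)
    cond_res = {r.gene_id: r.essential for r in conditional_essentiality(
        cond, medium, genes=["aceA_toy"])}
    assert cond_res["aceA_toy"] is True


def test_all_high_conditional_equals_unconditional(toy_model, aerobic_hb3):
    cond = build_condition_model(
        toy_model, _profile_for(toy_model, off=()), aerobic_hb3)
    uncond = {r.gene_id: r.essential
              for r in gene_deletion_screen(toy_model, aerobic_hb3)}
    conditional = {r.gene_id: r.essential
                   for r in conditional_essentiality(cond, aerobic_hb3)}
    assert conditional == uncond


# ---------------------------------------------------------------------------
# ACHR sampling
# ---------------------------------------------------------------------------

def _segment_model(hi=10.0):
    model = MetabolicModel(
        id="segment",
        metabolites=[Metabolite(id="a[c]"), Metabolite(id="b[c]")],
        reactions=[
            Reaction(id="SRC", stoichiometry={"a[c]": 1.0}, kind="sink",
                     lower_bound=0.0, upper_bound=hi),
            Reaction(id="CONV", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="DRAIN", stoichiometry={"b[c]": -1.0}, kind="sink",
                     lower_bound=0.0, upper_bound=1000.0),
        ],
        genes=[])
    model.validate()
    return model


def test_segment_sampling_matches_uniform_mean():
    """The 1-D flux segment v in [0, 10] is sampled with mean ~5
    (analytic uniform mean) within 3 standard errors."""
    model = _segment_model()
    samples = sample_flux_space(model, n_samples=3000, seed=11,
                                warmup=300, thinning=5)
    col = samples.column("CONV")
    se = col.std(ddof=1) / np.sqrt(len(col))
    assert abs(col.mean() - 5.0) < 3 * se + 0.15


def test_samples_are_feasible(toy_model, aerobic_hb3):
    samples = sample_flux_space(toy_model, n_samples=200, seed=5,
                                warmup=200, thinning=5, medium=aerobic_hb3)
    S = build_stoichiometric_matrix(toy_model, dense=True)
    lb, ub = effective_bounds(toy_model, aerobic_hb3)
    lb = np.maximum(lb, -1000.0)
    ub = np.minimum(ub, 1000.0)
    for row in samples.samples:
        assert np.max(np.abs(S @ row)) < 1e-6
        assert np.all(row >= lb - 1e-6) and np.all(row <= ub + 1e-6)


def test_sampling_is_deterministic_given_seed():
    model = _segment_model()
    a = sample_flux_space(model, 50, seed=3, warmup=50, thinning=2)
    b = sample_flux_space(model, 50, seed=3, warmup=50, thinning=2)
    np.testing.assert_array_equal(a.samples, b.samples)
    c = sample_flux_space(model, 50, seed=4, warmup=50, thinning=2)
    assert not np.array_equal(a.samples, c.samples)


def test_point_polytope_gives_identical_samples():
    model = _segment_model()
    for rxn in list(model.reactions):
        model.set_reaction(rxn.with_bounds(2.0, 2.0))
    samples = sample_flux_space(model, 20, seed=1, warmup=10, thinning=1)
    assert np.allclose(samples.samples, 2.0, atol=1e-6)


def test_condition_model_narrows_sampled_ranges(toy_model):
    """Removing the silent route shrinks the sampled flux range of the
    affected reaction to zero while the parent still explores it."""
    medium = toy_minimal_medium(carbon="EX_lac_e")
    cond = build_condition_model(
        toy_model, _profile_for(toy_model, off=("aceA_toy",)), medium)
    parent_samples = sample_flux_space(toy_model, 100, seed=2, warmup=100,
                                       thinning=3, medium=medium)
    cond_samples = sample_flux_space(cond.to_model(), 100, seed=2, warmup=100,
                                     thinning=3, medium=medium)
    span = lambda s, rid: float(np.ptp(s.column(rid)))
    assert span(cond_samples, "GLYOX") < 1e-6
    assert span(parent_samples, "GLYOX") > 1e-3


# ---------------------------------------------------------------------------
# Flux ratios
# ---------------------------------------------------------------------------

def test_flux_ratio_uptake_is_one(toy_model, aerobic_hb3):
    sol = solve_fba(toy_model, aerobic_hb3)
    ratios = flux_ratio_map(sol, "EX_hb3_e")
    assert ratios["EX_hb3_e"] == pytest.approx(1.0)


def test_flux_ratio_unit_chain(chain_model):
    sol = solve_fba(chain_model, None, "biomass_aerobic")
    ratios = flux_ratio_map(sol, "EX_s_e")
    assert ratios["T_s"] == pytest.approx(1.0)
    assert ratios["GROW"] == pytest.approx(1.0)


def test_flux_ratio_branch_split():
    """A 70/30 branch node yields ratios 0.7 and 0.3 (LP with the split
    fixed by bounds)."""
    model = MetabolicModel(
        id="branch",
        metabolites=[Metabolite(id="a[c]"), Metabolite(id="b[c]"),
                     Metabolite(id="c[c]")],
        reactions=[
            Reaction(id="IN", stoichiometry={"a[c]": 1.0}, kind="sink",
                     lower_bound=10.0, upper_bound=10.0),
            Reaction(id="TOP", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                     lower_bound=0.0, upper_bound=7.0),
            Reaction(id="BOT", stoichiometry={"a[c]": -1.0, "c[c]": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="OUT_B", stoichiometry={"b[c]": -1.0}, kind="sink",
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="OUT_C", stoichiometry={"c[c]": -1.0}, kind="sink",
                     lower_bound=0.0, upper_bound=1000.0),
        ],
        genes=[], objectives={"top": "TOP"})
    sol = solve_fba(model, None, "top")
    ratios = flux_ratio_map(sol, "IN")
    assert ratios["TOP"] == pytest.approx(0.7)
    assert ratios["BOT"] == pytest.approx(0.3)


def test_flux_ratio_zero_uptake_is_an_error(toy_model, aerobic_hb3):
    sol = solve_fba(toy_model, aerobic_hb3)
    with pytest.raises(ValueError, match="zero"):
        flux_ratio_map(sol, "EX_glc_e")
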