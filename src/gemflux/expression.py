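"""Transcriptome integration: GIMME condition-specific models, flux
sampling and flux-ratio maps.

The GIMME-style procedure flags every reaction whose GPR-level
expression falls below a cut-off (by default the first quartile of all
FPKM values in the profile), then finds a flux distribution that
minimizes the total flux carried by flagged reactions while still
attaining a required fraction of the parent model's optimal objective.
Flagged reactions that carry no flux in that penalty solution are
removed (bounds pinned to zero), yielding a condition-specific model
that is guaranteed to reach the required objective fraction.

Mapping gene FPKM to reactions follows the standard convention:
AND-joined genes (enzyme complexes) take the minimum of their children,
OR-joined genes (isozymes) the maximum.  Genes without data are neutral
— they propagate the other child's value and never flag a reaction on
their own; orphan reactions have no expression and are never removed.

The feasible flux space of a (condition) model is explored with an
artificially-centered hit-and-run (ACHR) walk, and flux-ratio maps
normalize each reaction's flux by the carbon uptake flux so that flux
routing can be compared across substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.linalg import null_space
from scipy.optimize import linprog

from .core import (
    GprAnd,
    GprGene,
    GprOr,
    MetabolicModel,
    build_stoichiometric_matrix,
)
from .fba import _LP_OPTIONS, FluxSolution, effective_bounds, gene_deletion_screen, solve_fba
from .io import ExpressionProfile, MediumSpec

__all__ = [
    "ConditionModel",
    "FluxSampleSet",
    "fpkm_threshold",
    "reaction_expression",
    "build_condition_model",
    "conditional_essentiality",
    "sample_flux_space",
    "flux_ratio_map",
]


# ---------------------------------------------------------------------------
# Expression thresholds and GPR-level expression
# ---------------------------------------------------------------------------

def fpkm_threshold(profile: ExpressionProfile, quantile: float = 0.25) -> float:
    """Expression cut-off: a quantile of all FPKM values in the profile.

    The first quartile (quantile = 0.25) is the default cut-off below
    which a gene counts as unexpressed.  Quantiles use linear
    interpolation between order statistics, so {1,2,3,4} → 1.75.  At
    least four genes with data are required for a quartile to be
    meaningful.
    """
    values = profile.values()
    if len(values) < 4:
        raise ValueError(
            f"profile {profile.condition!r} has {len(values)} genes with "
            f"data; need at least 4 to take a quantile")
    return float(np.quantile(np.asarray(values, dtype=float), quantile,
                             method="linear"))


def reaction_expression(gpr, profile: ExpressionProfile) -> Optional[float]:
    """Expression of a reaction from its GPR (None = no data).

    AND = min of children (a complex is limited by its scarcest
    subunit), OR = max (isozymes add capacity); children without data
    are skipped rather than treated as zero.
    """
    if gpr is None:
        return None
    if isinstance(gpr, GprGene):
        return profile.get(gpr.gene)
    values = [reaction_expression(c, profile) for c in gpr.children]
    values = [v for v in values if v is not None]
    if not values:
        return None
    if isinstance(gpr, GprAnd):
        return min(values)
    if isinstance(gpr, GprOr):
        return max(values)
    raise TypeError(f"not a GPR node: {gpr!r}")


# ---------------------------------------------------------------------------
# GIMME condition-specific models
# ---------------------------------------------------------------------------

@dataclass
class ConditionModel:
    """A parent model specialized to one growth condition."""

    parent: MetabolicModel
    condition: str
    fpkm_threshold: float
    flagged_reactions: set
    removed_reactions: set
    required_objective_fraction: float
    objective_name: str = "biomass_aerobic"

    def __post_init__(self):
        if not self.removed_reactions <= self.flagged_reactions:
            raise ValueError("removed reactions must be a subset of flagged")

    def to_model(self) -> MetabolicModel:
        """Materialize: the parent with removed reactions closed (0, 0)."""
        model = self.parent.copy()
        model.id = f"{self.parent.id}__{self.condition}"
        for rid in self.removed_reactions:
            model.set_reaction(model.get_reaction(rid).with_bounds(0.0, 0.0))
        return model


def build_condition_model(model: MetabolicModel, profile: ExpressionProfile,
                          medium: MediumSpec, quantile: float = 0.25,
                          required_objective_fraction: float = 0.9,
                          objective_name: str = "biomass_aerobic",
                          flux_zero_tol: float = 1e-8) -> ConditionModel:
    """GIMME-style reduction of a model with an expression profile.

    Reactions whose GPR expression is below the quantile cut-off are
    flagged; an LP minimizes the total absolute flux through flagged
    reactions subject to the objective reaching at least
    ``required_objective_fraction`` of the parent optimum; flagged
    reactions with zero flux in that solution are removed.
    """
    if not 0 < required_objective_fraction <= 1:
        raise ValueError("required_objective_fraction must be in (0, 1]")
    parent_sol = solve_fba(model, medium, objective_name, pfba=False)
    if not parent_sol.optimal:
        raise ValueError("parent model FBA is not optimal on this medium")
    parent_opt = parent_sol.objective_value

    threshold = fpkm_threshold(profile, quantile)
    flagged = set()
    for r in model.reactions:
        expr = reaction_expression(r.gpr, profile)
        if expr is not None and expr < threshold:
            flagged.add(r.id)

    S = build_stoichiometric_matrix(model)
    lb, ub = effective_bounds(model, medium)
    ridx = model.reaction_index()
    j_obj = ridx[model.objectives.get(objective_name, objective_name)]
    floor = required_objective_fraction * parent_opt
    lb = lb.copy()
    lb[j_obj] = max(lb[j_obj], floor - 1e-9)

    n = len(model.reactions)
    # v = p - n split; penalty 1 on flagged reactions' absolute flux
    p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    n_lo, n_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    cost = np.zeros(2 * n)
    for rid in flagged:
        cost[ridx[rid]] = 1.0
        cost[n + ridx[rid]] = 1.0
    S2 = sparse.hstack([S, -S]).tocsr()
    res = linprog(cost, A_eq=S2, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([np.concatenate([p_lo, n_lo]),
                                          np.concatenate([p_hi, n_hi])]),
                  method="highs", options=_LP_OPTIONS)
    if not res.success:
        raise ValueError(
            f"no feasible flux at {required_objective_fraction:.0%} of the "
            f"parent optimum {parent_opt:.6g}; maximum attainable fraction "
            f"is below the requirement")
    v = res.x[:n] - res.x[n:]
    removed = {rid for rid in flagged if abs(v[ridx[rid]]) < flux_zero_tol}

    cond = ConditionModel(model, profile.condition, threshold, flagged,
                          removed, required_objective_fraction, objective_name)
    # invariant: the reduced model still attains the required fraction
    check = solve_fba(cond.to_model(), medium, objective_name, pfba=False)
    if not check.optimal or check.objective_value < floor - 1e-6:
        raise ValueError(
            f"condition model lost feasibility: attains "
            f"{check.objective_value:.6g} < {floor:.6g}")
    return cond


def conditional_essentiality(condition_model: ConditionModel,
                             medium: MediumSpec,
                             genes: Optional[Iterable[str]] = None,
                             objective_name: Optional[str] = None):
    """Single-gene deletion screen on a condition-specific model."""
    return gene_deletion_screen(
        condition_model.to_model(), medium, genes,
        objective_name or condition_model.objective_name)


# ---------------------------------------------------------------------------
# ACHR flux sampling
# ---------------------------------------------------------------------------

@dataclass
class FluxSampleSet:
    samples: np.ndarray  # n_samples x n_reactions
    reaction_ids: list
    seed: int
    warmup: int
    thinning: int

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def mean(self) -> dict:
        mu = self.samples.mean(axis=0)
        return dict(zip(self.reaction_ids, mu))


def sample_flux_space(model: MetabolicModel, n_samples: int, seed: int,
                      warmup: int = 1000, thinning: int = 100,
                      medium: Optional[MediumSpec] = None,
                      bound_clip: float = 1000.0) -> FluxSampleSet:
    """Uniform-ish sampling of the steady-state flux polytope by ACHR.

    Warm-up points come from per-reaction flux minimization/maximization
    (FVA corners); the walk then repeatedly steps from the current point
    along the direction towards a random warm-up point relative to the
    running center, with the step length drawn uniformly from the
    feasible segment.  The first ``warmup`` steps are discarded and one
    sample is kept every ``thinning`` steps.  Deterministic given
    ``seed``.  Unbounded directions are pre-clipped at ±``bound_clip``.
    """
    rng = np.random.default_rng(seed)
    S = build_stoichiometric_matrix(model, dense=True)
    lb, ub = effective_bounds(model, medium)
    lb = np.maximum(lb, -bound_clip)
    ub = np.minimum(ub, bound_clip)
    n = len(lb)

    N = null_space(S) if S.size else np.eye(n)
    if N.size == 0:
        raise ValueError("flux space is a single point or empty (no null space)")

    def optimize(c):
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs",
                      options=_LP_OPTIONS)
        if not res.success:
            raise ValueError(f"infeasible model: cannot sample ({res.message})")
        return res.x

    warm = []
    order = rng.permutation(n)
    for j in order[: max(2, min(n, 50))]:
        for sgn in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sgn
            warm.append(optimize(c))
    warm = np.array(warm)
    # clean numerical noise: project onto the null space, clamp to bounds
    warm = warm @ N @ N.T
    warm = np.clip(warm, lb, ub)

    center = warm.mean(axis=0)
    if np.max(np.abs(warm - center)) < 1e-9:
        # point polytope (all bounds pinned): every sample is that point
        return FluxSampleSet(np.tile(center, (n_samples, 1)),
                             [r.id for r in model.reactions],
                             seed, warmup, thinning)
    x = center.copy()
    n_kept = 0
    samples = np.empty((n_samples, n))
    step = 0
    total_steps = warmup + n_samples * thinning
    count = len(warm)
    eps = 1e-12
    while n_kept < n_samples:
        w = warm[rng.integers(len(warm))]
        d = w - center
        d = N @ (N.T @ d)
        norm = np.linalg.norm(d)
        if norm < eps:
            step += 1
            continue
        d /= norm
        with np.errstate(divide="ignore", invalid="ignore"):
            a_lo = (lb - x) / d
            a_hi = (ub - x) / d
        mask = np.abs(d) > 1e-10
        lows = np.where(d[mask] > 0, a_lo[mask], a_hi[mask])
        highs = np.where(d[mask] > 0, a_hi[mask], a_lo[mask])
        alpha_min = lows.max(initial=-np.inf)
        alpha_max = highs.min(initial=np.inf)
        if not np.isfinite(alpha_min) or not np.isfinite(alpha_max) or \
                alpha_max < alpha_min:
            step += 1
            continue
        alpha = rng.uniform(alpha_min, alpha_max)
        x = x + alpha * d
        x = np.clip(x, lb, ub)
        count += 1
        center = center + (x - center) / count
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            samples[n_kept] = N @ (N.T @ x)
            n_kept += 1
        if step > 100 * total_steps + 1000:  # safety net for degenerate walks
            raise RuntimeError("ACHR walk failed to advance")
    return FluxSampleSet(samples, [r.id for r in model.reactions],
                         seed, warmup, thinning)


# ---------------------------------------------------------------------------
# Flux-ratio maps
# ---------------------------------------------------------------------------

def flux_ratio_map(solution: FluxSolution, carbon_exchange_id: str,
                   reactions: Optional[Sequence[str]] = None,
                   tol: float = 1e-9) -> dict:
    """Flux ratios |v_reaction| / |carbon uptake flux|.

    Dimensionless; the carbon uptake reaction itself maps to 1.  Raises
    if the carbon uptake flux is (numerically) zero.
    """
    uptake = solution.fluxes.get(carbon_exchange_id)
    if uptake is None:
        raise KeyError(carbon_exchange_id)
    if abs(uptake) < tol:
        raise ValueError(
            f"carbon uptake flux through {carbon_exchange_id} is zero; "
            f"flux ratios are undefined")
    rids = reactions if reactions is not None else list(solution.fluxes)
    return {rid: abs(solution.fluxes[rid]) / abs(uptake) for rid in rids}
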