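"""Steady-state constraint-based analyses.

Flux balance analysis (FBA) maximizes an objective flux — normally the
biomass pseudo-reaction, whose flux is the specific growth rate in h⁻¹ —
subject to the steady-state constraint S·v = 0 and per-reaction flux
bounds.  LPs are solved with HiGHS (scipy.optimize.linprog).

Because optimal flux vectors are usually degenerate, reported flux
distributions are post-processed by a second LP that minimizes the sum
of absolute fluxes at the fixed optimal objective (a pFBA-style
tie-break), so downstream flux-ratio maps are reproducible.  The
objective value itself is always taken from the first LP.

Built on top of FBA are: carbon/nitrogen source screening, inverse
fitting of an uptake rate to an observed growth rate, single-gene
deletion (essentiality) screens, storage-polymer demand sweeps and
oxygen-limited substrate hierarchies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicModel, build_stoichiometric_matrix, evaluate_gpr
from .io import MediumSpec

__all__ = [
    "FluxSolution",
    "SourceScreenResult",
    "EssentialityResult",
    "GROWTH_TOLERANCE",
    "solve_fba",
    "screen_sources",
    "fit_uptake_to_growth",
    "gene_deletion_screen",
    "phb_demand_sweep",
    "substrate_hierarchy",
]

#: growth below this (h⁻¹) counts as "no growth" for grows/essential calls
GROWTH_TOLERANCE = 1e-6

_LP_OPTIONS = {"primal_feasibility_tolerance": 1e-10,
               "dual_feasibility_tolerance": 1e-10}


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class SourceScreenResult:
    exchange_id: str
    role: str  # C | N | CN
    growth_rate: float
    grows: bool
    growth_per_carbon: Optional[float] = None  # h⁻¹ per carbon atom


@dataclass
class EssentialityResult:
    gene_id: str
    wild_type_growth: float
    deletion_growth: float
    essential: bool


# ---------------------------------------------------------------------------
# Bound assembly and raw LP layer
# ---------------------------------------------------------------------------

def effective_bounds(model: MetabolicModel, medium: Optional[MediumSpec],
                     extra_bounds: Optional[Mapping] = None):
    """Per-reaction (lb, ub) arrays after applying a medium and overrides.

    Exchanges listed in the medium take its bounds; all other exchanges
    are closed to uptake (lb = 0, paper bound scheme: nothing enters
    unless the medium supplies it) while keeping their secretion bound.
    A medium-level NGAM value pins the maintenance reaction's flux.
    """
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    ridx = model.reaction_index()
    if medium is not None:
        for j, r in enumerate(model.reactions):
            if r.kind == "exchange":
                if r.id in medium.bounds:
                    lb[j], ub[j] = medium.bounds[r.id]
                else:
                    lb[j] = max(lb[j], 0.0)
        if medium.ngam is not None and model.ngam_reaction_id is not None:
            j = ridx[model.ngam_reaction_id]
            lb[j] = ub[j] = float(medium.ngam)
    if extra_bounds:
        for rid, (blo, bhi) in extra_bounds.items():
            j = ridx[rid]
            lb[j], ub[j] = blo, bhi
    return lb, ub


def _linprog(c, S, lb, ub):
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs",
                  options=_LP_OPTIONS)
    return res


def _maximize(S, lb, ub, j_obj: int):
    n = len(lb)
    c = np.zeros(n)
    c[j_obj] = -1.0
    res = _linprog(c, S, lb, ub)
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    if not res.success:
        return "infeasible", None, None
    return "optimal", -res.fun, res.x


def _minimize_total_flux(S, lb, ub, j_obj: int, obj_value: float,
                         slack: float = 1e-9):
    """pFBA tie-break: min Σ|v| with the objective flux held at its optimum."""
    n = len(lb)
    lb = lb.copy()
    ub = ub.copy()
    lb[j_obj] = obj_value - abs(obj_value) * 1e-9 - slack
    ub[j_obj] = max(ub[j_obj], obj_value)
    # split v = p - n with p, n >= 0; ranges chosen so p - n spans [lb, ub]
    p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    n_lo, n_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    S2 = sparse.hstack([S, -S]).tocsr() if sparse.issparse(S) else \
        np.hstack([S, -S])
    c = np.ones(2 * n)
    res = linprog(c, A_eq=S2, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([np.concatenate([p_lo, n_lo]),
                                          np.concatenate([p_hi, n_hi])]),
                  method="highs", options=_LP_OPTIONS)
    if not res.success:
        return None
    return res.x[:n] - res.x[n:]


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def solve_fba(model: MetabolicModel, medium: Optional[MediumSpec] = None,
              objective_name: str = "biomass_aerobic",
              extra_bounds: Optional[Mapping] = None,
              pfba: bool = True) -> FluxSolution:
    """Maximize the named objective flux subject to S·v = 0 and bounds.

    ``extra_bounds`` overrides individual reaction bounds after the
    medium is applied (e.g. fixing a measured uptake).  With ``pfba``
    (default) the returned flux vector additionally minimizes the total
    absolute flux at the optimal objective, yielding a unique
    representative distribution; the objective value is from the first
    LP either way.
    """
    if objective_name in model.objectives:
        obj_rid = model.objectives[objective_name]
    elif objective_name in model.reaction_index():
        obj_rid = objective_name  # allow addressing a reaction directly
    else:
        raise KeyError(f"unknown objective {objective_name!r}; model has "
                       f"{sorted(model.objectives)}")
    S = build_stoichiometric_matrix(model)
    lb, ub = effective_bounds(model, medium, extra_bounds)
    j = model.reaction_index()[obj_rid]
    status, value, x = _maximize(S, lb, ub, j)
    if status != "optimal":
        return FluxSolution(status, 0.0, {})
    if pfba:
        x2 = _minimize_total_flux(S, lb, ub, j, value)
        if x2 is not None:
            x = x2
    fluxes = {r.id: float(x[k]) for k, r in enumerate(model.reactions)}
    return FluxSolution("optimal", float(value), fluxes)


# ---------------------------------------------------------------------------
# Carbon / nitrogen source screening
# ---------------------------------------------------------------------------

def carbon_count(model: MetabolicModel, exchange_id: str) -> Optional[float]:
    """Carbon atoms of the metabolite moved by an exchange reaction."""
    rxn = model.get_reaction(exchange_id)
    (mid,) = rxn.stoichiometry
    formula = model.get_metabolite(mid).formula
    if formula is None:
        return None
    return formula.get("C", 0.0)


def screen_sources(model: MetabolicModel, base_medium: MediumSpec,
                   role: str = "C",
                   candidates: Optional[Sequence[str]] = None,
                   test_uptake: float = -10.0,
                   background_uptake: float = -30.0,
                   objective_name: str = "biomass_aerobic",
                   growth_tolerance: float = GROWTH_TOLERANCE):
    """Sequentially test exchanges as carbon (C), nitrogen (N) or C+N sources.

    The candidate's uptake is opened to −10 mmol·gDW⁻¹·h⁻¹ while every
    remaining background nutrient of the minimal medium (oxygen included)
    is allowed up to −30, so that nothing but the tested source limits
    growth.  For role C the medium's default carbon source is removed
    from the background; for role N ammonium (the medium's nitrogen
    source) is omitted; CN removes both.  Growth per carbon atom is
    reported for C-containing candidates.
    """
    if role not in ("C", "N", "CN"):
        raise ValueError(f"role must be C, N or CN, got {role!r}")
    removed = set()
    if "C" in role and base_medium.carbon_source:
        removed.add(base_medium.carbon_source)
    if "N" in role and base_medium.nitrogen_source:
        removed.add(base_medium.nitrogen_source)

    background = base_medium.without(removed)
    background.bounds = {
        rid: (min(lb, background_uptake) if lb < 0 else lb, ub)
        for rid, (lb, ub) in background.bounds.items()}

    if candidates is None:
        candidates = [r.id for r in model.exchanges()
                      if r.id not in background.bounds]

    results = []
    for rid in candidates:
        medium = background.with_bound(rid, test_uptake, 1000.0)
        sol = solve_fba(model, medium, objective_name, pfba=False)
        growth = sol.objective_value if sol.optimal else 0.0
        grows = growth > growth_tolerance
        gpc = None
        if "C" in role:
            n_c = carbon_count(model, rid)
            if n_c is None:
                warnings.warn(f"{rid}: metabolite formula unknown, cannot "
                              f"normalize growth per carbon", stacklevel=2)
            elif n_c > 0:
                gpc = growth / n_c
        results.append(SourceScreenResult(rid, role, growth, grows, gpc))
    return results


# ---------------------------------------------------------------------------
# Inverse uptake fitting
# ---------------------------------------------------------------------------

def fit_uptake_to_growth(model: MetabolicModel, medium: MediumSpec,
                         exchange_id: str, target_growth: float,
                         tol: float = 1e-5, max_uptake: float = 100.0,
                         objective_name: str = "biomass_aerobic") -> float:
    """Smallest uptake magnitude u with FBA growth equal to the target.

    Bisection on u with the exchange's lower bound set to −u.  Growth is
    monotone non-decreasing in u (verified by probing the endpoints);
    the returned rate is negative (uptake), in mmol·gDW⁻¹·h⁻¹.
    """
    if target_growth < 0:
        raise ValueError("target growth must be non-negative")

    def growth(u: float) -> float:
        m = medium.with_bound(exchange_id, -u, 1000.0)
        sol = solve_fba(model, m, objective_name, pfba=False)
        return sol.objective_value if sol.optimal else 0.0

    g_lo, g_hi = growth(0.0), growth(max_uptake)
    if g_hi < g_lo - 1e-9:
        raise ValueError(f"growth not monotone in {exchange_id} uptake")
    if target_growth > g_hi + tol:
        raise ValueError(
            f"target growth {target_growth} unreachable: max attainable at "
            f"uptake {max_uptake} is {g_hi:.6g}")
    if target_growth <= g_lo:
        return 0.0
    # bisect for the smallest u with growth(u) >= target (growth is
    # continuous and monotone, so growth(u*) = target at the boundary)
    lo, hi = 0.0, max_uptake
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if growth(mid) >= target_growth:
            hi = mid
        else:
            lo = mid
        if hi - lo <= max(tol * 1e-2, 1e-12):
            break
    return -hi


# ---------------------------------------------------------------------------
# Gene essentiality
# ---------------------------------------------------------------------------

def gene_deletion_screen(model: MetabolicModel, medium: MediumSpec,
                         genes: Optional[Iterable[str]] = None,
                         objective_name: str = "biomass_aerobic",
                         growth_tolerance: float = GROWTH_TOLERANCE):
    """Single-gene deletion screen.

    Deleting a gene closes (bounds 0,0) every reaction whose GPR
    evaluates false without it; growth below the absolute tolerance
    calls the gene essential (binary growth/no-growth, not a wild-type
    fraction).  Orphan reactions are never switched off.
    """
    wt = solve_fba(model, medium, objective_name, pfba=False)
    if not wt.optimal:
        raise ValueError("wild-type FBA is not optimal; cannot screen")
    results = []
    for gene in (genes if genes is not None else model.genes):
        knocked = [r.id for r in model.reactions
                   if gene in r.genes and not evaluate_gpr(r.gpr, {gene})]
        if not knocked:
            growth = wt.objective_value
        else:
            sol = solve_fba(model, medium, objective_name,
                            extra_bounds={rid: (0.0, 0.0) for rid in knocked},
                            pfba=False)
            growth = sol.objective_value if sol.optimal else 0.0
        growth = min(growth, wt.objective_value + 1e-9)
        results.append(EssentialityResult(
            gene, wt.objective_value, growth, growth < growth_tolerance))
    return results


# ---------------------------------------------------------------------------
# Storage-polymer demand sweep and O2-limited substrate hierarchy
# ---------------------------------------------------------------------------

def phb_demand_sweep(model: MetabolicModel, medium: MediumSpec,
                     demand_fluxes: Sequence[float],
                     demand_reaction: str = "DM_phb",
                     objective_name: str = "biomass_aerobic"):
    """Growth as a function of a forced storage-polymer (PHB) drain.

    Each demand value is imposed as a fixed flux through the demand
    reaction; diverting carbon into the polymer monotonically reduces
    the attainable growth rate.  Returns (demand, growth, status) rows;
    infeasible demands record growth 0.
    """
    model.get_reaction(demand_reaction)  # KeyError if absent
    rows = []
    for d in demand_fluxes:
        sol = solve_fba(model, medium, objective_name,
                        extra_bounds={demand_reaction: (d, d)}, pfba=False)
        rows.append((float(d),
                     sol.objective_value if sol.optimal else 0.0,
                     sol.status))
    return rows


def substrate_hierarchy(model: MetabolicModel, medium: MediumSpec,
                        substrates: Sequence[str], o2_lb: float,
                        uptake_bound: float = -10.0,
                        objective_name: str = "biomass_aerobic") -> dict:
    """Preferred-substrate analysis under an oxygen-limited budget.

    All substrates are offered simultaneously (each uptake opened to
    ``uptake_bound``) while the O2 exchange lower bound is pinned at
    ``o2_lb``; the FBA optimum (with the total-flux tie-break) reports
    how the oxygen budget is allocated between them.  Returns the
    realized exchange flux per substrate (negative = uptake).
    """
    m = medium
    for rid in substrates:
        m = m.with_bound(rid, uptake_bound, 1000.0)
    lb_o2, ub_o2 = m.bounds.get(m.o2_exchange, (0.0, 1000.0))
    m.bounds[m.o2_exchange] = (o2_lb, ub_o2)
    sol = solve_fba(model, m, objective_name, pfba=True)
    if not sol.optimal:
        return {rid: 0.0 for rid in substrates}
    return {rid: sol.fluxes[rid] for rid in substrates}
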