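"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they verify: LP optima are found
by brute-force vertex enumeration, GPR rules by truth-table recursion
over raw tuples, and batch depletion times by the closed-form solution
of exponential growth at constant specific uptake.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_lp_max(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                     c: np.ndarray, tol: float = 1e-7):
    """Maximum of c·v over {v: S v = 0, lb <= v <= ub} by vertex enumeration.

    Every vertex of the (bounded) polytope fixes n - rank(S) variables
    at a bound while the rest solve the equality system uniquely; all
    such candidates are enumerated and filtered for feasibility.
    Returns None when the polytope is empty.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue  # no unique solution for the free block
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            x = np.empty(n)
            for j, val in zip(fixed, choice):
                x[j] = val
            if free:
                b = -S[:, fixed] @ np.array(choice) if fixed else np.zeros(S.shape[0])
                sol, residual, *_ = np.linalg.lstsq(A, b, rcond=None)
                x[free] = sol
            if np.max(np.abs(S @ x)) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            val = float(c @ x)
            if best is None or val > best:
                best = val
    return best


def truth_table_gpr(expr, deleted) -> bool:
    """Evaluate a tuple-encoded GPR: ('gene', g) | ('and'|'or', [children])
    | None, by plain recursion."""
    if expr is None:
        return True
    op, payload = expr
    if op == "gene":
        return payload not in deleted
    values = [truth_table_gpr(child, deleted) for child in payload]
    return all(values) if op == "and" else any(values)


def batch_depletion_time(c0: float, q: float, x0: float, mu: float) -> float:
    """Time until a substrate at c0 mM is exhausted by a culture growing
    exponentially from x0 g/L at rate mu h⁻¹ with constant specific
    uptake q mmol·gDW⁻¹·h⁻¹ (positive magnitude):
    c0 = q·x0·(e^{mu t} - 1)/mu."""
    if mu <= 0:
        return c0 / (q * x0)
    return math.log(1.0 + c0 * mu / (q * x0)) / mu
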