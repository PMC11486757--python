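"""Exact verification utilities for small flux networks.

For networks with a handful of reactions the FBA polytope
{v : S·v = 0, lb <= v <= ub} is small enough to enumerate all of its
vertices directly: a vertex has (n - rank S) fluxes pinned at a bound and
the rest determined by the steady-state equations.  The enumeration is
independent of any LP solver and serves to verify solver results on toy
models — it is exponential in the reaction count and is deliberately
refused for larger networks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .fba_core import build_stoichiometric_matrix
from .model_io import MetabolicModel

__all__ = ["enumerate_vertices", "brute_force_fba", "alternative_optima_total_flux"]

_MAX_REACTIONS = 12


def enumerate_vertices(model: MetabolicModel, *, tol: float = 1e-9) -> list[np.ndarray]:
    """All vertices of the flux polytope of a small model.

    For every choice of n - rank(S) fluxes pinned at a finite bound, solves
    the steady-state system for the remaining fluxes and keeps consistent,
    bound-feasible solutions.  Duplicate vertices are merged.
    """
    n = len(model.reactions)
    if n > _MAX_REACTIONS:
        raise ValueError(f"vertex enumeration limited to {_MAX_REACTIONS} reactions, got {n}")
    S = build_stoichiometric_matrix(model)
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    n_pinned = n - rank

    vertices: list[np.ndarray] = []
    for pinned in combinations(range(n), n_pinned):
        free = [j for j in range(n) if j not in pinned]
        choices = []
        for j in pinned:
            opts = [b for b in (lb[j], ub[j]) if np.isfinite(b)]
            if not opts:
                opts = []
            choices.append(sorted(set(opts)))
        if any(not c for c in choices):
            continue
        S_free = S[:, free]
        for assignment in product(*choices):
            rhs = -S[:, pinned] @ np.array(assignment) if pinned else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            else:
                sol = np.zeros(0)
            v = np.zeros(n)
            v[list(pinned)] = assignment
            v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue  # pinned assignment inconsistent with steady state
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            v = np.clip(v, lb, ub)
            if not any(np.allclose(v, w, atol=10 * tol) for w in vertices):
                vertices.append(v)
    return vertices


def brute_force_fba(model: MetabolicModel) -> tuple[float, np.ndarray]:
    """Exact FBA optimum of a small model by vertex enumeration.

    Returns (objective value, maximizing vertex).  The LP optimum of a
    bounded feasible LP is attained at a vertex, so the maximum over the
    enumerated vertices is the exact optimum.
    """
    verts = enumerate_vertices(model)
    if not verts:
        raise ValueError("flux polytope has no vertices (infeasible or unbounded model)")
    ids = model.reaction_ids()
    j = ids.index(model.objective_id)
    best = max(verts, key=lambda v: v[j])
    return float(best[j]), best


def alternative_optima_total_flux(
    model: MetabolicModel,
    optimum: float,
    *,
    n_perturbations: int = 100,
    seed: int = 0,
) -> list[float]:
    """Total |v| of alternative optimal flux vectors found by random secondary objectives.

    Fixes the primary objective flux at its optimum and optimizes random
    linear objectives over the remaining optimal face; the resulting
    vertices are alternative optima whose Σ|v| any parsimonious solution
    must not exceed.
    """
    from scipy.optimize import linprog

    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    ids = model.reaction_ids()
    c_obj = np.zeros(n)
    c_obj[ids.index(model.objective_id)] = 1.0
    A_eq = np.vstack([S, c_obj[None, :]])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [optimum]])
    rng = np.random.default_rng(seed)
    totals: list[float] = []
    for _ in range(n_perturbations):
        c_rand = rng.normal(size=n)
        res = linprog(c_rand, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status == 0:
            totals.append(float(np.abs(res.x).sum()))
    return totals
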