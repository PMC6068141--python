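"""Exhaustive vertex-enumeration oracle for small flux polytopes.

Independent of the LP solver path: enumerates every basic solution of
{S v = 0, lb <= v <= ub} by fixing (n - rank(S)) variables at a bound and
solving the remaining square system, then maximizes the objective over the
feasible vertices.  Exponential, so only usable on fixtures with a handful
of reactions — which is the point.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

FEAS_TOL = 1e-8


def enumerate_vertices(S, lb, ub):
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    n_fix = n - r
    vertices = []
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < len(free):
            continue
        for pattern in product((0, 1), repeat=n_fix):
            v = np.empty(n)
            for j, side in zip(fixed, pattern):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, fixed] @ v[list(fixed)] if n_fix else np.zeros(m)
            x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = x
            if np.linalg.norm(S @ v) > FEAS_TOL:
                continue
            if np.any(v < lb - FEAS_TOL) or np.any(v > ub + FEAS_TOL):
                continue
            vertices.append(v)
    return vertices


def max_objective(S, lb, ub, c):
    """Max of c.v over the flux polytope; None if no vertex is feasible."""
    c = np.asarray(c, dtype=float)
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    return max(float(c @ v) for v in vertices)


def oracle_biomass(model, state=None):
    """Vertex-enumeration optimum of a model's biomass reaction.

    ``state`` may be a ConstrainedState whose bounds replace the model's.
    """
    S = model.S
    ids = model.reaction_ids
    lb = np.array([model.cobra.reactions.get_by_id(r).lower_bound for r in ids])
    ub = np.array([model.cobra.reactions.get_by_id(r).upper_bound for r in ids])
    if state is not None:
        for i, rid in enumerate(ids):
            c = state.constraints[rid]
            lb[i], ub[i] = c.lb, c.ub
    c = np.zeros(len(ids))
    c[ids.index(model.biomass_reaction_id)] = 1.0
    return max_objective(S, lb, ub, c)
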