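"""Brute-force vertex-enumeration oracle for small flux LPs.

A bounded polyhedron's linear optimum is attained at a vertex, and every
vertex is the unique solution of n linearly independent active constraints.
For networks with a handful of reactions this can be enumerated directly:
the steady-state equalities are always active, and every choice of bound /
inequality rows completing them to rank n is tested for feasibility.  The
result is an independent check on the LP solver — it shares no code path
with :mod:`thermoflux.fba` beyond the stoichiometric matrix itself.
"""

from __future__ import annotations

import itertools

import numpy as np

from .model import MetabolicModel, assemble_stoichiometric_matrix

_FEAS_TOL = 1e-7


def enumerate_vertices(model: MetabolicModel,
                       max_reactions: int = 8) -> list[np.ndarray]:
    """All vertices of the model's flux polytope (small models only)."""
    S, met_ids, rxn_ids = assemble_stoichiometric_matrix(model)
    n = len(rxn_ids)
    if n > max_reactions:
        raise ValueError(f"{n} reactions exceeds enumeration limit "
                         f"{max_reactions}")
    idx = {r: j for j, r in enumerate(rxn_ids)}
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])

    eq_rows = [S[i] for i in range(S.shape[0])]
    eq_rhs = [0.0] * S.shape[0]
    ineq_rows: list[np.ndarray] = []
    ineq_rhs: list[float] = []
    for con in model.extra_constraints:
        row = np.zeros(n)
        for rid, coef in con.coefficients.items():
            row[idx[rid]] = coef
        if con.sense == "==":
            eq_rows.append(row)
            eq_rhs.append(con.rhs)
        elif con.sense == "<=":
            ineq_rows.append(row)
            ineq_rhs.append(con.rhs)
        else:
            ineq_rows.append(-row)
            ineq_rhs.append(-con.rhs)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        ineq_rows.append(e)
        ineq_rhs.append(ub[j])
        ineq_rows.append(-e)
        ineq_rhs.append(-lb[j])

    E = np.array(eq_rows)
    e_rhs = np.array(eq_rhs)
    rank_eq = np.linalg.matrix_rank(E) if len(E) else 0
    n_extra = n - rank_eq
    G = np.array(ineq_rows)
    g_rhs = np.array(ineq_rhs)

    vertices: list[np.ndarray] = []
    for combo in itertools.combinations(range(len(G)), n_extra):
        A = np.vstack([E, G[list(combo)]]) if len(E) else G[list(combo)]
        b = np.concatenate([e_rhs, g_rhs[list(combo)]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, residual, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > _FEAS_TOL:
            continue
        if len(E) and np.max(np.abs(E @ v - e_rhs)) > _FEAS_TOL:
            continue
        if np.any(G @ v - g_rhs > _FEAS_TOL):
            continue
        vertices.append(v)
    return vertices


def brute_force_optimum(model: MetabolicModel,
                        objective_id: str | None = None,
                        sense: str = "max",
                        max_reactions: int = 8) -> float | None:
    """Best objective over all enumerated vertices; None if infeasible."""
    objective_id = objective_id or model.objective_id
    _, _, rxn_ids = assemble_stoichiometric_matrix(model)
    j = rxn_ids.index(objective_id)
    vertices = enumerate_vertices(model, max_reactions)
    if not vertices:
        return None
    values = [v[j] for v in vertices]
    return max(values) if sense == "max" else min(values)
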