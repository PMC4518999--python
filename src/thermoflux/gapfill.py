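"""Minimal-additions gap filling.

Given a draft network that cannot sustain biomass flux and a universal
reaction database, propose the smallest set of database reactions whose
addition restores growth above a threshold.  The selection is a single
mixed-integer program: binary z_r activates universe reaction r by opening
its bounds (lb_r*z_r <= v_r <= ub_r*z_r) inside the combined
draft+universe steady-state system, and the objective minimises the number
(or optional per-reaction cost) of activated reactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, sparse

from .fba import build_lp, solve_fba, _objective_vector, _solve
from .model import MetabolicModel

#: default growth threshold, h^-1
DEFAULT_MIN_GROWTH = 1e-3

INFEASIBLE = "infeasible"
OPTIMAL = "optimal"


@dataclass
class GapfillResult:
    status: str
    added_reactions: frozenset[str] = frozenset()
    achieved_growth: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


def merge_models(draft: MetabolicModel, universe: MetabolicModel
                 ) -> tuple[MetabolicModel, list[str]]:
    """Combine draft and universe into one model; duplicate-id universe
    reactions are dropped.  Returns (combined, universe reaction ids)."""
    combined = draft.copy()
    known_rxns = set(combined.reaction_ids())
    known_mets = set(combined.metabolite_ids())
    added = []
    for met in universe.metabolites:
        if met.id not in known_mets:
            combined.metabolites.append(met)
            known_mets.add(met.id)
    for rxn in universe.reactions:
        if rxn.id in known_rxns:
            continue
        combined.reactions.append(rxn)
        added.append(rxn.id)
    return combined, added


def gapfill(draft: MetabolicModel, universe: MetabolicModel,
            min_growth: float = DEFAULT_MIN_GROWTH,
            costs: Mapping[str, float] | None = None) -> GapfillResult:
    """Smallest (or cheapest) universe addition set restoring growth.

    A feasible draft returns an empty addition set.  When even the full
    universe cannot reach ``min_growth`` the result status is
    ``infeasible``.
    """
    base = solve_fba(draft)
    if base.ok and base.objective_value >= min_growth:
        return GapfillResult(OPTIMAL, frozenset(), base.objective_value)

    combined, univ_ids = merge_models(draft, universe)
    lp = build_lp(combined)
    n = len(lp.rxn_ids)
    nz = len(univ_ids)
    grow = _objective_vector(lp, {combined.objective_id: 1.0})

    nvar = n + nz
    rows, lo, hi = [], [], []
    A_eq_rows = [lp.S]
    if lp.A_extra_eq is not None:
        A_eq_rows.append(lp.A_extra_eq)
    E = np.vstack(A_eq_rows)
    for i in range(E.shape[0]):
        row = np.zeros(nvar)
        row[:n] = E[i]
        rows.append(row)
        lo.append(0.0)
        hi.append(0.0)
    if lp.A_ub is not None:
        for i in range(lp.A_ub.shape[0]):
            row = np.zeros(nvar)
            row[:n] = lp.A_ub[i]
            rows.append(row)
            lo.append(-np.inf)
            hi.append(lp.b_ub[i])
    row = np.zeros(nvar)
    row[:n] = grow
    rows.append(row)
    lo.append(min_growth)
    hi.append(np.inf)

    lbv = lp.lb.copy()
    ubv = lp.ub.copy()
    for t, rid in enumerate(univ_ids):
        j = lp.index[rid]
        row = np.zeros(nvar)
        row[j] = 1.0
        row[n + t] = -lp.ub[j]
        rows.append(row)                  # v_j <= ub_j z
        lo.append(-np.inf)
        hi.append(0.0)
        row = np.zeros(nvar)
        row[j] = -1.0
        row[n + t] = lp.lb[j]
        rows.append(row)                  # v_j >= lb_j z
        lo.append(-np.inf)
        hi.append(0.0)
        lbv[j] = min(lbv[j], 0.0)
        ubv[j] = max(ubv[j], 0.0)

    c = np.zeros(nvar)
    for t, rid in enumerate(univ_ids):
        c[n + t] = costs.get(rid, 1.0) if costs else 1.0
    bounds = optimize.Bounds(
        np.concatenate([lbv, np.zeros(nz)]),
        np.concatenate([ubv, np.ones(nz)]))
    integrality = np.zeros(nvar)
    integrality[n:] = 1
    con = optimize.LinearConstraint(sparse.csr_matrix(np.array(rows)),
                                    np.array(lo), np.array(hi))
    res = optimize.milp(c, constraints=con, bounds=bounds,
                        integrality=integrality)
    if res.status == 2 or res.x is None:
        return GapfillResult(INFEASIBLE)
    z = res.x[n:]
    added = frozenset(rid for t, rid in enumerate(univ_ids) if z[t] > 0.5)
    achieved = _apply_and_grow(draft, universe, added)
    return GapfillResult(OPTIMAL, added, achieved)


def _apply_and_grow(draft: MetabolicModel, universe: MetabolicModel,
                    additions: frozenset[str]) -> float:
    patched = draft.copy()
    known_mets = set(patched.metabolite_ids())
    for rxn in universe.reactions:
        if rxn.id in additions:
            patched.reactions.append(rxn)
            for met_id in rxn.stoichiometry:
                if met_id not in known_mets:
                    patched.metabolites.append(
                        universe.get_metabolite(met_id))
                    known_mets.add(met_id)
    res = solve_fba(patched)
    return res.objective_value if res.ok else 0.0


def verify_gapfill(draft: MetabolicModel, universe: MetabolicModel,
                   result: GapfillResult,
                   min_growth: float = DEFAULT_MIN_GROWTH) -> bool:
    """A-posteriori check: additions restore growth and no proper subset
    does (brute force over subsets — intended for small addition sets)."""
    if not result.ok:
        return False
    if _apply_and_grow(draft, universe, result.added_reactions) \
            < min_growth - 1e-9:
        return False
    ids = sorted(result.added_reactions)
    for k in range(len(ids)):
        for sub in itertools.combinations(ids, k):
            if _apply_and_grow(draft, universe, frozenset(sub)) \
                    >= min_growth - 1e-9:
                return False
    return True
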