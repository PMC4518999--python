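"""Growth-coupled knockout design (bilevel optimisation).

The design problem is bilevel: the outer level picks up to K reaction
knockouts so as to maximise product secretion, while the inner level is the
cell's own objective — maximise growth.  Inner optimality is enforced
exactly by LP strong duality: the single-level mixed-integer master program
carries the inner LP's primal constraints, dual constraints, and the
primal-dual objective equality, with knockout binaries y_j gating both the
flux bounds (lb_j*y_j <= v_j <= ub_j*y_j) and the dual bound terms
(linearised exactly for binary y).

Design selection.  When the inner optimum admits alternate flux states the
product flux at optimal growth is an interval [min, max].  Designs here are
ranked by the GUARANTEED minimum product flux at the inner optimum — the
quantity that actually certifies growth coupling (a design whose optimum
merely *allows* high product is not coupled).  The classic at-optimum
maximum is computed and reported alongside.  Because the at-optimum maximum
upper-bounds the guaranteed minimum, the strong-duality master (whose value
is that maximum) is a valid bound: the search solves the master, evaluates
the incumbent design's guaranteed minimum by two LPs on the knocked-out
network, excludes the design, and stops as soon as the master bound falls
below the best guaranteed minimum found.  The result provably equals the
exhaustive search over candidate subsets.

Ties are broken by smallest knockout-set cardinality, then lexicographically
smallest id set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .fba import OPTIMAL, SolverError, _objective_vector, _solve, build_lp
from .model import MetabolicModel, ModelStructureError

#: tolerance for comparing design objective values (flux units)
VALUE_TOL = 1e-6
#: bound on dual variables in the linearised strong-duality coupling
DUAL_BOUND = 1000.0
#: enumeration guard for the exhaustive oracle
MAX_SUBSETS = 50_000


@dataclass(frozen=True)
class KnockoutDesign:
    """A knockout set with its inner-optimal growth and product fluxes."""

    reactions: frozenset[str]
    growth: float
    product_max: float  #: product flux attainable at the inner optimum
    product_min: float  #: guaranteed product flux at the inner optimum
    status: str = OPTIMAL

    @property
    def objective_value(self) -> float:
        return self.product_min


@dataclass
class NoDesign:
    """Returned when no knockout set meets the minimum-growth threshold."""

    status: str = "no-design"
    reactions: frozenset[str] = frozenset()


def default_candidates(model: MetabolicModel) -> list[str]:
    """Gene-associated internal reactions — the standard candidate pool.

    Exchanges, the biomass objective and the ATP maintenance drain are
    never valid knockouts.
    """
    out = []
    for r in model.reactions:
        if r.is_exchange or r.id == model.objective_id or r.id == "ATPM":
            continue
        if not r.gene_rule.is_empty:
            out.append(r.id)
    return out


def _design_key(value: float, kos: frozenset[str]) -> tuple:
    return (-value, len(kos), tuple(sorted(kos)))


def _better(value: float, kos: frozenset[str],
            best_value: float, best_kos: frozenset[str]) -> bool:
    if value > best_value + VALUE_TOL:
        return True
    if value < best_value - VALUE_TOL:
        return False
    return _design_key(best_value, kos)[1:] < _design_key(best_value,
                                                          best_kos)[1:]


def evaluate_design(model: MetabolicModel, knockouts, product_id: str,
                    min_growth: float = 0.0, *, lp=None
                    ) -> KnockoutDesign | None:
    """Growth optimum and at-optimum product interval for one knockout set.

    Returns None when the knocked network is infeasible or grows below
    ``min_growth``.
    """
    lp = lp or build_lp(model)
    kos = frozenset(knockouts)
    unknown = [k for k in kos if k not in lp.index]
    if unknown:
        raise ModelStructureError(f"unknown reaction ids: {sorted(unknown)}")
    fixed = {lp.index[k]: 0.0 for k in kos}
    obj = _objective_vector(lp, {model.objective_id: 1.0})
    inner = _solve(lp, obj, "max", fixed=fixed)
    if not inner.ok or inner.objective_value < min_growth - VALUE_TOL:
        return None
    g = inner.objective_value
    floor_row = [(-obj, -(g - 1e-9 * max(1.0, abs(g))))]
    prod = _objective_vector(lp, {product_id: 1.0})
    lo = _solve(lp, prod, "min", fixed=fixed, extra_ub=floor_row)
    hi = _solve(lp, prod, "max", fixed=fixed, extra_ub=floor_row)
    if not (lo.ok and hi.ok):
        raise SolverError("at-optimum product subproblem not optimal")
    return KnockoutDesign(reactions=kos, growth=g,
                          product_max=hi.objective_value,
                          product_min=lo.objective_value)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def exhaustive_design_search(model: MetabolicModel, product_id: str,
                             max_knockouts: int, candidates=None,
                             min_growth: float = 0.0
                             ) -> KnockoutDesign | NoDesign:
    """Enumerate every candidate subset of size <= K and return the best.

    Deterministic tie-breaking: smallest cardinality, then lexicographically
    smallest sorted id tuple.  Guarded at 50,000 subsets — beyond that use
    the mixed-integer solver.
    """
    cands = sorted(candidates) if candidates is not None \
        else sorted(default_candidates(model))
    n_subsets = sum(math.comb(len(cands), k)
                    for k in range(0, min(max_knockouts, len(cands)) + 1))
    if n_subsets > MAX_SUBSETS:
        raise ValueError(
            f"{n_subsets} subsets exceeds the enumeration guard "
            f"({MAX_SUBSETS}); use optknock()")
    lp = build_lp(model)
    best: KnockoutDesign | None = None
    for k in range(0, min(max_knockouts, len(cands)) + 1):
        for combo in itertools.combinations(cands, k):
            d = evaluate_design(model, combo, product_id, min_growth, lp=lp)
            if d is None:
                continue
            if best is None or _better(d.product_min, d.reactions,
                                       best.product_min, best.reactions):
                best = d
    return best if best is not None else NoDesign()


# ---------------------------------------------------------------------------
# Strong-duality master MILP
# ---------------------------------------------------------------------------

class _Master:
    """Single-level MILP: max product s.t. v is inner (growth) optimal.

    Variable blocks: v (n fluxes), y (binary, one per candidate), mu (free
    duals of steady state + extra equalities), nu (>=0 duals of extra
    inequalities), alpha/beta (>=0 duals of upper/lower bounds), wU/wL
    (linearisation of y_j*alpha_j / y_j*beta_j for candidates).
    """

    def __init__(self, model: MetabolicModel, product_id: str,
                 candidates: list[str], max_knockouts: int,
                 min_growth: float):
        lp = build_lp(model)
        self.lp = lp
        self.cands = candidates
        n = len(lp.rxn_ids)
        A_eq_rows = [lp.S]
        if lp.A_extra_eq is not None:
            A_eq_rows.append(lp.A_extra_eq)
        E = np.vstack(A_eq_rows)              # equality system, rhs 0
        G = lp.A_ub if lp.A_ub is not None else np.zeros((0, n))
        h = lp.b_ub if lp.b_ub is not None else np.zeros(0)
        m_eq, m_ub = E.shape[0], G.shape[0]
        c_grow = _objective_vector(lp, {model.objective_id: 1.0})
        d_prod = _objective_vector(lp, {product_id: 1.0})
        cand_idx = [lp.index[r] for r in candidates]
        is_cand = np.zeros(n, dtype=bool)
        is_cand[cand_idx] = True
        nc = len(cand_idx)
        M = DUAL_BOUND

        # variable layout
        self.n, self.nc, self.m_eq, self.m_ub = n, nc, m_eq, m_ub
        ofs_v = 0
        ofs_y = n
        ofs_mu = ofs_y + nc
        ofs_nu = ofs_mu + m_eq
        ofs_al = ofs_nu + m_ub
        ofs_be = ofs_al + n
        ofs_wu = ofs_be + n
        ofs_wl = ofs_wu + nc
        nvar = ofs_wl + nc
        self.ofs_y = ofs_y
        self.nvar = nvar

        L, U = lp.lb, lp.ub
        rows, lo_rhs, hi_rhs = [], [], []

        def add(row, lo, hi):
            rows.append(row)
            lo_rhs.append(lo)
            hi_rhs.append(hi)

        # primal: E v = 0
        for i in range(m_eq):
            row = np.zeros(nvar)
            row[ofs_v:ofs_v + n] = E[i]
            add(row, 0.0, 0.0)
        # primal: G v <= h
        for i in range(m_ub):
            row = np.zeros(nvar)
            row[ofs_v:ofs_v + n] = G[i]
            add(row, -np.inf, h[i])
        # primal bounds gated by y for candidates
        for t, j in enumerate(cand_idx):
            row = np.zeros(nvar)
            row[ofs_v + j] = 1.0
            row[ofs_y + t] = -U[j]
            add(row, -np.inf, 0.0)          # v_j - U_j y_j <= 0
            row = np.zeros(nvar)
            row[ofs_v + j] = -1.0
            row[ofs_y + t] = L[j]
            add(row, -np.inf, 0.0)          # -v_j + L_j y_j <= 0
        # minimum growth
        row = np.zeros(nvar)
        row[ofs_v:ofs_v + n] = -c_grow
        add(row, -np.inf, -min_growth)
        # dual feasibility: E' mu + G' nu + alpha - beta = c_grow
        for j in range(n):
            row = np.zeros(nvar)
            row[ofs_mu:ofs_mu + m_eq] = E[:, j]
            row[ofs_nu:ofs_nu + m_ub] = G[:, j]
            row[ofs_al + j] = 1.0
            row[ofs_be + j] = -1.0
            add(row, c_grow[j], c_grow[j])
        # strong duality: c'v = h'nu + sum_j U_j a~_j - L_j b~_j
        row = np.zeros(nvar)
        row[ofs_v:ofs_v + n] = c_grow
        row[ofs_nu:ofs_nu + m_ub] = -h
        for j in range(n):
            if not is_cand[j]:
                row[ofs_al + j] = -U[j]
                row[ofs_be + j] = L[j]
        for t, j in enumerate(cand_idx):
            row[ofs_wu + t] = -U[j]
            row[ofs_wl + t] = L[j]
        add(row, 0.0, 0.0)
        # exact linearisation of wU = y*alpha, wL = y*beta (y binary)
        for t, j in enumerate(cand_idx):
            for ofs_w, ofs_d in ((ofs_wu, ofs_al + j), (ofs_wl, ofs_be + j)):
                row = np.zeros(nvar)          # w - M y <= 0
                row[ofs_w + t] = 1.0
                row[ofs_y + t] = -M
                add(row, -np.inf, 0.0)
                row = np.zeros(nvar)          # w - dual <= 0
                row[ofs_w + t] = 1.0
                row[ofs_d] = -1.0
                add(row, -np.inf, 0.0)
                row = np.zeros(nvar)          # dual - w - M(1-y) <= 0
                row[ofs_d] = 1.0
                row[ofs_w + t] = -1.0
                row[ofs_y + t] = -M
                add(row, -np.inf, M)
        # knockout budget: sum (1 - y) <= K
        row = np.zeros(nvar)
        row[ofs_y:ofs_y + nc] = -1.0
        add(row, -np.inf, max_knockouts - nc)

        self.base_rows = rows
        self.base_lo = lo_rhs
        self.base_hi = hi_rhs

        lbv = np.concatenate([
            L, np.zeros(nc), np.full(m_eq, -np.inf), np.zeros(m_ub),
            np.zeros(n), np.zeros(n), np.zeros(nc), np.zeros(nc)])
        ubv = np.concatenate([
            U, np.ones(nc), np.full(m_eq, np.inf), np.full(m_ub, M),
            np.full(n, M), np.full(n, M), np.full(nc, M), np.full(nc, M)])
        self.bounds = optimize.Bounds(lbv, ubv)
        integrality = np.zeros(nvar)
        integrality[ofs_y:ofs_y + nc] = 1
        self.integrality = integrality
        self.objective = np.zeros(nvar)
        self.objective[:n] = -d_prod       # milp minimises
        self.cuts: list[tuple[np.ndarray, float, float]] = []

    def exclude(self, knocked: frozenset[str]) -> None:
        """No-good cut removing exactly this y pattern."""
        row = np.zeros(self.nvar)
        rhs_shift = 0
        for t, rid in enumerate(self.cands):
            if rid in knocked:
                row[self.ofs_y + t] = 1.0   # require some knocked y back on
            else:
                row[self.ofs_y + t] = -1.0  # or some kept y knocked off
                rhs_shift += 1
        # sum_{knocked} y + sum_{kept} (1-y) >= 1
        self.cuts.append((row, 1.0 - rhs_shift, np.inf))

    def solve(self) -> tuple[frozenset[str], float] | None:
        rows = self.base_rows + [c[0] for c in self.cuts]
        lo = self.base_lo + [c[1] for c in self.cuts]
        hi = self.base_hi + [c[2] for c in self.cuts]
        con = optimize.LinearConstraint(
            sparse.csr_matrix(np.array(rows)), np.array(lo), np.array(hi))
        res = optimize.milp(self.objective, constraints=con,
                            bounds=self.bounds, integrality=self.integrality)
        if res.status == 2:               # infeasible
            return None
        if res.x is None:
            raise SolverError(f"MILP solver failure: {res.message}")
        y = res.x[self.ofs_y:self.ofs_y + self.nc]
        knocked = frozenset(r for t, r in enumerate(self.cands)
                            if y[t] < 0.5)
        return knocked, float(-res.fun)


def optknock(model: MetabolicModel, product_id: str, max_knockouts: int,
             candidates=None, min_growth: float | None = None
             ) -> KnockoutDesign | NoDesign:
    """Best <=K-knockout design maximising guaranteed product at optimum.

    ``candidates`` defaults to the gene-associated internal reactions;
    ``min_growth`` defaults to 10% of the wild-type growth optimum.
    Returns :class:`NoDesign` when nothing (including the empty set)
    meets the growth threshold.
    """
    if max_knockouts < 0:
        raise ValueError("max_knockouts must be >= 0")
    cands = sorted(candidates) if candidates is not None \
        else sorted(default_candidates(model))
    bad = [c for c in cands if not model.has_reaction(c)]
    if bad:
        raise ModelStructureError(f"unknown candidate reactions: {bad}")
    if min_growth is None:
        lp0 = build_lp(model)
        wt = _solve(lp0, _objective_vector(lp0, {model.objective_id: 1.0}),
                    "max")
        min_growth = 0.1 * wt.objective_value if wt.ok else 0.0

    lp = build_lp(model)
    master = _Master(model, product_id, cands, max_knockouts, min_growth)
    best: KnockoutDesign | None = None
    for _ in range(MAX_SUBSETS):
        out = master.solve()
        if out is None:
            break
        knocked, bound = out
        if best is not None and bound < best.product_min - VALUE_TOL:
            break                          # bound below incumbent: done
        d = evaluate_design(model, knocked, product_id, min_growth, lp=lp)
        master.exclude(knocked)
        if d is None:
            continue
        if best is None or _better(d.product_min, d.reactions,
                                   best.product_min, best.reactions):
            best = d
    return best if best is not None else NoDesign()


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

@dataclass
class DesignVerification:
    growth: float
    product_min: float
    product_max: float
    discrepancies: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.discrepancies


def verify_design(model: MetabolicModel, design: KnockoutDesign,
                  product_id: str, tol: float = 1e-5) -> DesignVerification:
    """Re-derive a design's envelope statistics by plain FBA and compare.

    Applies the knockouts, recomputes growth and the at-optimum product
    interval from scratch, and flags any recorded value that deviates by
    more than ``tol``.
    """
    fresh = evaluate_design(model, design.reactions, product_id)
    if fresh is None:
        return DesignVerification(
            growth=float("nan"), product_min=float("nan"),
            product_max=float("nan"),
            discrepancies=["knocked-out model is infeasible"])
    out = DesignVerification(growth=fresh.growth,
                             product_min=fresh.product_min,
                             product_max=fresh.product_max)
    for label, recorded, fresh_val in (
            ("growth", design.growth, fresh.growth),
            ("product_min", design.product_min, fresh.product_min),
            ("product_max", design.product_max, fresh.product_max)):
        if abs(recorded - fresh_val) > tol:
            out.discrepancies.append(
                f"{label}: recorded {recorded} vs recomputed {fresh_val}")
    return out
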