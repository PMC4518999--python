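"""Linear-programming core: FBA, flux variability, fixed-flux optima.

All solves go through :func:`scipy.optimize.linprog` with the HiGHS
backend.  The steady-state system is ``S v = 0`` with elementwise bounds
``lb <= v <= ub``; a model's ``extra_constraints`` (arbitrary linear
inequalities over fluxes, e.g. a hydrogen-per-glucose yield cap) are carried
into every LP built here, so FBA, FVA, phase planes and the knockout-design
inner problems all see the same feasible space.

Numerical conventions: primal feasibility is left at the solver default
(~1e-9 for HiGHS); reported values are compared downstream at 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import (
    MetabolicModel,
    ModelStructureError,
    assemble_stoichiometric_matrix,
    validate,
)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS_MAP = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}

FEASIBILITY_TOL = 1e-9
VALUE_TOL = 1e-6


class SolverError(RuntimeError):
    """LP solver terminated abnormally (not optimal/infeasible/unbounded)."""


@dataclass
class FBAResult:
    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL

    def flux(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"no fluxes available (status {self.status})")
        return self.fluxes[reaction_id]


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass
class _LPData:
    """Cached standard-form pieces of a model's flux polytope."""

    S: np.ndarray
    met_ids: list[str]
    rxn_ids: list[str]
    index: dict[str, int]
    lb: np.ndarray
    ub: np.ndarray
    A_ub: np.ndarray | None
    b_ub: np.ndarray | None
    A_extra_eq: np.ndarray | None
    b_extra_eq: np.ndarray | None


def build_lp(model: MetabolicModel, *, check: bool = True) -> _LPData:
    """Assemble the polytope data; optionally validate the model first."""
    if check:
        report = validate(model)
        if not report.ok:
            raise ModelStructureError(
                f"model {model.id!r} fails validation: {report.errors}")
    S, met_ids, rxn_ids = assemble_stoichiometric_matrix(model)
    index = {r: j for j, r in enumerate(rxn_ids)}
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)

    ub_rows, ub_rhs, eq_rows, eq_rhs = [], [], [], []
    for con in model.extra_constraints:
        row = np.zeros(len(rxn_ids))
        for rid, coef in con.coefficients.items():
            row[index[rid]] = coef
        if con.sense == "<=":
            ub_rows.append(row)
            ub_rhs.append(con.rhs)
        elif con.sense == ">=":
            ub_rows.append(-row)
            ub_rhs.append(-con.rhs)
        else:
            eq_rows.append(row)
            eq_rhs.append(con.rhs)
    return _LPData(
        S=S, met_ids=met_ids, rxn_ids=rxn_ids, index=index, lb=lb, ub=ub,
        A_ub=np.array(ub_rows) if ub_rows else None,
        b_ub=np.array(ub_rhs) if ub_rhs else None,
        A_extra_eq=np.array(eq_rows) if eq_rows else None,
        b_extra_eq=np.array(eq_rhs) if eq_rhs else None,
    )


def _solve(lp: _LPData, objective: np.ndarray, sense: str,
           extra_ub: Sequence[tuple[np.ndarray, float]] = (),
           fixed: Mapping[int, float] | None = None) -> FBAResult:
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c = -objective if sense == "max" else objective

    A_eq = lp.S
    b_eq = np.zeros(lp.S.shape[0])
    if lp.A_extra_eq is not None:
        A_eq = np.vstack([A_eq, lp.A_extra_eq])
        b_eq = np.concatenate([b_eq, lp.b_extra_eq])

    A_ub, b_ub = lp.A_ub, lp.b_ub
    if extra_ub:
        rows = np.array([r for r, _ in extra_ub])
        rhs = np.array([v for _, v in extra_ub])
        A_ub = rows if A_ub is None else np.vstack([A_ub, rows])
        b_ub = rhs if b_ub is None else np.concatenate([b_ub, rhs])

    lb, ub = lp.lb.copy(), lp.ub.copy()
    if fixed:
        for j, val in fixed.items():
            lb[j] = ub[j] = val
    bounds = list(zip(lb, ub))

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    status = _STATUS_MAP.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failure: {res.message}")
    if status != OPTIMAL:
        return FBAResult(status=status)
    value = float(objective @ res.x)
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(lp.rxn_ids)}
    return FBAResult(status=OPTIMAL, objective_value=value, fluxes=fluxes)


def _objective_vector(lp: _LPData, coefficients: Mapping[str, float]) -> np.ndarray:
    vec = np.zeros(len(lp.rxn_ids))
    for rid, coef in coefficients.items():
        if rid not in lp.index:
            raise ModelStructureError(f"unknown reaction id {rid!r}")
        vec[lp.index[rid]] = coef
    return vec


def solve_fba(model: MetabolicModel, objective_id: str | None = None,
              sense: str = "max", *, lp: _LPData | None = None) -> FBAResult:
    """Maximise (or minimise) one reaction flux over the steady-state space.

    ``objective_id`` defaults to the model's declared objective.  The model
    is structurally validated before the solve; pass a prebuilt ``lp`` to
    skip revalidation in tight loops.
    """
    lp = lp or build_lp(model)
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction given or declared")
    return _solve(lp, _objective_vector(lp, {objective_id: 1.0}), sense)


def optimize_linear(model: MetabolicModel, coefficients: Mapping[str, float],
                    sense: str = "max", *, lp: _LPData | None = None,
                    extra_ub: Sequence[tuple[Mapping[str, float], float]] = (),
                    ) -> FBAResult:
    """Optimise an arbitrary linear combination of fluxes.

    ``extra_ub`` adds transient ``sum(coef*v) <= rhs`` rows for this solve
    only (used for objective-fraction constraints).
    """
    lp = lp or build_lp(model)
    rows = [( _objective_vector(lp, coefs), float(rhs))
            for coefs, rhs in extra_ub]
    return _solve(lp, _objective_vector(lp, coefficients), sense,
                  extra_ub=rows)


def flux_variability(model: MetabolicModel, fraction_of_optimum: float = 1.0,
                     reactions: Iterable[str] | None = None,
                     objective_id: str | None = None) -> list[FluxRange]:
    """Per-reaction min/max flux subject to near-optimal objective.

    The objective is constrained to ``>= fraction * optimum`` (for a
    non-negative optimum; the inequality is oriented so that fraction 1.0
    pins the optimal face and fraction 0 relaxes it completely).
    """
    if not (0.0 <= fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    lp = build_lp(model)
    objective_id = objective_id or model.objective_id
    base = solve_fba(model, objective_id, "max", lp=lp)
    if not base.ok:
        raise SolverError(
            f"base FBA problem is {base.status}; cannot run FVA")
    opt = base.objective_value
    # keep the objective within fraction of its optimum (small tolerance so
    # the optimal face itself stays feasible at fraction 1.0)
    floor = fraction_of_optimum * opt - max(1.0, abs(opt)) * 1e-9
    obj_row = -_objective_vector(lp, {objective_id: 1.0})
    extra = [(obj_row, -floor)]

    targets = list(reactions) if reactions is not None else lp.rxn_ids
    out = []
    for rid in targets:
        vec = _objective_vector(lp, {rid: 1.0})
        lo = _solve(lp, vec, "min", extra_ub=extra)
        hi = _solve(lp, vec, "max", extra_ub=extra)
        if not (lo.ok and hi.ok):
            raise SolverError(f"FVA subproblem for {rid!r} not optimal")
        out.append(FluxRange(rid, lo.objective_value, hi.objective_value))
    return out


def optimize_with_fixed_fluxes(model: MetabolicModel,
                               fixes: Mapping[str, float],
                               objective_id: str | None = None,
                               sense: str = "max", *,
                               lp: _LPData | None = None) -> FBAResult:
    """Solve FBA with selected fluxes pinned to given values.

    Fixing a flux outside its declared bounds is a precondition violation
    and raises ``ValueError`` — values are never silently clamped.
    """
    lp = lp or build_lp(model)
    fixed: dict[int, float] = {}
    for rid, val in fixes.items():
        if rid not in lp.index:
            raise ModelStructureError(f"unknown reaction id {rid!r}")
        j = lp.index[rid]
        if val < lp.lb[j] - VALUE_TOL or val > lp.ub[j] + VALUE_TOL:
            raise ValueError(
                f"fix {rid}={val} outside declared bounds "
                f"[{lp.lb[j]}, {lp.ub[j]}]")
        fixed[j] = float(val)
    objective_id = objective_id or model.objective_id
    return _solve(lp, _objective_vector(lp, {objective_id: 1.0}), sense,
                  fixed=fixed)


def steady_state_residual(model: MetabolicModel,
                          fluxes: Mapping[str, float]) -> float:
    """Max-norm of S*v for a reported flux vector (should be <= 1e-6)."""
    S, met_ids, rxn_ids = assemble_stoichiometric_matrix(model)
    v = np.array([fluxes[r] for r in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0
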