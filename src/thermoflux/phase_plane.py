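"""Phenotypic phase planes, production envelopes and coupling strength.

A phase plane is the surface of maximal growth over a grid of two fixed
fluxes (typically substrate uptake x product secretion); its shape shows
whether optimal growth pins the product flux.  A production envelope is the
min/max product flux attainable at each growth rate; growth coupling means
the envelope's lower edge is strictly positive at optimal growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fba import SolverError, build_lp, optimize_linear, solve_fba, _solve, \
    _objective_vector
from .model import MetabolicModel

#: default grid resolution per axis
DEFAULT_POINTS = 50

_NA = "NA"


def _fmt(x: float) -> str:
    return f"{x:.9g}"


@dataclass
class PhasePlaneGrid:
    x_id: str
    y_id: str
    x_values: np.ndarray
    y_values: np.ndarray
    #: max growth, shape (len(x_values), len(y_values)); NaN = infeasible
    growth: np.ndarray

    def to_tsv(self, path) -> None:
        """Matrix layout; infeasible cells are explicit NA tokens."""
        lines = ["\t".join([f"{self.x_id}\\{self.y_id}"]
                           + [_fmt(y) for y in self.y_values])]
        for i, x in enumerate(self.x_values):
            cells = [_fmt(x)] + [
                _NA if np.isnan(g) else _fmt(g) for g in self.growth[i]]
            lines.append("\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ProductionEnvelope:
    product_id: str
    growth_values: np.ndarray
    min_flux: np.ndarray
    max_flux: np.ndarray

    def to_tsv(self, path) -> None:
        lines = ["growth\tmin_" + self.product_id + "\tmax_" + self.product_id]
        for g, lo, hi in zip(self.growth_values, self.min_flux, self.max_flux):
            lines.append("\t".join(_fmt(v) for v in (g, lo, hi)))
        Path(path).write_text("\n".join(lines) + "\n")


def phase_plane(model: MetabolicModel, x_id: str, y_id: str,
                x_range: tuple[float, float], y_range: tuple[float, float],
                n_points: int = DEFAULT_POINTS,
                objective_id: str | None = None) -> PhasePlaneGrid:
    """Max growth over a grid with fluxes ``x_id`` and ``y_id`` fixed.

    Each finite cell is the LP optimum with both fluxes pinned; infeasible
    cells are NaN, never zero-filled.
    """
    if x_id == y_id:
        raise ValueError("phase-plane axes must be two distinct reactions")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    lp = build_lp(model)
    for rid, (lo, hi) in ((x_id, x_range), (y_id, y_range)):
        j = lp.index[rid]
        if lo < lp.lb[j] - 1e-9 or hi > lp.ub[j] + 1e-9:
            raise ValueError(
                f"range {lo}..{hi} for {rid} outside declared bounds "
                f"[{lp.lb[j]}, {lp.ub[j]}]")
    objective_id = objective_id or model.objective_id
    obj = _objective_vector(lp, {objective_id: 1.0})
    xs = np.linspace(x_range[0], x_range[1], n_points)
    ys = np.linspace(y_range[0], y_range[1], n_points)
    growth = np.full((n_points, n_points), np.nan)
    jx, jy = lp.index[x_id], lp.index[y_id]
    for i, xv in enumerate(xs):
        for k, yv in enumerate(ys):
            res = _solve(lp, obj, "max", fixed={jx: xv, jy: yv})
            if res.ok:
                growth[i, k] = res.objective_value
    return PhasePlaneGrid(x_id, y_id, xs, ys, growth)


def production_envelope(model: MetabolicModel, product_id: str,
                        n_points: int = DEFAULT_POINTS,
                        objective_id: str | None = None) -> ProductionEnvelope:
    """Min/max product flux at each growth value from 0 to the optimum."""
    lp = build_lp(model)
    objective_id = objective_id or model.objective_id
    base = solve_fba(model, objective_id, "max", lp=lp)
    if not base.ok:
        raise SolverError(f"model is {base.status}; no envelope exists")
    gmax = base.objective_value
    grid = np.linspace(0.0, gmax, n_points)
    # back off the top point by a whisker so the optimal face stays feasible
    if n_points > 1 and gmax > 0:
        grid[-1] = gmax - 1e-9 * max(1.0, gmax)
    prod = _objective_vector(lp, {product_id: 1.0})
    jg = lp.index[objective_id]
    lo = np.empty(n_points)
    hi = np.empty(n_points)
    for i, g in enumerate(grid):
        rmin = _solve(lp, prod, "min", fixed={jg: g})
        rmax = _solve(lp, prod, "max", fixed={jg: g})
        if not (rmin.ok and rmax.ok):
            raise SolverError(f"envelope point growth={g} not solvable")
        lo[i], hi[i] = rmin.objective_value, rmax.objective_value
    grid[-1] = gmax if n_points > 1 else grid[-1]
    return ProductionEnvelope(product_id, grid, lo, hi)


def coupling_strength(model: MetabolicModel, product_id: str,
                      fraction: float = 1.0,
                      objective_id: str | None = None) -> float:
    """Guaranteed minimum product flux at >= fraction of optimal growth.

    This is the degeneracy-proof statistic for growth coupling: it is the
    worst case over all alternate optima, so a strictly positive value
    means every near-optimal flux state secretes the product.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    lp = build_lp(model)
    objective_id = objective_id or model.objective_id
    base = solve_fba(model, objective_id, "max", lp=lp)
    if not base.ok:
        raise SolverError(f"model is {base.status}")
    floor = fraction * base.objective_value
    floor -= 1e-9 * max(1.0, abs(floor))
    res = optimize_linear(model, {product_id: 1.0}, "min", lp=lp,
                          extra_ub=[({objective_id: -1.0}, -floor)])
    if not res.ok:
        raise SolverError(f"coupling subproblem is {res.status}")
    return res.objective_value


def product_range_at_optimum(model: MetabolicModel, product_id: str,
                             fraction: float = 1.0,
                             objective_id: str | None = None
                             ) -> tuple[float, float]:
    """(min, max) product flux over flux states within ``fraction`` of the
    growth optimum — the degeneracy-aware version of 'product at optimum'."""
    lp = build_lp(model)
    objective_id = objective_id or model.objective_id
    base = solve_fba(model, objective_id, "max", lp=lp)
    if not base.ok:
        raise SolverError(f"model is {base.status}")
    floor = fraction * base.objective_value
    floor -= 1e-9 * max(1.0, abs(floor))
    extra = [({objective_id: -1.0}, -floor)]
    lo = optimize_linear(model, {product_id: 1.0}, "min", lp=lp, extra_ub=extra)
    hi = optimize_linear(model, {product_id: 1.0}, "max", lp=lp, extra_ub=extra)
    if not (lo.ok and hi.ok):
        raise SolverError("product range subproblem not optimal")
    return lo.objective_value, hi.objective_value
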