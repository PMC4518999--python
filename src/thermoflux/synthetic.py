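"""Seeded generators of toy stoichiometric networks with known answers.

These are the test substrate for the pipeline: every bundle records ground
truth (optimal objective, coupled minimum product, removed reactions) that
is derivable by hand from the construction, so solver results can be
checked against values that never came from the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fba import solve_fba, build_lp, _solve, _objective_vector
from .io import infer_exchange
from .model import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    Reaction,
)


@dataclass
class SyntheticModelBundle:
    model: MetabolicModel
    ground_truth: dict
    seed: int
    universe: MetabolicModel | None = None


def _mk(model: MetabolicModel, rid: str, stoich: dict[str, float],
        lb: float = 0.0, ub: float = 1000.0, rule: str = "") -> None:
    rxn = Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                   upper_bound=ub, gene_rule=GeneRule.parse(rule))
    rxn.is_exchange = infer_exchange(rxn)
    model.reactions.append(rxn)
    known = set(model.metabolite_ids())
    for met in stoich:
        if met not in known:
            comp = met[-2]
            model.metabolites.append(
                Metabolite(id=met, name=met.rsplit("[", 1)[0],
                           compartment=comp))


def generate_linear_pathway(n_steps: int, uptake_bound: float = 10.0,
                            seed: int = 0,
                            bottleneck: float | None = None
                            ) -> SyntheticModelBundle:
    """Chain EX_in -> M1 -> ... -> Mn -> EX_out with known optimum.

    Intermediate step capacities are drawn at random but kept >= the uptake
    bound, so the optimum is the uptake bound — unless ``bottleneck`` is
    given, in which case one random step is tightened to that value and the
    optimum is ``min(uptake_bound, bottleneck)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    model = MetabolicModel(id=f"chain{n_steps}_s{seed}")
    _mk(model, "EX_in", {"S[e]": -1.0}, lb=-uptake_bound, ub=0.0)
    _mk(model, "T_in", {"S[e]": -1.0, "M1[c]": 1.0})
    caps = rng.uniform(uptake_bound, 3.0 * uptake_bound, size=n_steps - 1)
    tight = rng.integers(0, n_steps - 1) if (bottleneck is not None
                                             and n_steps > 1) else None
    for i in range(n_steps - 1):
        cap = bottleneck if i == tight else float(caps[i])
        _mk(model, f"STEP{i + 1}", {f"M{i + 1}[c]": -1.0,
                                    f"M{i + 2}[c]": 1.0}, ub=cap)
    _mk(model, "SEC", {f"M{n_steps}[c]": -1.0, "P[e]": 1.0})
    _mk(model, "EX_out", {"P[e]": -1.0})
    model.objective_id = "EX_out"
    optimum = uptake_bound if tight is None \
        else min(uptake_bound, bottleneck)
    return SyntheticModelBundle(
        model=model,
        ground_truth={"optimal_objective": optimum,
                      "uptake_bound": uptake_bound},
        seed=seed)


def generate_coupled_toy(seed: int = 0) -> SyntheticModelBundle:
    """A small redox-branched network with known growth-coupling structure.

    Catabolism of substrate ``s`` yields precursor ``x``, ATP and a reduced
    cofactor (NADH) that must be re-oxidised through one of two sinks:

    * ``VENT`` — discards the electrons as a waste gas (no product), the
      analogue of a free-running hydrogenase;
    * ``PRODSYN`` — reduces precursor to the secreted product.

    Per unit substrate: 2 x, 2 ATP, 2 NADH.  With VENT open, growth is
    precursor/ATP-limited at 2 x uptake and the minimum product at optimum
    is 0.  With VENT knocked out, the 2 NADH force one PRODSYN turnover
    (2 NADH each), consuming one x: growth falls to 1 x uptake and the
    product is pinned at exactly 1 x uptake — all derivable by hand.
    """
    rng = np.random.default_rng(seed)
    u = float(np.round(rng.uniform(5.0, 15.0), 3))
    model = MetabolicModel(id=f"coupled_s{seed}")
    _mk(model, "EX_s", {"s[e]": -1.0}, lb=-u, ub=0.0)
    _mk(model, "T_s", {"s[e]": -1.0, "s[c]": 1.0})
    _mk(model, "CAT", {"s[c]": -1.0, "NAD[c]": -2.0, "ADP[c]": -2.0,
                       "x[c]": 2.0, "NADH[c]": 2.0, "ATP[c]": 2.0},
        rule="g_cat")
    _mk(model, "VENT", {"NADH[c]": -1.0, "NAD[c]": 1.0, "vgas[c]": 1.0},
        rule="g_vent")
    _mk(model, "T_vgas", {"vgas[c]": -1.0, "vgas[e]": 1.0})
    _mk(model, "EX_vgas", {"vgas[e]": -1.0})
    _mk(model, "PRODSYN", {"x[c]": -1.0, "NADH[c]": -2.0,
                           "prod[c]": 1.0, "NAD[c]": 2.0}, rule="g_prod")
    _mk(model, "T_prod", {"prod[c]": -1.0, "prod[e]": 1.0})
    _mk(model, "EX_prod", {"prod[e]": -1.0})
    _mk(model, "ATPM", {"ATP[c]": -1.0, "ADP[c]": 1.0})
    _mk(model, "BIO", {"x[c]": -1.0, "ATP[c]": -1.0, "ADP[c]": 1.0,
                       "bio[e]": 1.0})
    _mk(model, "EX_bio", {"bio[e]": -1.0})
    model.objective_id = "BIO"
    return SyntheticModelBundle(
        model=model,
        ground_truth={
            "uptake": u,
            "wt_growth": 2.0 * u,
            "wt_min_product_at_optimum": 0.0,
            "coupled_growth": u,
            "coupled_min_product": u,
            "sink_reaction": "VENT",
            "product_reaction": "EX_prod",
            "candidates": ["CAT", "PRODSYN", "VENT"],
        },
        seed=seed)


def essential_reactions(model: MetabolicModel,
                        min_growth: float = 1e-3) -> list[str]:
    """Reactions whose single knockout drops growth below ``min_growth``.

    The objective reaction itself is excluded.
    """
    lp = build_lp(model)
    obj = _objective_vector(lp, {model.objective_id: 1.0})
    out = []
    for rid in lp.rxn_ids:
        if rid == model.objective_id:
            continue
        res = _solve(lp, obj, "max", fixed={lp.index[rid]: 0.0})
        if not res.ok or res.objective_value < min_growth:
            out.append(rid)
    return out


def degrade_model(model: MetabolicModel, k: int, seed: int = 0,
                  n_decoys: int = 10,
                  min_growth: float = 1e-3) -> SyntheticModelBundle:
    """Remove ``k`` growth-essential reactions; supply them back (plus
    decoys) in a universe model.

    The draft is guaranteed repairable with at most k additions (the
    removed set itself).  Decoy reactions connect fresh dead-end metabolite
    pairs, so they are mass-balanced but can never carry steady-state flux.
    """
    base = solve_fba(model)
    if not base.ok or base.objective_value < min_growth:
        raise ValueError("model must grow before degradation")
    essentials = essential_reactions(model, min_growth)
    if k > len(essentials):
        raise ValueError(
            f"k={k} exceeds the {len(essentials)} growth-essential reactions")
    rng = np.random.default_rng(seed)
    removed = sorted(rng.choice(essentials, size=k, replace=False).tolist())

    draft = model.copy()
    draft.id = f"{model.id}_gapped{k}_s{seed}"
    removed_rxns = [r for r in draft.reactions if r.id in removed]
    draft.reactions = [r for r in draft.reactions if r.id not in removed]
    used = {m for r in draft.reactions for m in r.stoichiometry}
    draft.metabolites = [m for m in draft.metabolites if m.id in used]

    universe = MetabolicModel(id=f"universe_s{seed}")
    for rxn in removed_rxns:
        universe.reactions.append(rxn)
        for met_id in rxn.stoichiometry:
            if not any(m.id == met_id for m in universe.metabolites):
                universe.metabolites.append(model.get_metabolite(met_id))
    for i in range(n_decoys):
        _mk(universe, f"DECOY{i}", {f"dA{i}[c]": -1.0, f"dB{i}[c]": 1.0})

    return SyntheticModelBundle(
        model=draft,
        ground_truth={"removed_reactions": removed, "k": k,
                      "baseline_growth": base.objective_value,
                      "min_growth": min_growth},
        seed=seed,
        universe=universe)


def generate_random_network(seed: int, n_reactions: int = 6,
                            n_metabolites: int | None = None
                            ) -> SyntheticModelBundle:
    """Random small steady-state polytope for LP-oracle comparisons.

    Coefficients are small integers, bounds are finite (so the LP is always
    bounded) and include zero (so v = 0 is steady-state feasible whenever
    no lower bound is positive — positive lower bounds are allowed and can
    make the polytope genuinely infeasible, which the oracle must agree on).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_reactions + 1))
    m = int(n_metabolites if n_metabolites is not None
            else rng.integers(1, n))
    model = MetabolicModel(id=f"rand_s{seed}")
    S = rng.integers(-2, 3, size=(m, n))
    for i in range(m):
        model.metabolites.append(Metabolite(id=f"m{i}[c]", compartment="c"))
    for j in range(n):
        stoich = {f"m{i}[c]": float(S[i, j]) for i in range(m)
                  if S[i, j] != 0}
        if not stoich:
            stoich = {f"m{int(rng.integers(0, m))}[c]": 1.0}
        lb = float(np.round(rng.choice([-1.0, 0.0, 0.2])
                            * rng.uniform(0.5, 10.0), 3))
        ub = float(np.round(rng.uniform(max(lb, 0.0) + 0.1, 12.0), 3))
        rxn = Reaction(id=f"r{j}", stoichiometry=stoich,
                       lower_bound=lb, upper_bound=ub)
        model.reactions.append(rxn)
    model.objective_id = f"r{int(rng.integers(0, n))}"
    return SyntheticModelBundle(model=model, ground_truth={}, seed=seed)
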