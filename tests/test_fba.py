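"""LP core: FBA, fixed-flux optima, FVA, and oracle equivalence."""

import numpy as np
import pytest

from thermoflux.bruteforce import brute_force_optimum
from thermoflux.fba import (
    INFEASIBLE,
    flux_variability,
    optimize_linear,
    optimize_with_fixed_fluxes,
    solve_fba,
    steady_state_residual,
)
from thermoflux.model import (
    LinearConstraint,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    validate,
)
from thermoflux.synthetic import generate_linear_pathway, \
    generate_random_network


@pytest.fixture()
def chain():
    return generate_linear_pathway(3, uptake_bound=10.0, seed=0).model


@pytest.fixture()
def branched():
    """One substrate, two products with molar yields 1 and 2."""
    m = MetabolicModel(id="branched")
    for mid in ("S[e]", "A[c]", "P[e]", "Q[e]"):
        m.metabolites.append(Metabolite(id=mid, compartment=mid[-2]))
    m.reactions = [
        Reaction(id="EX_S", stoichiometry={"S[e]": -1.0},
                 lower_bound=-5.0, upper_bound=0.0, is_exchange=True),
        Reaction(id="T", stoichiometry={"S[e]": -1.0, "A[c]": 1.0}),
        Reaction(id="MK_P", stoichiometry={"A[c]": -1.0, "P[e]": 1.0}),
        Reaction(id="MK_Q", stoichiometry={"A[c]": -1.0, "Q[e]": 2.0}),
        Reaction(id="EX_P", stoichiometry={"P[e]": -1.0}, is_exchange=True),
        Reaction(id="EX_Q", stoichiometry={"Q[e]": -1.0}, is_exchange=True),
    ]
    m.objective_id = "EX_Q"
    return m


class TestSolveFBA:
    def test_chain_bottleneck(self, chain):
        res = solve_fba(chain)
        assert res.ok
        assert res.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_closed_uptake_with_maintenance_is_infeasible(self, core_model):
        closed = core_model.copy()
        closed.get_reaction("EX_glc").lower_bound = 0.0
        assert solve_fba(closed).status == INFEASIBLE

    def test_branched_yields_against_enumeration(self, branched):
        res = solve_fba(branched)
        assert res.objective_value == pytest.approx(10.0, abs=1e-6)
        assert brute_force_optimum(branched) == pytest.approx(10.0, abs=1e-6)

    def test_steady_state_residual(self, core_model):
        res = solve_fba(core_model)
        assert steady_state_residual(core_model, res.fluxes) <= 1e-6

    def test_invalid_model_rejected_before_solving(self, chain):
        bad = chain.copy()
        bad.reactions[0].lower_bound = 99.0
        bad.reactions[0].upper_bound = -99.0
        with pytest.raises(ModelStructureError):
            solve_fba(bad)

    def test_constraint_addition_never_raises_maximum(self, core_model):
        base = solve_fba(core_model).objective_value
        tight = core_model.copy()
        tight.extra_constraints.append(LinearConstraint(
            coefficients={"EX_etoh": 1.0}, sense="<=", rhs=5.0))
        assert solve_fba(tight).objective_value <= base + 1e-9


class TestVertexEnumerationOracle:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_small_networks(self, seed):
        model = generate_random_network(seed).model
        assert validate(model).ok
        lp = solve_fba(model)
        bf = brute_force_optimum(model)
        if bf is None:
            assert lp.status == INFEASIBLE
        else:
            assert lp.ok
            assert lp.objective_value == pytest.approx(
                bf, abs=1e-6 * max(1.0, abs(bf)))


class TestFixedFluxes:
    def test_fix_consistent_with_objective(self, chain):
        res = optimize_with_fixed_fluxes(chain, {"EX_out": 10.0})
        assert res.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_fix_above_reachable_flux_is_infeasible(self, chain):
        res = optimize_with_fixed_fluxes(chain, {"EX_out": 11.0})
        assert res.status == INFEASIBLE

    def test_fix_outside_declared_bounds_raises(self, chain):
        with pytest.raises(ValueError, match="outside declared bounds"):
            optimize_with_fixed_fluxes(chain, {"EX_in": -20.0})

    def test_matches_bound_encoded_model(self, core_model):
        # fixing a flux must equal solving a model whose bounds encode it
        fix = {"EX_etoh": 12.0}
        direct = optimize_with_fixed_fluxes(core_model, fix)
        encoded = core_model.copy()
        encoded.get_reaction("EX_etoh").lower_bound = 12.0
        encoded.get_reaction("EX_etoh").upper_bound = 12.0
        via_bounds = solve_fba(encoded)
        assert direct.objective_value == pytest.approx(
            via_bounds.objective_value, abs=1e-6)


class TestFluxVariability:
    def test_chain_fully_determined_at_optimum(self, chain):
        for fr in flux_variability(chain, 1.0):
            assert fr.max_flux - fr.min_flux <= 1e-6

    def test_fraction_zero_recovers_raw_bounds(self, chain):
        ranges = {r.reaction_id: r for r in flux_variability(chain, 0.0)}
        ex = chain.get_reaction("EX_in")
        assert ranges["EX_in"].min_flux == pytest.approx(ex.lower_bound,
                                                         abs=1e-6)
        assert ranges["EX_in"].max_flux == pytest.approx(ex.upper_bound,
                                                         abs=1e-6)

    def test_nesting_in_fraction(self, core_model):
        loose = {r.reaction_id: r
                 for r in flux_variability(core_model, 0.5)}
        tight = {r.reaction_id: r
                 for r in flux_variability(core_model, 0.95)}
        for rid, t in tight.items():
            assert t.min_flux >= loose[rid].min_flux - 1e-6
            assert t.max_flux <= loose[rid].max_flux + 1e-6


class TestAgainstCobrapy:
    """Independent cross-check against the cobrapy/GLPK stack."""

    @staticmethod
    def _to_cobra(model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model(model.id)
        mets = {m.id: cobra.Metabolite(m.id.replace("[", "_").rstrip("]"),
                                       compartment=m.compartment)
                for m in model.metabolites}
        rxns = []
        for r in model.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
            rxns.append(cr)
        cm.add_reactions(rxns)
        for r, cr in zip(model.reactions, rxns):
            cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        for con in model.extra_constraints:
            expr = sum(coef * cm.reactions.get_by_id(rid).flux_expression
                       for rid, coef in con.coefficients.items())
            kwargs = {"ub": con.rhs} if con.sense == "<=" else \
                {"lb": con.rhs} if con.sense == ">=" else \
                {"lb": con.rhs, "ub": con.rhs}
            cm.add_cons_vars(cm.problem.Constraint(expr, **kwargs))
        cm.objective = model.objective_id
        return cm

    def test_core_growth_and_variability(self, core_model):
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        cm = self._to_cobra(core_model)
        ours = solve_fba(core_model)
        theirs = cm.optimize()
        assert theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(
            theirs.objective_value, abs=1e-6)

        targets = ["EX_etoh", "EX_h2", "EX_ac", "ECH"]
        ours_fva = {r.reaction_id: r
                    for r in flux_variability(core_model, 1.0,
                                              reactions=targets)}
        theirs_fva = flux_variability_analysis(
            cm, [cm.reactions.get_by_id(t) for t in targets],
            fraction_of_optimum=1.0)
        for t in targets:
            assert ours_fva[t].min_flux == pytest.approx(
                theirs_fva.loc[t, "minimum"], abs=1e-5)
            assert ours_fva[t].max_flux == pytest.approx(
                theirs_fva.loc[t, "maximum"], abs=1e-5)
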