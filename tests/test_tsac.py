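"""The curated core organism model and its constraint set."""

import pytest

from thermoflux.fba import flux_variability, optimize_linear, solve_fba
from thermoflux.io import model_to_dict
from thermoflux.model import validate
from thermoflux.phase_plane import coupling_strength
from thermoflux.tsac import (
    HydrogenaseConstraintSet,
    ammonium_assimilation_atp_cost,
    apply_hydrogenase_constraints,
    build_constrained_model,
    strain,
)


class TestCoreModelStructure:
    def test_validates_clean(self, core_model):
        report = validate(core_model)
        assert report.ok, report.errors
        assert report.statistics["gene_associated_reactions"] == 6
        assert report.statistics["genes"] == 9

    def test_hydrogenase_complex_needs_all_four_genes(self, core_model):
        rule = core_model.get_reaction("HFS").gene_rule
        assert rule.genes() == {"Tsac_1550", "Tsac_1551",
                                "Tsac_1552", "Tsac_1553"}
        assert rule.expr[0] == "and"

    def test_wild_type_grows_on_glucose(self, core_model):
        res = solve_fba(core_model)
        assert res.ok and res.objective_value > 0.1

    def test_unconstrained_network_overproduces_acetate_and_h2(
            self, raw_core_model, core_model):
        """Left unconstrained, the hydrogenases let the network vent far
        more electrons as H2, making high acetate optimal."""
        raw = solve_fba(raw_core_model)
        con = solve_fba(core_model)
        assert raw.objective_value > con.objective_value
        # acetate production is feasible (and large) at the raw optimum
        floor = raw.objective_value * (1 - 1e-9)
        ac = optimize_linear(raw_core_model, {"EX_ac": 1.0}, "max",
                             extra_ub=[({"BIOMASS": -1.0}, -floor)])
        h2 = optimize_linear(raw_core_model, {"EX_h2": 1.0}, "max",
                             extra_ub=[({"BIOMASS": -1.0}, -floor)])
        assert ac.objective_value > 10.0
        assert h2.objective_value > 0.9 * 10.0  # beyond the observed yield


class TestHydrogenaseConstraints:
    def test_ech_is_blocked(self, core_model):
        ranges = {r.reaction_id: r
                  for r in flux_variability(core_model, 0.0,
                                            reactions=["ECH"])}
        assert ranges["ECH"].min_flux == pytest.approx(0.0, abs=1e-9)
        assert ranges["ECH"].max_flux == pytest.approx(0.0, abs=1e-9)

    def test_h2_yield_cap_holds_everywhere(self, core_model):
        # max of (v_H2 + 0.9 v_glc) over the whole feasible space; uptake
        # is negative, so <= 0 means H2 <= 0.9 |glucose| at every point
        worst = optimize_linear(core_model,
                                {"EX_h2": 1.0, "EX_glc": 0.9}, "max")
        assert worst.objective_value <= 1e-6

    def test_uptake_only_hydrogenases(self, core_model):
        for rid in ("BIFH2", "NADH2"):
            rxn = core_model.get_reaction(rid)
            assert rxn.upper_bound == 0.0
            assert rxn.lower_bound < 0

    def test_idempotent(self, raw_core_model, core_model):
        twice = apply_hydrogenase_constraints(core_model)
        assert model_to_dict(twice) == model_to_dict(core_model)

    def test_missing_reaction_rejected(self, raw_core_model):
        broken = raw_core_model.copy()
        broken.reactions = [r for r in broken.reactions if r.id != "ECH"]
        with pytest.raises(Exception, match="ECH"):
            apply_hydrogenase_constraints(broken)

    def test_negative_cap_rejected(self):
        with pytest.raises(ValueError):
            HydrogenaseConstraintSet(h2_yield_cap=-0.1)


class TestStrains:
    def test_wt_is_identity(self, core_model):
        assert model_to_dict(strain(core_model, "WT")) == \
            model_to_dict(core_model)

    def test_unknown_strain_lists_valid_names(self, core_model):
        with pytest.raises(ValueError, match="ldh_hfs"):
            strain(core_model, "nope")

    def test_electron_strategy_costs_growth(self, core_model):
        wt = solve_fba(core_model).objective_value
        hfs = solve_fba(strain(core_model, "ldh_hfs")).objective_value
        assert 0 < hfs < wt - 1e-6

    def test_all_strains_remain_viable(self, core_model):
        for name in ("WT", "ldh_pta", "ldh_hfs", "ldh_hfs_glud"):
            res = solve_fba(strain(core_model, name))
            assert res.ok and res.objective_value > 0.1

    def test_triple_knockout_guarantees_at_least_double(self, core_model):
        double = coupling_strength(strain(core_model, "ldh_hfs"), "EX_etoh")
        triple = coupling_strength(strain(core_model, "ldh_hfs_glud"),
                                   "EX_etoh")
        assert triple >= double - 1e-9


class TestAmmoniumAssimilation:
    """Stoichiometric ATP accounting over the two assimilation routes."""

    def test_direct_route_costs_no_atp(self, core_model):
        assert ammonium_assimilation_atp_cost(core_model, "GLUD") == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_step_route_costs_one_atp(self, core_model):
        assert ammonium_assimilation_atp_cost(core_model, "GLNS_GLUS") == \
            pytest.approx(1.0, abs=1e-12)

    def test_route_difference_is_exactly_one(self, core_model):
        diff = ammonium_assimilation_atp_cost(core_model, "GLNS+GLUS") - \
            ammonium_assimilation_atp_cost(core_model, "glud")
        assert diff == pytest.approx(1.0, abs=1e-12)

    def test_independent_of_bounds_and_scale(self, core_model):
        rescaled = core_model.copy()
        for r in rescaled.reactions:
            r.lower_bound *= 7.0
            r.upper_bound *= 7.0
        assert ammonium_assimilation_atp_cost(rescaled, "GLNS_GLUS") == 1.0

    def test_unknown_route(self, core_model):
        with pytest.raises(ValueError, match="route"):
            ammonium_assimilation_atp_cost(core_model, "nope")
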