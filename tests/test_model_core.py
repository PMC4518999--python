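"""Stoichiometric data model: S matrix, validation, gene rules, knockouts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoflux.model import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    RuleSyntaxError,
    assemble_stoichiometric_matrix,
    evaluate_gene_rule,
    knock_out_reactions,
    reactions_disabled_by_genes,
    validate,
)


def two_met_model():
    m = MetabolicModel(id="toy")
    m.metabolites = [Metabolite(id="A[c]"), Metabolite(id="B[c]")]
    m.reactions = [Reaction(id="R1",
                            stoichiometry={"A[c]": -1.0, "B[c]": 1.0})]
    return m


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        S, mets, rxns = assemble_stoichiometric_matrix(two_met_model())
        assert S.shape == (2, 1)
        assert S[mets.index("A[c]"), 0] == -1.0
        assert S[mets.index("B[c]"), 0] == 1.0

    def test_glutamine_synthetase_column(self, core_model):
        # one ATP and one ammonium consumed per glutamine formed
        S, mets, rxns = assemble_stoichiometric_matrix(core_model)
        col = S[:, rxns.index("GLNS")]
        expected = {"glu-L[c]": -1, "ATP[c]": -1, "NH4[c]": -1,
                    "ADP[c]": 1, "Pi[c]": 1, "H[c]": 1, "gln-L[c]": 1}
        for met, coef in expected.items():
            assert col[mets.index(met)] == coef
        assert np.count_nonzero(col) == len(expected)

    def test_empty_model(self):
        S, mets, rxns = assemble_stoichiometric_matrix(MetabolicModel())
        assert S.shape == (0, 0)

    def test_unresolved_metabolite_raises(self):
        m = two_met_model()
        m.reactions[0].stoichiometry["ghost[c]"] = 1.0
        with pytest.raises(ModelStructureError, match="R1.*ghost"):
            assemble_stoichiometric_matrix(m)


class TestValidate:
    def test_clean_toy_model(self):
        m = two_met_model()
        report = validate(m)
        assert report.ok
        assert report.statistics["reactions"] == 1
        assert report.statistics["metabolites"] == 2

    def test_inverted_bounds_reported(self):
        m = two_met_model()
        m.reactions[0].lower_bound, m.reactions[0].upper_bound = 5.0, 1.0
        report = validate(m)
        assert ("BOUNDS_INVERTED" in {code for code, _ in report.errors})

    def test_duplicate_and_unresolved(self):
        m = two_met_model()
        m.metabolites.append(Metabolite(id="A[c]"))
        m.reactions.append(Reaction(id="R1", stoichiometry={"X[c]": 1.0}))
        codes = {code for code, _ in validate(m).errors}
        assert {"DUPLICATE_METABOLITE", "DUPLICATE_REACTION",
                "UNRESOLVED_METABOLITE"} <= codes

    def test_orphan_metabolite_is_warning_only(self):
        m = two_met_model()
        m.metabolites.append(Metabolite(id="lonely[c]"))
        report = validate(m)
        assert report.ok
        assert ("ORPHAN_METABOLITE", "lonely[c]") in report.warnings

    def test_elemental_imbalance_is_advisory(self):
        m = two_met_model()
        m.metabolites[0].formula = "C2H4"
        m.metabolites[1].formula = "C2H6"
        report = validate(m)
        assert report.ok
        assert "ELEMENTAL_IMBALANCE" in {c for c, _ in report.warnings}

    def test_balanced_reaction_no_warning(self):
        m = two_met_model()
        m.metabolites[0].formula = "C2H4O"
        m.metabolites[1].formula = "C2H4O"
        assert validate(m).warnings == []

    def test_mass_balance_of_annotated_core_reactions(self, core_model):
        # every elementally annotated, non-exchange reaction balances
        assert not [w for w in validate(core_model).warnings
                    if w[0] == "ELEMENTAL_IMBALANCE"]


class TestGeneRules:
    def test_four_gene_conjunction(self):
        rule = GeneRule.parse(
            "Tsac_1550 & Tsac_1551 & Tsac_1552 & Tsac_1553")
        assert rule.evaluate(set())
        # losing any single subunit gene kills the complex
        for g in rule.genes():
            assert not rule.evaluate({g})

    def test_single_gene(self):
        rule = GeneRule.parse("Tsac_0179")
        assert rule.evaluate(set())
        assert not rule.evaluate({"Tsac_0179"})

    def test_or_of_and(self):
        rule = GeneRule.parse("(a & b) | c")
        assert rule.evaluate({"a"})           # isozyme c still there
        assert not rule.evaluate({"a", "c"})
        assert rule.evaluate({"b"})

    def test_empty_rule_is_always_true(self):
        assert evaluate_gene_rule(GeneRule.parse(""), {"anything"})
        assert evaluate_gene_rule(GeneRule.parse(None), set())

    @pytest.mark.parametrize("bad", ["a &", "(a | b", "a b", "& a", "a |)"])
    def test_malformed_rules_raise(self, bad):
        with pytest.raises(RuleSyntaxError):
            GeneRule.parse(bad)

    def test_string_round_trip(self):
        text = "(a & b) | (c & d) | e"
        rule = GeneRule.parse(text)
        assert GeneRule.parse(rule.to_string()) == rule

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_deletion_monotonicity(self, data):
        """Growing the deletion set can only flip catalysed -> dead."""
        genes = [f"g{i}" for i in range(6)]
        expr = data.draw(st.recursive(
            st.sampled_from(genes),
            lambda children: st.tuples(
                st.sampled_from(["&", "|"]),
                st.lists(children, min_size=2, max_size=3)),
            max_leaves=8))

        def to_text(node):
            if isinstance(node, str):
                return node
            op, parts = node
            return "(" + f" {op} ".join(to_text(p) for p in parts) + ")"

        rule = GeneRule.parse(to_text(expr))
        small = set(data.draw(st.sets(st.sampled_from(genes), max_size=4)))
        extra = set(data.draw(st.sets(st.sampled_from(genes), max_size=4)))
        if not rule.evaluate(small):
            assert not rule.evaluate(small | extra)


class TestKnockouts:
    def test_bounds_zeroed_and_original_untouched(self, core_model):
        ko = knock_out_reactions(core_model, {"LDH_L"})
        assert ko.get_reaction("LDH_L").lower_bound == 0.0
        assert ko.get_reaction("LDH_L").upper_bound == 0.0
        assert core_model.get_reaction("LDH_L").upper_bound > 0
        assert len(ko.reactions) == len(core_model.reactions)
        assert len(ko.metabolites) == len(core_model.metabolites)

    def test_empty_set_is_identity(self, core_model):
        ko = knock_out_reactions(core_model, set())
        assert [(r.lower_bound, r.upper_bound) for r in ko.reactions] == \
            [(r.lower_bound, r.upper_bound) for r in core_model.reactions]

    def test_unknown_ids_listed(self, core_model):
        with pytest.raises(ModelStructureError, match="NOPE"):
            knock_out_reactions(core_model, {"LDH_L", "NOPE"})


class TestGeneDeletionPropagation:
    def test_single_gene_deletion_maps_to_reaction(self, core_model):
        assert reactions_disabled_by_genes(core_model, {"Tsac_0179"}) == \
            {"LDH_L"}

    @pytest.mark.parametrize(
        "gene", ["Tsac_1550", "Tsac_1551", "Tsac_1552", "Tsac_1553"])
    def test_any_hydrogenase_subunit_disables_complex(self, core_model, gene):
        assert "HFS" in reactions_disabled_by_genes(core_model, {gene})

    def test_empty_deletion_set(self, core_model):
        assert reactions_disabled_by_genes(core_model, set()) == set()
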