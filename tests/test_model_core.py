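"""GPR parsing/evaluation, model validation, and JSON round-trips."""

import json
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polygea import (
    EMPTY_RULE,
    BoolAnd,
    BoolOr,
    GeneLeaf,
    GPRParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    evaluate_gpr,
    parse_gpr,
    reactions_disabled_by,
    read_model,
    write_model,
)
from polygea.model import model_from_dict, model_to_dict

MAT_RULE = BoolOr((GeneLeaf("MAT1A"), BoolAnd((GeneLeaf("MAT2A"), GeneLeaf("MAT2B")))))


class TestParseGPR:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("MAT1A or (MAT2A and MAT2B)", MAT_RULE),
            ("", EMPTY_RULE),
            ("   ", EMPTY_RULE),
            ("A and (B or C)", BoolAnd((GeneLeaf("A"), BoolOr((GeneLeaf("B"), GeneLeaf("C")))))),
            ("A", GeneLeaf("A")),
            ("a OR b Or c", BoolOr((GeneLeaf("a"), GeneLeaf("b"), GeneLeaf("c")))),
            ("((A))", GeneLeaf("A")),
        ],
    )
    def test_grammar(self, text, expected):
        assert parse_gpr(text) == expected

    @pytest.mark.parametrize(
        "text", ["A and (B or C", "A)", "(", "and A", "A or", "A B", "not A", "A and not B"]
    )
    def test_malformed_rules_rejected_with_position(self, text):
        with pytest.raises(GPRParseError) as exc:
            parse_gpr(text)
        assert "position" in str(exc.value)

    def test_unknown_gene_leaf_fails_validation(self):
        with pytest.raises(ModelValidationError, match="ODC1"):
            parse_gpr("ODC1", known_genes={"AMD1"})

    @pytest.mark.parametrize(
        "text", ["MAT1A or (MAT2A and MAT2B)", "A and (B or C) and D", "(A or B) and (C or D)"]
    )
    def test_round_trip_through_canonical_serializer(self, text):
        rule = parse_gpr(text)
        assert parse_gpr(rule.to_string()) == rule


class TestEvaluateGPR:
    @pytest.mark.parametrize(
        "deleted,expected",
        [
            ({"MAT1A", "MAT2A"}, False),  # synthetic lethal combination
            ({"MAT2A", "MAT2B"}, True),   # MAT1A isozyme survives
            ({"MAT1A"}, True),
            (set(), True),
        ],
    )
    def test_isozyme_complex_rule(self, deleted, expected):
        assert evaluate_gpr(MAT_RULE, deleted) is expected

    def test_empty_rule_survives_total_deletion(self):
        assert evaluate_gpr(EMPTY_RULE, {"MAT1A", "MAT2A", "MAT2B"}) is True

    @given(
        deleted=st.sets(st.sampled_from(["A", "B", "C", "D"])),
        extra=st.sets(st.sampled_from(["A", "B", "C", "D"])),
    )
    @settings(max_examples=200, derandomize=True)
    def test_evaluation_is_monotone_in_deletions(self, deleted, extra):
        """Enlarging the deleted set can never re-enable an AND/OR rule."""
        rule = parse_gpr("(A or B) and (C or (A and D))")
        if not evaluate_gpr(rule, deleted):
            assert not evaluate_gpr(rule, deleted | extra)


class TestReactionsDisabledBy:
    def test_single_gene_disables_its_sole_reaction(self, minimodel):
        assert reactions_disabled_by(minimodel, {"ODC1"}) == {"R_ODC1"}

    def test_empty_deletion_disables_nothing(self, minimodel):
        assert reactions_disabled_by(minimodel, set()) == frozenset()

    def test_pair_deletion_matches_brute_force(self, minimodel):
        """N({APRT, PNP}) computed by evaluating every GPR directly."""
        deleted = {"APRT", "PNP"}
        expected = frozenset(
            r.id for r in minimodel.reactions if not r.gpr.evaluate(frozenset(deleted))
        )
        assert expected == frozenset({"R_APRT", "R_PNP_ade"})
        assert reactions_disabled_by(minimodel, deleted) == expected

    def test_unknown_gene_rejected(self, minimodel):
        with pytest.raises(ModelValidationError):
            reactions_disabled_by(minimodel, {"NOT_A_GENE"})


class TestSerialization:
    def test_write_read_round_trip(self, minimodel, tmp_path):
        path = tmp_path / "model.json"
        write_model(minimodel, path)
        loaded = read_model(path)
        assert model_to_dict(loaded) == model_to_dict(minimodel)

    def test_round_trip_preserves_exact_fractions(self, tmp_path):
        model = MetabolicModel(
            metabolites=[Metabolite("a"), Metabolite("b")],
            reactions=[
                Reaction("EX_a", {"a": Fraction(-1)}, lower_bound=-10.0,
                         reversible=True, is_exchange=True),
                Reaction("R1", {"a": Fraction(-1, 3), "b": Fraction(2, 7)}),
                Reaction("BIO", {"b": Fraction("-0.01")}),
            ],
            genes=set(),
            biomass_reaction_id="BIO",
        )
        path = tmp_path / "m.json"
        write_model(model, path)
        loaded = read_model(path)
        r1 = loaded.reaction("R1")
        assert r1.stoichiometry == {"a": Fraction(-1, 3), "b": Fraction(2, 7)}
        assert loaded.reaction("BIO").stoichiometry == {"b": Fraction(-1, 100)}

    def test_missing_biomass_id_is_reported(self, minimodel, tmp_path):
        data = model_to_dict(minimodel)
        del data["biomass_reaction_id"]
        with pytest.raises(ModelValidationError, match="biomass_reaction_id"):
            model_from_dict(data)

    def test_validation_errors_are_aggregated(self, minimodel):
        data = model_to_dict(minimodel)
        data["biomass_reaction_id"] = "NOPE"
        data["reactions"][7]["stoichiometry"]["ghost_met"] = 1
        with pytest.raises(ModelValidationError) as exc:
            model_from_dict(data)
        assert len(exc.value.errors) >= 2

    def test_handwritten_cobra_style_export_loads(self, tmp_path):
        """A minimal COBRA-JSON-style file with only supported fields."""
        doc = {
            "metabolites": [{"id": "glc"}, {"id": "pyr"}],
            "reactions": [
                {"id": "EX_glc", "stoichiometry": {"glc": -1},
                 "lower_bound": -5, "upper_bound": 1000,
                 "reversible": True, "is_exchange": True},
                {"id": "GLYC", "stoichiometry": {"glc": -1, "pyr": 2},
                 "upper_bound": 1000, "gpr": "g1 or g2"},
                {"id": "BIO", "stoichiometry": {"pyr": -1}, "upper_bound": 1000},
            ],
            "genes": ["g1", "g2"],
            "biomass_reaction_id": "BIO",
            "medium": {"EX_glc": 5},
        }
        path = tmp_path / "tiny.json"
        path.write_text(json.dumps(doc))
        model = read_model(path)
        assert model.reaction("GLYC").stoichiometry["pyr"] == 2
        assert model.reaction("GLYC").gpr.genes() == {"g1", "g2"}

    def test_shipped_fixture_json_matches_code_built_model(self, minimodel):
        from pathlib import Path

        path = Path(__file__).parent / "data" / "polyamine_minimodel.json"
        assert model_to_dict(read_model(path)) == model_to_dict(minimodel)
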