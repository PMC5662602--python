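"""Single/double deletion screens, differential essentiality, threshold sweep."""

import pytest

from polygea import (
    DEFAULT_THRESHOLD,
    ScreenError,
    build_polyamine_minimodel,
    differential_essentials,
    double_deletion_screen,
    single_deletion_screen,
    threshold_sweep,
)
from polygea.screen import _GrowthCache
from polygea.fba import DEFAULT_CONFIG

TABLE1_ESSENTIAL = {"AMD1", "MTAP", "ODC1", "SRM"}
TABLE1_PAIRS = {
    ("APRT", "PNP"),
    ("ARG1", "OAT"),
    ("MAT1A", "MAT2A"),
    ("MAT1A", "MAT2B"),
}


class TestSingleDeletion:
    def test_uncorrected_model_recovers_polyamine_essentials(self, minimodel):
        res = single_deletion_screen(minimodel)
        assert TABLE1_ESSENTIAL <= res.essential_genes
        # the fixture includes the spermine synthase step, so SMS is also
        # essential under a spermine-containing biomass
        assert res.essential_genes - TABLE1_ESSENTIAL <= {"SMS"}

    def test_pnp_correction_makes_aprt_essential(self, corrected_minimodel):
        res = single_deletion_screen(corrected_minimodel)
        assert "APRT" in res.essential_genes
        assert TABLE1_ESSENTIAL | {"APRT"} <= res.essential_genes

    def test_unamended_biomass_has_no_pathway_essentials(self, base_minimodel):
        res = single_deletion_screen(base_minimodel)
        assert res.essential_genes == frozenset()

    def test_gene_without_gpr_occurrence_is_trivially_nonessential(self, minimodel):
        model = minimodel.copy()
        model.genes = set(model.genes) | {"ORPHAN"}
        res = single_deletion_screen(model)
        assert res.single_growth["ORPHAN"] == res.growth_wildtype
        assert "ORPHAN" not in res.essential_genes

    def test_nonviable_model_is_rejected(self, minimodel):
        from polygea import apply_medium

        starved = apply_medium(minimodel, {})
        with pytest.raises(ScreenError, match="cannot grow"):
            single_deletion_screen(starved)

    def test_growth_exactly_at_threshold_is_nonessential(self, minimodel):
        """Essentiality uses strict inequality: a tie at the threshold survives."""
        res = single_deletion_screen(minimodel, threshold=10.0)
        # every non-lethal knockout grows at exactly wild-type (10.0)
        assert "MAT1A" not in res.essential_genes
        assert res.single_growth["MAT1A"] == pytest.approx(10.0, abs=1e-6)


class TestDoubleDeletion:
    def test_uncorrected_model_recovers_synthetic_lethal_pairs(self, minimodel):
        res = double_deletion_screen(minimodel)
        assert res.synthetic_lethal_pairs == frozenset(TABLE1_PAIRS)
        for a, b in TABLE1_PAIRS:
            assert a not in res.essential_genes
            assert b not in res.essential_genes

    def test_correction_removes_aprt_pnp_pair(self, corrected_minimodel):
        res = double_deletion_screen(corrected_minimodel)
        assert ("APRT", "PNP") not in res.synthetic_lethal_pairs
        assert res.synthetic_lethal_pairs == frozenset(TABLE1_PAIRS - {("APRT", "PNP")})

    def test_pair_growth_keys_are_canonically_sorted(self, minimodel):
        res = double_deletion_screen(minimodel)
        assert all(a < b for a, b in res.pair_growth)

    def test_pair_growth_bounded_by_single_growths(self, minimodel):
        res = double_deletion_screen(minimodel)
        for (a, b), v in res.pair_growth.items():
            assert v <= min(res.single_growth[a], res.single_growth[b]) + 1e-9

    def test_candidate_restriction(self, minimodel):
        res = double_deletion_screen(minimodel, candidates={"MAT1A", "MAT2A", "ARG1"})
        assert set(res.pair_growth) == {("ARG1", "MAT1A"), ("ARG1", "MAT2A"), ("MAT1A", "MAT2A")}
        assert res.synthetic_lethal_pairs == {("MAT1A", "MAT2A")}

    def test_unknown_candidate_rejected(self, minimodel):
        from polygea import ModelValidationError

        with pytest.raises(ModelValidationError):
            double_deletion_screen(minimodel, candidates={"MAT1A", "NOPE"})

    def test_genes_absent_from_gprs_form_no_pair(self, minimodel):
        model = minimodel.copy()
        model.genes = set(model.genes) | {"X1", "X2"}
        res = double_deletion_screen(model)
        assert ("X1", "X2") not in res.pair_growth

    def test_memoization_solves_each_disabled_set_once(self, minimodel):
        from polygea import reactions_disabled_by

        cache = _GrowthCache(minimodel, DEFAULT_CONFIG)
        single_deletion_screen(minimodel, _cache=cache)
        distinct = {
            reactions_disabled_by(minimodel, {g}) for g in minimodel.genes
        } - {frozenset()}
        # wild-type + one LP per distinct nonempty disabled-reaction set;
        # genes disabling nothing (e.g. each MAT isozyme alone) cost no LP
        assert cache.lp_solves == 1 + len(distinct)


class TestDifferential:
    def test_polyamine_amendment_yields_table1_hits(self, base_minimodel, minimodel):
        base = double_deletion_screen(base_minimodel)
        augmented = double_deletion_screen(minimodel)
        diff = differential_essentials(base, augmented)
        assert diff.gained_essential & (TABLE1_ESSENTIAL | {"APRT", "PNP"}) == TABLE1_ESSENTIAL
        assert diff.gained_synthetic_lethal == frozenset(TABLE1_PAIRS)

    def test_identical_inputs_give_empty_report(self, minimodel):
        res = double_deletion_screen(minimodel)
        assert differential_essentials(res, res).empty()

    def test_threshold_mismatch_rejected(self, base_minimodel):
        a = single_deletion_screen(base_minimodel, threshold=1e-4)
        b = single_deletion_screen(base_minimodel, threshold=1e-3)
        with pytest.raises(ScreenError, match="threshold"):
            differential_essentials(a, b)

    def test_gene_universe_mismatch_rejected(self, base_minimodel, minimodel):
        other = minimodel.copy()
        other.genes = set(other.genes) | {"EXTRA"}
        a = single_deletion_screen(base_minimodel)
        b = single_deletion_screen(other)
        with pytest.raises(ScreenError, match="universe"):
            differential_essentials(a, b)


class TestThresholdSweep:
    def test_fixture_sets_stable_below_wildtype(self, minimodel):
        """All knockout growths are exactly 0 or wild-type, so the essential
        set is identical across any thresholds strictly between the two."""
        sweep = threshold_sweep(minimodel, [1e-6, 1e-4, 1e-2])
        assert sweep[1e-6] == sweep[1e-4] == sweep[1e-2]

    def test_sets_monotone_in_threshold(self, minimodel):
        sweep = threshold_sweep(minimodel, [1e-6, 1e-4, 1e-2, 1.0, 5.0])
        chain = [sweep[t] for t in sorted(sweep)]
        for lo, hi in zip(chain, chain[1:]):
            assert lo <= hi

    def test_threshold_above_wildtype_rejected(self, minimodel):
        with pytest.raises(ScreenError, match="exceeds wild-type"):
            threshold_sweep(minimodel, [11.0])

    def test_single_threshold_matches_single_screen(self, minimodel):
        sweep = threshold_sweep(minimodel, [DEFAULT_THRESHOLD])
        res = single_deletion_screen(minimodel)
        assert sweep[DEFAULT_THRESHOLD] == res.essential_genes
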