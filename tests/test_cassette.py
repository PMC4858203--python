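import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riplet import (
    CassetteSpec,
    DnaSegment,
    HomologyPattern,
    PERFECT,
    compose_cassette,
    delete_unit_triplet,
    enumerate_unit_triplets,
    generate_test,
    mask_runs,
    percent_identity,
)

from conftest import random_cassette, random_segment


class TestGenerateTest:
    def test_mask_sequence_consistency(self, reference_550):
        cassette = generate_test(reference_550, HomologyPattern(4, 7, 1, 550), seed=3)
        cassette.validate()  # raises on any mask/sequence disagreement

    def test_mismatch_forced_at_every_nonhomologous_position(self, reference_550):
        for seed in range(5):
            c = generate_test(reference_550, HomologyPattern(4, 7, 1, 550), seed)
            ref = np.array(list(c.reference_copy.seq))
            test = np.array(list(c.test_copy.seq))
            assert (ref[~c.homology_mask] != test[~c.homology_mask]).all()
            assert (ref[c.homology_mask] == test[c.homology_mask]).all()

    def test_deterministic_and_seed_sensitive(self, reference_550):
        p = HomologyPattern(4, 7, 1, 550)
        a = generate_test(reference_550, p, seed=9)
        b = generate_test(reference_550, p, seed=9)
        c = generate_test(reference_550, p, seed=10)
        assert a.test_copy.seq == b.test_copy.seq
        assert c.test_copy.seq != a.test_copy.seq
        # different seeds differ only at non-homologous positions
        diff = np.array(list(a.test_copy.seq)) != np.array(list(c.test_copy.seq))
        assert not diff[a.homology_mask].any()

    def test_perfect_pattern_returns_reference(self, reference_550):
        c = generate_test(reference_550, PERFECT, seed=0)
        assert c.test_copy.seq == reference_550.seq
        assert c.homology_mask.all()

    def test_length_mismatch_rejected(self, reference_550):
        with pytest.raises(ValueError, match="550"):
            generate_test(reference_550, HomologyPattern(4, 7, 1, 500), seed=0)

    def test_substitution_uniformity(self):
        """Each of the 3 alternative bases appears with frequency 1/3 within
        3 standard errors, over >= 10,000 substituted positions."""
        ref = random_segment(12000, seed=5)
        c = generate_test(ref, HomologyPattern(1, 11, 1, 12000), seed=77)
        subs = np.flatnonzero(~c.homology_mask)
        assert subs.size >= 10000
        # classify each substitution by the alternative's rank among the 3 options
        ranks = []
        for i in subs:
            alternatives = [b for b in "ACGT" if b != ref.seq[i]]
            ranks.append(alternatives.index(c.test_copy.seq[i]))
        counts = np.bincount(ranks, minlength=3)
        n = subs.size
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.abs(counts / n - 1 / 3).max() < 3 * se


class TestPercentIdentity:
    def test_identical_and_disjoint(self):
        a = DnaSegment("a", "ACGT")
        assert percent_identity(a, DnaSegment("b", "ACGT")) == 1.0
        assert percent_identity(a, DnaSegment("b", "TGCA")) == 0.0

    def test_length_mismatch_names_both_lengths(self):
        with pytest.raises(ValueError, match="4.*5|5.*4"):
            percent_identity(DnaSegment("a", "ACGT"), DnaSegment("b", "ACGTA"))

    def test_4h7n_identity_over_full_periods(self, reference_550):
        c = generate_test(reference_550, HomologyPattern(4, 7, 1, 550), seed=1)
        assert percent_identity(c.reference_copy, c.test_copy) == pytest.approx(200 / 550)


class TestDeleteUnitTriplet:
    def _unit_cassette(self, unit: str):
        """One 4-bp homologous unit at position 1 in an 11-bp cassette."""
        ref = DnaSegment("ref", unit + "AAAAAAA")
        pattern = HomologyPattern(4, 7, 1, 11)
        return generate_test(ref, pattern, seed=0)

    @pytest.mark.parametrize(
        "unit, edited",
        [("GACT", "CACT"), ("TGAC", "TGAG")],
    )
    def test_edge_base_complement_rule(self, unit, edited):
        """GAC at unit positions 1-3: G -> C; at positions 2-4: C -> G."""
        c = delete_unit_triplet(self._unit_cassette(unit), "GAC")
        assert c.test_copy.seq[:4] == edited

    def test_overlapping_triplet_preserved(self):
        before = self._unit_cassette("GACT")
        after = delete_unit_triplet(before, "GAC")
        census = enumerate_unit_triplets(after)
        assert census["ACT"] == 1
        assert census["GAC"] == 0

    def test_reverse_complement_occurrence_is_edited(self):
        # GTC is the reverse complement of GAC and must be targeted too
        c = delete_unit_triplet(self._unit_cassette("GTCA"), "GAC")
        assert c.test_copy.seq[:4] != "GTCA"
        assert enumerate_unit_triplets(c)["GAC"] == 0

    def test_no_occurrence_returns_cassette_unchanged(self):
        before = self._unit_cassette("ATTA")
        after = delete_unit_triplet(before, "GAC")
        assert after.test_copy.seq == before.test_copy.seq
        assert (after.homology_mask == before.homology_mask).all()

    def test_edited_position_becomes_nonhomologous(self):
        after = delete_unit_triplet(self._unit_cassette("GACT"), "GAC")
        assert not after.homology_mask[0]
        after.validate()

    def test_first_n_occurrences_only(self, cassette_4h7n):
        census = enumerate_unit_triplets(cassette_4h7n)
        n_gac = census["GAC"]
        if n_gac < 2:
            pytest.skip("fixture has too few GAC units")
        edited = delete_unit_triplet(cassette_4h7n, "GAC", occurrences=2)
        assert enumerate_unit_triplets(edited)["GAC"] == n_gac - 2

    def test_census_reduced_by_edit_count_other_classes_unchanged(self, cassette_4h7n):
        before = enumerate_unit_triplets(cassette_4h7n)
        edited = delete_unit_triplet(cassette_4h7n, "GAC")
        after = enumerate_unit_triplets(edited)
        n_edits = before["GAC"] - after["GAC"]
        assert after["GAC"] == 0
        assert n_edits == before["GAC"]
        # in 4-bp units every edit removes exactly the targeted window
        for t, n in before.counts.items():
            if t != "GAC":
                assert after.counts.get(t, 0) == n


class TestComposeCassette:
    def test_interruption_splits_block_into_38_and_40(self, reference_500):
        spec = CassetteSpec(
            reference_500,
            HomologyPattern(4, 7, 1, 500),
            block_len=100,
            block_side="right",
            interruption=(39, 22),
        )
        c = compose_cassette(spec, seed=5)
        c.validate()
        block_runs = mask_runs(c.homology_mask[500:])
        assert [length for _, length in block_runs] == [38, 40]

    def test_degenerate_spec_equals_generate_test(self, reference_500):
        spec = CassetteSpec(reference_500, HomologyPattern(4, 7, 1, 500))
        composed = compose_cassette(spec, seed=21)
        direct = generate_test(reference_500, HomologyPattern(4, 7, 1, 500), seed=21)
        assert composed.test_copy.seq == direct.test_copy.seq
        assert (composed.homology_mask == direct.homology_mask).all()

    def test_block_adds_its_length_to_homologous_total(self, reference_500):
        pattern = HomologyPattern(4, 7, 1, 500)
        base = generate_test(reference_500, pattern, seed=3)
        spec = CassetteSpec(reference_500, pattern, block_len=15, block_side="left")
        c = compose_cassette(spec, seed=3)
        assert int(c.homology_mask.sum()) == int(base.homology_mask.sum()) + 15
        assert len(c) == 515

    def test_block_does_not_perturb_region_sequence(self, reference_500):
        pattern = HomologyPattern(4, 7, 1, 500)
        with_block = compose_cassette(
            CassetteSpec(reference_500, pattern, block_len=100, block_side="left",
                         junction_insert_len=11),
            seed=8,
        )
        without = compose_cassette(CassetteSpec(reference_500, pattern), seed=8)
        assert with_block.test_copy.seq[111:] == without.test_copy.seq

    def test_junction_insert_is_nonhomologous(self, reference_500):
        spec = CassetteSpec(
            reference_500, HomologyPattern(4, 7, 1, 500),
            block_len=100, block_side="left", junction_insert_len=11,
        )
        c = compose_cassette(spec, seed=2)
        c.validate()
        assert len(c) == 611
        assert not c.homology_mask[100:111].any()

    def test_patterned_block(self, reference_500):
        spec = CassetteSpec(
            reference_500, HomologyPattern(4, 7, 1, 500),
            block_len=100, block_side="right",
            block_pattern=HomologyPattern(6, 4, 11, 100),
        )
        c = compose_cassette(spec, seed=4)
        c.validate()
        block_mask = c.homology_mask[500:]
        from riplet import homology_mask as hm
        assert (block_mask == hm(HomologyPattern(6, 4, 11, 100))).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(block_len=100, block_side="none"),
            dict(block_len=0, block_side="left"),
            dict(block_len=100, block_side="left", interruption=(90, 22)),
            dict(block_len=0, block_side="none", junction_insert_len=11),
        ],
    )
    def test_invalid_specs_rejected(self, reference_500, kwargs):
        with pytest.raises(ValueError):
            CassetteSpec(reference_500, HomologyPattern(4, 7, 1, 500), **kwargs)

    def test_deterministic(self, reference_500):
        spec = CassetteSpec(
            reference_500, HomologyPattern(4, 7, 1, 500),
            block_len=50, block_side="right", junction_insert_len=11,
        )
        assert (
            compose_cassette(spec, seed=1).test_copy.seq
            == compose_cassette(spec, seed=1).test_copy.seq
        )


@settings(max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000), density=st.floats(0.2, 0.8))
def test_random_cassettes_satisfy_mask_invariant(seed, density):
    random_cassette(120, seed, density).validate()
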