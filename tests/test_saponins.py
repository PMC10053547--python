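"""Peak annotation, differential sets and the reference profile fixture."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scabra import synthetic as syn
from scabra.saponins import (
    JUVENILE_INTEGUMENT,
    LEUCOSPILOTA_MUCUS,
    LibraryEntry,
    SampleProfile,
    SaponinLibrary,
    SaponinProfileSet,
    annotate_peaks,
    attractive_unique,
    diversity_summary,
    profile_matrix,
)


class TestLibrary:
    def test_duplicate_mz_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SaponinLibrary(
                [LibraryEntry(("a",), 905.4, 2), LibraryEntry(("b",), 905.4, 2)]
            )

    def test_nominal_mz_truncates(self):
        assert LibraryEntry(("Holothurin B",), 905.4, 2).nominal_mz == 905

    def test_reference_library_shape(self, reference_library):
        assert len(reference_library) == 16
        assert 905.4 in reference_library
        assert reference_library[905.4].n_sugars == 2
        # isomeric structures share one entry keyed on m/z
        assert len(reference_library[1243.3].names) == 3


class TestAnnotatePeaks:
    def test_nearest_match_within_tolerance(self, reference_library):
        detected, unmatched = annotate_peaks(
            [905.38, 889.41], reference_library, tolerance=0.5
        )
        assert detected == {905.4, 889.4}
        assert unmatched == []

    def test_far_peak_unmatched(self, reference_library):
        detected, unmatched = annotate_peaks([700.0], reference_library, tolerance=0.5)
        assert detected == set() and unmatched == [700.0]

    def test_nearest_wins_on_conflict(self, reference_library):
        detected, unmatched = annotate_peaks(
            [905.4, 905.45], reference_library, tolerance=0.5
        )
        assert detected == {905.4}
        assert unmatched == [905.45]

    def test_negative_tolerance_rejected(self, reference_library):
        with pytest.raises(ValueError, match="tolerance"):
            annotate_peaks([905.4], reference_library, tolerance=-1.0)

    @given(
        st.lists(
            st.floats(min_value=850.0, max_value=1350.0, allow_nan=False),
            max_size=10,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_assignments_respect_tolerance(self, peaks):
        from scabra.saponins import load_reference_library

        library = load_reference_library()
        detected, unmatched = annotate_peaks(peaks, library, tolerance=0.5)
        # one entry per matched peak, never more detections than peaks
        assert len(detected) + len(unmatched) == len(peaks)
        for mz in detected:
            assert min(abs(p - mz) for p in peaks) <= 0.5


def _tiny_set(attractive_detected, nonattractive_detected):
    lib = SaponinLibrary(
        [
            LibraryEntry(("A",), 900.0, 2),
            LibraryEntry(("B",), 910.0, 2),
            LibraryEntry(("C",), 1100.0, 4),
        ]
    )
    samples = [
        SampleProfile(f"att_{i}", True, d) for i, d in enumerate(attractive_detected)
    ] + [
        SampleProfile(f"non_{i}", False, d)
        for i, d in enumerate(nonattractive_detected)
    ]
    return SaponinProfileSet(lib, samples)


class TestAttractiveUnique:
    def test_all_rule_requires_every_attractive_sample(self):
        ps = _tiny_set([{900.0, 910.0}, {900.0}], [{1100.0}])
        assert {e.mz_na for e in attractive_unique(ps, "all-attractive")} == {900.0}
        assert {e.mz_na for e in attractive_unique(ps, "any-attractive")} == {900.0, 910.0}

    def test_blocked_by_any_nonattractive_presence(self):
        ps = _tiny_set([{900.0, 910.0}], [{910.0}])
        assert {e.mz_na for e in attractive_unique(ps, "any-attractive")} == {900.0}

    def test_empty_attractive_sets_give_empty_result(self):
        ps = _tiny_set([frozenset(), frozenset()], [{1100.0}])
        assert attractive_unique(ps, "any-attractive") == []

    def test_no_nonattractive_samples_is_error(self):
        lib = SaponinLibrary([LibraryEntry(("A",), 900.0, 2)])
        ps = SaponinProfileSet(lib, [SampleProfile("a", True, {900.0})])
        with pytest.raises(ValueError, match="non-attractive"):
            attractive_unique(ps)

    def test_all_subset_of_any(self, reference_profiles):
        all_rule = {e.mz_na for e in attractive_unique(reference_profiles, "all-attractive")}
        any_rule = {e.mz_na for e in attractive_unique(reference_profiles, "any-attractive")}
        assert all_rule <= any_rule

    def test_result_never_in_nonattractive(self, reference_profiles):
        result = attractive_unique(reference_profiles, "any-attractive")
        for s in reference_profiles.nonattractive_samples:
            assert not {e.mz_na for e in result} & s.detected

    def test_reference_all_attractive_differential(self, reference_profiles):
        """The two disaccharides shared by every attractive extract."""
        result = attractive_unique(reference_profiles, "all-attractive")
        assert {e.mz_na for e in result} == {889.4, 905.4}
        names = {n for e in result for n in e.names}
        assert "Holothurin B3" in names and "Holothurin B4" in names

    def test_reference_two_sugar_juvenile_exclusives(self, reference_profiles):
        result = attractive_unique(
            reference_profiles,
            rule="any-attractive",
            sugar_filter=2,
            focal_samples={JUVENILE_INTEGUMENT},
        )
        assert {e.mz_na for e in result} == {873.0, 889.4, 905.4}
        assert max(e.nominal_mz for e in result) == 905


class TestProfileMatrixAndDiversity:
    def test_reference_matrix_shape_and_column_sums(self, reference_profiles):
        m = profile_matrix(reference_profiles)
        assert m.shape == (16, 5)
        sums = m.sum().to_dict()
        assert sums[JUVENILE_INTEGUMENT] == 10
        assert sums[LEUCOSPILOTA_MUCUS] == 11
        assert list(m.index) == sorted(m.index, reverse=True)
        assert m.attrs["attractive"][JUVENILE_INTEGUMENT] is True

    def test_leucospilota_has_highest_diversity(self, reference_profiles):
        div = diversity_summary(reference_profiles)
        assert div["n_detected"].idxmax() == LEUCOSPILOTA_MUCUS

    def test_juvenile_two_sugar_count(self, reference_profiles):
        div = diversity_summary(reference_profiles)
        assert div.loc[JUVENILE_INTEGUMENT, "sugars_2"] == 3

    def test_single_sample_single_compound(self):
        lib = SaponinLibrary([LibraryEntry(("A",), 900.0, 2)])
        ps = SaponinProfileSet(
            lib,
            [SampleProfile("a", True, {900.0}), SampleProfile("b", False, frozenset())],
        )
        m = profile_matrix(ps)
        assert m.shape == (1, 2) and bool(m.loc[900.0, "a"]) is True

    def test_empty_sample_breakdown_all_zero(self):
        lib = SaponinLibrary([LibraryEntry(("A",), 900.0, 2)])
        ps = SaponinProfileSet(
            lib, [SampleProfile("a", True, frozenset()), SampleProfile("b", False, frozenset())]
        )
        div = diversity_summary(ps)
        assert (div[["n_detected", "sugars_2"]] == 0).all().all()


class TestGeneratedProfiles:
    def test_markers_always_in_differential(self, reference_library):
        markers = {905.4, 889.4}
        for seed in range(30):
            ps = syn.gen_profiles(reference_library, 3, 2, markers, 0.3, seed)
            result = {e.mz_na for e in attractive_unique(ps, "all-attractive")}
            assert markers <= result

    def test_zero_background_empties_nonattractive(self, reference_library):
        ps = syn.gen_profiles(reference_library, 2, 2, [905.4], 0.0, 1)
        for s in ps.nonattractive_samples:
            assert s.detected == frozenset()

    def test_saturated_background_empties_differential(self, reference_library):
        ps = syn.gen_profiles(reference_library, 2, 2, [905.4], 1.0, 2)
        result = attractive_unique(ps, "all-attractive")
        assert {e.mz_na for e in result} == {905.4}  # only markers survive

    def test_unknown_marker_rejected(self, reference_library):
        with pytest.raises(ValueError, match="marker"):
            syn.gen_profiles(reference_library, 1, 1, [123.4], 0.1, 3)
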