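"""Dinucleotide autocorrelation: histogram, normalization, peaks, period."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopattern import (
    IsochoreSegment,
    PeakList,
    PeriodicPlant,
    SegmentSpec,
    SyntheticSpec,
    compute_profile,
    distance_histogram,
    estimate_period,
    find_peaks,
    generate_genome,
    normalize,
    occurrence_positions,
    plant_periodic_dinucleotide,
    profile_by_isochore,
    profile_peaks,
    smooth,
)

from conftest import mseq


def revcomp_masked(seq):
    comp = str.maketrans("ACGTN", "TGCAN")
    return type(seq)(seq.name, seq.bases.translate(comp)[::-1], seq.mask[::-1].copy())


class TestOccurrencePositions:
    @pytest.mark.parametrize(
        "s,dinuc,expected",
        [
            ("CGCG", "CG", [0, 2]),
            ("AAA", "AA", [0, 1]),  # overlaps allowed
            ("CgCG", "CG", [2]),  # masked occurrence excluded
            ("ACGT", "TT", []),
        ],
    )
    def test_examples(self, s, dinuc, expected):
        assert occurrence_positions(mseq(s), dinuc).tolist() == expected

    def test_invalid_dinucleotide(self):
        with pytest.raises(ValueError):
            occurrence_positions(mseq("ACGT"), "CGA")


def brute_force_histogram(positions, d_min, d_max, seq_length):
    """Independent oracle: double loop with the left-member reach rule."""
    counts = np.zeros(d_max - d_min + 1, dtype=int)
    if seq_length < d_max + 4:
        return counts
    for i in positions:
        if i > seq_length - 2 - d_max:
            continue
        for j in positions:
            if d_min <= j - i <= d_max:
                counts[j - i - d_min] += 1
    return counts


class TestDistanceHistogram:
    def test_single_pair(self):
        counts = distance_histogram([0, 3], 2, 80, seq_length=85)
        assert counts[3 - 2] == 1 and counts.sum() == 1

    def test_derived_pair_counts(self):
        counts = distance_histogram([0, 10, 21, 31], 2, 40, seq_length=200)
        expected = brute_force_histogram([0, 10, 21, 31], 2, 40, 200)
        assert np.array_equal(counts, expected)
        assert counts[21 - 2] == 2  # pairs 0-21 and 10-31

    def test_empty_positions(self):
        assert distance_histogram([], 2, 80, seq_length=1000).sum() == 0

    def test_short_sequence_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            counts = distance_histogram([0, 5], 2, 80, seq_length=50)
        assert counts.sum() == 0

    def test_dmin_below_two_rejected(self):
        with pytest.raises(ValueError, match="d_min"):
            distance_histogram([0], 1, 10, seq_length=100)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=300), st.sampled_from(["CG", "AA", "AG"]))
    def test_matches_brute_force_on_random_sequences(self, s, dinuc):
        seq = mseq(s)
        pos = occurrence_positions(seq, dinuc)
        d_max = 20
        counts = distance_histogram(pos, 2, d_max, seq_length=len(s))
        assert np.array_equal(counts, brute_force_histogram(pos.tolist(), 2, d_max, len(s)))


class TestNormalizeSmooth:
    def test_normalize_by_interval_mean(self):
        normed, c = normalize(np.array([1, 1, 4]))
        assert normed.tolist() == [0.5, 0.5, 2.0] and c == 2.0

    def test_uniform_counts_normalize_to_one(self):
        normed, _ = normalize(np.full(79, 7))
        assert np.allclose(normed, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            normalize(np.zeros(5))

    def test_smooth_truncates_at_edges(self):
        assert smooth(np.array([1.0, 1.0, 4.0])).tolist() == [1.0, 2.0, 2.5]

    def test_smooth_window_one_is_identity(self):
        v = np.array([3.0, 1.0, 2.0])
        assert smooth(v, window=1).tolist() == v.tolist()

    def test_smooth_constant_unchanged(self):
        assert np.allclose(smooth(np.full(10, 1.3)), 1.3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.ones(5), window=4)


class TestFindPeaks:
    def test_single_bump(self):
        v = np.ones(30)
        v[8] = 2.0  # d = 10 with d_min = 2
        peaks = find_peaks(v, d_min=2)
        assert peaks.positions == [10]

    def test_equal_maxima_within_separation_keep_leftmost(self):
        v = np.full(20, 0.5)
        v[6] = v[9] = 2.0  # 3 apart < min_separation 5
        peaks = find_peaks(v, d_min=0, min_height=1.0, min_separation=5)
        assert peaks.positions == [6]

    def test_plateau_resolves_leftmost(self):
        v = np.full(20, 0.5)
        v[6] = v[7] = 2.0
        assert find_peaks(v, d_min=0).positions == [6]

    def test_min_height_filters(self):
        v = np.full(20, 0.5)
        v[6] = 0.9
        assert find_peaks(v, d_min=0, min_height=1.0).positions == []

    def test_refinement_moves_to_mass_bin(self):
        # smoothed plateau over two bins; the normalized profile carries the mass at the right bin
        sm = np.full(30, 0.8)
        sm[18] = sm[19] = 2.0
        nz = np.full(30, 0.8)
        nz[18], nz[19] = 1.2, 3.0
        peaks = find_peaks(sm, d_min=2, refine_with=nz)
        assert peaks.positions == [21]  # index 19 + d_min

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            find_peaks(np.array([]))


class TestEstimatePeriod:
    def test_harmonic_regression_fixture(self):
        est = estimate_period(PeakList([10, 21, 31, 42], [1] * 4))
        assert est.period == pytest.approx(313 / 30)
        assert est.n_peaks_used == 4

    def test_exact_multiples(self):
        assert estimate_period([10, 20, 30]).period == pytest.approx(10.0)

    def test_missing_fundamental_documented_consequence(self):
        assert estimate_period([21, 42]).period == pytest.approx(21.0)

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            estimate_period([10])


def planted_genome(seed=0, count=800, jitter=0.0, length=100_000, gc=0.5):
    spec = SyntheticSpec(
        segments=[SegmentSpec(length, gc, "H1")],
        planted_periodicities=[PeriodicPlant("CG", 10.4, count, jitter_sd=jitter)],
        seed=seed,
    )
    return generate_genome(spec)[0]


class TestPlantedSignal:
    def test_normalized_value_at_period_exceeds_baseline(self):
        prof = compute_profile(planted_genome(seed=11), "CG")
        assert prof.normalized[10 - 2] > 1.0

    def test_first_four_peaks_at_rounded_multiples(self):
        peaks = profile_peaks(compute_profile(planted_genome(seed=12), "CG"))
        assert peaks.positions[:4] == [10, 21, 31, 42]

    def test_iid_background_profile_is_flat(self):
        """No plants: every smoothed value within 20% of the 1.00 level."""
        seq, _ = generate_genome(
            SyntheticSpec(segments=[SegmentSpec(100_000, 0.5, "H1")], seed=13)
        )
        prof = compute_profile(seq, "CG")
        assert prof.smoothed.min() > 0.8 and prof.smoothed.max() < 1.2

    def test_normalized_profile_mean_is_one(self):
        prof = compute_profile(planted_genome(seed=14), "CG")
        assert prof.normalized.mean() == pytest.approx(1.0, abs=1e-12)


class TestStrandSymmetry:
    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGTacgt", min_size=40, max_size=300),
           st.sampled_from(["CG", "AG", "AA"]))
    def test_profile_matches_revcomp_profile(self, s, dinuc):
        """D on S equals revcomp(D) on revcomp(S) under symmetric end-exclusion."""
        seq = mseq(s)
        rc = revcomp_masked(seq)
        rc_dinuc = dinuc.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        d_max = 15
        fwd = distance_histogram(
            occurrence_positions(seq, dinuc), 2, d_max, seq_length=len(seq), exclude="both"
        )
        rev = distance_histogram(
            occurrence_positions(rc, rc_dinuc), 2, d_max, seq_length=len(rc), exclude="both"
        )
        assert np.array_equal(fwd, rev)


class TestProfileByIsochore:
    def test_single_segment_single_key(self):
        seq = planted_genome(seed=15, length=50_000)
        segs = [IsochoreSegment("synth", 0, len(seq), "L1", 0.5)]
        assert set(profile_by_isochore([seq], segs, "CG")) == {"L1"}

    def test_same_class_histograms_pool_additively(self):
        seq = planted_genome(seed=16, length=60_000, count=400)
        half = len(seq) // 2
        segs2 = [
            IsochoreSegment("synth", 0, half, "H1", 0.5),
            IsochoreSegment("synth", half, len(seq), "H1", 0.5),
        ]
        pooled = profile_by_isochore([seq], segs2, "CG")["H1"]
        a = compute_profile(seq.subsequence(0, half), "CG")
        b = compute_profile(seq.subsequence(half, len(seq)), "CG")
        assert np.array_equal(pooled.raw, a.raw + b.raw)

    def test_signal_confined_to_planted_class(self):
        """CG planted only in H3: H3 profile peaks, L1 profile stays flat."""
        spec = SyntheticSpec(
            segments=[SegmentSpec(600_000, 0.32, "L1"), SegmentSpec(300_000, 0.55, "H3")],
            seed=17,
        )
        seq, _ = generate_genome(spec)
        seq, _ = plant_periodic_dinucleotide(
            seq, "CG", 10.4, 800, seed=18, origin=650_000
        )
        segs = [
            IsochoreSegment("synth", 0, 600_000, "L1", 0.32),
            IsochoreSegment("synth", 600_000, 900_000, "H3", 0.55),
        ]
        profiles = profile_by_isochore([seq], segs, "CG")
        h3_peaks = profile_peaks(profiles["H3"])
        assert 21 in h3_peaks.positions
        assert profiles["L1"].smoothed.max() < 1.15

    def test_empty_class_omitted_with_warning(self):
        seq = mseq("AT" * 200)
        segs = [IsochoreSegment("s", 0, 400, "L1", 0.0)]
        with pytest.warns(UserWarning, match="no CG pairs"):
            assert profile_by_isochore([seq], segs, "CG") == {}
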