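"""Polymerase-usage chain: binning, normalization, smoothing, initiation
index, fork directionality and peak calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import pnampkit as pk
from pnampkit.puseq import _differential
from oracles import brute_histogram, brute_initiation_index, brute_windowed_mean


def track(values, mask=None, bin_size=100):
    return pk.BinnedTrack("chr", bin_size, np.asarray(values, float), mask=mask)


def usage_set(ew, ec, dw, dc, mask=None):
    return pk.UsageSet(
        ew=track(ew, mask), ec=track(ec, mask), dw=track(dw, mask), dc=track(dc, mask)
    )


class TestBinFivePrimeEnds:
    def test_single_watson_record_lands_in_bin_zero(self):
        rec = pk.AlignmentRecord("r1", "chrIV", 0, "watson")
        watson, crick = pk.bin_five_prime_ends([rec], 300, 100)
        assert watson.values.tolist() == [1.0, 0.0, 0.0]
        assert not crick.values.any()

    def test_bin_boundary_at_100bp(self):
        recs = [
            pk.AlignmentRecord("a", "chrIV", 99, "watson"),
            pk.AlignmentRecord("b", "chrIV", 100, "watson"),
        ]
        watson, _ = pk.bin_five_prime_ends(recs, 300, 100)
        assert watson.values.tolist() == [1.0, 1.0, 0.0]

    def test_matches_bruteforce_histogram(self):
        rng = np.random.default_rng(1)
        positions = rng.integers(0, 10_000, 10_000)
        strands = rng.random(10_000) < 0.5
        recs = [
            pk.AlignmentRecord(f"r{i}", "c", int(p), "watson" if w else "crick")
            for i, (p, w) in enumerate(zip(positions, strands))
        ]
        watson, crick = pk.bin_five_prime_ends(recs, 10_000, 100)
        assert np.array_equal(watson.values, brute_histogram(positions[strands], 100, 100))
        assert np.array_equal(crick.values, brute_histogram(positions[~strands], 100, 100))

    def test_out_of_range_position_rejected(self):
        rec = pk.AlignmentRecord("r", "c", 500, "watson")
        with pytest.raises(ValueError, match="outside"):
            pk.bin_five_prime_ends([rec], 300, 100)


class TestExcludeAmbiguousAlignments:
    @pytest.mark.parametrize(
        "primary,secondary,kept",
        [
            (40.0, 40.0, False),  # best and second-best tie: multimapper
            (40.0, 35.0, True),   # strictly better best placement
            (40.0, None, True),   # unique alignment
        ],
    )
    def test_tie_rule(self, primary, secondary, kept):
        rec = pk.AlignmentRecord("r", "c", 0, "watson", primary, secondary)
        out = pk.exclude_ambiguous_alignments([rec])
        assert (len(out) == 1) is kept


class TestNormalizeByTotal:
    def test_simple_arithmetic(self):
        out = pk.normalize_by_total(track([2.0, 2.0, 4.0]))
        assert out.values.tolist() == [0.25, 0.25, 0.5]
        assert out.unmasked_sum() == 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="empty dataset"):
            pk.normalize_by_total(track([0.0, 0.0]))

    def test_mask_aware_total(self):
        out = pk.normalize_by_total(track([5.0, 100.0, 5.0], mask=[False, True, False]))
        assert out.values[0] == 0.5 and out.values[2] == 0.5
        assert out.mask[1]


class TestRelativePolymeraseUsage:
    def test_identity_when_mutant_equals_control(self):
        t = track([0.2, 0.3, 0.5])
        out = pk.relative_polymerase_usage(t, t)
        assert np.allclose(out.values, 1.0)

    def test_control_zero_bins_masked(self):
        out = pk.relative_polymerase_usage(track([1.0, 1.0]), track([0.5, 0.0]))
        assert not out.mask[0] and out.mask[1]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            pk.relative_polymerase_usage(track([1.0]), track([1.0, 2.0]))


class TestSmooth:
    def test_constant_track_unchanged(self):
        t = track([3.0] * 20)
        for m in (0, 1, 3, 7):
            assert np.allclose(pk.smooth(t, m).values, 3.0)

    def test_m_zero_is_identity(self):
        t = track([1.0, 5.0, 2.0])
        assert np.array_equal(pk.smooth(t, 0).values, t.values)

    def test_spike_spread_matches_windowed_mean(self):
        values = [0.0, 0.0, 0.0, 0.0, 7.0, 0.0, 0.0, 0.0, 0.0]
        out = pk.smooth(track(values), 3)
        assert out.values[4] == 1.0  # interior bin: 7 / (2m+1)
        assert out.values[1] == pytest.approx(7 / 5)  # edge window shrinks
        expected = brute_windowed_mean(np.array(values), np.zeros(9, bool), 3)
        assert np.allclose(out.values, expected)

    @settings(max_examples=50, deadline=None)
    @given(
        values=hnp.arrays(float, st.integers(5, 60),
                          elements=st.floats(-50, 50, allow_nan=False)),
        m=st.integers(0, 5),
        mask_seed=st.integers(0, 2**16),
    )
    def test_matches_bruteforce_for_random_masked_tracks(self, values, m, mask_seed):
        rng = np.random.default_rng(mask_seed)
        mask = rng.random(len(values)) < 0.25
        out = pk.smooth(track(values, mask), m)
        expected = brute_windowed_mean(values, mask, m)
        assert np.allclose(out.values[~mask], expected[~mask])
        assert np.array_equal(out.mask, mask)


class TestUsageFraction:
    def test_equal_usage_gives_half(self):
        e_frac, d_frac = pk.usage_fraction(track([2.0, 4.0]), track([2.0, 4.0]))
        assert np.allclose(e_frac.values, 0.5)
        assert np.allclose(d_frac.values, 0.5)

    def test_pure_epsilon_gives_one(self):
        e_frac, _ = pk.usage_fraction(track([2.0]), track([0.0]))
        assert e_frac.values[0] == 1.0

    def test_fractions_sum_to_one_and_zero_total_masked(self):
        rng = np.random.default_rng(3)
        e = track(rng.random(50))
        d = track(rng.random(50))
        e_frac, d_frac = pk.usage_fraction(e, d)
        assert np.allclose(e_frac.values + d_frac.values, 1.0)
        e_frac, d_frac = pk.usage_fraction(track([0.0]), track([0.0]))
        assert e_frac.mask[0] and d_frac.mask[0]


class TestInitiationIndex:
    def test_constant_usage_gives_all_zero_undefined(self):
        usage = usage_set([1.0] * 20, [1.0] * 20, [1.0] * 20, [1.0] * 20)
        ini = pk.initiation_index(usage)
        assert not ini.values.any()
        assert not ini.defined_mask.any()

    def test_too_short_track_rejected(self):
        usage = usage_set([1.0] * 5, [1.0] * 5, [1.0] * 5, [1.0] * 5)
        with pytest.raises(ValueError, match="short"):
            pk.initiation_index(usage)

    def test_matches_independent_bruteforce_bit_for_bit(self):
        """Oracle equivalence on random <=200-bin usage with masked bins."""
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = int(rng.integers(30, 200))
            mask = rng.random(n) < 0.1
            tracks = [rng.random(n) * 2 for _ in range(4)]
            usage = usage_set(*tracks, mask=mask)
            ini = pk.initiation_index(usage)
            expected, defined, sd = brute_initiation_index(*tracks, mask, 3)
            assert np.array_equal(ini.values, expected)
            assert np.array_equal(ini.defined_mask, defined)
            assert ini.sd == sd

    def test_zscaling_preserves_signs(self):
        rng = np.random.default_rng(23)
        tracks = [rng.random(100) for _ in range(4)]
        usage = usage_set(*tracks)
        ini = pk.initiation_index(usage)
        raw, _, sd = brute_initiation_index(*tracks, np.zeros(100, bool), 3)
        assert np.array_equal(np.sign(ini.values), np.sign(raw))

    def test_simulated_origin_yields_positive_peak_at_origin(self, two_origin_simulation):
        usage = two_origin_simulation["usage"]
        ini = pk.initiation_index(usage)
        origin_bin = 150  # strong origin at 15 kb, 100-bp bins
        window = ini.values[origin_bin - 2 : origin_bin + 3]
        assert window.max() > 0
        assert abs(int(np.argmax(ini.values)) - origin_bin) <= 2

    def test_termination_zone_between_origins_is_negative(self, two_origin_simulation):
        """Fork-merging between the origins carries the reversed sign set."""
        ini = pk.initiation_index(two_origin_simulation["usage"])
        between = ini.values[200:300]  # 20-30 kb, between the origins
        assert between.min() < 0
        assert between.min() == ini.values.min()


class TestRfd:
    def test_pure_rightward_is_plus_one(self):
        usage = usage_set([1.0] * 10, [0.0] * 10, [0.0] * 10, [1.0] * 10)
        out = pk.rfd(usage)
        assert np.allclose(out.values, 1.0)

    def test_symmetric_usage_is_zero(self):
        usage = usage_set([0.6] * 10, [0.6] * 10, [0.4] * 10, [0.4] * 10)
        assert np.allclose(pk.rfd(usage).values, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**16), n=st.integers(10, 80))
    def test_bounded_for_nonnegative_usage(self, seed, n):
        rng = np.random.default_rng(seed)
        usage = usage_set(*[rng.random(n) * 3 for _ in range(4)])
        values = pk.rfd(usage).values
        assert np.all(values >= -1.0) and np.all(values <= 1.0)

    def test_delta_variant_runs_and_differs(self):
        rng = np.random.default_rng(5)
        usage = usage_set(*[rng.random(40) for _ in range(4)])
        plain = pk.rfd(usage)
        delta = pk.rfd(usage, use_delta=True)
        assert not np.allclose(plain.values, delta.values)

    def test_single_origin_rfd_tracks_fork_truth(self):
        """Single central origin: RFD is -1 left of the origin and +1 right
        of it, within +/-0.1 of 2*rightward_fraction - 1 after identical
        smoothing."""
        cfg = pk.SimConfig(n_cells=500, depth=200, fork_speed=1000, seed=31)
        field = pk.simulate_replication(
            30_000, [pk.OriginSpec(15_000, 1.0, 10, 3)], cfg
        )
        counts = pk.simulate_puseq_counts(field, cfg)
        usage = pk.usage_from_counts(
            counts.eps_watson, counts.eps_crick,
            counts.delta_watson, counts.delta_crick,
            counts.control_watson, counts.control_crick,
        )
        params = pk.AnalysisParams()
        out = pk.rfd(usage, params)
        truth = field.rightward_fraction
        truth_smoothed = pk.smooth(truth.with_values(2 * truth.values - 1), params.m)
        err = np.abs(out.values - truth_smoothed.values)
        assert err.max() <= 0.1
        assert np.all(out.values[:140] < -0.9)
        assert np.all(out.values[160:] > 0.9)


class TestCallOriginPeaks:
    def test_flat_zero_track_yields_no_peaks(self):
        ini = pk.IniTrack(track([0.0] * 50), np.zeros(50, bool), 0.0)
        assert pk.call_origin_peaks(ini) == []

    def test_two_planted_origins_recovered_within_two_bins(self, two_origin_simulation):
        ini = pk.initiation_index(two_origin_simulation["usage"])
        peaks = pk.call_origin_peaks(ini)
        truth_bins = [150, 350]
        assert len(peaks) == 2
        for peak, truth in zip(peaks, truth_bins):
            assert abs(peak.bin_index - truth) <= 2
            assert peak.height >= 1.0

    def test_close_maxima_suppressed_by_separation(self):
        values = np.zeros(50)
        values[20], values[24] = 3.0, 2.5  # within min separation of 10
        ini = pk.IniTrack(track(values), values > 0, 1.0)
        peaks = pk.call_origin_peaks(ini)
        assert len(peaks) == 1
        assert peaks[0].bin_index == 20  # greedy by height


class TestDifferential:
    def test_forward_difference_assigned_to_left_bin(self):
        out = _differential(track([1.0, 4.0, 2.0]))
        assert out.values[:2].tolist() == [3.0, -2.0]
        assert out.mask[2]  # last bin undefined


class TestEndToEndRecovery:
    def test_usage_from_counts_recovers_planted_origins(self):
        """Simulate -> analyze on a fresh seed: every efficiency>=0.5 origin
        is called within 2 bins, with no extra peak."""
        cfg = pk.SimConfig(n_cells=2000, depth=200, fork_speed=1000, seed=77)
        origins = [pk.OriginSpec(12_000, 0.8, 10, 3), pk.OriginSpec(30_000, 0.5, 12, 3)]
        field = pk.simulate_replication(40_000, origins, cfg)
        counts = pk.simulate_puseq_counts(field, cfg)
        usage = pk.usage_from_counts(
            counts.eps_watson, counts.eps_crick,
            counts.delta_watson, counts.delta_crick,
            counts.control_watson, counts.control_crick,
        )
        peaks = pk.call_origin_peaks(pk.initiation_index(usage))
        assert len(peaks) == 2
        for peak, origin in zip(peaks, origins):
            assert abs(peak.bin_index - origin.position // 100) <= 2
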