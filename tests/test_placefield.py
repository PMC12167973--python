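"""Place-field pipeline: analytic SI, delineation oracle, gates, classification."""

import numpy as np
import pytest

from pcdrift.placefield import (
    PlaceField,
    SpatialBinning,
    TuningCurve,
    classify_cell,
    find_peaks,
    global_si_test,
    lap_coverage,
    local_si_test,
    merge_bases,
    odd_even_gate,
    peak_base,
    prune_adjacent,
    spatial_information,
    tuning_curve,
    valid_sample_mask,
)
from pcdrift.synth import BehaviorConfig, BehaviorTrace, GroundTruthCell, NoiseConfig, gen_behavior, gen_session


def constant_speed_trace(n_laps=4, speed=35.0, track=800.0, fr=30.0):
    cfg = BehaviorConfig(n_laps=n_laps, mean_speed_cm_s=speed,
                         speed_noise_sd=0.0, slowdown_factor=1.0,
                         lap_speed_sd=0.0, stop_rate_hz=0.0,
                         track_length_cm=track, frame_rate_hz=fr)
    return gen_behavior(cfg, seed=0)


def curve(rates, occupancy=None):
    rates = np.asarray(rates, float)
    occ = (np.full(rates.size, 1.0 / rates.size) if occupancy is None
           else np.asarray(occupancy, float))
    return TuningCurve(rates, occ)


class TestValidSampleMask:
    def test_constant_speed_all_valid(self):
        b = constant_speed_trace()
        binning = SpatialBinning(800, 80)
        assert valid_sample_mask(b, binning).all()

    def test_stationary_bin_excluded_per_lap(self):
        b = constant_speed_trace(n_laps=2)
        binning = SpatialBinning(800, 80)
        # make lap 1's bin-7 frames stationary
        bins = binning.bin_of(b.position_cm)
        sel = (bins == 7) & (b.lap_index == 1)
        speed = b.speed_cm_s.copy()
        speed[sel] = 0.0
        b2 = BehaviorTrace(b.time_s, b.position_cm, speed, b.lap_index,
                           b.lick, b.track_length_cm, b.frame_rate_hz)
        mask = valid_sample_mask(b2, binning)
        assert not mask[sel].any()
        other = (bins == 7) & (b.lap_index == 2)
        assert mask[other].all()

    def test_boundary_speed_exactly_threshold_kept(self):
        b = constant_speed_trace(n_laps=1, speed=4.0)
        binning = SpatialBinning(800, 80)
        assert valid_sample_mask(b, binning).all()


class TestTuningCurve:
    def test_zero_spks_zero_curve(self, behavior_20laps, binning):
        c = tuning_curve(np.zeros(behavior_20laps.n_frames),
                         behavior_20laps, binning)
        visited = ~np.isnan(c.rate)
        assert (c.rate[visited] == 0).all()

    def test_constant_spks_flat_regardless_of_occupancy(self, binning):
        # slowdown before the RZ doubles occupancy there; rates stay 1
        b = gen_behavior(BehaviorConfig(n_laps=10, slowdown_factor=0.4),
                         seed=3)
        c = tuning_curve(np.ones(b.n_frames), b, binning)
        visited = ~np.isnan(c.rate)
        assert c.rate[visited] == pytest.approx(np.ones(visited.sum()))
        assert c.occupancy.sum() == pytest.approx(1.0)

    def test_synthetic_place_cell_peak_bin(self, binning):
        b = gen_behavior(BehaviorConfig(n_laps=200), seed=4)
        cell = GroundTruthCell(0, "place", [400.0], [20.0], [2.5],
                               baseline_rate_hz=0.05)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)), seed=5)
        c = tuning_curve(s.spks[0], b, binning)
        assert abs(int(np.nanargmax(c.rate)) - binning.bin_of(np.array([400.0]))[0]) <= 1

    def test_no_valid_frames_raises(self, binning):
        b = constant_speed_trace(n_laps=1, speed=35.0)
        with pytest.raises(ValueError):
            tuning_curve(np.zeros(b.n_frames), b, binning,
                         valid_mask=np.zeros(b.n_frames, bool))


class TestOddEvenGate:
    def test_identical_curves_pass(self):
        r, ok, _ = odd_even_gate(curve([1, 2, 3]), curve([1, 2, 3]))
        assert r == pytest.approx(1.0) and ok

    def test_anticorrelated_fail(self):
        r, ok, _ = odd_even_gate(curve([1.0, 0.0]), curve([0.0, 1.0]))
        assert r == pytest.approx(-1.0) and not ok

    def test_degenerate_zero_variance(self):
        r, ok, why = odd_even_gate(curve([1.0, 1.0, 1.0]), curve([1, 2, 3]))
        assert np.isnan(r) and not ok and why == "degenerate"

    def test_untuned_cell_usually_fails(self, behavior_50laps, binning):
        r_ = np.random.default_rng(21)
        fails = 0
        n_sim = 200
        for _ in range(n_sim):
            spks = (r_.random(behavior_50laps.n_frames) < 1.0 / 30) * 150.0
            odd = tuning_curve(spks, behavior_50laps, binning, "odd")
            even = tuning_curve(spks, behavior_50laps, binning, "even")
            _, ok, _ = odd_even_gate(odd, even)
            fails += not ok
        assert fails > n_sim / 2


class TestSpatialInformation:
    def test_uniform_tuning_zero(self):
        assert spatial_information(curve([3.0] * 8)) == pytest.approx(0.0, abs=1e-12)

    def test_single_active_bin_log2_n(self):
        for n in (4, 8, 16):
            lam = np.zeros(n)
            lam[2 % n] = 5.0
            assert spatial_information(curve(lam)) == pytest.approx(
                np.log2(n), abs=1e-12)

    def test_closed_form_two_bins(self):
        c = TuningCurve(np.array([2.0, 0.0]), np.array([0.5, 0.5]))
        assert spatial_information(c) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        lam = rng.exponential(1.0, 40)
        occ = rng.dirichlet(np.ones(40))
        a = spatial_information(TuningCurve(lam, occ))
        b = spatial_information(TuningCurve(lam * 7.3, occ))
        assert a == pytest.approx(b, abs=1e-12)

    def test_silent_cell_nan(self):
        assert np.isnan(spatial_information(curve([0.0] * 5)))


class TestGlobalSITest:
    def test_constant_spks_fails(self, behavior_20laps, binning):
        si, p, ok = global_si_test(np.ones(behavior_20laps.n_frames),
                                   behavior_20laps, binning,
                                   n_shuffle=200, seed=0)
        assert si == pytest.approx(0.0, abs=1e-9)
        assert not ok

    def test_too_few_shuffles_rejected(self, behavior_20laps, binning):
        with pytest.raises(ValueError):
            global_si_test(np.ones(behavior_20laps.n_frames),
                           behavior_20laps, binning, n_shuffle=50)

    def test_strong_place_cell_power(self, binning):
        b = gen_behavior(BehaviorConfig(n_laps=50), seed=31)
        passes = 0
        n_sim = 30
        for i in range(n_sim):
            cell = GroundTruthCell(0, "place", [150.0 + 10 * i], [20.0],
                                   [2.5], baseline_rate_hz=0.05)
            s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)),
                            seed=100 + i)
            _, _, ok = global_si_test(s.spks[0], b, binning,
                                      n_shuffle=300, seed=i)
            passes += ok
        assert passes >= int(0.9 * n_sim)


class TestPeakOps:
    def test_simple_peak(self):
        assert find_peaks(curve([0, 7, 0])).tolist() == [1]

    def test_below_height_ignored(self):
        assert find_peaks(curve([0, 5, 0])).tolist() == []

    def test_height_inclusive(self):
        assert find_peaks(curve([0, 6, 0])).tolist() == [1]

    def test_plateau_leftmost(self):
        assert find_peaks(curve([0, 8, 8, 8, 0])).tolist() == [1]

    def test_prune_shallow_valley_drops_smaller(self):
        c = curve([0, 10, 6, 7, 0])
        kept = prune_adjacent(c, np.array([1, 3]))
        assert kept.tolist() == [1]

    def test_prune_deep_valley_keeps_both(self):
        c = curve([0, 10, 4, 7, 0])
        kept = prune_adjacent(c, np.array([1, 3]))
        assert kept.tolist() == [1, 3]

    def test_prune_single_peak_unchanged(self):
        c = curve([0, 10, 0])
        assert prune_adjacent(c, np.array([1])).tolist() == [1]

    def test_triangular_base_hand_worked(self):
        # prominence 10, eval height 0.7, crossings at 0.07 / 1.93
        assert peak_base(curve([0.0, 10.0, 0.0]), 1) == (0, 2)

    def test_symmetric_base(self):
        lam = np.array([0, 1, 4, 9, 4, 1, 0.0]) + 3.0
        lam[3] = 12.0
        s, e = peak_base(curve(lam), 3)
        assert (3 - s) == (e - 3)

    def test_scale_invariance_of_base(self, rng):
        lam = np.abs(rng.normal(5, 3, 60))
        lam[30] = lam.max() + 10
        assert peak_base(curve(lam), 30) == peak_base(curve(lam * 3.7), 30)

    def test_merge_overlapping_and_adjacent(self):
        lam = np.zeros(12)
        lam[4] = 8.0
        lam[7] = 9.0
        c = curve(lam)
        fields = [PlaceField(4, 3, 5), PlaceField(7, 5, 8)]
        merged = merge_bases(c, fields)
        assert len(merged) == 1
        assert (merged[0].base_start_bin, merged[0].base_end_bin) == (3, 8)
        assert merged[0].peak_bin == 7
        fields = [PlaceField(4, 3, 5), PlaceField(7, 6, 8)]
        assert len(merge_bases(c, fields)) == 1   # adjacent: 5+1 == 6
        fields = [PlaceField(4, 3, 5), PlaceField(8, 7, 9)]
        assert len(merge_bases(c, fields)) == 2

    def test_merge_idempotent(self, rng):
        lam = np.abs(rng.normal(5, 3, 40))
        fields = [PlaceField(int(p), max(int(p) - 2, 0), min(int(p) + 2, 39))
                  for p in rng.choice(40, 6, replace=False)]
        once = merge_bases(curve(lam), fields)
        twice = merge_bases(curve(lam), once)
        assert [(f.base_start_bin, f.base_end_bin) for f in once] == \
               [(f.base_start_bin, f.base_end_bin) for f in twice]

    def test_base_contains_peak_random_curves(self, rng):
        for _ in range(200):
            lam = np.abs(rng.normal(3, 2, 50))
            pk = find_peaks(curve(lam), height=0.0)
            for p in pk:
                s, e = peak_base(curve(lam), int(p))
                assert s <= p <= e


def oracle_peak_base(lam, peak, rel_height=0.93):
    """Independent prominence + interpolated-crossing delineation.

    Walks outward to the nearest higher sample (or curve end) on each
    side, takes the minimum in between as the flanking valley, computes
    prominence, then scans for the linear-interpolated crossings of the
    evaluation height.
    """
    lam = np.asarray(lam, float)
    n = lam.size
    h = lam[peak]
    # left valley
    i = peak
    lv = h
    while i > 0:
        i -= 1
        lv = min(lv, lam[i])
        if lam[i] > h:
            break
    # right valley
    i = peak
    rv = h
    while i < n - 1:
        i += 1
        rv = min(rv, lam[i])
        if lam[i] > h:
            break
    prom = h - max(lv, rv)
    eval_h = h - rel_height * prom
    # left crossing
    i = peak
    while i > 0 and lam[i - 1] >= eval_h:
        i -= 1
    if i == 0 or lam[i] == eval_h:
        left = float(i)
    else:
        left = i - (lam[i] - eval_h) / (lam[i] - lam[i - 1])
    i = peak
    while i < n - 1 and lam[i + 1] >= eval_h:
        i += 1
    if i == n - 1 or lam[i] == eval_h:
        right = float(i)
    else:
        right = i + (lam[i] - eval_h) / (lam[i] - lam[i + 1])
    return left, right


class TestPeakBaseOracle:
    def test_matches_independent_oracle_on_random_curves(self, rng):
        import scipy.signal as sps
        n_checked = 0
        while n_checked < 1000:
            lam = np.abs(rng.normal(3, 2, 60))
            peaks, _ = sps.find_peaks(lam)
            for p in peaks:
                left, right = oracle_peak_base(lam, int(p))
                widths = sps.peak_widths(lam, [int(p)], rel_height=0.93)
                assert widths[2][0] == pytest.approx(left, abs=1e-9)
                assert widths[3][0] == pytest.approx(right, abs=1e-9)
                s, e = peak_base(curve(lam), int(p))
                assert s == int(np.floor(left))
                assert e == int(np.ceil(right))
                n_checked += 1


class TestLocalSIAndCoverage:
    def test_constant_region_fails(self, behavior_20laps, binning):
        f = PlaceField(40, 36, 44)
        si, p, ok = local_si_test(np.ones(behavior_20laps.n_frames),
                                  behavior_20laps, binning, f,
                                  n_shuffle=200, seed=0)
        assert not ok

    def test_strong_field_passes(self, binning):
        b = gen_behavior(BehaviorConfig(n_laps=50), seed=41)
        cell = GroundTruthCell(0, "place", [400.0], [20.0], [3.0],
                               baseline_rate_hz=0.05)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)), seed=42)
        f = PlaceField(40, 36, 44)
        _, _, ok = local_si_test(s.spks[0], b, binning, f,
                                 n_shuffle=300, seed=1)
        assert ok

    def test_coverage_boundary_inclusive(self, binning):
        b = constant_speed_trace(n_laps=50)
        bins = binning.bin_of(b.position_cm)
        f = PlaceField(40, 38, 42)
        in_base = (bins >= 38) & (bins <= 42)
        spks = np.zeros(b.n_frames)
        # one event in the base on exactly 15 of 50 laps -> 0.30
        for lap in range(1, 16):
            idx = np.flatnonzero(in_base & (b.lap_index == lap))[0]
            spks[idx] = 1.0
        frac, ok = lap_coverage(spks, b, binning, f)
        assert frac == pytest.approx(0.30) and ok
        # 14 of 50 -> 0.28 fails
        spks[np.flatnonzero(in_base & (b.lap_index == 15))[0]] = 0.0
        frac, ok = lap_coverage(spks, b, binning, f)
        assert frac == pytest.approx(0.28) and not ok

    def test_every_lap_covered(self, binning):
        b = constant_speed_trace(n_laps=10)
        f = PlaceField(40, 38, 42)
        bins = binning.bin_of(b.position_cm)
        spks = ((bins >= 38) & (bins <= 42)).astype(float)
        frac, ok = lap_coverage(spks, b, binning, f)
        assert frac == 1.0 and ok


class TestClassifyCell:
    def test_no_events_silent(self, behavior_20laps, binning):
        c = classify_cell(np.zeros(behavior_20laps.n_frames),
                          behavior_20laps, binning, n_shuffle=200)
        assert c.label == "silent"

    def test_putative_when_no_peak_reaches_height(self, binning):
        # strongly tuned but tiny amplitudes: passes SI, no peak >= 6
        b = gen_behavior(BehaviorConfig(n_laps=50), seed=51)
        cell = GroundTruthCell(0, "place", [400.0], [20.0], [2.5],
                               baseline_rate_hz=0.05)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32),
                                               spks_amp=10.0), seed=52)
        c = classify_cell(s.spks[0], b, binning, n_shuffle=300, seed=5)
        assert c.label == "putative_place"
        assert not c.fields or not any(f.significant for f in c.fields)

    def test_strong_place_cell_classified(self, binning):
        b = gen_behavior(BehaviorConfig(n_laps=50), seed=53)
        cell = GroundTruthCell(0, "place", [250.0], [20.0], [2.5],
                               baseline_rate_hz=0.05)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)), seed=54)
        c = classify_cell(s.spks[0], b, binning, n_shuffle=300, seed=6)
        assert c.label == "place"
        (f,) = [f for f in c.fields if f.significant]
        true_bin = binning.bin_of(np.array([250.0]))[0]
        assert f.base_start_bin <= true_bin <= f.base_end_bin

    def test_determinism(self, binning):
        b = gen_behavior(BehaviorConfig(n_laps=30), seed=55)
        cell = GroundTruthCell(0, "place", [600.0], [25.0], [2.0],
                               baseline_rate_hz=0.1)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)), seed=56)
        a = classify_cell(s.spks[0], b, binning, n_shuffle=200, seed=7)
        bb = classify_cell(s.spks[0], b, binning, n_shuffle=200, seed=7)
        assert a.label == bb.label
        assert a.global_si_p == bb.global_si_p
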