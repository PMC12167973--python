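"""ROI matching, registration, cross-day linking, footprint validation."""

import numpy as np
import pytest

from pcdrift.synth import (
    BehaviorConfig,
    CohortConfig,
    GroundTruthCell,
    NoiseConfig,
    gen_behavior,
    gen_cohort,
    gen_session,
    render_movie,
)
from pcdrift.tracking import (
    CellTrack,
    RoiMask,
    classify_silent,
    footprint_validate,
    link_tracks,
    masks_from_labels,
    match_roi_sets,
    persistent_silence,
    register_days,
)


def rect_mask(roi_id, r0, c0, h, w, source="anatomy"):
    return RoiMask(roi_id, frozenset((r, c) for r in range(r0, r0 + h)
                                     for c in range(c0, c0 + w)), source)


class TestMatchRoiSets:
    def test_identical_masks_match(self):
        a = rect_mask(0, 0, 0, 10, 10)
        s = rect_mask(3, 0, 0, 10, 10, "activity")
        matched, unmatched = match_roi_sets([a], [s])
        assert matched == {0: 3} and unmatched == []

    def test_seventy_percent_overlap_unmatched(self):
        a = rect_mask(0, 0, 0, 10, 10)          # |a| = 100
        s = rect_mask(1, 0, 0, 10, 7, "activity")  # overlap 70
        matched, unmatched = match_roi_sets([a], [s])
        assert matched == {} and unmatched == [0]

    def test_largest_overlap_wins(self):
        a = rect_mask(0, 0, 0, 10, 10)
        s1 = rect_mask(1, 0, 0, 10, 8, "activity")   # 0.8
        s2 = rect_mask(2, 0, 0, 10, 9, "activity")   # 0.9
        matched, _ = match_roi_sets([a], [s1, s2])
        assert matched == {0: 2}

    def test_permutation_invariance(self):
        anatomy = [rect_mask(i, 12 * i, 0, 10, 10) for i in range(4)]
        activity = [rect_mask(10 + i, 12 * i, 0, 10, 9, "activity")
                    for i in range(4)]
        m1, u1 = match_roi_sets(anatomy, activity)
        m2, u2 = match_roi_sets(anatomy[::-1], activity[::-1])
        assert m1 == m2 and u1 == u2

    def test_duplicate_ids_rejected(self):
        a = [rect_mask(0, 0, 0, 5, 5), rect_mask(0, 10, 10, 5, 5)]
        with pytest.raises(ValueError):
            match_roi_sets(a, [])

    def test_threshold_is_strict(self):
        a = rect_mask(0, 0, 0, 10, 10)
        s = rect_mask(1, 0, 0, 10, 10, "activity")
        # exactly 75% overlap -> not matched (strict >)
        s75 = RoiMask(1, frozenset(list(sorted(s.pixels))[:75]), "activity")
        matched, unmatched = match_roi_sets([a], [s75])
        assert matched == {} and unmatched == [0]


class TestClassifySilent:
    def test_unmatched_is_silent_matched_is_active(self):
        a1 = rect_mask(0, 0, 0, 10, 10)
        a2 = rect_mask(1, 20, 0, 10, 10)
        s = rect_mask(7, 0, 0, 10, 10, "activity")
        labels = classify_silent([a1, a2], [s])
        assert labels == {0: "active", 1: "silent"}

    def test_composite_zero_valid_events(self):
        a = rect_mask(0, 0, 0, 10, 10)
        s = rect_mask(7, 0, 0, 10, 10, "activity")
        labels = classify_silent([a], [s], valid_event_counts={7: 0})
        assert labels == {0: "silent"}
        labels = classify_silent([a], [s], valid_event_counts={7: 3})
        assert labels == {0: "active"}

    def test_cohort_silent_fraction(self):
        cfg = CohortConfig(n_cells_per_fov=400, n_days=1, p_silent=0.5, seed=9)
        sessions, truths = gen_cohort(
            cfg, BehaviorConfig(n_laps=3), NoiseConfig(frame_shape=(512, 505)))
        s = sessions[0][0]
        labels = classify_silent(masks_from_labels(s.cellpose_labels),
                                 masks_from_labels(s.suite2p_labels, "activity"))
        frac = np.mean([v == "silent" for v in labels.values()])
        # truth: silent state or no drawn events
        truth_silent = np.mean([not s.spks[i].any() for i in range(400)])
        assert frac == pytest.approx(truth_silent, abs=0.01)
        se = np.sqrt(0.25 / 400)
        assert abs(frac - 0.5) <= 4 * se


class TestRegisterDays:
    def test_exact_shift_recovery(self, rng):
        a = rng.normal(10, 3, (64, 64))
        b = np.roll(np.roll(a, 3, axis=0), -2, axis=1)
        assert register_days(a, b) == (3, -2)

    def test_identity(self, rng):
        a = rng.normal(10, 3, (64, 64))
        assert register_days(a, a) == (0, 0)

    def test_noisy_shift_monte_carlo(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(10, 3, (64, 64))
            dy, dx = rng.integers(-8, 9, 2)
            b = np.roll(np.roll(a, dy, axis=0), dx, axis=1)
            b = b + rng.normal(0, 0.1 * b.std(), b.shape)
            hits += register_days(a, b) == (dy, dx)
        assert hits >= 95

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            register_days(np.ones((16, 16)), np.ones((16, 16)))


class TestLinkTracks:
    def test_identical_sets_full_tracks(self):
        day = [rect_mask(i, 15 * i, 0, 10, 10) for i in range(5)]
        tracks = link_tracks([day] * 6, [(0, 0)] * 6)
        assert len(tracks) == 5
        for t in tracks:
            assert len(set(t.anatomy_roi_ids)) == 1

    def test_missing_roi_excludes_track(self):
        day = [rect_mask(i, 15 * i, 0, 10, 10) for i in range(5)]
        day3 = [m for m in day if m.roi_id != 2]
        tracks = link_tracks([day, day, day3, day], [(0, 0)] * 4)
        assert len(tracks) == 4
        assert all(2 not in t.anatomy_roi_ids for t in tracks)

    def test_shift_compensation_ground_truth(self):
        shifts = [(0, 0), (4, -3), (-2, 5)]
        base = [rect_mask(i, 20 + 15 * i, 20, 10, 10) for i in range(4)]
        days = [[m.shifted(dy, dx) for m in day_base]
                for (dy, dx), day_base in zip(shifts, [base] * 3)]
        tracks = link_tracks(days, shifts)
        assert len(tracks) == 4
        for t in tracks:
            assert len(set(t.anatomy_roi_ids)) == 1

    def test_simulated_cohort_linkage_perfect(self):
        cfg = CohortConfig(n_cells_per_fov=50, n_days=4, max_shift_px=5, seed=11)
        sessions, truths = gen_cohort(
            cfg, BehaviorConfig(n_laps=3), NoiseConfig(frame_shape=(256, 256)))
        days, truth = sessions[0], truths[0]
        shifts = [(0, 0)] + [register_days(days[0].mean_image, d.mean_image)
                             for d in days[1:]]
        assert shifts == truth.shifts
        anatomy = [masks_from_labels(s.cellpose_labels) for s in days]
        tracks = link_tracks(anatomy, shifts)
        assert len(tracks) == 50
        assert all(len(set(t.anatomy_roi_ids)) == 1 for t in tracks)


class TestPersistentSilence:
    def make_tracks(self, state_rows):
        return [CellTrack(i, [0] * len(r), states=list(r))
                for i, r in enumerate(state_rows)]

    def test_always_silent_constant(self):
        tracks = self.make_tracks([["silent"] * 4] * 3)
        out = persistent_silence(tracks)
        assert out["count"].tolist() == [3, 3, 3, 3]
        assert out["normalized"].tolist() == [1.0] * 4

    def test_interrupted_silence_counts_once(self):
        tracks = self.make_tracks([["silent", "active", "silent", "silent"]])
        out = persistent_silence(tracks)
        assert out["count"].tolist() == [1, 0, 0, 0]

    def test_nonincreasing_random(self, rng):
        rows = [[rng.choice(["silent", "active"]) for _ in range(6)]
                for _ in range(50)]
        out = persistent_silence(self.make_tracks(rows))
        assert (np.diff(out["count"].to_numpy()) <= 0).all()

    def test_markov_decay_matches_closed_form(self):
        from pcdrift.synth import gen_state_matrix
        cfg = CohortConfig(n_cells_per_fov=2000, n_days=6, p_silent=0.5,
                           unsilencing_rate=0.5, persistent_silent_frac=0.0,
                           seed=13)
        states, _ = gen_state_matrix(cfg)
        tracks = self.make_tracks(states.tolist())
        out = persistent_silence(tracks)
        n1 = out["count"][0]
        for k in range(6):
            expected = 0.5 ** k
            se = np.sqrt(expected * (1 - expected) / n1)
            assert abs(out["normalized"][k] - expected) <= 3 * se + 1e-9


class TestFootprint:
    def _two_roi_session(self):
        b = gen_behavior(BehaviorConfig(n_laps=3), seed=2)
        cells = [GroundTruthCell(0, "active_nonplace", baseline_rate_hz=0.25),
                 GroundTruthCell(1, "active_nonplace", baseline_rate_hz=0.25)]
        s = gen_session(b, cells, NoiseConfig(frame_shape=(64, 64),
                                              fc_noise_sd=0.0), seed=3,
                        roi_centers=[(30.0, 30.0), (30.0, 38.0)])
        return b, s

    def test_perfect_footprint_accepted(self):
        _, s = self._two_roi_session()
        movie = render_movie(s, [0], seed=0, pixel_noise_sd=1e-6)
        roi = [m for m in masks_from_labels(s.cellpose_labels) if m.roi_id == 0][0]
        res = footprint_validate(movie, roi, s.fc[0])
        assert res.r_values and all(r > 0.9 for r in res.r_values)
        assert all(res.accepted)

    def test_anticorrelated_footprint_rejected(self):
        _, s = self._two_roi_session()
        movie = render_movie(s, [0], seed=0, pixel_noise_sd=1e-6)
        movie.frames = -movie.frames   # complement-like: bright outside dips
        roi = [m for m in masks_from_labels(s.cellpose_labels) if m.roi_id == 0][0]
        res = footprint_validate(movie, roi, s.fc[0])
        assert res.r_values and all(r < 0 for r in res.r_values)
        assert not any(res.accepted)

    def test_overlapping_rois_disjoint_events_attributed(self):
        # hand-built traces with disjoint transients on overlapping ROIs
        b = gen_behavior(BehaviorConfig(n_laps=2), seed=4)
        n = b.n_frames
        cells = [GroundTruthCell(0, "silent"), GroundTruthCell(1, "silent")]
        s = gen_session(b, cells, NoiseConfig(frame_shape=(64, 64),
                                              fc_noise_sd=0.0), seed=5,
                        roi_centers=[(30.0, 30.0), (30.0, 38.0)])
        fc = np.full((2, n), 1.0)
        for f in (200, 600, 1000):
            fc[0, f:f + 20] += 5.0
        for f in (400, 800, 1200):
            fc[1, f:f + 20] += 5.0
        s.fc = fc
        movie = render_movie(s, [0, 1], seed=6, pixel_noise_sd=0.01)
        masks = {m.roi_id: m for m in masks_from_labels(s.cellpose_labels)}
        for cid in (0, 1):
            own = footprint_validate(movie, masks[cid], s.fc[cid])
            assert own.r_values and all(own.accepted)
            other = footprint_validate(movie, masks[cid], s.fc[1 - cid])
            assert not any(other.accepted)

    def test_affine_intensity_invariance(self):
        _, s = self._two_roi_session()
        movie = render_movie(s, [0], seed=0, pixel_noise_sd=0.01)
        roi = [m for m in masks_from_labels(s.cellpose_labels) if m.roi_id == 0][0]
        res1 = footprint_validate(movie, roi, s.fc[0])
        movie.frames = 3.5 * movie.frames + 11.0
        res2 = footprint_validate(movie, roi, s.fc[0])
        assert res1.r_values == pytest.approx(res2.r_values, abs=1e-9)
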