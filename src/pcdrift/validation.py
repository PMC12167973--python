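"""Calibration and recovery studies of the pipeline on synthetic data.

Each routine runs the package's own analysis path on freshly generated
ground-truth data and measures a property the method must have: null
calibration of the shuffle tests, power and field recovery on true
place cells, unsilencing-rate recovery on Markov cohorts, bootstrap
coverage, and ephys-property recovery. They are used by the
acceptance checks and runnable in their own right.
"""

from __future__ import annotations

import numpy as np

from .ephys import VoltageSweep, ap_threshold, input_resistance
from .placefield import (
    PlaceField,
    SpatialBinning,
    classify_cell,
    global_si_test,
    local_si_test,
    valid_sample_mask,
)
from .stats import bootstrap_diff_ci, theoretical_decay, unsilencing_rate
from .synth import (
    BehaviorConfig,
    CohortConfig,
    GroundTruthCell,
    NoiseConfig,
    gen_behavior,
    gen_session,
    gen_state_matrix,
)
from .tracking import CellTrack, persistent_silence

__all__ = [
    "null_calibration_global", "null_calibration_local",
    "place_cell_recovery", "multifield_recovery",
    "markov_recovery", "bootstrap_coverage", "ephys_recovery",
]


def _null_spks(n_frames: int, rng: np.random.Generator,
               rate_hz: float = 1.0, amp: float = 150.0,
               frame_rate: float = 30.0) -> np.ndarray:
    """Spatially untuned Poisson event train in deconvolved units."""
    return (rng.random(n_frames) < rate_hz / frame_rate) * amp


def null_calibration_global(
    n_cells: int = 500,
    n_shuffle: int = 500,
    n_laps: int = 20,
    seed: int = 0,
) -> tuple[int, int]:
    """False-positive count of the global SI shuffle test on untuned cells."""
    rng = np.random.default_rng(seed)
    b = gen_behavior(BehaviorConfig(n_laps=n_laps), rng)
    binning = SpatialBinning(b.track_length_cm)
    valid = valid_sample_mask(b, binning)
    n_pass = 0
    for _ in range(n_cells):
        spks = _null_spks(b.n_frames, rng)
        _, _, ok = global_si_test(spks, b, binning, n_shuffle=n_shuffle,
                                  seed=rng, valid_mask=valid)
        n_pass += ok
    return n_pass, n_cells


def null_calibration_local(
    n_cells: int = 500,
    n_shuffle: int = 500,
    n_laps: int = 20,
    seed: int = 0,
) -> tuple[int, int]:
    """False-positive count of the local SI test on a forced candidate region."""
    rng = np.random.default_rng(seed)
    b = gen_behavior(BehaviorConfig(n_laps=n_laps), rng)
    binning = SpatialBinning(b.track_length_cm)
    valid = valid_sample_mask(b, binning)
    field = PlaceField(40, 36, 44)
    n_pass = 0
    for _ in range(n_cells):
        spks = _null_spks(b.n_frames, rng)
        _, _, ok = local_si_test(spks, b, binning, field,
                                 n_shuffle=n_shuffle, seed=rng,
                                 valid_mask=valid)
        n_pass += ok
    return n_pass, n_cells


def place_cell_recovery(
    n_cells: int = 100,
    n_shuffle: int = 500,
    n_laps: int = 50,
    seed: int = 0,
) -> dict:
    """Classification power and field localization on single-field cells.

    Every simulated cell carries one Gaussian field whose tuning peak
    clears the detection height. Reports the fraction labelled
    ``place`` and, among detections, the fraction whose significant
    field base contains the true center.
    """
    rng = np.random.default_rng(seed)
    binning = SpatialBinning(800.0)
    n_place = 0
    n_centered = 0
    n_detected = 0
    for i in range(n_cells):
        b = gen_behavior(BehaviorConfig(n_laps=n_laps), rng)
        center = float(rng.uniform(60.0, 740.0))
        cell = GroundTruthCell(0, "place", [center], [20.0],
                               [rng.uniform(2.0, 3.0)], baseline_rate_hz=0.05)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)), rng)
        c = classify_cell(s.spks[0], b, binning, n_shuffle=n_shuffle, seed=rng)
        if c.label == "place":
            n_place += 1
            true_bin = binning.bin_of(np.array([center]))[0]
            sig = [f for f in c.fields if f.significant]
            n_detected += 1
            if any(f.base_start_bin <= true_bin <= f.base_end_bin for f in sig):
                n_centered += 1
    return {
        "n_cells": n_cells,
        "place_frac": n_place / n_cells,
        "center_hit_frac": n_centered / n_detected if n_detected else 0.0,
    }


def multifield_recovery(
    n_cells: int = 50,
    n_shuffle: int = 500,
    n_laps: int = 50,
    seed: int = 0,
) -> dict:
    """Field-count recovery for cells with 2-6 well-separated fields."""
    rng = np.random.default_rng(seed)
    binning = SpatialBinning(800.0)
    n_correct = 0
    for i in range(n_cells):
        b = gen_behavior(BehaviorConfig(n_laps=n_laps), rng)
        k = int(rng.integers(2, 7))
        # evenly spread centers with jitter keeps fields >= ~90 cm apart
        slots = np.linspace(80.0, 720.0, k)
        centers = slots + rng.uniform(-20.0, 20.0, k)
        cell = GroundTruthCell(0, "place", centers, np.full(k, 15.0),
                               rng.uniform(2.2, 3.0, k), baseline_rate_hz=0.02)
        s = gen_session(b, [cell], NoiseConfig(frame_shape=(32, 32)), rng)
        c = classify_cell(s.spks[0], b, binning, n_shuffle=n_shuffle, seed=rng)
        n_correct += c.n_significant_fields == k
    return {"n_cells": n_cells, "count_match_frac": n_correct / n_cells}


def markov_recovery(
    u: float = 0.5,
    n_animals: int = 20,
    n_cells: int = 1000,
    n_days: int = 6,
    persistent_frac: float = 0.0,
    seed: int = 0,
) -> dict:
    """Unsilencing-rate estimation and persistently-silent decay.

    Simulates the silent/active Markov chains for a full cohort, runs
    the tracking-side estimators, and compares the normalized
    persistently-silent counts with the theoretical (1-u)^(k-1).
    """
    root = np.random.SeedSequence(seed)
    cfg = CohortConfig(n_cells_per_fov=n_cells, n_days=n_days, p_silent=0.5,
                       unsilencing_rate=u, silencing_rate=u,
                       persistent_silent_frac=persistent_frac)
    all_tracks: list[CellTrack] = []
    tid = 0
    for ss in root.spawn(n_animals):
        states, _ = gen_state_matrix(cfg, np.random.default_rng(ss))
        for row in states:
            all_tracks.append(CellTrack(tid, [0] * n_days, states=list(row)))
            tid += 1
    u_hat = unsilencing_rate(all_tracks)
    ps = persistent_silence(all_tracks)
    return {
        "u_hat": u_hat,
        "counts": ps["count"].to_numpy(),
        "normalized": ps["normalized"].to_numpy(),
        "theoretical": theoretical_decay(u, n_days),
    }


def bootstrap_coverage(
    n_rep: int = 1000,
    n_resamples: int = 2000,
    group_size: int = 100,
    seed: int = 0,
) -> dict:
    """Coverage of the 95% percentile-bootstrap CI for equal-mean groups."""
    rng = np.random.default_rng(seed)
    n_cover = 0
    for _ in range(n_rep):
        a = rng.normal(0.0, 1.0, group_size)
        b = rng.normal(0.0, 1.0, group_size)
        ci = bootstrap_diff_ci(a, b, "mean", n=n_resamples, seed=rng)
        n_cover += ci.ci_low <= 0.0 <= ci.ci_high
    return {"coverage": n_cover / n_rep, "n_rep": n_rep}


def ephys_recovery(n_cells: int = 30, seed: int = 0) -> dict:
    """Worst-case recovery errors over a simulated cell cohort.

    Each cell gets a ramp-to-AP sweep (generative threshold ~
    N(-45.2, 2.4) mV, pre-threshold slope 5 mV/ms) and RC step sweeps
    (R ~ N(129.8, 37.2) MOhm, tau 15 ms). Reports the maximum absolute
    threshold error (bounded by one sample's voltage step) and the
    maximum input-resistance error in MOhm.
    """
    rng = np.random.default_rng(seed)
    sr = 50_000.0
    dt_ms = 1000.0 / sr
    thr_errs, r_errs = [], []
    for _ in range(n_cells):
        thr = float(rng.normal(-45.2, 2.4))
        slow, fast = 5.0, 20.0
        n_slow = int(round((thr + 70.0) / (slow * dt_ms)))
        vm = np.concatenate([
            np.full(200, -70.0),
            -70.0 + slow * dt_ms * np.arange(n_slow + 1),
            -70.0 + slow * dt_ms * n_slow + fast * dt_ms * np.arange(1, 200)])
        sweep = VoltageSweep(vm, sr, 200.0, 200, vm.size)
        thr_true = vm[200 + n_slow]   # the kink sample
        thr_errs.append(abs(ap_threshold(sweep) - thr_true))

        r_true = float(np.clip(rng.normal(129.8, 37.2), 40.0, 300.0))
        sweeps = []
        for i_pa in (-100.0, -50.0):
            n = int(0.5 * sr)
            onset, offset = int(0.1 * sr), int(0.4 * sr)
            t = np.arange(n) / sr
            dv = i_pa * r_true / 1000.0
            v = np.full(n, -67.0)
            tt = t[onset:offset] - t[onset]
            v[onset:offset] += dv * (1 - np.exp(-tt / 0.015))
            v[offset:] += dv * np.exp(-(t[offset:] - t[offset]) / 0.015)
            sweeps.append(VoltageSweep(v, sr, i_pa, onset, offset))
        r_errs.append(abs(input_resistance(sweeps) - r_true))
    return {
        "max_threshold_err_mv": float(np.max(thr_errs)),
        "voltage_step_mv": slow * dt_ms,
        "max_rin_err_mohm": float(np.max(r_errs)),
    }
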