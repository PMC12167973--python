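"""Place-cell classification and place-field delineation.

Per session, each cell is pushed through a gated pipeline:

1. cells with no noise-filter-surviving activity are *silent*;
2. frames in (lap, space-bin) cells where the animal's mean speed is
   below 4 cm/s are excluded from all tuning computations;
3. reliability gate: Pearson correlation of the odd-lap and even-lap
   tuning curves must reach 0.25;
4. global spatial information (SI, bits/event, Skaggs-style) must
   exceed the 99th percentile of a circular-time-shift shuffle null
   (1,500 shuffles) -> *putative place cell*;
5. candidate fields are tuning-curve peaks (height >= 6, in
   deconvolved-activity units), pruned when the valley between
   neighbors is shallow, delineated at 93% of prominence, and
   overlapping/adjacent bases merged;
6. each field must pass a local SI test against a per-lap circular
   permutation null (95th percentile) and carry at least one event in
   at least 30% of laps -> *place cell* if any field survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth.behavior import BehaviorTrace

__all__ = [
    "SpatialBinning", "TuningCurve", "PlaceField", "CellClassification",
    "valid_sample_mask", "tuning_curve", "odd_even_gate",
    "spatial_information", "global_si_test", "find_peaks",
    "prune_adjacent", "peak_base", "merge_bases", "local_si_test",
    "lap_coverage", "classify_cell",
]

SPEED_THRESHOLD_CM_S = 4.0
ODD_EVEN_MIN_R = 0.25
DEFAULT_N_SHUFFLE = 1500
GLOBAL_SI_PERCENTILE = 99.0
LOCAL_SI_PERCENTILE = 95.0
PEAK_HEIGHT = 6.0
REL_HEIGHT = 0.93
LAP_COVERAGE_MIN = 0.30


@dataclass(frozen=True)
class SpatialBinning:
    """Half-open spatial bins [left, right) covering the corridor."""

    track_length_cm: float = 800.0
    n_bins: int = 80

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.track_length_cm <= 0:
            raise ValueError("invalid binning")

    @property
    def bin_edges_cm(self) -> np.ndarray:
        return np.linspace(0.0, self.track_length_cm, self.n_bins + 1)

    def bin_of(self, position_cm: np.ndarray) -> np.ndarray:
        b = np.floor(np.asarray(position_cm) / self.track_length_cm
                     * self.n_bins).astype(int)
        return np.clip(b, 0, self.n_bins - 1)


@dataclass
class TuningCurve:
    """Mean activity per space bin; unvisited bins are NaN."""

    rate: np.ndarray        # lambda_i, a.u.
    occupancy: np.ndarray   # p_i, fraction of valid frames
    lap_subset: str = "all"

    @property
    def n_bins(self) -> int:
        return self.rate.size

    def filled(self, fill: float = 0.0) -> np.ndarray:
        out = self.rate.copy()
        out[np.isnan(out)] = fill
        return out


@dataclass
class PlaceField:
    peak_bin: int
    base_start_bin: int
    base_end_bin: int
    local_si: float = np.nan
    local_si_p: float = np.nan
    lap_coverage_frac: float = np.nan
    significant: bool = False


@dataclass
class CellClassification:
    label: str                      # silent / active_nonplace / putative_place / place
    odd_even_r: float = np.nan
    global_si: float = np.nan
    global_si_p: float = np.nan
    fields: list[PlaceField] = dc_field(default_factory=list)
    reason: str = ""

    @property
    def n_significant_fields(self) -> int:
        return sum(f.significant for f in self.fields)


def valid_sample_mask(
    behavior: BehaviorTrace,
    binning: SpatialBinning,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
) -> np.ndarray:
    """Frames in (lap, bin) cells with mean speed < threshold are invalid.

    The exclusion is strict (<): a cell averaging exactly the threshold
    is kept.
    """
    bins = binning.bin_of(behavior.position_cm)
    laps = behavior.lap_index
    key = (laps - laps.min()) * binning.n_bins + bins
    n_keys = key.max() + 1
    speed_sum = np.bincount(key, weights=behavior.speed_cm_s, minlength=n_keys)
    count = np.bincount(key, minlength=n_keys)
    with np.errstate(invalid="ignore"):
        mean_speed = speed_sum / count
    slow = mean_speed < speed_threshold
    return ~slow[key]


def _lap_subset_mask(laps: np.ndarray, lap_subset: str) -> np.ndarray:
    if lap_subset == "all":
        return np.ones(laps.size, dtype=bool)
    if lap_subset == "odd":
        return laps % 2 == 1   # lap 1 is odd
    if lap_subset == "even":
        return laps % 2 == 0
    raise ValueError(f"unknown lap_subset {lap_subset!r}")


def tuning_curve(
    spks_filtered: np.ndarray,
    behavior: BehaviorTrace,
    binning: SpatialBinning,
    lap_subset: str = "all",
    valid_mask: np.ndarray | None = None,
) -> TuningCurve:
    """Mean filtered activity per space bin over valid frames.

    lambda_i is a plain per-frame mean within each bin, so it is
    occupancy-normalized by construction; p_i is the fraction of valid
    frames spent in bin i.
    """
    spks_filtered = np.asarray(spks_filtered, float)
    if valid_mask is None:
        valid_mask = valid_sample_mask(behavior, binning)
    sel = valid_mask & _lap_subset_mask(behavior.lap_index, lap_subset)
    if not sel.any():
        raise ValueError("no valid frames for tuning curve")
    bins = binning.bin_of(behavior.position_cm[sel])
    sums = np.bincount(bins, weights=spks_filtered[sel], minlength=binning.n_bins)
    counts = np.bincount(bins, minlength=binning.n_bins)
    with np.errstate(invalid="ignore"):
        rate = sums / counts
    occupancy = counts / counts.sum()
    return TuningCurve(rate, occupancy, lap_subset)


def odd_even_gate(curve_odd: TuningCurve, curve_even: TuningCurve,
                  min_r: float = ODD_EVEN_MIN_R) -> tuple[float, bool, str]:
    """Pearson correlation of odd- vs even-lap tuning; pass iff r >= min_r.

    Bins missing in either curve are dropped pairwise; a zero-variance
    curve makes r undefined and fails with reason "degenerate".
    """
    a, b = curve_odd.rate, curve_even.rate
    if a.size != b.size:
        raise ValueError("curves must share binning")
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan, False, "degenerate"
    r = float(np.corrcoef(a, b)[0, 1])
    return r, bool(r >= min_r), ""


def spatial_information(curve: TuningCurve) -> float:
    """Skaggs spatial information in bits per event.

    ``SI = sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar)``
    over visited bins, with zero-rate bins contributing 0. NaN when the
    mean rate is zero (silent cell).
    """
    keep = ~np.isnan(curve.rate)
    lam = curve.rate[keep]
    p = curve.occupancy[keep]
    p = p / p.sum()
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return float("nan")
    ratio = lam / lam_bar
    nz = ratio > 0
    return float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))


def _si_from_binned(sums: np.ndarray, counts: np.ndarray) -> float:
    """SI straight from per-bin activity sums and frame counts."""
    keep = counts > 0
    lam = sums[keep] / counts[keep]
    p = counts[keep] / counts[keep].sum()
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return float("nan")
    ratio = lam / lam_bar
    nz = ratio > 0
    return float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))


def global_si_test(
    spks_filtered: np.ndarray,
    behavior: BehaviorTrace,
    binning: SpatialBinning,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    seed: int | np.random.Generator = 0,
    valid_mask: np.ndarray | None = None,
    percentile: float = GLOBAL_SI_PERCENTILE,
) -> tuple[float, float, bool]:
    """Shuffle test of global SI against circular time rotations.

    Each shuffle rotates the full activity vector by a uniform shift in
    {1..T-1} (identity excluded) against the unshuffled behavior, then
    recomputes the tuning curve and SI. Pass iff the observed SI
    strictly exceeds the given percentile (linear interpolation) of the
    shuffle distribution. Returns ``(si, p, pass)`` where p is the
    add-one shuffle p-value.
    """
    if n_shuffle < 100:
        raise ValueError("need at least 100 shuffles")
    rng = np.random.default_rng(seed)
    spks_filtered = np.asarray(spks_filtered, float)
    if valid_mask is None:
        valid_mask = valid_sample_mask(behavior, binning)
    if not valid_mask.any():
        raise ValueError("no valid frames")
    t = spks_filtered.size
    idx_valid = np.flatnonzero(valid_mask)
    bins_valid = binning.bin_of(behavior.position_cm[idx_valid])
    counts = np.bincount(bins_valid, minlength=binning.n_bins)

    obs_sums = np.bincount(bins_valid, weights=spks_filtered[idx_valid],
                           minlength=binning.n_bins)
    si_obs = _si_from_binned(obs_sums, counts)
    if np.isnan(si_obs):
        return si_obs, 1.0, False

    shifts = rng.integers(1, t, size=n_shuffle)
    null = np.empty(n_shuffle)
    for j, s in enumerate(shifts):
        rolled = spks_filtered[(idx_valid - s) % t]
        sums = np.bincount(bins_valid, weights=rolled, minlength=binning.n_bins)
        null[j] = _si_from_binned(sums, counts)
    crit = float(np.percentile(null, percentile))
    p = (1 + int(np.sum(null >= si_obs))) / (n_shuffle + 1)
    return si_obs, p, bool(si_obs > crit)


def find_peaks(curve: TuningCurve, height: float = PEAK_HEIGHT) -> np.ndarray:
    """Interior local maxima of the tuning curve at least ``height`` tall.

    Plateaus report their leftmost bin; unvisited bins count as zero
    activity. The height criterion is inclusive.
    """
    lam = curve.filled(0.0)
    _, props = sps.find_peaks(lam, height=height, plateau_size=1)
    return props["left_edges"].astype(int)


def prune_adjacent(curve: TuningCurve, peaks: np.ndarray) -> np.ndarray:
    """Drop the smaller of two adjacent peaks separated by a shallow valley.

    If the minimum between two neighboring peaks exceeds half the
    larger peak's height, the smaller peak is discarded (on equal
    heights, the right one); re-evaluated left-to-right until stable.
    """
    lam = curve.filled(0.0)
    peaks = sorted(int(p) for p in peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for i in range(len(peaks) - 1):
            p1, p2 = peaks[i], peaks[i + 1]
            valley = lam[p1 + 1:p2].min() if p2 - p1 > 1 else min(lam[p1], lam[p2])
            if valley > 0.5 * max(lam[p1], lam[p2]):
                drop = p2 if lam[p2] <= lam[p1] else p1
                peaks.remove(drop)
                changed = True
                break
    return np.asarray(peaks, dtype=int)


def peak_base(curve: TuningCurve, peak_bin: int,
              rel_height: float = REL_HEIGHT) -> tuple[int, int]:
    """Field base bins at ``rel_height`` of the peak's prominence.

    The evaluation height is ``peak - rel_height * prominence``
    (standard prominence definition); the left/right crossings are
    found by linear interpolation along the curve and widened to the
    covering integer bins.
    """
    lam = curve.filled(0.0)
    widths, _, left_ips, right_ips = sps.peak_widths(
        lam, [int(peak_bin)], rel_height=rel_height)
    start = int(np.floor(left_ips[0]))
    end = int(np.ceil(right_ips[0]))
    return max(start, 0), min(end, curve.n_bins - 1)


def merge_bases(curve: TuningCurve, fields: list[PlaceField]) -> list[PlaceField]:
    """Unify overlapping or touching field bases into single fields.

    The merged field's peak is the bin of maximal activity within the
    union. Idempotent.
    """
    if not fields:
        return []
    lam = curve.filled(0.0)
    fs = sorted(fields, key=lambda f: (f.base_start_bin, f.base_end_bin))
    merged = [fs[0]]
    for f in fs[1:]:
        last = merged[-1]
        if f.base_start_bin <= last.base_end_bin + 1:
            start = last.base_start_bin
            end = max(last.base_end_bin, f.base_end_bin)
            peak = start + int(np.argmax(lam[start:end + 1]))
            merged[-1] = PlaceField(peak, start, end)
        else:
            merged.append(f)
    return merged


def _region_bins(field: PlaceField, n_bins: int) -> tuple[int, int]:
    """Base extended by half its width on both sides, rounded outward."""
    w = field.base_end_bin - field.base_start_bin + 1
    ext = int(np.ceil(0.5 * w))
    return max(field.base_start_bin - ext, 0), min(field.base_end_bin + ext, n_bins - 1)


def local_si_test(
    spks_filtered: np.ndarray,
    behavior: BehaviorTrace,
    binning: SpatialBinning,
    field: PlaceField,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    seed: int | np.random.Generator = 0,
    valid_mask: np.ndarray | None = None,
    percentile: float = LOCAL_SI_PERCENTILE,
) -> tuple[float, float, bool]:
    """Per-lap circular-permutation test of a candidate field's local SI.

    The field's base is extended by half a base width on each side; SI
    is computed over valid frames whose position falls in that region.
    Each shuffle independently rotates, within each lap, the activity
    samples of that lap's region frames by a uniform shift in
    {1..L-1}; laps with fewer than two region frames stay unshuffled.
    Pass iff observed SI strictly exceeds the ``percentile`` of the
    null. Returns ``(local_si, p, pass)``.
    """
    rng = np.random.default_rng(seed)
    spks_filtered = np.asarray(spks_filtered, float)
    if valid_mask is None:
        valid_mask = valid_sample_mask(behavior, binning)
    lo, hi = _region_bins(field, binning.n_bins)
    bins_all = binning.bin_of(behavior.position_cm)
    in_region = valid_mask & (bins_all >= lo) & (bins_all <= hi)
    idx = np.flatnonzero(in_region)
    if idx.size == 0:
        return float("nan"), 1.0, False
    vals = spks_filtered[idx]
    bins = bins_all[idx] - lo
    n_region_bins = hi - lo + 1
    counts = np.bincount(bins, minlength=n_region_bins)

    si_obs = _si_from_binned(
        np.bincount(bins, weights=vals, minlength=n_region_bins), counts)
    if np.isnan(si_obs):
        return si_obs, 1.0, False

    laps = behavior.lap_index[idx]
    # contiguous per-lap slices (frames are time-ordered)
    lap_bounds = np.flatnonzero(np.diff(laps) != 0) + 1
    slices = np.split(np.arange(idx.size), lap_bounds)
    lap_lens = [s.size for s in slices]

    null = np.empty(n_shuffle)
    shuffled = vals.copy()
    for j in range(n_shuffle):
        for s, ln in zip(slices, lap_lens):
            if ln < 2:
                continue
            k = int(rng.integers(1, ln))
            shuffled[s] = np.roll(vals[s], k)
        sums = np.bincount(bins, weights=shuffled, minlength=n_region_bins)
        null[j] = _si_from_binned(sums, counts)
    crit = float(np.percentile(null, percentile))
    p = (1 + int(np.sum(null >= si_obs))) / (n_shuffle + 1)
    return si_obs, p, bool(si_obs > crit)


def lap_coverage(
    spks_filtered: np.ndarray,
    behavior: BehaviorTrace,
    binning: SpatialBinning,
    field: PlaceField,
    min_frac: float = LAP_COVERAGE_MIN,
    valid_mask: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Fraction of laps with at least one event inside the field base.

    Pass iff the fraction reaches ``min_frac`` (inclusive).
    """
    spks_filtered = np.asarray(spks_filtered, float)
    if valid_mask is None:
        valid_mask = valid_sample_mask(behavior, binning)
    bins = binning.bin_of(behavior.position_cm)
    in_base = (bins >= field.base_start_bin) & (bins <= field.base_end_bin)
    hit = valid_mask & in_base & (spks_filtered > 0)
    laps_hit = np.unique(behavior.lap_index[hit]).size
    frac = laps_hit / behavior.n_laps
    return float(frac), bool(frac >= min_frac)


def classify_cell(
    spks_filtered: np.ndarray,
    behavior: BehaviorTrace,
    binning: SpatialBinning | None = None,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    seed: int | np.random.Generator = 0,
    *,
    peak_height: float = PEAK_HEIGHT,
    rel_height: float = REL_HEIGHT,
    min_odd_even_r: float = ODD_EVEN_MIN_R,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
    coverage_min: float = LAP_COVERAGE_MIN,
) -> CellClassification:
    """Run the full per-cell gate sequence and label the cell."""
    binning = binning or SpatialBinning(behavior.track_length_cm)
    rng = np.random.default_rng(seed)
    spks_filtered = np.asarray(spks_filtered, float)
    if not (spks_filtered > 0).any():
        return CellClassification("silent", reason="no valid events")
    valid = valid_sample_mask(behavior, binning, speed_threshold)

    odd = tuning_curve(spks_filtered, behavior, binning, "odd", valid)
    even = tuning_curve(spks_filtered, behavior, binning, "even", valid)
    r, ok, why = odd_even_gate(odd, even, min_odd_even_r)
    if not ok:
        return CellClassification("active_nonplace", odd_even_r=r,
                                  reason=why or "odd-even gate")

    si, p, ok = global_si_test(spks_filtered, behavior, binning,
                               n_shuffle, rng, valid)
    if not ok:
        return CellClassification("active_nonplace", odd_even_r=r,
                                  global_si=si, global_si_p=p,
                                  reason="global SI")

    curve = tuning_curve(spks_filtered, behavior, binning, "all", valid)
    peaks = prune_adjacent(curve, find_peaks(curve, peak_height))
    fields = merge_bases(curve, [
        PlaceField(int(pk), *peak_base(curve, pk, rel_height)) for pk in peaks])

    for f in fields:
        f.local_si, f.local_si_p, sig = local_si_test(
            spks_filtered, behavior, binning, f, n_shuffle, rng, valid)
        if sig:
            f.lap_coverage_frac, cov_ok = lap_coverage(
                spks_filtered, behavior, binning, f, coverage_min, valid)
            f.significant = cov_ok
    label = "place" if any(f.significant for f in fields) else "putative_place"
    return CellClassification(label, odd_even_r=r, global_si=si,
                              global_si_p=p, fields=fields)


def classification_table(results: dict[int, CellClassification]) -> pd.DataFrame:
    rows = []
    for cid, c in results.items():
        rows.append({
            "cell_id": cid, "label": c.label, "odd_even_r": c.odd_even_r,
            "global_si": c.global_si, "global_si_p": c.global_si_p,
            "n_fields": len(c.fields),
            "n_significant_fields": c.n_significant_fields,
        })
    return pd.DataFrame(rows)
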