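"""ROI matching, silent-cell identification and multi-day tracking.

The activity-based segmenter (Suite2p-like) only finds cells that were
active, while the anatomy-based segmenter (Cellpose-like) run on the
mean image finds every visible soma. Matching the two ROI sets by mask
overlap identifies the silent cells: anatomy ROIs with no corresponding
activity ROI. Across days the mean images are registered by rigid
translation and anatomy ROIs are linked day-to-day with the same
overlap criterion; only cells with an anatomy ROI on every day are
analyzed. Spatial-footprint validation attributes fluorescence
transients to their source ROI by correlating the event-triggered
pixel image with the mask shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.registration import phase_cross_correlation

__all__ = [
    "RoiMask", "CellTrack", "FootprintResult",
    "masks_from_labels", "match_roi_sets", "classify_silent",
    "register_days", "link_tracks", "persistent_silence",
    "footprint_validate",
]

OVERLAP_THRESHOLD = 0.75
FOOTPRINT_R_THRESHOLD = 0.5


@dataclass(frozen=True)
class RoiMask:
    """One ROI as a set of (row, col) pixels on the imaging grid."""

    roi_id: int
    pixels: frozenset
    source: str = "anatomy"   # {"anatomy", "activity"}

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("ROI mask must be non-empty")

    @property
    def size(self) -> int:
        return len(self.pixels)

    def shifted(self, dy: int, dx: int) -> "RoiMask":
        return RoiMask(self.roi_id,
                       frozenset((r + dy, c + dx) for r, c in self.pixels),
                       self.source)

    def bbox(self) -> tuple[int, int, int, int]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return min(rows), min(cols), max(rows), max(cols)


@dataclass
class CellTrack:
    """One cell linked across days by its anatomy ROI."""

    track_id: int
    anatomy_roi_ids: list[int]                    # one per day, required
    activity_roi_ids: list[int | None] = field(default_factory=list)
    states: list[str] = field(default_factory=list)   # {"silent", "active"}
    metrics: list[dict] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return len(self.anatomy_roi_ids)


@dataclass
class FootprintResult:
    """Per-transient spatial correlations with the ROI shape."""

    event_runs: list[tuple[int, int]]     # [start, stop) frame ranges
    r_values: list[float]
    accepted: list[bool]
    n_skipped: int = 0


def masks_from_labels(labels: np.ndarray, source: str = "anatomy"
                      ) -> list[RoiMask]:
    """Build ROI masks from a label image (0 = background)."""
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rr, cc = np.nonzero(labels == lab)
        out.append(RoiMask(int(lab) - 1,
                           frozenset(zip(rr.tolist(), cc.tolist())), source))
    return out


def _check_unique_ids(rois: list[RoiMask], what: str) -> None:
    ids = [r.roi_id for r in rois]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate roi_ids in {what} set")


def match_roi_sets(
    anatomy: list[RoiMask],
    activity: list[RoiMask],
    threshold: float = OVERLAP_THRESHOLD,
) -> tuple[dict[int, int], list[int]]:
    """Pair anatomy ROIs with activity ROIs by mask overlap.

    A pair is accepted iff ``|a & s| / |a| > threshold`` (fraction of
    the *anatomy* mask covered). Each anatomy ROI takes its
    largest-overlap activity ROI; ties go to the lower activity
    ``roi_id``. Returns ``(matched, unmatched)``: a mapping anatomy
    roi_id -> activity roi_id, and the unmatched anatomy roi_ids
    (silent-cell candidates) in ascending order.
    """
    _check_unique_ids(anatomy, "anatomy")
    _check_unique_ids(activity, "activity")
    matched: dict[int, int] = {}
    unmatched: list[int] = []
    for a in sorted(anatomy, key=lambda r: r.roi_id):
        best: tuple[float, int] | None = None
        for s in activity:
            frac = len(a.pixels & s.pixels) / a.size
            if frac > threshold:
                key = (frac, -s.roi_id)   # higher overlap, then lower id
                if best is None or key > best:
                    best = key
        if best is None:
            unmatched.append(a.roi_id)
        else:
            matched[a.roi_id] = -best[1]
    return matched, unmatched


def classify_silent(
    anatomy: list[RoiMask],
    activity: list[RoiMask],
    *,
    valid_event_counts: dict[int, int] | None = None,
    threshold: float = OVERLAP_THRESHOLD,
) -> dict[int, str]:
    """Per-anatomy-ROI {"silent", "active"} labels.

    Default rule: an anatomy ROI with no matched activity ROI is
    silent. When ``valid_event_counts`` (activity roi_id -> number of
    noise-filter-surviving events) is given, the stricter composite is
    applied: matched cells with zero valid events are silent too.
    """
    matched, unmatched = match_roi_sets(anatomy, activity, threshold)
    labels = {rid: "silent" for rid in unmatched}
    for a_id, s_id in matched.items():
        if valid_event_counts is not None and valid_event_counts.get(s_id, 0) == 0:
            labels[a_id] = "silent"
        else:
            labels[a_id] = "active"
    return labels


def register_days(mean_img_a: np.ndarray, mean_img_b: np.ndarray
                  ) -> tuple[int, int]:
    """Rigid integer translation (dy, dx) of image *b* relative to *a*.

    ``b ~ a`` translated by ``(dy, dx)``; found by maximizing the image
    cross-correlation (phase correlation, integer-pixel resolution).
    """
    a = np.asarray(mean_img_a, float)
    b = np.asarray(mean_img_b, float)
    if a.shape != b.shape:
        raise ValueError("mean images must share shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("registration undefined for flat images")
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=1,
                                          normalization=None)
    # phase_cross_correlation returns the shift that maps b onto a
    return int(round(-shift[0])), int(round(-shift[1]))


def link_tracks(
    daily_anatomy: list[list[RoiMask]],
    daily_shifts: list[tuple[int, int]],
    threshold: float = OVERLAP_THRESHOLD,
) -> list[CellTrack]:
    """Link anatomy ROIs across days into cell tracks.

    ``daily_shifts[d]`` is day *d*'s rigid shift relative to day 1 (so
    ``daily_shifts[0] == (0, 0)``); masks are moved back to day-1
    coordinates before overlap is computed. Consecutive days are linked
    with the same >threshold fraction-of-earlier-mask criterion, each
    later ROI claimable by one track only; a track is returned only if
    its chain spans every day.
    """
    n_days = len(daily_anatomy)
    if len(daily_shifts) != n_days:
        raise ValueError("one shift per day required")
    for d, day in enumerate(daily_anatomy):
        _check_unique_ids(day, f"day {d + 1} anatomy")
    aligned = [
        [m.shifted(-dy, -dx) for m in day]
        for day, (dy, dx) in zip(daily_anatomy, daily_shifts)
    ]
    # chains[i] = list of roi_ids, one per day so far
    chains: list[list[int]] = [[m.roi_id] for m in
                               sorted(aligned[0], key=lambda r: r.roi_id)]
    prev_masks = {m.roi_id: m for m in aligned[0]}
    for d in range(1, n_days):
        cur = sorted(aligned[d], key=lambda r: r.roi_id)
        claimed: set[int] = set()
        new_chains: list[list[int]] = []
        new_prev: dict[int, RoiMask] = {}
        for chain in chains:
            a = prev_masks[chain[-1]]
            best: tuple[float, int] | None = None
            for s in cur:
                if s.roi_id in claimed:
                    continue
                frac = len(a.pixels & s.pixels) / a.size
                if frac > threshold:
                    key = (frac, -s.roi_id)
                    if best is None or key > best:
                        best = key
            if best is not None:
                sid = -best[1]
                claimed.add(sid)
                chain.append(sid)
                new_chains.append(chain)
                new_prev[sid] = next(m for m in cur if m.roi_id == sid)
        chains = new_chains
        prev_masks = new_prev
    return [CellTrack(track_id=i, anatomy_roi_ids=chain)
            for i, chain in enumerate(chains)]


def persistent_silence(tracks: list[CellTrack]) -> pd.DataFrame:
    """Counts of cells silent on every one of days 1..k, for each k.

    Returns a frame with columns ``day`` (1-based k), ``count`` and
    ``normalized`` (count / day-1 count; NaN when no day-1 silent
    cells). The count is non-increasing in k by construction.
    """
    if not tracks:
        raise ValueError("no tracks")
    n_days = tracks[0].n_days
    states = np.array([t.states for t in tracks])  # (n_tracks, n_days)
    if states.shape[1] != n_days or not all(t.n_days == n_days for t in tracks):
        raise ValueError("tracks must span the same days")
    silent = states == "silent"
    counts = np.array([int(silent[:, :k].all(axis=1).sum())
                       for k in range(1, n_days + 1)])
    day1 = counts[0]
    norm = counts / day1 if day1 > 0 else np.full(n_days, np.nan)
    return pd.DataFrame({"day": np.arange(1, n_days + 1),
                         "count": counts, "normalized": norm})


def footprint_validate(
    movie,
    roi: RoiMask,
    raw_trace: np.ndarray,
    *,
    smooth_sigma: float = 2.0,
    sd_mult: float = 2.0,
    r_threshold: float = FOOTPRINT_R_THRESHOLD,
    dilate_px: int = 5,
) -> FootprintResult:
    """Validate a cell's transients by their spatial footprint.

    The raw trace is smoothed (Gaussian, sigma ``smooth_sigma``
    frames); putative events are maximal runs where the smoothed trace
    exceeds its median + ``sd_mult`` x SD. Each event's footprint is
    the mean movie frame over the run minus the mean over an
    equal-length immediately-preceding baseline, restricted to the ROI
    bounding box dilated by ``dilate_px``; the Pearson correlation of
    footprint pixels with the binary mask decides acceptance
    (``r > r_threshold``). Events with no room for a baseline are
    skipped and counted in ``n_skipped``.
    """
    trace = np.asarray(raw_trace, float)
    if trace.size != movie.n_frames:
        raise ValueError("trace length must match the movie")
    smoothed = gaussian_filter1d(trace, smooth_sigma)
    thr = np.median(smoothed) + sd_mult * np.std(smoothed)
    above = smoothed > thr

    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, above.size))

    r0m, c0m = movie.origin
    h, w = movie.frames.shape[1:]
    rmin, cmin, rmax, cmax = roi.bbox()
    br0 = max(rmin - dilate_px - r0m, 0)
    bc0 = max(cmin - dilate_px - c0m, 0)
    br1 = min(rmax + dilate_px + 1 - r0m, h)
    bc1 = min(cmax + dilate_px + 1 - c0m, w)
    mask = np.zeros((br1 - br0, bc1 - bc0))
    for (r, c) in roi.pixels:
        rr, cc = r - r0m - br0, c - c0m - bc0
        if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
            mask[rr, cc] = 1.0

    kept_runs, r_values, accepted = [], [], []
    n_skipped = 0
    for (s, e) in runs:
        n = e - s
        if s - n < 0:
            n_skipped += 1
            continue
        event_img = movie.frames[s:e, br0:br1, bc0:bc1].mean(axis=0)
        base_img = movie.frames[s - n:s, br0:br1, bc0:bc1].mean(axis=0)
        fp = (event_img - base_img).ravel()
        m = mask.ravel()
        if np.std(fp) == 0 or np.std(m) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(fp, m)[0, 1])
        kept_runs.append((s, e))
        r_values.append(r)
        accepted.append(r > r_threshold)
    return FootprintResult(kept_runs, r_values, accepted, n_skipped)
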