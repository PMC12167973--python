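"""Noise filtering of deconvolved calcium event trains.

Upstream deconvolution (Suite2p-style) emits a non-negative per-frame
activity train ``spks`` alongside the neuropil-subtracted fluorescence
``fc``. Deconvolution is permissive: small ``spks`` entries often
correspond to fluorescence fluctuations indistinguishable from noise.
To obtain a conservative activity estimate, each putative event is
validated against both a local and a global noise estimate of the
fluorescence trace, and events whose fluorescence amplitude does not
exceed the noise are zeroed out.

The per-event procedure:

1. find the fluorescence local maximum within the 10-frame window
   starting at the spike frame; replace it by the mean of the three
   samples around it (``fc_max``);
2. fit a line to the fluorescence 30 to 20 frames before the spike;
   the fitted value at the -20 frame is the baseline ``fc_base`` and
   the fit RMSE is the local noise SD;
3. the global noise SD is the SD of fluorescence samples lying within
   [0.5, 1.5] x the trace median;
4. the event is valid iff ``fc_max - fc_base`` strictly exceeds the
   noise SD (by default the larger of the local and global estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluorTrace",
    "EventRecord",
    "FilteredTrain",
    "global_noise_sd",
    "event_peak",
    "local_baseline",
    "filter_train",
    "activity_metrics",
    "events_to_frame",
]

#: frames after the spike (inclusive window length is PEAK_WINDOW + 1)
PEAK_WINDOW = 9
#: baseline fit window, frames before the spike (inclusive)
BASELINE_START = 30
BASELINE_END = 20


@dataclass(frozen=True)
class FluorTrace:
    """A cell's neuropil-subtracted fluorescence trace.

    Parameters
    ----------
    fc : ndarray
        Per-frame fluorescence, arbitrary units.
    frame_rate_hz : float
        Acquisition rate.
    """

    fc: np.ndarray
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        fc = np.asarray(self.fc, dtype=float)
        if fc.ndim != 1 or fc.size < 1:
            raise ValueError("fc must be a non-empty 1-D array")
        if np.isnan(fc).all():
            raise ValueError("fc is all-NaN")
        object.__setattr__(self, "fc", fc)

    @property
    def fc_med(self) -> float:
        """Median of the whole trace (NaNs ignored)."""
        return float(np.nanmedian(self.fc))

    @property
    def duration_s(self) -> float:
        return self.fc.size / self.frame_rate_hz


@dataclass
class EventRecord:
    spike_frame: int
    peak_frame: int
    fc_max: float
    fc_base: float
    local_sd: float
    amplitude: float
    valid: bool
    has_local_baseline: bool = True


@dataclass
class FilteredTrain:
    """Noise-filtered event train: rejected events zeroed in ``spks_filtered``."""

    spks_filtered: np.ndarray
    events: list[EventRecord] = field(default_factory=list)
    global_sd: float = 0.0

    @property
    def valid_events(self) -> list[EventRecord]:
        return [e for e in self.events if e.valid]

    def to_table(self) -> pd.DataFrame:
        cols = ["spike_frame", "peak_frame", "fc_max", "fc_base",
                "local_sd", "amplitude", "valid"]
        return pd.DataFrame(
            [{c: getattr(e, c) for c in cols} for e in self.events],
            columns=cols,
        )


def global_noise_sd(trace: FluorTrace, *, ddof: int = 0) -> float:
    """SD of fluorescence samples within [0.5, 1.5] x the trace median.

    The band is degenerate (single value) when the median is 0; with a
    negative median the numeric bounds swap, so they are sorted first.
    Returns 0.0 when fewer than two samples fall inside the band.
    """
    med = trace.fc_med
    lo, hi = sorted((0.5 * med, 1.5 * med))
    subset = trace.fc[(trace.fc >= lo) & (trace.fc <= hi)]
    if subset.size < 2:
        return 0.0
    return float(np.std(subset, ddof=ddof))


def event_peak(trace: FluorTrace, spike_frame: int) -> tuple[int, float]:
    """Locate the fluorescence peak for a spike and its 3-point mean.

    The peak is the argmax of ``fc`` over ``[spike, spike + 9]`` (clipped
    to the trace end; ties broken by the first index). ``fc_max`` is the
    mean of the three samples centred on the peak, clipped at trace edges.
    """
    fc = trace.fc
    n = fc.size
    if not 0 <= spike_frame < n:
        raise IndexError(f"spike_frame {spike_frame} outside trace of length {n}")
    hi = min(spike_frame + PEAK_WINDOW, n - 1)
    window = fc[spike_frame:hi + 1]
    m = spike_frame + int(np.argmax(window))
    lo3 = max(m - 1, 0)
    hi3 = min(m + 1, n - 1)
    fc_max = float(np.mean(fc[lo3:hi3 + 1]))
    return m, fc_max


def local_baseline(trace: FluorTrace, spike_frame: int) -> tuple[float, float]:
    """Linear baseline fit on the 11 samples 30..20 frames before the spike.

    Returns the fitted value at frame ``spike - 20`` and the RMSE of the
    fit residuals (the local noise SD).

    Raises
    ------
    ValueError
        If ``spike_frame < 30`` (no room for the fit window); callers
        fall back to the global noise SD alone.
    """
    if spike_frame < BASELINE_START:
        raise ValueError("spike too early for local baseline window")
    frames = np.arange(spike_frame - BASELINE_START, spike_frame - BASELINE_END + 1)
    y = trace.fc[frames]
    slope, intercept = np.polyfit(frames, y, 1)
    fitted = slope * frames + intercept
    fc_base = float(slope * (spike_frame - BASELINE_END) + intercept)
    local_sd = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return fc_base, local_sd


def filter_train(
    trace: FluorTrace,
    spks: np.ndarray,
    *,
    mode: str = "both",
    ddof: int = 0,
    noise_floor: float = 0.0,
) -> FilteredTrain:
    """Validate every deconvolved event against the fluorescence noise.

    Each frame with ``spks > 0`` becomes one event. An event is valid iff
    its amplitude ``fc_max - fc_base`` strictly exceeds the noise SD:
    with ``mode="both"`` (default, conservative) the larger of the local
    and global SD; with ``mode="either"`` the smaller. Events too early
    for the local baseline window use the global SD alone. Invalid events
    are zeroed in ``spks_filtered``.

    ``noise_floor`` imposes a minimum on the comparison SD, for traces
    whose noise level is known independently of the estimates.
    """
    spks = np.asarray(spks, dtype=float)
    if spks.shape != trace.fc.shape:
        raise ValueError("spks and fc must have equal length")
    if (spks < 0).any():
        raise ValueError("spks must be non-negative")
    if mode not in ("both", "either"):
        raise ValueError(f"unknown mode {mode!r}")

    g_sd = global_noise_sd(trace, ddof=ddof)
    spks_filtered = spks.copy()
    events: list[EventRecord] = []
    for s in np.flatnonzero(spks > 0):
        s = int(s)
        m, fc_max = event_peak(trace, s)
        try:
            fc_base, local_sd = local_baseline(trace, s)
            has_local = True
            crit = max(local_sd, g_sd) if mode == "both" else min(local_sd, g_sd)
        except ValueError:
            # documented fallback: no room for the baseline window
            fc_base, local_sd = trace.fc_med, np.nan
            has_local = False
            crit = g_sd
        amplitude = fc_max - fc_base
        valid = amplitude > max(crit, noise_floor)
        if not valid:
            spks_filtered[s] = 0.0
        events.append(EventRecord(s, m, fc_max, fc_base,
                                  local_sd, amplitude, valid, has_local))
    return FilteredTrain(spks_filtered, events, g_sd)


def activity_metrics(train: FilteredTrain, duration_s: float) -> dict:
    """Mean activity, valid-event frequency and mean event amplitude.

    ``mean_activity`` is the mean of the filtered train over all frames
    (not only event frames). ``mean_amplitude`` is NaN when no event
    survived filtering.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    valid = train.valid_events
    amps = [e.amplitude for e in valid]
    return {
        "mean_activity": float(np.mean(train.spks_filtered)),
        "event_freq_hz": len(valid) / duration_s,
        "mean_amplitude": float(np.mean(amps)) if amps else float("nan"),
    }


def events_to_frame(trains: dict[int, FilteredTrain]) -> pd.DataFrame:
    """Concatenate per-cell event tables into one tidy frame."""
    parts = []
    for cell_id, train in trains.items():
        t = train.to_table()
        t.insert(0, "cell_id", cell_id)
        parts.append(t)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)
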