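"""Forward model for one imaging session.

Each ground-truth cell has a spatial firing-rate function: a baseline
plus Gaussian place-field bumps in position. Events are drawn from an
inhomogeneous Poisson process evaluated along the simulated trajectory;
each event carries a lognormal amplitude in deconvolved-activity units.
Fluorescence is the event train convolved with an exponential indicator
kernel plus Gaussian noise. Small-amplitude false events with no
fluorescence signature can be injected into ``spks`` so the downstream
noise filter has both true positives and true rejects.

ROI masks are circular footprints on the imaging grid from two
simulated segmenters: an anatomy-based one that finds every cell and an
activity-based one that only finds cells with at least one true event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import BehaviorTrace

__all__ = ["GroundTruthCell", "NoiseConfig", "SessionData",
           "gen_session", "make_cells"]

CLASSES = ("silent", "active_nonplace", "place")


@dataclass
class GroundTruthCell:
    """Generative parameters of one cell. Rates in Hz, positions in cm."""

    cell_id: int
    cls: str
    field_centers_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    field_widths_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    field_peak_rate_hz: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_rate_hz: float = 0.0
    day_state: list[str] | None = None  # per-day {silent, active}

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")
        self.field_centers_cm = np.atleast_1d(np.asarray(self.field_centers_cm, float))
        self.field_widths_cm = np.atleast_1d(np.asarray(self.field_widths_cm, float))
        self.field_peak_rate_hz = np.atleast_1d(np.asarray(self.field_peak_rate_hz, float))
        if self.cls == "place" and not 1 <= self.n_fields <= 6:
            raise ValueError("place cells carry 1-6 fields")
        if self.cls == "silent" and (self.baseline_rate_hz != 0
                                     or self.field_peak_rate_hz.size):
            raise ValueError("silent cells have zero rates")

    @property
    def n_fields(self) -> int:
        return int(self.field_centers_cm.size)

    def rate_at(self, position_cm: np.ndarray) -> np.ndarray:
        """Instantaneous rate (Hz) along a position trace."""
        r = np.full(position_cm.shape, self.baseline_rate_hz, dtype=float)
        for c, w, p in zip(self.field_centers_cm, self.field_widths_cm,
                           self.field_peak_rate_hz):
            r += p * np.exp(-0.5 * ((position_cm - c) / w) ** 2)
        return r

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "cls": self.cls,
            "field_centers_cm": self.field_centers_cm.tolist(),
            "field_widths_cm": self.field_widths_cm.tolist(),
            "field_peak_rate_hz": self.field_peak_rate_hz.tolist(),
            "baseline_rate_hz": self.baseline_rate_hz,
            "day_state": self.day_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthCell":
        return cls(
            cell_id=d["cell_id"], cls=d["cls"],
            field_centers_cm=np.asarray(d["field_centers_cm"]),
            field_widths_cm=np.asarray(d["field_widths_cm"]),
            field_peak_rate_hz=np.asarray(d["field_peak_rate_hz"]),
            baseline_rate_hz=d["baseline_rate_hz"],
            day_state=d.get("day_state"),
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-model parameters.

    spks amplitudes are scaled so the tuning-curve peak of a typical
    place cell clears the downstream peak-detection height parameter
    (default 6) in deconvolved-activity units.
    """

    #: mean deconvolved amplitude per true event (a.u.)
    spks_amp: float = 150.0
    #: lognormal sigma of event amplitudes
    spks_amp_sigma: float = 0.25
    #: fluorescence units per spks unit
    fluor_gain: float = 0.02
    #: exponential indicator decay (GCaMP6s-like)
    tau_s: float = 1.0
    fc_baseline: float = 1.0
    fc_noise_sd: float = 0.05
    #: rate (Hz) of injected small false events in spks
    false_event_rate_hz: float = 0.0
    #: amplitude of false events, near the deconvolution noise floor
    false_event_amp: float = 1.0
    #: imaging grid (rows, cols)
    frame_shape: tuple[int, int] = (512, 505)
    roi_radius_px: float = 6.0


@dataclass
class SessionData:
    """One day's recording: behavior + population activity + segmentation."""

    behavior: BehaviorTrace
    fc: np.ndarray                 # (n_cells, n_frames)
    spks: np.ndarray               # (n_cells, n_frames), >= 0
    cellpose_labels: np.ndarray    # anatomy label image; label = cell_id + 1
    suite2p_labels: np.ndarray     # activity label image; label = cell_id + 1
    mean_image: np.ndarray
    truth: list[GroundTruthCell]

    def __post_init__(self) -> None:
        if self.fc.shape != self.spks.shape:
            raise ValueError("fc and spks shapes differ")
        if self.fc.shape[1] != self.behavior.n_frames:
            raise ValueError("trace length does not match behavior")

    @property
    def n_cells(self) -> int:
        return self.fc.shape[0]


def make_cells(
    n_cells: int,
    rng: np.random.Generator,
    *,
    track_length_cm: float = 800.0,
    p_silent: float = 0.5,
    p_place_given_active: float = 0.5,
    n_fields_weights: tuple = (0.55, 0.2, 0.1, 0.07, 0.05, 0.03),
    field_width_cm: tuple[float, float] = (15.0, 30.0),
    field_peak_rate_hz: tuple[float, float] = (1.5, 3.0),
    nonplace_rate_hz: tuple[float, float] = (0.3, 1.0),
    place_baseline_hz: float = 0.05,
    id_offset: int = 0,
) -> list[GroundTruthCell]:
    """Sample a population with the study-like class mix.

    Roughly half the cells are silent; active cells split between
    spatially untuned cells and place cells carrying 1-6 Gaussian
    fields (most with a single field).
    """
    cells = []
    for i in range(n_cells):
        u = rng.random()
        if u < p_silent:
            cells.append(GroundTruthCell(id_offset + i, "silent"))
        elif rng.random() < p_place_given_active:
            k = 1 + rng.choice(6, p=np.asarray(n_fields_weights) / sum(n_fields_weights))
            centers = rng.uniform(0.05, 0.95, k) * track_length_cm
            widths = rng.uniform(*field_width_cm, k)
            peaks = rng.uniform(*field_peak_rate_hz, k)
            cells.append(GroundTruthCell(
                id_offset + i, "place", centers, widths, peaks,
                baseline_rate_hz=place_baseline_hz))
        else:
            cells.append(GroundTruthCell(
                id_offset + i, "active_nonplace",
                baseline_rate_hz=rng.uniform(*nonplace_rate_hz)))
    return cells


def _draw_events(rate_hz: np.ndarray, frame_rate_hz: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-frame event counts from an inhomogeneous Poisson process."""
    return rng.poisson(rate_hz / frame_rate_hz)


def _disk_coords(center: tuple[float, float], radius: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    return rr[inside], cc[inside]


def _place_rois(n_cells: int, shape: tuple[int, int], radius: float,
                rng: np.random.Generator) -> list[tuple[float, float]]:
    """Jittered-grid cell centers, non-overlapping by construction."""
    pitch = max(int(np.ceil(2 * radius)) + 4, 10)
    margin = int(np.ceil(radius)) + 1
    rows = np.arange(margin + pitch // 2, shape[0] - margin, pitch)
    cols = np.arange(margin + pitch // 2, shape[1] - margin, pitch)
    grid = [(float(r), float(c)) for r in rows for c in cols]
    if len(grid) < n_cells:
        raise ValueError(f"grid {shape} fits only {len(grid)} ROIs of radius {radius}")
    idx = rng.choice(len(grid), size=n_cells, replace=False)
    jit = rng.uniform(-1.5, 1.5, size=(n_cells, 2))
    return [(grid[i][0] + jit[k, 0], grid[i][1] + jit[k, 1])
            for k, i in enumerate(idx)]


def gen_session(
    behavior: BehaviorTrace,
    cells: list[GroundTruthCell],
    noise_cfg: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
    *,
    roi_centers: list[tuple[float, float]] | None = None,
    image_shift: tuple[int, int] = (0, 0),
) -> SessionData:
    """Render one session from ground-truth cells and a behavior trace.

    ``roi_centers`` pins anatomical positions (used by the cohort
    generator so a cell keeps its location across days); ``image_shift``
    rigidly translates all footprints and the mean image, emulating
    day-to-day field-of-view repositioning.
    """
    cfg = noise_cfg or NoiseConfig()
    rng = np.random.default_rng(seed)
    n_frames = behavior.n_frames
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("need at least one cell")

    fr = behavior.frame_rate_hz
    kernel_len = int(np.ceil(5 * cfg.tau_s * fr))
    kernel = np.exp(-np.arange(kernel_len) / (cfg.tau_s * fr))

    fc = np.empty((n_cells, n_frames))
    spks = np.zeros((n_cells, n_frames))
    any_true_event = np.zeros(n_cells, dtype=bool)

    for i, cell in enumerate(cells):
        rate = cell.rate_at(behavior.position_cm)
        counts = _draw_events(rate, fr, rng) if rate.any() else np.zeros(n_frames, int)
        amp = np.zeros(n_frames)
        ev = counts > 0
        if ev.any():
            # lognormal amplitudes, mean spks_amp
            mu = np.log(cfg.spks_amp) - 0.5 * cfg.spks_amp_sigma ** 2
            amp[ev] = counts[ev] * rng.lognormal(mu, cfg.spks_amp_sigma, ev.sum())
            any_true_event[i] = True
        spks[i] = amp
        # false events only where the activity-based segmenter would
        # have produced a trace at all
        if cfg.false_event_rate_hz > 0 and any_true_event[i]:
            n_false = rng.poisson(cfg.false_event_rate_hz * n_frames / fr)
            if n_false:
                frames = rng.choice(n_frames, size=min(n_false, n_frames),
                                    replace=False)
                spks[i, frames] += cfg.false_event_amp
        fluor = np.convolve(amp * cfg.fluor_gain, kernel)[:n_frames]
        fc[i] = (cfg.fc_baseline + fluor
                 + rng.normal(0.0, cfg.fc_noise_sd, n_frames))

    shape = cfg.frame_shape
    if roi_centers is None:
        roi_centers = _place_rois(n_cells, shape, cfg.roi_radius_px, rng)
    centers = [(r + image_shift[0], c + image_shift[1]) for r, c in roi_centers]

    cellpose = np.zeros(shape, dtype=np.int32)
    suite2p = np.zeros(shape, dtype=np.int32)
    mean_img = rng.normal(10.0, 1.0, shape)
    for i, cell in enumerate(cells):
        rr, cc = _disk_coords(centers[i], cfg.roi_radius_px, shape)
        cellpose[rr, cc] = cell.cell_id + 1
        mean_img[rr, cc] += 20.0 + 5.0 * float(np.mean(spks[i]) > 0)
        if any_true_event[i]:
            # activity-based segmenter: slightly smaller footprint
            rr2, cc2 = _disk_coords(centers[i], cfg.roi_radius_px - 0.5, shape)
            suite2p[rr2, cc2] = cell.cell_id + 1

    return SessionData(behavior, fc, spks, cellpose, suite2p, mean_img, cells)
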