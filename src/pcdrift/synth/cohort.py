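"""Multi-day cohorts: Markov silent/active dynamics and drift.

Each cell's day-to-day activity state follows a two-state Markov chain
(silent -> active with the unsilencing rate u, active -> silent with
the silencing rate), except for a designated persistently silent
subpopulation that never unsilences. Place-field centers jitter from
day to day (representational drift) and the field of view shifts by a
small rigid translation so cross-day registration is exercised.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .behavior import BehaviorConfig, gen_behavior
from .session import GroundTruthCell, NoiseConfig, SessionData, gen_session, make_cells

__all__ = ["CohortConfig", "CohortTruth", "gen_state_matrix", "gen_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    n_animals: int = 1
    n_cells_per_fov: int = 100
    n_days: int = 6
    #: probability a cell is silent on day 1
    p_silent: float = 0.5
    #: per-day silent -> active transition probability
    unsilencing_rate: float = 0.54
    #: per-day active -> silent transition probability
    silencing_rate: float = 0.3
    #: day-to-day place-field-center jitter SD
    drift_sd_cm: float = 20.0
    #: fraction of day-1 silent cells that never unsilence
    persistent_silent_frac: float = 0.0
    #: max |rigid shift| of the mean image per day, pixels
    max_shift_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_silent", "unsilencing_rate", "silencing_rate",
                     "persistent_silent_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass
class CohortTruth:
    """Ground-truth bookkeeping for one simulated animal."""

    states: np.ndarray            # (n_cells, n_days) of {"silent", "active"}
    persistent_ids: np.ndarray    # cell ids forced silent on all days
    shifts: list[tuple[int, int]] = field(default_factory=list)  # per day
    cells_by_day: list[list[GroundTruthCell]] = field(default_factory=list)


def gen_state_matrix(config: CohortConfig,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the silent/active Markov chain for one animal.

    Returns ``(states, persistent_ids)`` where ``states`` is an
    (n_cells, n_days) array of ``"silent"``/``"active"`` strings. Day-1
    states are Bernoulli(p_silent); a ``persistent_silent_frac`` subset
    of the day-1 silent cells is pinned silent for the whole series.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, d = config.n_cells_per_fov, config.n_days
    silent = rng.random(n) < config.p_silent
    day1_silent = np.flatnonzero(silent)
    n_persist = int(round(config.persistent_silent_frac * day1_silent.size))
    persistent = (rng.choice(day1_silent, size=n_persist, replace=False)
                  if n_persist else np.empty(0, dtype=int))
    is_persistent = np.zeros(n, dtype=bool)
    is_persistent[persistent] = True

    states = np.empty((n, d), dtype=object)
    cur = silent.copy()
    states[:, 0] = np.where(cur, "silent", "active")
    for k in range(1, d):
        r = rng.random(n)
        unsilence = cur & ~is_persistent & (r < config.unsilencing_rate)
        silence = ~cur & (r < config.silencing_rate)
        cur = (cur & ~unsilence) | silence
        states[:, k] = np.where(cur, "silent", "active")
    return states, persistent


def _drift_cells(cells: list[GroundTruthCell], drift_sd: float,
                 track_length: float, rng: np.random.Generator
                 ) -> list[GroundTruthCell]:
    out = []
    for c in cells:
        c2 = copy.deepcopy(c)
        if c2.n_fields:
            c2.field_centers_cm = np.clip(
                c2.field_centers_cm + rng.normal(0, drift_sd, c2.n_fields),
                0.0, track_length)
        out.append(c2)
    return out


def _silenced(cell: GroundTruthCell) -> GroundTruthCell:
    return GroundTruthCell(cell.cell_id, "silent", day_state=cell.day_state)


def gen_cohort(
    config: CohortConfig,
    behavior_cfg: BehaviorConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
) -> tuple[list[list[SessionData]], list[CohortTruth]]:
    """Generate per-animal, per-day sessions with linked ground truth.

    Returns ``(sessions, truths)``: ``sessions[a][d]`` is animal *a*'s
    day-*d* session; ``truths[a]`` records the state matrix, the
    persistently silent ids and the per-day rigid image shifts.
    """
    bcfg = behavior_cfg or BehaviorConfig()
    ncfg = noise_cfg or NoiseConfig()
    root = np.random.SeedSequence(config.seed)
    sessions: list[list[SessionData]] = []
    truths: list[CohortTruth] = []

    for animal_ss in root.spawn(config.n_animals):
        rng = np.random.default_rng(animal_ss)
        states, persistent = gen_state_matrix(config, rng)
        # archetype population: what each cell does when active
        base_cells = make_cells(
            config.n_cells_per_fov, rng,
            track_length_cm=bcfg.track_length_cm, p_silent=0.0)
        from .session import _place_rois
        roi_centers = _place_rois(config.n_cells_per_fov, ncfg.frame_shape,
                                  ncfg.roi_radius_px, rng)
        truth = CohortTruth(states, persistent)
        day_sessions = []
        cells_today = base_cells
        for d in range(config.n_days):
            if d > 0:
                cells_today = _drift_cells(cells_today, config.drift_sd_cm,
                                           bcfg.track_length_cm, rng)
            day_cells = []
            for i, c in enumerate(cells_today):
                c = copy.deepcopy(c)
                c.day_state = list(states[i])
                day_cells.append(c if states[i, d] == "active" else _silenced(c))
            shift = ((0, 0) if d == 0 else tuple(
                rng.integers(-config.max_shift_px, config.max_shift_px + 1, 2)))
            behavior = gen_behavior(bcfg, rng)
            day_sessions.append(gen_session(
                behavior, day_cells, ncfg, rng,
                roi_centers=roi_centers, image_shift=shift))
            truth.shifts.append(tuple(int(s) for s in shift))
            truth.cells_by_day.append(day_cells)
        sessions.append(day_sessions)
        truths.append(truth)
    return sessions, truths
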