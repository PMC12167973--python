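"""Virtual-corridor running behavior.

A head-fixed mouse runs laps in a linear virtual corridor (~8 m). Speed
is roughly constant (~30-40 cm/s) with frame-to-frame noise, dips in an
approach window before the reward zone, and licking becomes likely
there. At the corridor end the animal is teleported back to the start
and the lap counter increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BehaviorConfig", "BehaviorTrace", "gen_behavior"]


@dataclass(frozen=True)
class BehaviorConfig:
    track_length_cm: float = 800.0
    n_laps: int = 50
    frame_rate_hz: float = 30.0
    mean_speed_cm_s: float = 35.0
    speed_noise_sd: float = 4.0
    rz_start_cm: float = 700.0
    rz_end_cm: float = 800.0
    #: speed multiplier inside the approach window before the reward zone
    slowdown_factor: float = 0.6
    #: approach window length before rz_start
    approach_cm: float = 100.0
    #: per-frame lick probability outside / inside approach+RZ
    lick_p_base: float = 0.002
    lick_p_rz: float = 0.15
    #: multiplicative lap-to-lap speed variability (SD of a factor ~ 1)
    lap_speed_sd: float = 0.15
    #: rate of spontaneous stop bouts while running
    stop_rate_hz: float = 0.05
    #: stop bout duration bounds
    stop_duration_s: tuple[float, float] = (0.3, 2.0)
    teleport: bool = True

    def __post_init__(self) -> None:
        if self.track_length_cm <= 0:
            raise ValueError("track_length_cm must be positive")
        if not (0 < self.rz_start_cm < self.rz_end_cm <= self.track_length_cm):
            raise ValueError("reward zone must satisfy 0 < start < end <= track length")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.mean_speed_cm_s <= 0:
            raise ValueError("mean speed must be positive")
        if self.n_laps < 1:
            raise ValueError("need at least one lap")


@dataclass
class BehaviorTrace:
    """Per-frame behavior: time, position, speed, 1-based lap index, licks."""

    time_s: np.ndarray
    position_cm: np.ndarray
    speed_cm_s: np.ndarray
    lap_index: np.ndarray
    lick: np.ndarray
    track_length_cm: float
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def n_laps(self) -> int:
        return int(self.lap_index.max())

    @property
    def n_teleports(self) -> int:
        """Completed-lap teleports: recorded position drops plus the
        terminal teleport that ends the trace."""
        return int(np.sum(np.diff(self.position_cm) < 0)) + 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s,
            "position_cm": self.position_cm,
            "speed_cm_s": self.speed_cm_s,
            "lap": self.lap_index,
            "lick": self.lick.astype(int),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, track_length_cm: float,
                       frame_rate_hz: float) -> "BehaviorTrace":
        return cls(
            time_s=df["time_s"].to_numpy(float),
            position_cm=df["position_cm"].to_numpy(float),
            speed_cm_s=df["speed_cm_s"].to_numpy(float),
            lap_index=df["lap"].to_numpy(int),
            lick=df["lick"].to_numpy(bool),
            track_length_cm=track_length_cm,
            frame_rate_hz=frame_rate_hz,
        )


def gen_behavior(config: BehaviorConfig, seed: int | np.random.Generator = 0
                 ) -> BehaviorTrace:
    """Simulate lap running until ``n_laps`` laps complete.

    Each lap has its own mean speed, ``mean_speed x N(1, lap_speed_sd)``;
    per-frame speed adds ``N(0, speed_noise_sd)`` clipped at a small
    positive floor and is multiplied by ``slowdown_factor`` inside the
    approach window ``[rz_start - approach_cm, rz_start)``. Spontaneous
    stop bouts (rate ``stop_rate_hz``, duration uniform in
    ``stop_duration_s``) drop speed to a crawl — the low-speed periods
    the 4 cm/s analysis filter is built to discard, and the temporal
    variability that makes circular-shift shuffles a valid null.
    Position integrates speed; crossing the corridor end teleports to 0
    and increments the lap. Lick events are Bernoulli with elevated
    probability in the approach window and reward zone. Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    dt = 1.0 / cfg.frame_rate_hz
    approach_lo = cfg.rz_start_cm - cfg.approach_cm

    pos_l: list[float] = []
    speed_l: list[float] = []
    lap_l: list[int] = []
    lick_l: list[bool] = []

    pos = 0.0
    lap = 1
    lap_factor = max(1.0 + rng.normal(0.0, cfg.lap_speed_sd), 0.3) \
        if cfg.lap_speed_sd > 0 else 1.0
    stop_frames_left = 0
    # hard cap so a pathological config cannot loop forever
    max_frames = int(cfg.n_laps * cfg.track_length_cm
                     / (cfg.mean_speed_cm_s * min(cfg.slowdown_factor, 1.0) * dt)
                     * 10) + 1000
    for _ in range(max_frames):
        if stop_frames_left > 0:
            stop_frames_left -= 1
            v = rng.uniform(0.0, 1.0)
        else:
            if cfg.stop_rate_hz > 0 and rng.random() < cfg.stop_rate_hz * dt:
                dur = rng.uniform(*cfg.stop_duration_s)
                stop_frames_left = max(int(dur * cfg.frame_rate_hz) - 1, 0)
                v = rng.uniform(0.0, 1.0)
            else:
                v = (cfg.mean_speed_cm_s * lap_factor
                     + rng.normal(0.0, cfg.speed_noise_sd))
                v = max(v, 1.0)
        in_approach = approach_lo <= pos < cfg.rz_start_cm
        if in_approach:
            v *= cfg.slowdown_factor
        in_rz = cfg.rz_start_cm <= pos < cfg.rz_end_cm
        p_lick = cfg.lick_p_rz if (in_approach or in_rz) else cfg.lick_p_base
        pos_l.append(pos)
        speed_l.append(v)
        lap_l.append(lap)
        lick_l.append(bool(rng.random() < p_lick))
        pos += v * dt
        if pos >= cfg.track_length_cm:
            pos = pos - cfg.track_length_cm if not cfg.teleport else 0.0
            if lap == cfg.n_laps:
                break
            lap += 1
            lap_factor = max(1.0 + rng.normal(0.0, cfg.lap_speed_sd), 0.3) \
                if cfg.lap_speed_sd > 0 else 1.0
    else:
        raise RuntimeError("behavior simulation did not finish in frame budget")

    n = len(pos_l)
    return BehaviorTrace(
        time_s=np.arange(n) * dt,
        position_cm=np.asarray(pos_l),
        speed_cm_s=np.asarray(speed_l),
        lap_index=np.asarray(lap_l, dtype=int),
        lick=np.asarray(lick_l, dtype=bool),
        track_length_cm=cfg.track_length_cm,
        frame_rate_hz=cfg.frame_rate_hz,
    )
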