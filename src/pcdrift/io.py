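"""Session directory layout: read/write simulated or exported sessions.

One directory per day::

    day_01/
      fc.npy            (n_cells, n_frames) fluorescence
      spks.npy          (n_cells, n_frames) deconvolved activity
      cellpose_labels.npy   anatomy label image (label = cell_id + 1)
      suite2p_labels.npy    activity label image
      mean_image.npy
      behavior.csv      time_s, position_cm, speed_cm_s, lap, lick
      truth.json        ground truth (simulated sessions only)
      meta.json         track_length_cm, frame_rate_hz
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth.behavior import BehaviorTrace
from .synth.session import GroundTruthCell, SessionData

__all__ = ["write_session", "read_session", "write_cohort", "read_cohort"]


def write_session(session: SessionData, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "fc.npy", session.fc)
    np.save(out / "spks.npy", session.spks)
    np.save(out / "cellpose_labels.npy", session.cellpose_labels)
    np.save(out / "suite2p_labels.npy", session.suite2p_labels)
    np.save(out / "mean_image.npy", session.mean_image)
    session.behavior.to_dataframe().to_csv(out / "behavior.csv", index=False)
    (out / "truth.json").write_text(json.dumps(
        [c.to_dict() for c in session.truth], indent=1))
    (out / "meta.json").write_text(json.dumps({
        "track_length_cm": session.behavior.track_length_cm,
        "frame_rate_hz": session.behavior.frame_rate_hz,
    }))
    return out


def read_session(session_dir: str | Path) -> SessionData:
    d = Path(session_dir)
    for name in ("fc.npy", "spks.npy", "cellpose_labels.npy",
                 "suite2p_labels.npy", "mean_image.npy",
                 "behavior.csv", "meta.json"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file: {d / name}")
    meta = json.loads((d / "meta.json").read_text())
    behavior = BehaviorTrace.from_dataframe(
        pd.read_csv(d / "behavior.csv"),
        meta["track_length_cm"], meta["frame_rate_hz"])
    truth_file = d / "truth.json"
    truth = ([GroundTruthCell.from_dict(c)
              for c in json.loads(truth_file.read_text())]
             if truth_file.exists() else [])
    return SessionData(
        behavior=behavior,
        fc=np.load(d / "fc.npy"),
        spks=np.load(d / "spks.npy"),
        cellpose_labels=np.load(d / "cellpose_labels.npy"),
        suite2p_labels=np.load(d / "suite2p_labels.npy"),
        mean_image=np.load(d / "mean_image.npy"),
        truth=truth,
    )


def write_cohort(days: list[SessionData], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    for d, session in enumerate(days, start=1):
        write_session(session, out / f"day_{d:02d}")
    return out


def read_cohort(cohort_dir: str | Path) -> list[SessionData]:
    d = Path(cohort_dir)
    day_dirs = sorted(p for p in d.iterdir() if p.is_dir()
                      and p.name.startswith("day_"))
    if len(day_dirs) < 2:
        raise ValueError(f"cohort directory {d} needs >= 2 day_* subdirectories")
    return [read_session(p) for p in day_dirs]
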