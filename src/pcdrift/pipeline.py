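"""End-to-end orchestration: session-level and cohort-level runs.

``run_session`` executes noise filtering -> ROI matching / silent-cell
identification -> place-cell classification for one day and returns
(and optionally writes) tidy result tables. ``run_cohort`` adds
cross-day registration, identity linking, persistent-silence counts,
the measured unsilencing rate and its theoretical decay curve.

One global seed fans out deterministically to per-stage, per-cell
child seeds, so reruns are byte-identical while cells stay
statistically independent.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .events import FluorTrace, activity_metrics, filter_train
from .io import read_cohort, read_session
from .placefield import (
    CellClassification,
    SpatialBinning,
    classification_table,
    classify_cell,
)
from .stats import CohortSummary, session_fractions, theoretical_decay, unsilencing_rate
from .synth.session import SessionData
from .tracking import (
    CellTrack,
    classify_silent,
    link_tracks,
    masks_from_labels,
    match_roi_sets,
    persistent_silence,
    register_days,
)

__all__ = ["run_session", "run_cohort", "SessionResult"]

log = logging.getLogger(__name__)


def _cell_seed(root_seed: int, stage: str, cell_id: int) -> np.random.Generator:
    # crc32 keeps the stage token stable across processes
    stage_token = zlib.crc32(stage.encode()) % (2**31)
    ss = np.random.SeedSequence([root_seed, stage_token, cell_id])
    return np.random.default_rng(ss)


class SessionResult:
    """Per-session outputs: state labels, classifications, tables."""

    def __init__(self, states: dict[int, str],
                 classifications: dict[int, CellClassification],
                 filtered_metrics: dict[int, dict]):
        self.states = states
        self.classifications = classifications
        self.filtered_metrics = filtered_metrics

    def cells_table(self) -> pd.DataFrame:
        tab = classification_table(self.classifications)
        if tab.empty:
            tab = pd.DataFrame(columns=["cell_id", "label"])
        met = pd.DataFrame([
            {"cell_id": cid, **m} for cid, m in self.filtered_metrics.items()])
        return tab.merge(met, on="cell_id", how="outer").sort_values(
            "cell_id").reset_index(drop=True)

    def fields_table(self, binning: SpatialBinning) -> pd.DataFrame:
        w = binning.track_length_cm / binning.n_bins
        rows = []
        for cid, c in self.classifications.items():
            for f in c.fields:
                rows.append({
                    "cell_id": cid,
                    "start_cm": f.base_start_bin * w,
                    "end_cm": (f.base_end_bin + 1) * w,
                    "peak_bin": f.peak_bin,
                    "local_si": f.local_si,
                    "local_si_p": f.local_si_p,
                    "coverage": f.lap_coverage_frac,
                    "significant": f.significant,
                })
        return pd.DataFrame(rows, columns=[
            "cell_id", "start_cm", "end_cm", "peak_bin", "local_si",
            "local_si_p", "coverage", "significant"])


def run_session(
    config: PipelineConfig,
    session: SessionData | str | Path,
    out_dir: str | Path | None = None,
) -> SessionResult:
    """Analyze one session end to end.

    Anatomy ROIs with no matched activity ROI are silent; matched
    cells' deconvolved trains are noise-filtered and pushed through
    the place-cell gates. Row *i* of ``fc``/``spks`` is the trace of
    activity ROI id *i*.
    """
    if not isinstance(session, SessionData):
        session = read_session(session)
    binning = SpatialBinning(session.behavior.track_length_cm, config.n_bins)
    anatomy = masks_from_labels(session.cellpose_labels, "anatomy")
    activity = masks_from_labels(session.suite2p_labels, "activity")
    matched, unmatched = match_roi_sets(anatomy, activity,
                                        config.overlap_threshold)
    log.info("ROI matching (threshold %.2f): %d anatomy, %d activity, "
             "%d matched, %d silent candidates", config.overlap_threshold,
             len(anatomy), len(activity), len(matched), len(unmatched))

    filtered: dict[int, np.ndarray] = {}
    metrics: dict[int, dict] = {}
    valid_counts: dict[int, int] = {}
    duration = session.behavior.n_frames / session.behavior.frame_rate_hz
    for s_id in sorted(set(matched.values())):
        trace = FluorTrace(session.fc[s_id], session.behavior.frame_rate_hz)
        train = filter_train(trace, session.spks[s_id],
                             mode=config.filter_mode, ddof=config.sd_ddof)
        filtered[s_id] = train.spks_filtered
        metrics[s_id] = activity_metrics(train, duration)
        valid_counts[s_id] = len(train.valid_events)

    n_events = sum(len(np.flatnonzero(v)) for v in filtered.values())
    log.info("event filter (mode=%s): %d surviving event frames over %d "
             "active cells", config.filter_mode, n_events, len(filtered))
    states = classify_silent(anatomy, activity,
                             threshold=config.overlap_threshold)

    classifications: dict[int, CellClassification] = {}
    for a_id, state in sorted(states.items()):
        if state == "silent":
            classifications[a_id] = CellClassification(
                "silent", reason="no activity ROI")
            continue
        s_id = matched[a_id]
        rng = _cell_seed(config.seed, "placefield", a_id)
        classifications[a_id] = classify_cell(
            filtered[s_id], session.behavior, binning,
            n_shuffle=config.n_shuffle, seed=rng,
            peak_height=config.peak_height, rel_height=config.rel_height,
            min_odd_even_r=config.min_odd_even_r,
            speed_threshold=config.speed_threshold_cm_s,
            coverage_min=config.lap_coverage_min)

    counts: dict[str, int] = {}
    for c in classifications.values():
        counts[c.label] = counts.get(c.label, 0) + 1
    log.info("place-cell pipeline (%d shuffles, seed %d): %s",
             config.n_shuffle, config.seed, counts)
    result = SessionResult(
        states, classifications,
        {a_id: metrics[matched[a_id]] for a_id in matched})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.cells_table().to_csv(out / "cells.csv", index=False)
        result.fields_table(binning).to_csv(out / "fields.csv", index=False)
        config.to_yaml(out / "config.yaml")
    return result


def run_cohort(
    config: PipelineConfig,
    days: list[SessionData] | str | Path,
    out_dir: str | Path | None = None,
    *,
    classify_place: bool = False,
) -> tuple[CohortSummary, list[CellTrack]]:
    """Analyze a multi-day cohort for one field of view.

    Registers consecutive mean images (rigid translation), links
    anatomy ROIs across days, assigns per-day silent/active states,
    and summarizes persistent silence against the theoretical
    (1-u)^(k-1) decay. ``classify_place=True`` additionally runs the
    full place-cell pipeline every day (slower); otherwise per-day
    place fractions are NaN.
    """
    if not isinstance(days, list):
        days = read_cohort(days)
    if len(days) < 2:
        raise ValueError("cohort needs at least two days")

    shifts = [(0, 0)]
    for d in range(1, len(days)):
        dy, dx = register_days(days[0].mean_image, days[d].mean_image)
        shifts.append((dy, dx))
    log.info("registration: day shifts %s", shifts)

    daily_anatomy = [masks_from_labels(s.cellpose_labels, "anatomy")
                     for s in days]
    tracks = link_tracks(daily_anatomy, shifts, config.overlap_threshold)

    day_states = []
    day_results: list[SessionResult | None] = []
    for d, s in enumerate(days):
        if classify_place:
            res = run_session(config, s)
            day_results.append(res)
            day_states.append({a: c.label for a, c in res.classifications.items()})
        else:
            anatomy = daily_anatomy[d]
            activity = masks_from_labels(s.suite2p_labels, "activity")
            day_results.append(None)
            day_states.append(classify_silent(
                anatomy, activity, threshold=config.overlap_threshold))

    for t in tracks:
        t.states = []
        for d, roi_id in enumerate(t.anatomy_roi_ids):
            lab = day_states[d].get(roi_id, "silent")
            t.states.append("silent" if lab == "silent" else "active")

    persistence = persistent_silence(tracks)
    ps = persistence
    u = unsilencing_rate(tracks)
    fractions = []
    for d in range(len(days)):
        labels = (day_states[d] if classify_place else None)
        fractions.append(session_fractions(tracks, d, labels))

    summary = CohortSummary(
        per_day_fractions=fractions,
        persistently_silent_counts=ps["count"].to_numpy(),
        persistently_silent_normalized=ps["normalized"].to_numpy(),
        unsilencing_rate=u,
        theoretical_curve=theoretical_decay(u, len(days)),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cohort_summary.json").write_text(
            json.dumps(summary.to_dict(), indent=1))
        persistence.to_csv(out / "persistent_silence.csv", index=False)
        pd.DataFrame([
            {"track_id": t.track_id, "day": d + 1,
             "roi_id": t.anatomy_roi_ids[d], "state": t.states[d]}
            for t in tracks for d in range(t.n_days)
        ]).to_csv(out / "tracks.csv", index=False)
    return summary, tracks
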