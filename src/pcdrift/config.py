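"""Pipeline configuration: every tunable constant in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults.

    Defaults mirror the analysis constants the pipeline was designed
    around: a 4 cm/s speed filter, 0.25 odd-even reliability gate,
    1,500 shuffles with 99th (global) / 95th (local) percentile
    criteria, tuning-peak height 6, 93% relative prominence height for
    field bases, 30% lap coverage, 75% ROI-overlap matching, 0.5
    footprint correlation with sigma-2 smoothing and a median+2SD
    event threshold, and 5,000 bootstrap resamples.
    """

    # spatial binning
    n_bins: int = 80
    track_length_cm: float = 800.0
    # event filter
    filter_mode: str = "both"        # noise criterion: max or min of local/global SD
    sd_ddof: int = 0                 # population SD
    # place-cell pipeline
    speed_threshold_cm_s: float = 4.0
    min_odd_even_r: float = 0.25
    n_shuffle: int = 1500
    global_si_percentile: float = 99.0
    local_si_percentile: float = 95.0
    peak_height: float = 6.0
    rel_height: float = 0.93
    lap_coverage_min: float = 0.30
    # ROI matching / tracking
    overlap_threshold: float = 0.75
    footprint_r_threshold: float = 0.5
    footprint_smooth_sigma: float = 2.0
    footprint_sd_mult: float = 2.0
    footprint_dilate_px: int = 5
    # statistics
    n_bootstrap: int = 5000
    # ephys
    dvdt_crit_mv_ms: float = 10.0
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
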