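"""Intrinsic electrophysiological properties from current-clamp sweeps.

Three properties per cell: the action-potential threshold (membrane
potential where dV/dt first exceeds 10 mV/ms), the resting membrane
potential (mean Vm without current injection), and the input
resistance (steady-state voltage deflection divided by injected
current, averaged over subthreshold sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VoltageSweep", "EphysProperties",
           "ap_threshold", "resting_vm", "input_resistance",
           "extract_properties"]

DVDT_CRITERION_MV_MS = 10.0


@dataclass(frozen=True)
class VoltageSweep:
    """One current-clamp sweep.

    ``step_onset``/``step_offset`` are sample indices bounding the
    current step; ``injected_current_pa`` is the step amplitude.
    """

    vm_mv: np.ndarray
    sample_rate_hz: float = 50_000.0
    injected_current_pa: float = 0.0
    step_onset: int = 0
    step_offset: int | None = None

    def __post_init__(self) -> None:
        vm = np.asarray(self.vm_mv, dtype=float)
        if vm.ndim != 1 or vm.size < 3:
            raise ValueError("vm_mv must be a 1-D array of >= 3 samples")
        if not np.isfinite(vm).all():
            raise ValueError("vm_mv contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "vm_mv", vm)

    @property
    def n_samples(self) -> int:
        return self.vm_mv.size

    def dvdt_mv_per_ms(self, smooth_samples: int = 1) -> np.ndarray:
        """First derivative by central differences, in mV/ms.

        ``smooth_samples > 1`` applies a boxcar pre-filter; useful when
        wide-band noise at 50 kHz produces spurious slope excursions.
        """
        vm = self.vm_mv
        if smooth_samples > 1:
            k = np.ones(smooth_samples) / smooth_samples
            vm = np.convolve(vm, k, mode="same")
        dt_ms = 1000.0 / self.sample_rate_hz
        return np.gradient(vm, dt_ms)


@dataclass
class EphysProperties:
    ap_threshold_mv: float
    resting_vm_mv: float
    input_resistance_mohm: float

    def to_dict(self) -> dict:
        return {"ap_threshold_mv": self.ap_threshold_mv,
                "resting_vm_mv": self.resting_vm_mv,
                "input_resistance_mohm": self.input_resistance_mohm}


class NoActionPotential(ValueError):
    """The sweep contains no dV/dt crossing of the slope criterion."""


def _crossings(sweep: VoltageSweep, dvdt_crit: float,
               smooth_samples: int = 1) -> np.ndarray:
    """First sample of each run where dV/dt exceeds the criterion."""
    above = sweep.dvdt_mv_per_ms(smooth_samples) > dvdt_crit
    starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    return starts


def ap_threshold(
    sweep: VoltageSweep,
    dvdt_crit: float = DVDT_CRITERION_MV_MS,
    *,
    per_ap: bool = False,
    smooth_samples: int = 1,
) -> float | np.ndarray:
    """Membrane potential where dV/dt first exceeds ``dvdt_crit``.

    With ``per_ap=True`` returns one threshold per suprathreshold run
    (each AP's onset); callers may average them. Raises
    :class:`NoActionPotential` when no sample crosses the criterion.
    """
    starts = _crossings(sweep, dvdt_crit, smooth_samples)
    if starts.size == 0:
        raise NoActionPotential("no AP detected: dV/dt never exceeds criterion")
    thresholds = sweep.vm_mv[starts]
    return thresholds if per_ap else float(thresholds[0])


def has_ap(sweep: VoltageSweep, dvdt_crit: float = DVDT_CRITERION_MV_MS,
           smooth_samples: int = 1) -> bool:
    return _crossings(sweep, dvdt_crit, smooth_samples).size > 0


def resting_vm(sweep: VoltageSweep, *, baseline_ms: float = 100.0) -> float:
    """Mean Vm over the pre-step baseline of a zero-current sweep.

    Uses the ``baseline_ms`` window ending at step onset; with no step
    (onset 0 on a zero-current sweep) the whole trace is the baseline.
    """
    if sweep.injected_current_pa != 0:
        raise ValueError("resting Vm requires a zero-current sweep")
    if sweep.step_onset <= 0:
        return float(np.mean(sweep.vm_mv))
    n_base = int(baseline_ms / 1000.0 * sweep.sample_rate_hz)
    lo = max(sweep.step_onset - n_base, 0)
    if lo >= sweep.step_onset:
        raise ValueError("no baseline window before the step")
    return float(np.mean(sweep.vm_mv[lo:sweep.step_onset]))


def input_resistance(
    sweeps: list[VoltageSweep],
    dvdt_crit: float = DVDT_CRITERION_MV_MS,
    *,
    steady_frac: float = 0.2,
    baseline_ms: float = 100.0,
) -> float:
    """Mean input resistance (MOhm) over subthreshold current steps.

    Per sweep: R = (steady-state Vm - baseline Vm) / I. Steady state is
    the mean over the last ``steady_frac`` of the step; baseline the
    ``baseline_ms`` window before step onset. Sweeps containing an AP
    (by the dV/dt criterion) or with zero current are excluded.
    """
    rs = []
    for sw in sweeps:
        if sw.injected_current_pa == 0 or has_ap(sw, dvdt_crit):
            continue
        onset = sw.step_onset
        offset = sw.step_offset if sw.step_offset is not None else sw.n_samples
        n_base = int(baseline_ms / 1000.0 * sw.sample_rate_hz)
        lo = max(onset - n_base, 0)
        if lo >= onset or offset <= onset:
            continue
        base = float(np.mean(sw.vm_mv[lo:onset]))
        n_ss = max(int(steady_frac * (offset - onset)), 1)
        steady = float(np.mean(sw.vm_mv[offset - n_ss:offset]))
        # mV / pA = GOhm; x1000 -> MOhm
        rs.append((steady - base) / sw.injected_current_pa * 1000.0)
    if not rs:
        raise ValueError("no usable subthreshold sweep")
    return float(np.mean(rs))


def extract_properties(
    sweeps: list[VoltageSweep],
    dvdt_crit: float = DVDT_CRITERION_MV_MS,
) -> EphysProperties:
    """All three intrinsic properties from one cell's sweep family."""
    ap_sweeps = [s for s in sweeps if has_ap(s, dvdt_crit)]
    if not ap_sweeps:
        raise NoActionPotential("no sweep contains an AP")
    # threshold from the strongest depolarizing suprathreshold sweep
    ap_sweeps.sort(key=lambda s: -s.injected_current_pa)
    thr = ap_threshold(ap_sweeps[0], dvdt_crit)
    rest_sweeps = [s for s in sweeps if s.injected_current_pa == 0]
    if not rest_sweeps:
        raise ValueError("no zero-current sweep for resting Vm")
    return EphysProperties(
        ap_threshold_mv=thr,
        resting_vm_mv=resting_vm(rest_sweeps[0]),
        input_resistance_mohm=input_resistance(sweeps, dvdt_crit),
    )


def sweeps_from_frame(df: pd.DataFrame, sample_rate_hz: float = 50_000.0
                      ) -> list[VoltageSweep]:
    """Build sweeps from a tidy table (sweep, time_s, vm_mv, i_pa).

    The current step window is inferred from where ``i_pa`` is nonzero;
    for zero-current sweeps onset/offset stay at the trace bounds.
    """
    out = []
    for _, g in df.groupby("sweep"):
        vm = g["vm_mv"].to_numpy(float)
        i = g["i_pa"].to_numpy(float)
        nz = np.flatnonzero(i != 0)
        if nz.size:
            out.append(VoltageSweep(vm, sample_rate_hz, float(i[nz[0]]),
                                    int(nz[0]), int(nz[-1]) + 1))
        else:
            out.append(VoltageSweep(vm, sample_rate_hz, 0.0, 0, None))
    return out
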