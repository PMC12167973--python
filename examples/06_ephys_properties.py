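"""Extract intrinsic properties from simulated current-clamp sweeps.

Builds a family of sweeps for one cell (resting trace, subthreshold
RC steps, a suprathreshold ramp) and extracts resting Vm, input
resistance, and AP threshold.
"""

import numpy as np

from pcdrift.ephys import VoltageSweep, extract_properties

SR = 50_000.0
rng = np.random.default_rng(10)

# resting sweep: -67 mV with (band-limited) recording noise
rest = VoltageSweep(-67.0 + rng.normal(0, 0.05, 25_000), SR, 0.0)

# two subthreshold RC steps, R = 130 MOhm, tau = 15 ms
sweeps = [rest]
for i_pa in (-100.0, -50.0):
    n, onset, offset = 25_000, 5_000, 20_000
    t = np.arange(n) / SR
    dv = i_pa * 130.0 / 1000.0
    vm = np.full(n, -67.0)
    tt = t[onset:offset] - t[onset]
    vm[onset:offset] += dv * (1 - np.exp(-tt / 0.015))
    vm[offset:] += dv * np.exp(-(t[offset:] - t[offset]) / 0.015)
    sweeps.append(VoltageSweep(vm + rng.normal(0, 0.05, n), SR, i_pa,
                               onset, offset))

# suprathreshold ramp: dV/dt jumps from 5 to 20 mV/ms at -45 mV
dt_ms = 1000.0 / SR
vm = np.concatenate([np.full(200, -70.0),
                     -70.0 + 5.0 * dt_ms * np.arange(251),
                     -45.0 + 20.0 * dt_ms * np.arange(1, 200)])
sweeps.append(VoltageSweep(vm, SR, 200.0, 200, vm.size))

props = extract_properties(sweeps)
print(f"resting Vm:       {props.resting_vm_mv:8.2f} mV   (generative -67.0)")
print(f"input resistance: {props.input_resistance_mohm:8.1f} MOhm "
      f"(generative 130.0)")
print(f"AP threshold:     {props.ap_threshold_mv:8.2f} mV   (generative -45.0)")
# The threshold is the Vm where dV/dt first exceeds 10 mV/ms; the
# input resistance is the steady-state deflection over the injected
# current, averaged over AP-free sweeps.
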