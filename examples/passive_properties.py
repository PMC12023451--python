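"""Measure passive membrane properties of a synthetic cell with known ground truth.

Generates the standard step protocols (voltage-clamp test pulses, 500 ms
hyperpolarizing current steps, 100 ms pulses for the time constant, deep
steps for sag) and runs each estimator.  Printed values should sit within a
few percent of the generator's ground truth.
"""

import numpy as np

from olfephys import intrinsic, synth

membrane = synth.MembraneParams(
    input_resistance=133.0,   # MΩ
    capacitance=90.2256,      # pF → τ = 12 ms
    series_resistance=10.0,   # MΩ
    sag_fraction=0.05,
    noise_sd=0.3,             # mV of current-clamp noise
)
print(f"ground truth: Rin={membrane.input_resistance} MΩ, τ={membrane.tau_ms:.1f} ms, "
      f"Cm={membrane.capacitance:.0f} pF, Rs={membrane.series_resistance} MΩ, sag=5 %")

vc = synth.gen_vc_test_pulses(
    synth.MembraneParams(input_resistance=500, capacitance=50, series_resistance=10, noise_sd=2.0),
    seed=0,
)
rs, qc_pass = intrinsic.series_resistance_qc(vc)
print(f"series resistance: {rs:.1f} MΩ (QC {'pass' if qc_pass else 'FAIL'})")
print(f"capacitance (VC cell, truth 50 pF): {intrinsic.capacitance(vc):.1f} pF")

rin_sweeps = synth.gen_passive_step_traces(
    membrane, synth.StepProtocol([-60, -50, -40, -30, -20]), seed=1
)
print(f"input resistance: {intrinsic.input_resistance(rin_sweeps):.1f} MΩ")

tau_sweeps = synth.gen_passive_step_traces(
    membrane, synth.StepProtocol([-20.0] * 10, duration=0.1), seed=2
)
print(f"membrane time constant: {intrinsic.time_constant(tau_sweeps):.2f} ms")

sag_sweeps = synth.gen_passive_step_traces(
    membrane, synth.StepProtocol(list(np.arange(-120, -211, -30.0))), seed=3
)
per_step, sag_mean = intrinsic.sag_ratio(sag_sweeps)
print(f"sag: {sag_mean:.2f} % (per step: {np.round(per_step, 2)})")
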