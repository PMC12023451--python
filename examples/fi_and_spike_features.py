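"""F-I curve, rheobase, and first-spike features from synthetic spiking sweeps.

The coarse protocol (25 pA → 625 pA in 50 pA steps, 500 ms) yields the F-I
curve and its gain; a fine 5 pA protocol around threshold yields rheobase and
the first evoked spike, whose threshold is read off the phase plot as the
first point with dV/dt > 10 mV/ms.
"""

import numpy as np

from olfephys import intrinsic, synth

cell = synth.SpikingParams(rheobase_true=120.0, gain_true=0.1, threshold_true=-56.0)
print(f"ground truth: rheobase={cell.rheobase_true} pA, gain={cell.gain_true} Hz/pA, "
      f"threshold={cell.threshold_true} mV")

coarse = synth.gen_spiking_traces(cell, synth.StepProtocol(list(range(25, 626, 50))),
                                  noise_sd=0.1, seed=0)
fic = intrinsic.fi_curve(coarse)
print("step currents (pA):", fic.step_currents.astype(int))
print("spike counts /500 ms:", fic.spike_counts)
print(f"gain: {fic.gain:.3f} Hz/pA over points {fic.linear_region}")

fine = synth.gen_spiking_traces(cell, synth.StepProtocol(list(np.arange(100, 146, 5.0))),
                                noise_sd=0.1, seed=1)
rheo = intrinsic.rheobase(fine)
print(f"rheobase (5 pA grid): {rheo:.0f} pA")

first_spiking = next(t for t in fine if t.stimulus.amplitude >= rheo)
ap = intrinsic.ap_features(first_spiking)
print(f"AP threshold {ap.threshold:.1f} mV | amplitude {ap.amplitude:.1f} mV | "
      f"overshoot {ap.overshoot:.1f} mV | half-width {ap.half_width:.2f} ms | "
      f"fAHP {ap.fahp:.1f} mV | latency {ap.latency:.1f} ms")
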