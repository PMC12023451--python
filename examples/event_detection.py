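"""Detect spontaneous synaptic currents on a synthetic voltage-clamp trace.

A 60 s trace carries Poisson events (3 Hz, log-normal amplitudes ≥ 10 pA,
0.5 ms rise / 4 ms decay) on 2 pA Gaussian noise.  The detector smooths with
a 25-term binomial kernel, applies the 5 pA and 2.5×SD amplitude rules, fits
single-exponential decays on the raw trace, and rejects events with decay
< 1 ms or decay < rise.
"""

import numpy as np

from olfephys import events, synth

spec = synth.EventGenSpec(rate=3.0, duration=60.0, min_amplitude=10.0, baseline_noise_sd=2.0)
trace, truth = synth.gen_synaptic_trace(spec, seed=42)
print(f"ground truth: {len(truth)} events in {spec.duration:.0f} s ({spec.rate} Hz)")

detected = events.detect_events(trace)
accepted = [e for e in detected if e.accepted]
onsets = np.array([e.onset_time for e in accepted])
hits = sum(np.any(np.abs(onsets - t0) < 2e-3) for t0 in truth.onset_s)
print(f"accepted {len(accepted)} events; sensitivity {hits / len(truth):.3f} "
      f"(±2 ms onset matching)")

train = events.build_train(detected)
amps = [e.peak_amplitude for e in accepted]
taus = [e.decay_tau for e in accepted]
print(f"mean amplitude {np.mean(amps):.1f} pA | mean decay τ {np.mean(taus):.2f} ms "
      f"| mean frequency {train.mean_frequency:.2f} Hz (truth {spec.rate} Hz)")
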