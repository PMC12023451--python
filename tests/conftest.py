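import numpy as np
import pandas as pd
import pytest

from olfephys import synth
from olfephys.traces import VC_CURRENT, StepStimulus, Trace


@pytest.fixture
def vc_trace_factory():
    """Build voltage-clamp traces from rendered events plus Gaussian noise."""

    def make(onsets, amps, noise_sd=1.0, duration=2.0, rise=0.5e-3, decay=4e-3, seed=0):
        spec = synth.EventGenSpec(
            rate=0.0, rise_tau=rise, decay_tau=decay, duration=duration,
            baseline_noise_sd=noise_sd,
        )
        n = int(round(duration / spec.dt))
        rng = np.random.default_rng(seed)
        samples = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        samples = samples + synth.render_events(np.asarray(onsets, float), np.asarray(amps, float), spec, n)
        return Trace(samples=samples, dt=spec.dt, signal_kind=VC_CURRENT,
                     stimulus=StepStimulus(0.0, 0.0, duration)), spec

    return make


@pytest.fixture
def session_factory():
    """Build a session table from explicit per-trial (cs_label, lick-count) pairs."""

    def make(rows, intervals=4):
        recs = []
        for i, (lab, count) in enumerate(rows):
            licks = ";".join(["1"] * count + ["0"] * (intervals - count))
            recs.append({"trial_index": i, "block": i // 20, "cs_label": lab,
                         "interval_licks": licks, "valid_flag": True})
        return pd.DataFrame(recs)

    return make
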