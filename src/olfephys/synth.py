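"""Synthetic patch-clamp traces and go/no-go sessions with ground truth.

Every generator here produces data with the statistical structure the analysis
modules assume, plus the underlying ground truth, so each estimator can be
validated by parameter recovery:

* passive current-clamp / voltage-clamp step responses of a single-compartment
  RC membrane (optional phenomenological sag relaxation),
* integrate-and-fire-style spiking sweeps with a stylized action-potential
  template and known rheobase/gain/threshold,
* voltage-clamp baselines with Gaussian noise plus Poisson-timed biexponential
  synaptic events with configurable amplitude distributions,
* behavioral sessions with block-wise lick probabilities and balanced,
  randomized CS+/CS− assignment.

All generators are deterministic under a fixed seed.  Membrane ODEs are
integrated with fixed-step exponential Euler on the trace grid (exact for the
piecewise-constant commands used here); units follow the package conventions
(mV, pA, MΩ, pF, seconds internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .traces import CC_VOLTAGE, VC_CURRENT, StepStimulus, SweepSet, Trace

__all__ = [
    "MembraneParams",
    "SpikingParams",
    "EventGenSpec",
    "SessionSpec",
    "StepProtocol",
    "gen_passive_step_traces",
    "gen_vc_test_pulses",
    "gen_spiking_traces",
    "gen_synaptic_trace",
    "biexp_kernel",
    "render_events",
    "gen_session",
]

DEFAULT_DT = 5e-5  # 20 kHz


class InvalidProtocolError(ValueError):
    """Raised when a stimulation protocol is internally inconsistent."""


@dataclass(frozen=True)
class StepProtocol:
    """A family of rectangular steps sharing onset/duration/total length."""

    amplitudes: Sequence[float]
    onset: float = 0.1
    duration: float = 0.5
    total: float | None = None
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidProtocolError(f"dt must be positive, got {self.dt}")
        if self.duration <= 0 or self.onset < 0:
            raise InvalidProtocolError("step duration must be > 0 and onset >= 0")
        if self.total is None:
            object.__setattr__(self, "total", self.onset + self.duration + 0.1)
        if self.total < self.onset + self.duration:
            raise InvalidProtocolError("total sweep length shorter than the step")

    @property
    def n_samples(self) -> int:
        return int(round(self.total / self.dt))


@dataclass(frozen=True)
class MembraneParams:
    """Ground-truth passive membrane; τ_true = Rin·Cm."""

    resting_potential: float = -85.0  # mV (LJP-corrected frame)
    input_resistance: float = 133.0   # MΩ
    capacitance: float = 90.0         # pF
    series_resistance: float = 10.0   # MΩ
    sag_fraction: float = 0.0         # dimensionless, [0,1)
    sag_tau: float = 0.05             # s, slow relaxation time constant
    noise_sd: float = 0.0             # mV in CC, pA in VC

    def __post_init__(self) -> None:
        if self.input_resistance <= 0 or self.capacitance <= 0:
            raise ValueError("input_resistance and capacitance must be positive")
        if not 0 <= self.sag_fraction < 1:
            raise ValueError("sag_fraction must lie in [0,1)")

    @property
    def tau(self) -> float:
        """Membrane time constant in seconds (Rin·Cm)."""
        return self.input_resistance * self.capacitance * 1e-6

    @property
    def tau_ms(self) -> float:
        return self.tau * 1e3


@dataclass(frozen=True)
class SpikingParams:
    """Ground truth for the F-I / rheobase / AP-feature generators."""

    rheobase_true: float = 120.0    # pA
    gain_true: float = 0.1          # Hz per pA (slope of firing frequency vs current)
    threshold_true: float = -56.0   # mV
    ap_peak: float = 44.0           # mV
    fahp_depth: float = -8.0        # mV, post-spike minimum relative to threshold
    refractory: float = 5e-3        # s
    approach_rate: float = 2.5      # mV/ms subthreshold depolarization toward threshold
    upstroke_ms: float = 0.4
    downstroke_ms: float = 0.8

    def __post_init__(self) -> None:
        if self.rheobase_true <= 0 or self.gain_true <= 0:
            raise ValueError("rheobase_true and gain_true must be positive")
        if self.ap_peak <= self.threshold_true:
            raise ValueError("ap_peak must exceed threshold_true")


@dataclass(frozen=True)
class EventGenSpec:
    """Poisson-timed biexponential synaptic events on a noisy baseline."""

    rate: float = 3.0                       # Hz
    amplitude_dist: tuple = ("lognormal", {"median": 20.0, "sigma": 0.3})  # pA
    min_amplitude: float | None = None      # pA, truncate the draw from below
    rise_tau: float = 0.5e-3                # s
    decay_tau: float = 4e-3                 # s
    polarity: str = "inward"
    duration: float = 60.0                  # s
    baseline_noise_sd: float = 2.0          # pA
    baseline_mean: float = 0.0              # pA
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


@dataclass(frozen=True)
class SessionSpec:
    """Block-structured go/no-go session with per-block lick probabilities.

    ``p_lick_csplus``/``p_lick_csminus`` are scalars or per-block sequences.
    With ``lick_semantics='interval'`` they are the per-0.5 s-interval lick
    probability (a trial counts as a lick response only when every interval
    contains a lick); with ``'trial'`` they are the probability of an
    all-or-none lick response.
    """

    n_blocks: int = 10
    trials_per_block: int = 20
    p_lick_csplus: float | Sequence[float] = 1.0
    p_lick_csminus: float | Sequence[float] = 0.0
    lick_intervals: int = 4
    lick_semantics: str = "interval"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even (balanced CS+/CS−)")
        if self.n_blocks < 1 or self.lick_intervals < 1:
            raise ValueError("n_blocks and lick_intervals must be >= 1")
        if self.lick_semantics not in ("interval", "trial"):
            raise ValueError("lick_semantics must be 'interval' or 'trial'")
        for p in (*np.atleast_1d(self.p_lick_csplus), *np.atleast_1d(self.p_lick_csminus)):
            if not 0 <= p <= 1:
                raise ValueError("lick probabilities must lie in [0,1]")


# ---------------------------------------------------------------------------
# Passive membrane
# ---------------------------------------------------------------------------

def _rc_voltage_response(params: MembraneParams, stim_pa: np.ndarray, dt: float) -> np.ndarray:
    """Exponential-Euler integration of C·dV/dt = (E−V)/R + I, with optional sag.

    Sag is phenomenological: a multiplicative relaxation of the deflection
    toward (1−sag_fraction) of its instantaneous value, engaging only after
    the fast RC charge is essentially complete (10τ after a step change), with
    time constant ``sag_tau``.  This keeps the peak deflection at the full RC
    value so the deflection-based sag estimator recovers sag_fraction.
    """
    e, r, tau = params.resting_potential, params.input_resistance, params.tau
    n = len(stim_pa)
    decay = math.exp(-dt / tau)
    sag_decay = math.exp(-dt / params.sag_tau)
    v = np.empty(n)
    vm = e
    sag_r = 1.0
    engage_after = int(round(10 * tau / dt))
    last_change = -engage_after - 1
    prev_i = stim_pa[0] if n else 0.0
    for k in range(n):
        i_now = stim_pa[k]
        if i_now != prev_i:
            last_change = k
            prev_i = i_now
        # record the pre-update state: the sample at step onset is still at rest
        v[k] = e + (vm - e) * sag_r
        vinf = e + i_now * r * 1e-3  # pA·MΩ → mV with 1e-3
        vm = vinf + (vm - vinf) * decay
        target = 1.0 - params.sag_fraction if (i_now != 0 and k - last_change >= engage_after) else 1.0
        sag_r = target + (sag_r - target) * sag_decay
    return v


def gen_passive_step_traces(
    params: MembraneParams,
    protocol: StepProtocol,
    seed: int | None = 0,
    cell_id: str = "",
    group_label: str = "",
) -> SweepSet:
    """Current-clamp voltage responses to a set of current steps.

    Ground truth (the MembraneParams) is attached to every sweep under
    ``meta['truth']``.
    """
    rng = np.random.default_rng(seed)
    n = protocol.n_samples
    t = np.arange(n) * protocol.dt
    traces = []
    truth = {
        "resting_potential": params.resting_potential,
        "input_resistance": params.input_resistance,
        "capacitance": params.capacitance,
        "tau_ms": params.tau_ms,
        "sag_fraction": params.sag_fraction,
    }
    for amp in protocol.amplitudes:
        stim = np.where((t >= protocol.onset) & (t < protocol.onset + protocol.duration), amp, 0.0)
        v = _rc_voltage_response(params, stim, protocol.dt)
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, n)
        traces.append(
            Trace(
                samples=v,
                dt=protocol.dt,
                signal_kind=CC_VOLTAGE,
                stimulus=StepStimulus(amp, protocol.onset, protocol.duration),
                cell_id=cell_id,
                group_label=group_label,
                meta={"truth": truth},
            )
        )
    return SweepSet(traces, protocol="passive_cc_steps")


def gen_vc_test_pulses(
    params: MembraneParams,
    step_amplitudes_mv: Sequence[float] = (-1.0, -2.0, -3.0, -4.0, -5.0),
    onset: float = 0.05,
    duration: float = 0.1,
    total: float = 0.2,
    holding_mv: float = -60.0,
    dt: float = DEFAULT_DT,
    seed: int | None = 0,
    cell_id: str = "",
    group_label: str = "",
) -> SweepSet:
    """Voltage-clamp current responses to small test pulses (Rs/Cm protocol).

    The pipette series resistance Rs is in series with the membrane (Rm ∥ Cm);
    the clamp current is (Vcmd − Vm)/Rs, so the sample at step onset carries
    the instantaneous capacitive peak ΔV/Rs.
    """
    if dt <= 0 or duration <= 0:
        raise InvalidProtocolError("dt and duration must be positive")
    rng = np.random.default_rng(seed)
    e, rm, rs, cm = (
        params.resting_potential,
        params.input_resistance,
        params.series_resistance,
        params.capacitance,
    )
    n = int(round(total / dt))
    t = np.arange(n) * dt
    # access-plus-leak time constant for Vm under voltage clamp
    r_par = rs * rm / (rs + rm)
    tau = r_par * cm * 1e-6
    decay = math.exp(-dt / tau)
    traces = []
    truth = {"series_resistance": rs, "capacitance": cm, "input_resistance": rm}
    for amp in step_amplitudes_mv:
        vcmd = np.where((t >= onset) & (t < onset + duration), holding_mv + amp, holding_mv)
        i_out = np.empty(n)
        # steady state of Vm for a given command
        vm = (e / rm + holding_mv / rs) * r_par
        for k in range(n):
            i_out[k] = (vcmd[k] - vm) / rs * 1e3  # mV/MΩ → nA; ×1e3 → pA
            vinf = (e / rm + vcmd[k] / rs) * r_par
            vm = vinf + (vm - vinf) * decay
        if params.noise_sd > 0:
            i_out = i_out + rng.normal(0.0, params.noise_sd, n)
        traces.append(
            Trace(
                samples=i_out,
                dt=dt,
                signal_kind=VC_CURRENT,
                stimulus=StepStimulus(amp, onset, duration, holding=holding_mv),
                cell_id=cell_id,
                group_label=group_label,
                meta={"truth": truth},
            )
        )
    return SweepSet(traces, protocol="vc_test_pulses")


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------

def _spike_template_indices(p: SpikingParams, dt: float):
    n_up = max(2, int(round(p.upstroke_ms * 1e-3 / dt)))
    n_down = max(2, int(round(p.downstroke_ms * 1e-3 / dt)))
    up = p.threshold_true + (p.ap_peak - p.threshold_true) * (
        1 - np.cos(np.pi * np.arange(n_up + 1) / n_up)
    ) / 2
    fahp_min = p.threshold_true + p.fahp_depth
    down = p.ap_peak - (p.ap_peak - fahp_min) * (
        1 - np.cos(np.pi * np.arange(1, n_down + 1) / n_down)
    ) / 2
    return np.concatenate([up, down]), n_up


def gen_spiking_traces(
    params: SpikingParams,
    protocol: StepProtocol,
    membrane: MembraneParams | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    cell_id: str = "",
    group_label: str = "",
) -> SweepSet:
    """Current-clamp sweeps with stylized spiking and recorded true spike times.

    For a step of amplitude I ≥ rheobase_true and length T the number of
    spikes is round(gain_true·(I−rheobase_true)·T), at least 1 and clipped at
    the refractory limit, so firing frequency (spikes/T) recovers gain_true.
    Sub-rheobase steps depolarize toward (but never reach) threshold.
    The waveform guarantees dV/dt < 10 mV/ms until threshold_true and a fast
    upstroke after it, so the phase-plot threshold rule can be validated.
    """
    if protocol.duration < params.refractory:
        raise InvalidProtocolError("step shorter than the refractory period")
    membrane = membrane or MembraneParams()
    rng = np.random.default_rng(seed)
    dt = protocol.dt
    n = protocol.n_samples
    t = np.arange(n) * dt
    e = membrane.resting_potential
    thr = params.threshold_true
    template, n_up = _spike_template_indices(params, dt)
    fahp_min = thr + params.fahp_depth
    rate_per_s = params.approach_rate * 1e3  # mV/s
    traces = []
    for amp in protocol.amplitudes:
        i_on = int(round(protocol.onset / dt))
        i_off = int(round((protocol.onset + protocol.duration) / dt))
        v = np.full(n, e)
        true_spikes: list[float] = []
        if amp >= params.rheobase_true:
            n_spk = int(round(params.gain_true * (amp - params.rheobase_true) * protocol.duration))
            n_spk = max(1, n_spk)
            latency = (thr - e) / rate_per_s
            n_max = int((protocol.duration - latency - len(template) * dt) // params.refractory) + 1
            n_spk = min(n_spk, max(1, n_max))
            i_thr0 = i_on + int(round(latency / dt))
            if n_spk > 1:
                isi = (i_off - len(template) - i_thr0) // n_spk * dt
                isi = max(isi, params.refractory)
            else:
                isi = protocol.duration
            thr_idx = [i_thr0 + int(round(k * isi / dt)) for k in range(n_spk)]
            thr_idx = [i for i in thr_idx if i + len(template) < i_off]
            if not thr_idx:
                raise InvalidProtocolError(
                    "step too short to fit one action potential after the latency"
                )
            # subthreshold ramp to first threshold crossing
            ramp = e + rate_per_s * (t[i_on:thr_idx[0] + 1] - t[i_on])
            v[i_on:thr_idx[0] + 1] = np.minimum(ramp, thr)
            for j, i0 in enumerate(thr_idx):
                i1 = i0 + len(template)
                v[i0:i1] = template[: i1 - i0]
                true_spikes.append(t[i0 + n_up])
                nxt = thr_idx[j + 1] if j + 1 < len(thr_idx) else None
                if nxt is not None:
                    # exponential recovery from the fAHP minimum back to threshold
                    span = max(nxt - i1, 1)
                    tau_r = span * dt / 3.0
                    tt = (np.arange(span) + 1) * dt
                    v[i1:nxt] = thr + (fahp_min - thr) * np.exp(-tt[: nxt - i1] / tau_r)
                else:
                    span = i_off - i1
                    if span > 0:
                        tt = (np.arange(span) + 1) * dt
                        v[i1:i_off] = (thr - 5.0) + (fahp_min - (thr - 5.0)) * np.exp(-tt / 5e-3)
        else:
            # subthreshold: RC approach toward the Ohmic target, capped below threshold
            vinf = min(e + amp * membrane.input_resistance * 1e-3, thr - 2.0)
            seg = t[i_on:i_off] - t[i_on]
            v[i_on:i_off] = vinf + (e - vinf) * np.exp(-seg / membrane.tau)
        # relax back to rest after the step
        if i_off < n:
            v0 = v[i_off - 1] if i_off > 0 else e
            seg = t[i_off:] - t[i_off]
            v[i_off:] = e + (v0 - e) * np.exp(-seg / membrane.tau)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, n)
        traces.append(
            Trace(
                samples=v,
                dt=dt,
                signal_kind=CC_VOLTAGE,
                stimulus=StepStimulus(amp, protocol.onset, protocol.duration),
                cell_id=cell_id,
                group_label=group_label,
                meta={
                    "truth": {
                        "rheobase_true": params.rheobase_true,
                        "gain_true": params.gain_true,
                        "threshold_true": params.threshold_true,
                        "ap_peak": params.ap_peak,
                    },
                    "true_spike_times": np.asarray(true_spikes),
                },
            )
        )
    return SweepSet(traces, protocol="fi_steps")


# ---------------------------------------------------------------------------
# Synaptic events
# ---------------------------------------------------------------------------

def biexp_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak biexponential (difference of exponentials), t in seconds."""
    tp = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    norm = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
    out = np.where(t >= 0, (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / norm, 0.0)
    return out


def _draw_amplitudes(spec: EventGenSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    name, kw = spec.amplitude_dist
    def draw(k):
        if name == "lognormal":
            return kw["median"] * np.exp(rng.normal(0.0, kw["sigma"], k))
        if name == "normal":
            return rng.normal(kw["mean"], kw["sd"], k)
        if name == "constant":
            return np.full(k, float(kw["value"]))
        raise ValueError(f"unknown amplitude distribution {name!r}")
    amps = draw(size)
    if spec.min_amplitude is not None:
        for _ in range(1000):
            low = amps < spec.min_amplitude
            if not low.any():
                break
            amps[low] = draw(int(low.sum()))
        else:
            raise ValueError("amplitude truncation failed to converge; min_amplitude too high")
    return amps


def render_events(
    onsets_s: np.ndarray,
    amplitudes_pa: np.ndarray,
    spec: EventGenSpec,
    n_samples: int,
) -> np.ndarray:
    """Linear superposition of biexponential kernels on a zero baseline.

    This is the exact function used inside :func:`gen_synaptic_trace`, so
    trace − render_events(truth) equals the pure-noise baseline bit-for-bit.
    """
    out = np.zeros(n_samples)
    sign = -1.0 if spec.polarity == "inward" else 1.0
    span = int(round(10 * spec.decay_tau / spec.dt))
    for t0, a in zip(onsets_s, amplitudes_pa):
        i0 = int(math.ceil(t0 / spec.dt))
        i1 = min(i0 + span, n_samples)
        if i0 >= n_samples:
            continue
        tt = np.arange(i0, i1) * spec.dt - t0
        out[i0:i1] += sign * a * biexp_kernel(tt, spec.rise_tau, spec.decay_tau)
    return out


def gen_synaptic_trace(spec: EventGenSpec, seed: int = 0):
    """Voltage-clamp trace with Poisson synaptic events plus Gaussian noise.

    Returns (Trace, truth) with the truth table holding exact onset times
    (seconds, continuous) and peak amplitudes (pA, positive magnitudes).
    Noise and event streams are independent child generators of the seed, so
    the same seed with rate=0 yields the identical noise floor.
    """
    rng = np.random.default_rng(seed)
    noise_rng, event_rng = rng.spawn(2)
    n = int(round(spec.duration / spec.dt))
    noise = spec.baseline_mean + noise_rng.normal(0.0, spec.baseline_noise_sd, n)
    n_ev = event_rng.poisson(spec.rate * spec.duration)
    onsets = np.sort(event_rng.uniform(0.0, spec.duration, n_ev))
    amps = _draw_amplitudes(spec, event_rng, n_ev)
    samples = noise + render_events(onsets, amps, spec, n)
    truth = pd.DataFrame({"onset_s": onsets, "amplitude_pA": amps})
    trace = Trace(
        samples=samples,
        dt=spec.dt,
        signal_kind=VC_CURRENT,
        stimulus=StepStimulus(0.0, 0.0, spec.duration, holding=-60.0),
        meta={"event_spec": spec},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Behavioral sessions
# ---------------------------------------------------------------------------

def _per_block(p, n_blocks: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if arr.size == 1:
        return np.full(n_blocks, arr[0])
    if arr.size != n_blocks:
        raise ValueError(f"need 1 or {n_blocks} per-block probabilities, got {arr.size}")
    return arr


def gen_session(spec: SessionSpec) -> pd.DataFrame:
    """Simulate one go/no-go session as a trial table (see traces.SESSION_COLUMNS).

    CS+/CS− are presented an equal number of times in randomized order within
    each block; lick outcomes are drawn from the block's probabilities under
    the spec's lick semantics.
    """
    rng = np.random.default_rng(spec.seed)
    p_plus = _per_block(spec.p_lick_csplus, spec.n_blocks)
    p_minus = _per_block(spec.p_lick_csminus, spec.n_blocks)
    half = spec.trials_per_block // 2
    rows = []
    idx = 0
    for b in range(spec.n_blocks):
        labels = np.array(["CS+"] * half + ["CS-"] * half)
        rng.shuffle(labels)
        for lab in labels:
            p = p_plus[b] if lab == "CS+" else p_minus[b]
            if spec.lick_semantics == "interval":
                licks = (rng.random(spec.lick_intervals) < p).astype(int)
            else:
                licks = np.full(spec.lick_intervals, int(rng.random() < p))
            rows.append(
                {
                    "trial_index": idx,
                    "block": b,
                    "cs_label": lab,
                    "interval_licks": ";".join(map(str, licks)),
                    "valid_flag": True,
                }
            )
            idx += 1
    return pd.DataFrame(rows)
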