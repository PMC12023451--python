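"""Passive and active membrane-property extraction from step protocols.

Implements the standard whole-cell workflow:

* series-resistance estimate and QC from small voltage-clamp test pulses
  (discard when Rs > 30 MΩ or its within-experiment variation exceeds 30 %),
* membrane capacitance as the slope of the charge–voltage plot (Cm = Q/V),
  with an optional series-resistance correction (see :func:`capacitance`),
* input resistance from the steady-state V–I slope of 500 ms hyperpolarizing
  steps, membrane time constant from a single-exponential fit to the early
  response, sag percentage from peak vs steady-state deflection,
* spike detection (0 mV upward crossings, 1 ms refractory), F-I curve with
  gain from the linear region, rheobase, and first-spike AP features with the
  phase-plot threshold rule (first point where dV/dt > 10 mV/ms).

Windows that the protocol definitions leave open (steady state, baseline,
fit ranges) default to: last 10 % of the step for steady state, 50 ms
pre-stimulus mean for baseline, and a τ-fit window from 5 % of the step past
onset out to 3× an initial τ guess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .traces import CC_VOLTAGE, VC_CURRENT, StepStimulus, SweepSet, Trace

__all__ = [
    "PassiveProps",
    "FICurve",
    "APFeatures",
    "MeasurementError",
    "series_resistance_qc",
    "capacitance",
    "input_resistance",
    "time_constant",
    "sag_ratio",
    "detect_spikes",
    "fi_curve",
    "rheobase",
    "ap_features",
]

RS_QC_LIMIT_MOHM = 30.0
RS_QC_VARIATION = 0.30
DVDT_THRESHOLD = 10.0  # mV/ms, phase-plot threshold rule


class MeasurementError(RuntimeError):
    """Raised when a measurement cannot be made on the supplied sweeps."""


@dataclass(frozen=True)
class PassiveProps:
    resting_potential: float | None = None  # mV
    input_resistance: float | None = None   # MΩ
    time_constant: float | None = None      # ms
    capacitance: float | None = None        # pF
    sag_percent: float | None = None        # %
    series_resistance: float | None = None  # MΩ
    qc_pass: bool = True


@dataclass(frozen=True)
class FICurve:
    step_currents: np.ndarray   # pA
    spike_counts: np.ndarray    # per step
    frequencies: np.ndarray     # Hz = count / step duration
    gain: float | None          # Hz/pA over the linear region
    rheobase: float | None      # pA (grid resolution of this protocol)
    linear_region: tuple | None  # (first, last) indices used for the gain fit


@dataclass(frozen=True)
class APFeatures:
    threshold: float    # mV
    amplitude: float    # mV, threshold→peak
    overshoot: float    # mV, peak above 0
    half_width: float   # ms
    fahp: float         # mV, post-peak minimum − threshold (typically negative)
    latency: float      # ms, stimulus onset → threshold


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _step(trace: Trace) -> StepStimulus:
    if not isinstance(trace.stimulus, StepStimulus):
        raise MeasurementError("sweep lacks a step stimulus descriptor")
    return trace.stimulus


def _baseline_window(trace: Trace, pre_s: float = 0.05) -> slice:
    step = _step(trace)
    i_on = int(round(step.onset / trace.dt))
    i0 = max(0, i_on - int(round(pre_s / trace.dt)))
    if i_on <= i0:
        raise MeasurementError("no pre-stimulus baseline available")
    return slice(i0, i_on)


def _steady_window(trace: Trace, fraction: float = 0.1) -> slice:
    step = _step(trace)
    i_on = int(round(step.onset / trace.dt))
    i_off = int(round(step.offset / trace.dt))
    i0 = i_off - max(1, int(round(fraction * (i_off - i_on))))
    return slice(i0, i_off)


# ---------------------------------------------------------------------------
# voltage-clamp test pulses: Rs and Cm
# ---------------------------------------------------------------------------

def series_resistance_qc(sweeps: SweepSet) -> tuple[float, bool]:
    """Series resistance from the initial peak transient of VC test pulses.

    Per sweep, Rs = step amplitude / peak transient current; QC fails when
    any Rs exceeds 30 MΩ or the (max−min)/min variation across sweeps exceeds
    30 %.  Returns (mean Rs in MΩ, qc_pass).
    """
    if sweeps.signal_kind != VC_CURRENT:
        raise MeasurementError("series resistance needs voltage-clamp sweeps")
    rs_values = []
    for tr in sweeps:
        step = _step(tr)
        base = float(np.mean(tr.samples[_baseline_window(tr, 0.02)]))
        i_on = int(round(step.onset / tr.dt))
        i_end = min(tr.n, i_on + int(round(0.01 / tr.dt)))  # search 10 ms
        transient = tr.samples[i_on:i_end] - base
        peak = float(np.max(np.abs(transient)))
        if peak <= 0:
            raise MeasurementError("no detectable capacitive transient")
        rs_values.append(abs(step.amplitude) / peak * 1e3)  # mV/pA → GΩ; ×1e3 → MΩ
    rs = np.asarray(rs_values)
    variation = (rs.max() - rs.min()) / rs.min() if rs.min() > 0 else np.inf
    qc = bool(rs.max() <= RS_QC_LIMIT_MOHM and variation <= RS_QC_VARIATION)
    return float(rs.mean()), qc


def capacitance(sweeps: SweepSet, correct_rs: bool = True, integrate_s: float = 0.02) -> float:
    """Membrane capacitance (pF) from the charge–voltage slope of test pulses.

    Per step, the transient capacitive charge Q = ∫(I − I_ss)dt is integrated
    over ``integrate_s`` after onset; Cm is the least-squares slope of Q vs V.
    On a pipette-in-series circuit the raw Q/V slope underestimates Cm by
    (Rm/(Rm+Rs))²; with ``correct_rs`` (default) the factor is estimated from
    the same sweeps (peak → Rs, steady state → Rs+Rm) and divided out.
    """
    if sweeps.signal_kind != VC_CURRENT:
        raise MeasurementError("capacitance needs voltage-clamp sweeps")
    volts, charges, corr = [], [], []
    for tr in sweeps:
        step = _step(tr)
        base = float(np.mean(tr.samples[_baseline_window(tr, 0.02)]))
        i_on = int(round(step.onset / tr.dt))
        i_end = min(tr.n, i_on + int(round(integrate_s / tr.dt)))
        i_ss = float(np.mean(tr.samples[_steady_window(tr)]))
        q = float(np.trapezoid(tr.samples[i_on:i_end] - i_ss, dx=tr.dt))  # pA·s = pC
        volts.append(step.amplitude)
        charges.append(q)
        peak = float(np.max(np.abs(tr.samples[i_on:i_end] - base)))
        d_iss = i_ss - base
        if peak > 0 and abs(d_iss) > 0:
            rs = abs(step.amplitude) / peak * 1e3            # MΩ
            rtot = abs(step.amplitude) / abs(d_iss) * 1e3    # Rs + Rm, MΩ
            if rtot > rs:
                corr.append((rtot / (rtot - rs)) ** 2)
    v = np.asarray(volts)
    q = np.asarray(charges)
    if np.ptp(v) == 0:
        raise MeasurementError("need at least two distinct step amplitudes for the Q–V slope")
    slope = np.polyfit(v, q, 1)[0]  # pC/mV → nF; ×1e3 → pF
    cm = abs(slope) * 1e3
    if correct_rs and corr:
        cm *= float(np.mean(corr))
    return cm


# ---------------------------------------------------------------------------
# current-clamp passive properties
# ---------------------------------------------------------------------------

def input_resistance(sweeps: SweepSet) -> float:
    """Input resistance (MΩ) from the steady-state V–I slope of hyperpolarizing steps."""
    if sweeps.signal_kind != CC_VOLTAGE:
        raise MeasurementError("input resistance needs current-clamp sweeps")
    amps = sweeps.step_amplitudes()
    if np.any(amps >= 0):
        raise MeasurementError("input-resistance protocol must use hyperpolarizing steps")
    if len(np.unique(amps)) < 2:
        raise MeasurementError("need at least two current levels")
    deflections = []
    for tr in sweeps:
        base = float(np.mean(tr.samples[_baseline_window(tr)]))
        ss = float(np.mean(tr.samples[_steady_window(tr)]))
        deflections.append(ss - base)
    slope = np.polyfit(amps, deflections, 1)[0]  # mV/pA → GΩ
    return float(slope * 1e3)


def _single_exp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def time_constant(sweeps: SweepSet, fit_start_frac: float = 0.05) -> float:
    """Membrane time constant (ms) from a single-exponential fit.

    Sweeps (typically ten 100 ms, −20 pA pulses) are averaged onset-aligned;
    the fit runs from ``fit_start_frac`` of the step past onset (skipping the
    pipette transient) to 3× an initial τ guess taken from the 63 % crossing.
    """
    if sweeps.signal_kind != CC_VOLTAGE:
        raise MeasurementError("time constant needs current-clamp sweeps")
    ref = sweeps[0]
    step = _step(ref)
    avg = np.mean([tr.samples for tr in sweeps], axis=0)
    dt = sweeps.dt
    i_on = int(round(step.onset / dt))
    i_off = int(round(step.offset / dt))
    base = float(np.mean(avg[_baseline_window(ref)]))
    ss = float(np.mean(avg[_steady_window(ref)]))
    deflection = ss - base
    if abs(deflection) < 1e-9:
        raise MeasurementError("flat trace: no voltage deflection to fit")
    # initial τ guess: first crossing of 63.2 % of the deflection
    seg = avg[i_on:i_off] - base
    crossed = np.nonzero(np.abs(seg) >= 0.632 * abs(deflection))[0]
    tau0 = (crossed[0] if crossed.size else (i_off - i_on) // 3) * dt
    tau0 = max(tau0, 2 * dt)
    i0 = i_on + max(1, int(round(fit_start_frac * (i_off - i_on))))
    i1 = min(i_off, i_on + int(round(3 * tau0 / dt)))
    if i1 - i0 < 4:
        i1 = min(i_off, i0 + 4)
    t = (np.arange(i0, i1) - i_on) * dt
    y = avg[i0:i1]
    try:
        popt, _ = optimize.curve_fit(
            _single_exp, t, y, p0=(base - ss, tau0, ss), maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise MeasurementError(f"exponential fit did not converge: {exc}") from exc
    tau = abs(popt[1])
    if not np.isfinite(tau) or tau <= 0:
        raise MeasurementError("exponential fit returned a non-physical time constant")
    return float(tau * 1e3)


def sag_ratio(sweeps: SweepSet, method: str = "deflection") -> tuple[np.ndarray, float]:
    """Sag of hyperpolarizing steps; returns (per-step values, mean summary).

    ``method='deflection'`` (default): sag% = 100·(Vss − Vpeak)/(Vbase − Vpeak),
    the fraction of the peak deflection relaxed away at steady state.
    ``method='ratio'``: the literal peak/steady-state deflection ratio.
    """
    if sweeps.signal_kind != CC_VOLTAGE:
        raise MeasurementError("sag needs current-clamp sweeps")
    values = []
    for tr in sweeps:
        step = _step(tr)
        if step.amplitude >= 0:
            raise MeasurementError("sag protocol must use hyperpolarizing steps")
        base = float(np.mean(tr.samples[_baseline_window(tr)]))
        i_on = int(round(step.onset / tr.dt))
        i_off = int(round(step.offset / tr.dt))
        # peak on a ~1 ms boxcar-smoothed copy: the raw minimum of thousands of
        # noisy samples is biased by several noise SDs
        k = max(1, int(round(1e-3 / tr.dt)))
        kern = np.ones(k) / k
        sm = np.convolve(tr.samples[i_on:i_off], kern, mode="valid")
        vpeak = float(np.min(sm))
        vss = float(np.mean(tr.samples[_steady_window(tr)]))
        if vpeak >= base:
            raise MeasurementError("no hyperpolarizing deflection found")
        if method == "deflection":
            values.append(100.0 * (vss - vpeak) / (base - vpeak))
        elif method == "ratio":
            values.append((vpeak - base) / (vss - base))
        else:
            raise ValueError(f"unknown sag method {method!r}")
    per_step = np.asarray(values)
    return per_step, float(per_step.mean())


# ---------------------------------------------------------------------------
# spikes and F-I
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, crossing_mv: float = 0.0, refractory_s: float = 1e-3) -> np.ndarray:
    """Spike times (s) from upward 0 mV crossings with a 1 ms refractory rule.

    Each accepted crossing is timed at the subsequent voltage peak (the sample
    of maximum V before the trace falls back below the crossing level).
    """
    if trace.signal_kind != CC_VOLTAGE:
        raise MeasurementError("spike detection needs a current-clamp trace")
    v = trace.samples
    above = v >= crossing_mv
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times = []
    last = -np.inf
    for idx in crossings:
        t_cross = idx * trace.dt
        if t_cross - last < refractory_s:
            continue
        last = t_cross
        below = np.nonzero(v[idx:] < crossing_mv)[0]
        end = idx + (below[0] if below.size else len(v) - idx)
        peak_idx = idx + int(np.argmax(v[idx:end])) if end > idx else idx
        times.append(peak_idx * trace.dt)
    return np.asarray(times)


def fi_curve(sweeps: SweepSet, linear_points: tuple[int, ...] = (3, 4)) -> FICurve:
    """F-I curve with gain from the best linear fit over the first 3–4 nonzero points.

    Frequency per step is spikes / step duration (Hz).  The gain is the
    regression slope of frequency vs current over the first k nonzero-count
    points, with k chosen among ``linear_points`` by best R²; with fewer
    nonzero points than min(k) the available ones (≥2) are used.
    """
    amps = sweeps.step_amplitudes()
    order = np.argsort(amps)
    amps = amps[order]
    counts = []
    dur = _step(sweeps[0]).duration
    for i in order:
        tr = sweeps[int(i)]
        step = _step(tr)
        spikes = detect_spikes(tr)
        counts.append(int(np.sum((spikes >= step.onset) & (spikes < step.offset))))
    counts = np.asarray(counts)
    freqs = counts / dur
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        warnings.warn("no spikes at any step: gain and rheobase undefined")
        return FICurve(amps, counts, freqs, None, None, None)
    rheo = float(amps[nz[0]])
    gain = None
    region = None
    if nz.size >= 2:
        best_r2 = -np.inf
        ks = [k for k in linear_points if k <= nz.size] or [nz.size]
        for k in ks:
            pts = nz[:k]
            if pts.size < 2:
                continue
            slope, intercept = np.polyfit(amps[pts], freqs[pts], 1)
            resid = freqs[pts] - (slope * amps[pts] + intercept)
            tot = np.sum((freqs[pts] - freqs[pts].mean()) ** 2)
            r2 = 1 - np.sum(resid**2) / tot if tot > 0 else 1.0
            if r2 > best_r2:
                best_r2, gain, region = r2, float(slope), (int(pts[0]), int(pts[-1]))
    return FICurve(amps, counts, freqs, gain, rheo, region)


def rheobase(sweeps: SweepSet) -> float:
    """Smallest step current (pA) eliciting at least one spike (fine protocol)."""
    amps = sweeps.step_amplitudes()
    order = np.argsort(amps)
    spiking = []
    for i in order:
        tr = sweeps[int(i)]
        step = _step(tr)
        spikes = detect_spikes(tr)
        spiking.append(np.any((spikes >= step.onset) & (spikes < step.offset)))
    spiking = np.asarray(spiking)
    if not spiking.any():
        raise MeasurementError("no sweep elicited a spike; extend the protocol")
    if spiking.all():
        warnings.warn(
            "every sweep spiked: rheobase is at or below the smallest tested current"
        )
    return float(amps[order][np.argmax(spiking)])


# ---------------------------------------------------------------------------
# AP features
# ---------------------------------------------------------------------------

def dvdt(trace: Trace) -> np.ndarray:
    """Central-difference dV/dt in mV/ms on the raw grid (no smoothing)."""
    v = trace.samples
    out = np.empty_like(v)
    out[1:-1] = (v[2:] - v[:-2]) / (2 * trace.dt)
    out[0] = (v[1] - v[0]) / trace.dt
    out[-1] = (v[-1] - v[-2]) / trace.dt
    return out * 1e-3  # mV/s → mV/ms


def ap_features(trace: Trace, stimulus_onset: float | None = None) -> APFeatures:
    """First-spike AP features via the phase-plot threshold rule.

    Threshold is the voltage of the first point after stimulus onset where
    dV/dt exceeds 10 mV/ms; amplitude is threshold→peak, overshoot the peak
    above 0 mV, half-width the time between half-amplitude crossings (linear
    interpolation), fAHP the post-peak minimum minus threshold, latency the
    onset→threshold time.
    """
    if stimulus_onset is None:
        stimulus_onset = _step(trace).onset
    spikes = detect_spikes(trace)
    spikes = spikes[spikes >= stimulus_onset]
    if spikes.size == 0:
        raise MeasurementError("no spike in the analyzed sweep")
    v = trace.samples
    dt = trace.dt
    i_on = int(round(stimulus_onset / dt))
    i_peak0 = int(round(spikes[0] / dt))
    slope = dvdt(trace)
    fast = np.nonzero(slope[i_on : i_peak0 + 1] > DVDT_THRESHOLD)[0]
    if fast.size == 0:
        raise MeasurementError("dV/dt never exceeded 10 mV/ms before the first peak")
    i_thr = i_on + int(fast[0])
    threshold = float(v[i_thr])
    # refine the peak as the maximum between threshold and the next sub-threshold return
    i_end = i_peak0
    while i_end + 1 < len(v) and v[i_end + 1] >= threshold:
        i_end += 1
    i_peak = i_thr + int(np.argmax(v[i_thr : i_end + 1]))
    peak = float(v[i_peak])
    amplitude = peak - threshold
    overshoot = peak if peak > 0 else 0.0
    half_level = threshold + amplitude / 2
    # rising crossing (interpolated)
    rise_idx = np.nonzero(v[i_thr : i_peak + 1] >= half_level)[0]
    ir = i_thr + int(rise_idx[0])
    t_rise = (ir - 1 + (half_level - v[ir - 1]) / (v[ir] - v[ir - 1])) * dt if ir > i_thr else ir * dt
    # falling crossing
    fall_idx = np.nonzero(v[i_peak:] <= half_level)[0]
    if fall_idx.size == 0:
        raise MeasurementError("voltage never returned to half amplitude after the peak")
    if_ = i_peak + int(fall_idx[0])
    t_fall = (if_ - 1 + (half_level - v[if_ - 1]) / (v[if_] - v[if_ - 1])) * dt
    half_width = (t_fall - t_rise) * 1e3
    # fAHP: post-peak minimum within 20 ms or until the next spike
    i_next = int(round(spikes[1] / dt)) if spikes.size > 1 else len(v)
    i_win = min(len(v), i_peak + int(round(0.02 / dt)), i_next)
    fahp = float(np.min(v[i_peak:i_win])) - threshold
    latency = (i_thr - i_on) * dt * 1e3
    return APFeatures(
        threshold=threshold,
        amplitude=float(amplitude),
        overshoot=float(overshoot),
        half_width=float(half_width),
        fahp=fahp,
        latency=float(latency),
    )
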