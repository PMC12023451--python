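"""Spontaneous postsynaptic-current (sPSC) detection and characterization.

The detector follows the amplitude-plus-kinetics recipe used for sEPSC/sIPSC
analysis in whole-cell voltage clamp:

1. the current trace is smoothed with a 25-coefficient binomial kernel;
2. putative events are local deflections exceeding **both** a 5 pA threshold
   relative to the preceding baseline **and** 2.5× the baseline SD;
3. kinetics are measured on the raw trace: 10–90 % rise time by linear
   interpolation, decay time constant by a single-exponential least-squares
   fit from the peak to 90 % recovery (truncated at the next event onset);
4. events with decay < 1 ms or decay < rise time are discarded, each with a
   single recorded rejection reason.

"Preceding baseline" is a 10 ms window ending 1 ms before the event onset,
excluding samples belonging to earlier events (extended backwards when the
window is crowded).  Detection operates on a sign-rectified copy (inward
events negative in the recording, reported as positive magnitudes); the peak
is measured on the smoothed trace while decay fits use the raw samples, since
smoothing biases τ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, special

from .traces import VC_CURRENT, Trace

__all__ = [
    "SynapticEvent",
    "EventTrain",
    "binomial_kernel",
    "smooth",
    "detect_events",
    "build_train",
    "events_to_frame",
    "ACCEPTED",
    "REJECTED_AMPLITUDE",
    "REJECTED_DECAY_LT_1MS",
    "REJECTED_DECAY_LT_RISE",
    "REJECTED_FIT",
]

AMPLITUDE_THRESHOLD_PA = 5.0
SD_MULTIPLE = 2.5
MIN_DECAY_MS = 1.0

ACCEPTED = "accepted"
REJECTED_AMPLITUDE = "rejected_amplitude"
REJECTED_DECAY_LT_1MS = "rejected_decay_lt_1ms"
REJECTED_DECAY_LT_RISE = "rejected_decay_lt_rise"
REJECTED_FIT = "rejected_fit"


@dataclass(frozen=True)
class SynapticEvent:
    onset_time: float           # s
    peak_time: float            # s
    peak_amplitude: float       # pA, magnitude relative to local baseline
    rise_time_10_90: float | None  # ms
    decay_tau: float | None     # ms
    baseline_mean: float        # pA (signed as recorded)
    baseline_sd: float          # pA
    status: str

    @property
    def accepted(self) -> bool:
        return self.status == ACCEPTED


@dataclass(frozen=True)
class EventTrain:
    cell_id: str
    group_label: str
    events: tuple            # accepted events, ordered by onset
    inter_event_intervals: np.ndarray  # s
    mean_frequency: float | None       # Hz, 1/mean(IEI); None with <2 events


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def binomial_kernel(n_coeff: int = 25) -> np.ndarray:
    """Unit-sum symmetric binomial (Pascal-row) kernel of ``n_coeff`` terms."""
    k = np.arange(n_coeff)
    w = special.comb(n_coeff - 1, k)
    return w / w.sum()


def smooth(trace: Trace, n_coeff: int = 25) -> Trace:
    """Binomial smoothing; length preserved by symmetric edge reflection."""
    if trace.n < n_coeff:
        raise ValueError(f"trace of {trace.n} samples is shorter than the {n_coeff}-term kernel")
    w = binomial_kernel(n_coeff)
    half = n_coeff // 2
    padded = np.pad(trace.samples, half, mode="reflect")
    sm = np.convolve(padded, w, mode="valid")
    from dataclasses import replace

    return replace(trace, samples=sm)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _baseline_stats(
    y_raw: np.ndarray,
    onset: int,
    event_mask: np.ndarray,
    dt: float,
    window_s: float = 0.010,
    gap_s: float = 0.001,
    max_reach_s: float = 0.060,
) -> tuple[float, float]:
    """Mean/SD of the preceding baseline, excluding samples of earlier events."""
    n_want = max(4, int(round(window_s / dt)))
    b1 = max(0, onset - int(round(gap_s / dt)))
    b0 = max(0, b1 - n_want)
    sel = np.arange(b0, b1)
    sel = sel[~event_mask[sel]]
    reach = int(round(max_reach_s / dt))
    while sel.size < n_want and b0 > 0 and (onset - b0) < reach:
        b0 = max(0, b0 - n_want)
        sel = np.arange(b0, b1)
        sel = sel[~event_mask[sel]]
    if sel.size < 4:
        sel = np.arange(max(0, b1 - n_want), b1)  # crowded trace: fall back to raw window
    if sel.size == 0:
        sel = np.arange(0, min(n_want, len(y_raw)))  # event at the very start of the trace
    return float(np.mean(y_raw[sel])), float(np.std(y_raw[sel]))


def _fit_decay(
    y_raw: np.ndarray, start: int, end: int, base: float, dt: float
) -> float | None:
    """Single-exponential τ (ms) fitted to the raw decay phase; None on failure.

    ``start`` should sit at the 90 %-of-peak point: a biexponential's rounded
    top still carries the rising component, which inflates a from-peak fit.
    """
    if end - start < 4:
        return None
    t = (np.arange(start, end) - start) * dt
    y = y_raw[start:end]
    a0 = max(y[0] - base, 1e-6)
    # crude τ guess from the 1/e crossing of the smoothed-ish decay
    below = np.nonzero(y - base < a0 / math.e)[0]
    tau0 = (below[0] * dt) if below.size else (end - start) * dt / 3
    tau0 = max(tau0, dt)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t,
            y,
            p0=(a0, tau0, base),
            bounds=([0, dt / 10, -np.inf], [np.inf, 1.0, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    tau = popt[1]
    if not np.isfinite(tau) or tau <= 0:
        return None
    return float(tau * 1e3)


def detect_events(
    trace: Trace,
    polarity: str = "inward",
    amplitude_threshold: float = AMPLITUDE_THRESHOLD_PA,
    sd_multiple: float = SD_MULTIPLE,
    n_coeff: int = 25,
    candidate_floor: float = 3.0,
    max_decay_window_s: float = 0.05,
) -> list[SynapticEvent]:
    """Detect and characterize spontaneous PSCs on one voltage-clamp trace.

    Returns every enumerated candidate with its accept/reject status;
    amplitudes are positive magnitudes relative to the local baseline.
    ``candidate_floor`` (pA) bounds which local extrema are enumerated at all
    — it only needs to sit below the 5 pA acceptance threshold.
    """
    if trace.signal_kind != VC_CURRENT:
        raise ValueError("event detection expects a voltage-clamp current trace")
    sign = -1.0 if polarity == "inward" else 1.0
    smoothed = smooth(trace, n_coeff)
    y_sm = sign * smoothed.samples
    y_raw = sign * trace.samples
    dt = trace.dt
    n = len(y_sm)
    # global noise scale (robust, from the differentiated smoothed trace)
    sigma = float(np.median(np.abs(np.diff(y_sm))) / 0.6745 / math.sqrt(2)) or 1e-9
    prominence = max(candidate_floor, 4.0 * sigma)
    peaks, _ = signal.find_peaks(y_sm, prominence=prominence, distance=max(1, int(1e-3 / dt)))
    event_mask = np.zeros(n, dtype=bool)
    out: list[SynapticEvent] = []
    for p in peaks:
        # preliminary onset: start of the monotonic rise on the smoothed trace
        j = int(p)
        while j > 0 and y_sm[j - 1] < y_sm[j] and not event_mask[j - 1]:
            j -= 1
        base_mean, base_sd = _baseline_stats(y_raw, j, event_mask, dt)
        # refine onset: last baseline-mean crossing before the peak, searched over
        # a 10 ms pre-peak window (skipping samples that belong to prior events);
        # events riding a previous decay keep the local-minimum onset
        search = np.arange(max(0, p - int(round(10e-3 / dt))), p)
        search = search[~event_mask[search]]
        under = search[y_sm[search] <= base_mean] if search.size else search
        onset = int(under[-1]) if under.size else j
        amp = float(y_sm[p] - base_mean)
        t_on = onset * dt
        t_pk = p * dt
        if amp < amplitude_threshold or amp < sd_multiple * base_sd:
            out.append(
                SynapticEvent(t_on, t_pk, amp, None, None,
                              sign * base_mean, base_sd, REJECTED_AMPLITUDE)
            )
            continue
        # 10–90 % rise time: last 10 % crossing before the first 90 % crossing,
        # both linearly interpolated on the smoothed rising limb
        lo, hi = base_mean + 0.1 * amp, base_mean + 0.9 * amp
        rise_seg = y_sm[onset : p + 1]
        above90 = np.nonzero(rise_seg >= hi)[0]
        i90 = int(above90[0]) if above90.size else rise_seg.size - 1
        below10 = np.nonzero(rise_seg[: i90 + 1] <= lo)[0]
        i10 = int(below10[-1]) if below10.size else 0
        t10 = float(i10)
        if i10 + 1 < rise_seg.size and rise_seg[i10] <= lo <= rise_seg[i10 + 1]:
            t10 += (lo - rise_seg[i10]) / (rise_seg[i10 + 1] - rise_seg[i10])
        t90 = float(i90)
        if i90 > 0 and rise_seg[i90 - 1] <= hi <= rise_seg[i90]:
            t90 = i90 - 1 + (hi - rise_seg[i90 - 1]) / (rise_seg[i90] - rise_seg[i90 - 1])
        rise_ms = float(max(t90 - t10, 0.0) * dt * 1e3)
        # decay phase: from the 90 %-of-peak point down to 90 % recovery,
        # truncated at the next candidate onset or the cap
        rec_level = base_mean + 0.1 * amp
        after = y_sm[p:]
        below90 = np.nonzero(after <= base_mean + 0.9 * amp)[0]
        d90 = p + (int(below90[0]) if below90.size else 0)
        # push the start past ~3 rise times (capped at 3 ms) so the rising
        # exponential has died off
        dstart = max(d90, p + min(int(round(3 * rise_ms * 1e-3 / dt)), int(round(3e-3 / dt))))
        rec = np.nonzero(after <= rec_level)[0]
        end = p + (int(rec[0]) if rec.size else len(after))
        nxt = peaks[peaks > p]
        if nxt.size:
            # truncate at the start of the next candidate's rise
            k = int(nxt[0])
            while k > p and y_sm[k - 1] < y_sm[k]:
                k -= 1
            end = min(end, k)
        end = min(end, p + int(round(max_decay_window_s / dt)), n)
        event_mask[onset:end] = True
        if end - dstart < 6:  # truncated by the next event: fall back to the 90 % point
            dstart = d90
        tau_ms = _fit_decay(y_raw, int(dstart), int(end), base_mean, dt)
        if tau_ms is None:
            status = REJECTED_FIT
        elif tau_ms < MIN_DECAY_MS:
            status = REJECTED_DECAY_LT_1MS
        elif tau_ms < rise_ms:
            status = REJECTED_DECAY_LT_RISE
        else:
            status = ACCEPTED
        out.append(
            SynapticEvent(t_on, t_pk, amp, rise_ms, tau_ms,
                          sign * base_mean, base_sd, status)
        )
    return out


# ---------------------------------------------------------------------------
# trains and tables
# ---------------------------------------------------------------------------

def build_train(
    events: list[SynapticEvent], cell_id: str = "", group_label: str = ""
) -> EventTrain:
    """Accepted events → IEIs (consecutive onsets) and mean frequency = 1/mean(IEI)."""
    acc = tuple(sorted((e for e in events if e.accepted), key=lambda e: e.onset_time))
    onsets = np.array([e.onset_time for e in acc])
    ieis = np.diff(onsets)
    freq = float(1.0 / ieis.mean()) if ieis.size >= 1 else None
    return EventTrain(cell_id, group_label, acc, ieis, freq)


def events_to_frame(events: list[SynapticEvent], cell_id: str = "", group_label: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "group": group_label,
            "onset_s": [e.onset_time for e in events],
            "peak_s": [e.peak_time for e in events],
            "amplitude_pA": [e.peak_amplitude for e in events],
            "rise_ms": [e.rise_time_10_90 for e in events],
            "decay_ms": [e.decay_tau for e in events],
            "baseline_mean_pA": [e.baseline_mean for e in events],
            "baseline_sd_pA": [e.baseline_sd for e in events],
            "status": [e.status for e in events],
        }
    )
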