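# Methods

`olfephys` re-implements, as a tested library, a complete desk-scale analysis
chain for whole-cell patch-clamp recordings from cortical neurons and for
olfactory go/no-go behavior: intrinsic-excitability feature extraction,
spontaneous postsynaptic-current (sPSC) detection, per-cell-balanced
bootstrap statistics with a permutation Kolmogorov–Smirnov (KS) test, and
ROC/AUC session scoring.  Because no raw recordings are distributable, a
first-class synthetic-data module generates every input with known ground
truth, and all estimators are validated by parameter recovery.

## Synthetic data: what it emulates and what it does not

**Passive membrane.**  A single-compartment RC cell (resting potential E,
input resistance Rin in MΩ, capacitance Cm in pF; τ = Rin·Cm) integrated
with fixed-step exponential Euler on the 20 kHz trace grid.  For the
piecewise-constant step commands used here exponential Euler is exact, so
noise-free traces match the closed-form step response to round-off; traces
record the pre-update state, so the sample at step onset still sits at the
pre-step level.  Sag is phenomenological: the deflection relaxes
multiplicatively toward (1 − sag_fraction) of its instantaneous value with a
slow time constant (default 50 ms), engaging only 10·τ after a step change so
that the peak deflection carries the full RC value and the deflection-based
sag estimator recovers sag_fraction on long (≥500 ms) steps.  No h-current
kinetics, rebound, or voltage dependence are modeled — enough to validate
the sag estimator, not to study Ih.

**Voltage-clamp test pulses.**  The pipette series resistance Rs is in
series with the membrane (Rm ∥ Cm); the recorded current is
(V_cmd − V_m)/Rs, so the sample at step onset carries the instantaneous
capacitive peak ΔV/Rs exactly.

**Spiking.**  Integrate-and-fire-style: a step of amplitude I ≥ rheobase and
duration T produces round(gain·(I − rheobase)·T) spikes (at least one, and
clipped at the refractory limit), evenly spaced after a deterministic
latency set by a sub-threshold depolarization ramp (default 2.5 mV/ms).  The
action potential is a stylized template — half-cosine upstroke to the peak
(0.4 ms), half-cosine repolarization into the fast afterhyperpolarization
(0.8 ms), exponential recovery — built so that dV/dt stays below 10 mV/ms
until the true threshold and rises fast beyond it, which is exactly what the
phase-plot threshold rule needs to be testable.  Near-rheobase steps are
subject to count quantization: when the true rheobase falls just below a
sparse (50 pA) grid point, the forced minimum of one spike distorts the
first F-I point and gain recovery there can err by ~20 %; recovery tests use
configurations where the first nonzero point is informative.

**Synaptic events.**  Gaussian baseline noise (default 2 pA SD) plus a
Poisson train (default 3 Hz) of unit-peak biexponential kernels
(exp(−t/τ_decay) − exp(−t/τ_rise), defaults 4 ms / 0.5 ms) with log-normal
amplitudes (median 20 pA, σ = 0.3, optionally truncated from below).  Noise
and event streams are independent child generators of the seed, so the same
seed with rate = 0 reproduces the identical noise floor and superposition is
bit-exactly additive.  Not modeled: series-resistance filtering of events,
baseline drift, multiquantal shapes, or rate nonstationarity — so detector
performance numbers here bound what clean recordings allow, not what noisy
ones deliver.

**Sessions.**  Balanced CS+/CS− labels shuffled within each block (default
10 blocks × 20 trials); lick outcomes drawn per block.  Two semantics:
`interval` (per-0.5 s-interval lick probability; a lick response requires a
lick in every interval) and `trial` (all-or-none response).  No lick-latency
structure, satiation, or inter-trial dependence.

The recordings being emulated carry no published noise figures; the defaults
above (0.1–0.5 mV current-clamp, 2 pA voltage-clamp) were chosen once as
values a practitioner would call clean-but-realistic, and tests sweep them.

## Intrinsic-property estimators

* **Series resistance**: Rs = step / peak transient per test pulse; QC fails
  above 30 MΩ or when (max−min)/min across sweeps exceeds 30 %.
* **Capacitance**: per-step transient charge Q = ∫(I − I_ss)dt (trapezoidal,
  20 ms window); Cm is the least-squares slope of Q vs V.  On a
  pipette-in-series circuit the raw slope underestimates Cm by
  (Rm/(Rm+Rs))²; by default the factor is estimated from the same sweeps
  (peak → Rs, steady state → Rs+Rm) and divided out (`correct_rs=False`
  restores the plain Q/V slope).
* **Input resistance**: slope of steady-state deflection vs current over
  hyperpolarizing 500 ms steps.  Steady state = last 10 % of the step;
  baseline = 50 ms pre-stimulus mean (the protocol definitions leave both
  open).
* **Time constant**: single-exponential least squares on the onset-aligned
  sweep average, from 5 % of the step past onset (skipping the pipette
  transient) to 3× an initial τ guess from the 63 % crossing.
* **Sag**: default estimator 100·(V_ss − V_peak)/(V_base − V_peak).  The
  literal peak/steady-state deflection ratio is available
  (`method="ratio"`), but it is a number near 1 and cannot produce the
  few-percent values this quantity is conventionally reported at, so the
  deflection form is the default.  The peak is taken on a 1 ms boxcar-
  smoothed copy: the raw minimum of ~10⁴ noisy samples is biased by several
  noise SDs; the residual noise floor is ~0.2 mV, i.e. below 1 % sag on
  deep steps.
* **Spikes**: upward 0 mV crossings, 1 ms refractory, timed at the peak.
* **F-I and gain**: frequency = spikes / step duration (Hz); gain is the
  regression slope (Hz/pA) over the first k nonzero points, k ∈ {3,4} by
  best R².  Counting spikes per step rather than inverse-ISI is a choice;
  so is reporting Hz/pA consistently with frequency in Hz.
* **Rheobase**: smallest current with ≥1 spike on the fine (5 pA) protocol;
  accurate to the grid.
* **AP features**: threshold = voltage of the first point with
  dV/dt > 10 mV/ms (central differences on the raw 20 kHz grid, no
  pre-smoothing — the rule is threshold-sensitive to smoothing, and central
  differences amplify voltage noise ~14×/mV·ms⁻¹, so the rule assumes
  ≲0.15 mV RMS noise); amplitude threshold→peak; overshoot = peak above
  0 mV; half-width between interpolated half-amplitude crossings; fAHP =
  post-peak minimum (≤20 ms) − threshold; latency onset→threshold.

## Event detection

The trace is smoothed with a 25-coefficient binomial (Pascal-row) kernel
(unit sum, symmetric edge reflection).  Candidate local maxima (on the
sign-rectified smoothed trace) become events when their deflection from the
preceding baseline exceeds both 5 pA and 2.5× the baseline SD — the two
rules are conjunctive.  "Preceding baseline" is a 10 ms window ending 1 ms
before onset, excluding samples of earlier events and extending backwards
(≤60 ms) when crowded.  Onset is the last baseline-mean crossing within
10 ms before the peak (events riding a previous decay keep the local-minimum
onset).  The 10–90 % rise time is interpolated on the smoothed rising limb;
the decay τ is a single-exponential least-squares fit on the **raw** trace
(smoothing biases τ), from ~3 rise times past the peak (the biexponential's
rounded top still contains the rising component; fitting from the peak
inflates τ by ~4 %) down to 90 % recovery, truncated at the next candidate's
onset.  Events with τ < 1 ms or τ < rise time are rejected; every event
carries exactly one status.  Sub-threshold candidates are retained with
`rejected_amplitude` so rejection accounting is auditable.

## Balanced bootstrap and permutation KS

Each bootstrap iteration draws n_per_cell values with replacement from every
cell (default: the rounded mean event count across cells) and pools them;
the cumulative probability distribution (CPD) is the pointwise mean of the
per-iteration empirical CDFs on a 512-point grid spanning the pooled range.
This weights every cell equally regardless of how many events it
contributed.

The group test statistic is the mean two-sample KS D over balanced-resample
iterations (reported as mean ± SD).  The null distribution repeats the
*identical* computation after shuffling; the default shuffling unit is the
event (pool all values, reassign to pseudo-cells preserving per-cell
counts), with cell-label shuffling available as a conservative option for
within-cell correlation.  Matching the null statistic to the observed one is
what makes the permutation test exactly valid under exchangeability — a null
built from single-resample D values would have extra Monte-Carlo spread and
the test would lose calibration.  The p-value uses the (b+1)/(m+1)
correction by default (`plain` proportion available).  The D computation is
tie-aware (ECDF gaps evaluated only after all tied points are counted),
vectorized across iterations, and matches brute-force ECDF enumeration
exactly on small samples.

Because the null must re-run the full mean-D computation per permutation,
desk-scale defaults are 200 iterations × 199 permutations; both are plain
arguments for larger runs.

## Behavior

Hits (lick to CS+) and correct rejections (no lick to CS−) are correct; the
lick-response criterion is a lick in every 0.5 s interval.  Learning
criterion: ≥85 % correct in two blocks of the session (default), with a
three-consecutive-blocks variant selectable — both conventions circulate and
neither is presumed.  The ROC decision variable is the count of
lick-positive intervals (0–4), the minimal graded score the lick-interval
protocol supports; sweeping its threshold yields the curve and the
trapezoidal AUC, which equals the normalized Mann–Whitney U with half-credit
ties.  All-or-none responders reduce to the single-point trapezoid
AUC = (TPR + 1 − FPR)/2.  AUC standard errors use the Hanley–McNeil closed
form with Q1 = A/(2−A), Q2 = 2A²/(1+A); group comparisons use the
independent-samples z (different animals, zero correlation term; the
correlated variant is deliberately not implemented).  Windows ("first60",
"last60") are taken over valid trials in presentation order.

## Problem sizes and tolerances in the test suite

Recovery tests run at the protocols' native scales (500 ms steps at 20 kHz;
5 pA rheobase grids).  Detection performance uses 3 × 40 s traces at 3 Hz,
amplitudes ≥ 10 pA on 2 pA noise (sensitivity ≥ 0.95, FDR ≤ 0.05, ±2 ms
onset matching).  Statistical calibration uses 1000 exchangeable-null runs
at 10 iterations × 39 permutations — small by design; the permutation test's
validity is scale-free, so calibration at small counts certifies the
procedure, with larger counts only tightening p-value granularity.  CPD
accuracy is checked against the analytic normal CDF with 10 cells × 1000
values (sup distance < 0.02).

## Known limitations

* The phase-plot threshold rule degrades above ~0.15 mV RMS voltage noise;
  no pre-smoothing is offered by design.
* The Q/V capacitance correction assumes the single-compartment Rs–Rm–Cm
  circuit; on real dendritic cells it removes only the access-resistance
  part of the bias.
* The event detector's baseline tracker handles events riding one previous
  decay; dense compound bursts (>3 overlapping events within a decay) will
  merge or mis-baseline candidates.
* ABF/NWB readers are declared adapters behind the same loader contract but
  require optional third-party packages; the native formats are HDF5 and
  CSV+JSON.
* Mixed-effects/Bonferroni group statistics are out of scope: the pipeline
  exports per-block and per-cell tables for external statistics packages.
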