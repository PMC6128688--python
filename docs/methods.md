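# Methods

## Gating model

Channels follow a linear three-state continuous-time Markov scheme

```
C  ⇌  O  →  I          (with a slow I → O recovery)
```

with rates in 1/ms. The closed-to-open rate is multiplied by a Boltzmann
activation factor `f(s) = 1/(1 + exp((s_half − s)/slope))` of the mechanical
stimulus `s` (probe depth in µm or pressure in mmHg). This is the simplest
mechanism consistent with the observed phenomenology — monotone
stimulus-dependent activation, single-current-level openings, and
inactivation during a maintained step; it makes no claim about the true
conformational landscape of Piezo1. One scheme serves both presets; only the
rate constants differ.

No quantitative stimulus–response (depth → current) relation is available
for these cells, so the Boltzmann midpoint is an abstract stimulus
coordinate: `s_half = 4`, `slope = 0.8` (stimulus units), making the
standard protocols (8 µm poke, 60 mmHg pressure) saturating. Pressure steps
ramp at 8.3 mmHg/ms, the maximum slew rate of a high-speed pressure clamp;
poke steps are ideal rectangles. Poke mechanics are not modeled physically.

### Presets

| preset | k(C→O) max | k(O→C) | k(O→I) | k(I→O) | behaviour |
|---|---|---|---|---|---|
| `canonical_fast` | 0.8 | 0.08 | 0.08 | 0.0005 | decay τ ≈ 13 ms, slow fraction ≈ 0.02 |
| `mes_slow` | 0.12 | 0.08 | 0.012 | 0.0005 | slow fraction ≈ 0.67 |

Both presets use γ = 24.7 pS and E_rev = 0 mV, the measured unitary
conductance and reversal potential of the mES mechanosensitive channel in
physiological solutions. `canonical_fast` was chosen so the open-probability
decay constant sits well below the canonical 20-ms bound. `mes_slow` was
calibrated once, using the master-equation solution plus a pilot batch of
rendered 500-channel sweeps, so that the *measured* whole-cell slow fraction
averages ≈ 0.67; the master-equation value is slightly higher (≈ 0.70)
because the measured peak of a stochastic, noisy trace systematically
overshoots the ensemble-mean peak, which depresses the measured ratio. The
slower opening rate of `mes_slow` (0.12 vs 0.8) keeps single-channel dwell
times near 10 ms, long enough to be resolved through a 1 kHz filter, and
yields an open probability ≈ 0.6 at saturation so that multi-channel patches
populate all current levels.

### Simulation and rendering

Because the `n_channels` channels are independent and identical, the
population is itself a Markov chain on aggregated state counts, and a
Gillespie loop with propensities `count_i · q_ij` is *exact* — no
per-channel bookkeeping and no time-step error. Stimulus time dependence is
handled piecewise-constant (pressure ramps are discretized at ≤ 0.25 ms).
The deterministic master equation, solved by matrix exponentials over the
same segments, is the oracle used in tests: replicate-averaged open counts
must match `N·Po(t)` within binomial standard errors.

Rendering converts the open count to current via `i = γ(V − E_rev)`
(24.7 pS at −80 mV: −1.976 pA per channel), adds white Gaussian noise
*before* the filter (as amplifier headstage noise enters the analog chain),
and filters with a digital 4-pole Bessel low-pass, −3 dB at the cutoff
(`scipy.signal.bessel(..., norm="mag")`), matching a patch-clamp amplifier's
built-in filter; defaults are 1 kHz cutoff and 20 kHz digitization. The
filter state is initialized at the first sample's level to avoid a spurious
start-up transient. Whole-cell defaults use 5 pA pre-filter noise (≈1.7 pA
after filtering), single-channel 0.3 pA (≈0.1 pA after filtering).

Every simulation call takes one seeded `numpy` generator; seeds are spawned
per sweep from the set-level seed via `SeedSequence` (kept below 2³¹) and
recorded in the sweep annotations, so identical inputs reproduce
bit-identical traces.

## Whole-cell metrics

- Baseline: mean current over a pre-stimulus window (≥ 10 samples).
- Peak: max |I − baseline| inside the stimulus window, with a 2-ms blanking
  window after the step edge to exclude capacitive transients (shown but
  not quantified in typical recordings; configurable).
- Slow current: |I − baseline| averaged over a 5-ms window centred at
  onset + 75 ms. Only the time point is standard; the windowed average is
  this package's choice for noise robustness and is configurable.
- Slow fraction = slow/peak. Values > 1 (current still growing at 75 ms)
  are reported and flagged, never clipped. Fast component = peak − slow;
  negative values (possible under noise) are flagged, not clipped.
- Inactivation fits: `A·e^(−t/τ) + C` (or two exponentials) from the peak to
  the stimulus end via `scipy.optimize.curve_fit`, with a quality flag that
  fails fits with R² < 0.8 or a time constant at the bounds — real decays
  with variable initial steps often cannot be fit reliably, and the flag
  records that instead of returning a misleading τ.
- Stage summaries report mean ± SEM (SEM chosen where the error type is
  ambiguous in conventional figures; SD available from the raw values), and
  pooled across differentiations without batch terms. Group comparisons of
  slow fractions use the two-tailed Welch t-test.

Currents are stored signed (inward negative); all reported metrics are
magnitudes over baseline.

## Single-channel analysis

Level detection fits a Gaussian mixture to the raw sample values of the
analysis segment (the histogram is descriptive); the model order (1 to
`max_levels`) is chosen by BIC. All components share a single variance:
recording noise is level-independent, and with free per-component variances
the criterion absorbs the sparse filter-smeared transition samples into one
artificially broad component and under-counts the levels. Levels are
ordered from the component nearest the baseline (closed) outward.

The unitary current is the mean adjacent-level spacing weighted by the
summed occupancy of each pair — robust in multi-channel patches where outer
levels are sparse. Conductance comes from ordinary least squares of unitary
current on command voltage (command voltages carry negligible error, so
errors-in-variables machinery is unwarranted); E_rev is a free parameter of
the line, not pinned to zero. Ensemble averages are baseline-subtracted
pointwise means of aligned sweeps and reconstruct `i·Po(t)`. Idealization
uses half-amplitude thresholds with 0.25-spacing hysteresis and warns when
levels overlap (spacing < 2 sd); no hidden-Markov idealization or
missed-event correction is attempted.

## Selectivity biophysics

Nernst, GHK voltage (monovalent ions), Henderson LJP, and bi-ionic
permeability ratios (monovalent, and Fatt–Ginsborg for external Ca²⁺ vs
internal K⁺) are implemented in closed form; concentrations are used as
activities, and buffers (Hepes, glucose, EGTA at working pH) are treated as
electro-neutral and excluded from junction sums. The LJP sign convention is
bath relative to pipette, and corrected E_rev = measured − LJP; the
convention is fixed by requiring that it reproduce the signs of the four
published estimates for these solutions.

The bundled mobility table uses classical limiting equivalent conductivities
(S·cm²/equiv, 25 °C): K⁺ 73.50, Na⁺ 50.11, Cl⁻ 76.35, Ca²⁺ 59.50 (per
equivalent), Mg²⁺ 53.06, gluconate⁻ 24.4. NMDG⁺ has no canonical table
value; the junction-potential literature uses relative mobilities between
≈ 0.32 and 0.40 of Cl⁻, and the bundled 28.3 (0.37 × Cl⁻) sits in that range
and reproduces the published 9.3 mV NMDG-Cl/KCl estimate. Only mobility
*ratios* matter in the Henderson equation, so the absolute scale is
irrelevant.

**Temperature.** Patch-clamp recordings are made at room temperature, which
is conventionally 20–25 °C and is rarely reported precisely. The default
here is 295.15 K (22 °C): with the bundled table it reproduces all four
published LJP estimates within 0.45 mV (NaCl 4.32, NaGluconate −6.78,
CaCl₂ 8.63, NMDG-Cl 9.20 mV vs 4.3 / −6.7 / 8.2 / 9.3), whereas at 25 °C the
CaCl₂ estimate drifts to 8.72 mV. Every function takes `temperature`
explicitly, and all potentials scale exactly linearly with T through RT/F.

Reversal potentials are estimated by linear interpolation between the two
I–V points bracketing the zero crossing (no smoothing or global fitting).
The permeability-sequence builder groups ions whose ratios agree within a
10 % relative tolerance and flags chained ties.

## Cohort statistics

Growth series are normalized to each line's own day-0 count (an alternative
day-1 anchor is exposed as an option, since both conventions circulate for
such tables). Growth constants come from nonlinear least squares of
`N0·e^(kt)` in natural scale — log-linear regression weights early, small
counts too heavily and behaves differently under multiplicative noise; a
log-linear seed initializes the optimizer. "Two-sample unequal variance"
t-tests are Welch tests with Welch–Satterthwaite degrees of freedom; the
one-tailed direction is a required argument, never defaulted. Dead-cell
subtraction is assumed done upstream (inputs are live-cell counts).

The worked mitotic-fraction example bundles the per-line percent-PH3⁺
values for 2 WT and 3 knockout mES lines; group means (3.224 / 3.424) and
the one-tailed Welch p (0.292) are recomputed from those per-line inputs.
The analogous printed group-level growth-constant summary rows in the
original tabulation are internally inconsistent with their own per-line
constants (the group labels appear transposed); this package always computes
group statistics from per-line values and does not attempt to reproduce
transposed summary rows.

## What the synthetic data can and cannot show

The simulator emulates: Boltzmann-saturating activation, single- or
multi-exponential-like inactivation, discrete unitary currents of 24.7 pS,
Gaussian recording noise shaped by a 1 kHz Bessel filter, and 20 kHz
sampling. It does **not** emulate: capacitive transients, seal drift and
rundown, series-resistance error, heterogeneous channel populations,
cell-to-cell variability beyond stochastic gating (real cohorts show
peak currents from 0 to > 2000 pA), or any mechanical coupling between
probe depth and membrane tension. Passing recovery tests therefore
demonstrates that the *analysis* is correct and unbiased under the stated
noise model — not that it is robust to every artifact of real recordings.
Published cohort statistics that depend on unpublished per-cell recordings
(stage-wise current amplitudes, knockout abolition) are deliberately not
reproduced; the simulator-based checks are consistency checks against the
preset ground truth and are labelled as such.

## Problem sizes and numerical choices

Test and reproduction runs use desk-scale sizes chosen to keep statistical
power adequate: 500 channels per whole-cell sweep (peak ≈ 550–700 pA,
matching the scale of real mES recordings), cohorts of 30 cells, 15 sweeps
per voltage × 5 voltages for conductance recovery, 200 replicates for
Gillespie-vs-master-equation checks, and 500 simulated null datasets for
t-test calibration. Stochastic assertions use 3-standard-error bounds
derived from binomial/CLT arguments at those sizes. Master-equation
propagators are cached per (stimulus, Δt); probabilities are clipped to
[0, 1] against round-off. Degenerate inputs (zero peak, empty groups,
zero day-0 counts, missing mobilities, non-bracketing I–V points) raise
errors naming the problem rather than guessing.
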