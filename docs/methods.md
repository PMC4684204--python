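# Methods

## Model and integrator

The core model is a four-population Wilson–Cowan-type firing-rate system
with discrete transmission delays (see README for the equations). All time
is handled internally in milliseconds; frequencies are reported in Hz.
Fixed physiological constants: `T_SG = T_GS = 6 ms`, `T_GG = 4 ms`,
`T_CS = 5.5 ms` (hyperdirect cortex→STN), `T_SC = 21.5 ms` (the collapsed
STN→GPi→thalamus→cortex path), `τ_S = 12.8 ms`, `τ_G = 20 ms`, STN sigmoid
(M, B) = (300, 10) spk/s, GPe sigmoid (400, 20) spk/s. The cortical
parameters (`T_CC`, `τ_E`, `τ_I`, `B_E`, `B_I`, `M_E`, `M_I`) and all
connection weights are free parameters of the fit.

Integration uses the method of steps with classical RK4 at a fixed step
(default 0.05 ms) and cubic Hermite interpolation of the stored solution
(values and derivatives on the step grid) for delayed lookups, so delays
need not be commensurate with the step; the only structural requirement is
`step ≤ min(delay)`. The default history is constant at each population's
baseline with a +1 spk/s perturbation on S to break symmetry; linear runs
start at the system's fixed point plus the same kick, which keeps the
envelope fit free of drift contamination. The first 1 s of each run is
flagged as transient and excluded from metrics; the default total duration
is 5 s.

Convergence: step halving shows clean second-order behaviour (successive
difference ratios 3.91 → 3.96 → 3.98). The derivative jump of the constant
history at t = 0 propagates along the delay lattice, which caps the
observable global order at 2 even though the smooth-region scheme is
higher order; this is inherent to fixed-step DDE integration without
breaking-point tracking and is ample for the ≤ 20 Hz dynamics studied
here. On a near-delay-free parameterization the trajectories agree with a
stiff ODE solution of the same right-hand side to better than
10⁻³ spk/s.

## The printed parameter sets

The two published best-fit parameter lists are exposed verbatim as presets
`fig3A` and `fig3C`. As printed, the lists are mutually inconsistent with
their model variants: the resonance list carries `w_SC = 8.93` although
that parameter is clamped to zero during a resonance fit, while the
feedback list carries `w_SC = 0.00` although its own blockade panel shows
the long-loop cut stopping the oscillation. Simulation resolves the
ambiguity: the `fig3C` list run with `w_SC = 0` oscillates at 14.93 Hz
(matching the published 15 Hz resonance frequency), and the `fig3A` list
run with `w_SC = 8.93` oscillates at 11.98 Hz (matching the published
12 Hz feedback frequency), whereas no other pairing reproduces either
number. The two lists were therefore evidently interchanged in print, and
the package treats the `fig3C` values (with `w_SC = 0`) as the resonance
best fit and the `fig3A` values with `w_SC = 8.93` (preset
`fig3A-feedback`) as the feedback best fit. Presets for every reading
(`fig3A`, `fig3A-feedback`, `fig3C`, `fig3C-swapped`) are provided.

Two quantitative residuals remain under every reading and are reported as
measured: the intact resonance simulation's mean rates are 82.7 (STN) and
77.6 (GPe) spk/s against fitted targets of 65 and 100, and the STN trace
keeps oscillating after the GPe→STN cut (the cortical oscillator continues
to drive it through `w_CS`; structurally unavoidable whenever the cortex
is autonomously rhythmic). The blockade checks therefore evaluate each cut
on the population recorded in the corresponding experiment (STN→GPe cut →
GPe; GPe→STN and cortex→STN cuts → STN; striatal cut → GPe).

## Lesion protocol

`apply_lesion` zeroes a single connection (or the striatal drive). The
cortex→STN cut can be *compensated*: a constant input
`C_adj = w_CS · mean(E)` — the original weight times the mean post-transient
cortical rate of the intact run — is injected into the STN activation
argument, so the cut removes the rhythm without removing tonic excitation.
The averaging window for `mean(E)` is the post-transient portion of the
intact simulation.

## Metrics and cost

Per-population minimum and maximum rates are medians of per-cycle extrema
(robust to residual transients); the mean is the time average; amplitude
is peak-to-trough (max − min). A trace counts as oscillating when its
amplitude exceeds ε = 1 spk/s. The dominant frequency is the reciprocal of
the median inter-peak interval of the STN trace, with peak spacing guided
by the spectral period; the spectral cross-estimate is the power-weighted
centroid of the periodogram line within ±3 Hz of its maximum, which is
stable under the line broadening that phase noise produces. The two
estimators agree within 0.5 Hz on noisy sinusoids up to noise strength
N = 4. Where a waveform is period-doubled (as near delay-scan branch
transitions) the spectral estimate defines the dominant frequency.

The fitting cost sums squared min/mean/max errors for STN and GPe against
the constraint table (5/65/125 and 45/100/155 spk/s), a frequency error
against 14 Hz weighted by k = 20, squared post-cut amplitudes for the
three oscillation-abolishing cuts, and a striatal-cut amplitude term. The
striatal term is printed ambiguously in the source material; both the
symmetric squared difference (default) and the one-sided
`max(0, amp_data − amp_model)²` reading are implemented (`str_form`).
Out-of-bounds parameters add 10⁶ each plus their squared excursion;
integration or period-detection failure assigns the candidate the penalty
value.

Simulated annealing perturbs one coordinate at a time with a Gaussian
whose scale shrinks with an exponentially cooled temperature (initial
temperature from the cost spread of 50 random neighbours; 2000 iterations
by default); the incumbent best is always retained, multi-start jitters
the start by 10% of each range, and an optional bounded Powell polish
refines the best point. On a shifted 15-dimensional quadratic the
optimizer recovers the minimizer to within 1% of each range. The default
search box follows the published ranges except for the constant drives C
and Str, whose stated range (0–30) excludes the published fitted values
(172.18, 277.94; 40.51); the box used is 0–300. Baseline rates are bounded
below at 0.5 spk/s because the sigmoid is undefined at B = 0.

## Synthetic spike trains

The rate process is `fr(t) = A sin θ + b` with `dθ = 2πf dt + N dw`,
`dw ~ Normal(0, dt)` with dt in seconds inside the phase increment; spike
sampling is one Bernoulli draw per 1 ms bin with probability `fr(t)·dt`
(40 s trains by default). The units of N are not externally anchored; the
published values (3.3 STN, 3.9 GPe) are used as-is and validated through
self-recovery rather than external matching. Auto-correlograms bin all
pairwise spike-time differences (2 ms bins, ±200 ms, self-pairs excluded,
symmetry exact by construction). Correlogram matching minimizes the mean
squared difference between lightly smoothed (5-bin moving average)
absolute-count profiles over a coarse (A, b, f, N) grid followed by
Nelder–Mead refinement, with common random numbers so the objective is
deterministic per seed. Absolute counts are essential: the correlogram
level scales with the squared rate and is the only statistic identifying
b (min-max normalization loses it). Targets without a concentrated
spectral peak (peak-power fraction < 0.35) are fitted baseline-only and
flagged frequency-unidentifiable. Self-recovery on the GPe process
recovers f within 0.5 Hz and b within 10 spk/s averaged over five seeds.
The derived constraint rows are exact: (b−A, b, b+A) = (5, 65, 125) for
STN and (45, 100, 155) for GPe.

## Linear stability analysis

With identity activations the model is linear and each coupling triple
(tied `w_SG = w_GS`, `w_CC`, tied `w_CS = w_SC`; base delays/time
constants from the feedback best fit, constant drives zeroed since they
only shift the fixed point) is classified by the sign of the exponential
growth rate of the STN envelope: log of the Hilbert-envelope magnitude
regressed on time over the final 60% of the window (10% edge trim);
|rate| < 10⁻⁶/ms is flagged as boundary-proximal. Strongly unstable runs
are truncated at |y| = 10⁹ and fitted on the available window. The
stability surface bisects the tied long-loop weight per (w_SG, w_CC) cell
(tolerance 10⁻³), recording the onset frequency just above the boundary
(zero-crossing based, robust to envelope growth). Classifications agree
with the sign of the rightmost characteristic root on random triples.

The critical tied long-loop weight with the other loops at zero measures
1.284, confirmed analytically by the two-population phase/gain condition
(ω ≈ 0.066 rad/ms, i.e. ~10.5 Hz onset). The published description places
this threshold "around 1.6", which matches the critical loop *product*
`w_CS·w_SC = 1.65` rather than the tied weight; the package reports the
tied weight as defined. The cortical-loop and STN–GPe-loop thresholds
(~1.8 and ~1.9) match their published values (~2). The GPe
self-inhibition `w_GG` acts as a stabilizing leak throughout its fitted
range (≤ 0.9); at much larger gain its 4 ms delay itself adds
destabilizing phase lag, so the leak characterization is regime-bound.

The delay scan multiplies `T_CS` and `T_SC` by α ∈ [0.25, 3] in the full
nonlinear feedback model and reports the dominant spectral frequency
against `T_SS = α(T_CS + T_SC)`; the curve is non-monotonic with a jump
back up when the circuit locks onto the next resonance branch.

The reduced model collapses the circuit into
`s' = −w_GS g − w_SS s(t−T_SS) − s`, `g' = w_SG s − g` in time units of
τ = 16 ms, with `w_GS·w_SG = 6.4771` from the feedback best fit. Its Hopf
boundary follows from `λ² + 2λ + (w_GS w_SG + 1) + w_SS(1+λ)e^(−λT) = 0`
with λ = iω, solved parametrically in ω for (T(ω), w_SS(ω)); onset
frequencies are ω/(2πτ) in Hz. The analytic boundary agrees with
simulation bisection to ≲ 0.05% and with direct complex root finding; at
`w_SS = 2` stability alternates periodically with the delay. At T = 0 the
characteristic polynomial has all-positive coefficients, so the system is
stable for every `w_SS ≥ 0`.

## Synthetic data and scope

All inputs are generated programmatically: the spike-train module is the
data generator (its defaults — 40 s, 1 ms bins, the published A, b, f, N —
are the study conditions), and the models themselves generate every
trajectory. Nothing here emulates features of real recordings beyond a
rate-modulated Poisson spike process: no refractoriness, bursting, unit
isolation noise, or non-stationarity, so passing tests validate the
models' internal consistency and their agreement with the published
summary statistics, not fidelity to raw electrophysiology. The multi-start
capability emulates the published 200-run optimization only at reduced
scale (restart counts of order 3 in the tests), and no claim is made about
the cluster structure of fitted parameter sets.

## Problem sizes and numerical defaults

Headline simulations use 5 s at step 0.05 ms with 1 s transient (8001
analyzed samples at the 0.5 ms output spacing). Fitting evaluations use
2–3 s at step 0.1 ms, which keeps a candidate evaluation (intact plus four
cuts) around 10 ms of CPU. Linear bisection runs 2–3 s per simulation with
coupling tolerance 10⁻³; the reduced-model numeric boundary uses
dimensionless duration 400–800 at step 0.01. Spike-train matching
evaluates a 4×4×9×3 grid plus ≤ 200 refinement steps, each a full 40 s
train. These sizes were chosen so every analysis is comfortably resolved
(halving any of them changes no reported digit at the printed precision).
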