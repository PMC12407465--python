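# Methods

This note documents the models, numerical choices and limitations of
`histbias`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the example scripts.

## The decision model

Choices and response times are modelled as first passages of a Wiener
diffusion between two absorbing bounds,

    dy = (s·v + v_bias) dt + c dW,   y(0) = z·a,

where s ∈ {−1, +1} is the stimulus category, v ≥ 0 the drift rate
(evidence units/s, one value per signal-strength level), v_bias an
evidence-independent drift offset, a the boundary separation, z ∈ (0, 1)
the relative starting point, and c the noise scale. The response time is
the first-passage time plus a non-decision time t0. Choice history bias
enters by conditioning both z and v_bias on the previous available choice;
the *history shift* of a parameter (prev-right minus prev-left) is the
quantity of scientific interest, with positive values meaning attraction
toward the previous choice. A starting-point shift produces early biased
responses; a drift-bias shift biases responses throughout the RT
distribution — which is why the two mechanisms are separable from RT data
at all.

Assumptions worth stating: no across-trial variability parameters (sv, sz,
st), no collapsing bounds or urgency, and c fixed to 1 — the standard
identifiability convention, since (a, v, v_bias, c) are jointly determined
only up to a common scale.

### Densities

First-passage densities use the two classical series representations of
the Wiener FPT density (a small-time expansion in image charges and a
large-time sine series), switching per evaluation point to whichever needs
fewer terms for an absolute tolerance of 1e−8. The two representations are
independent derivations; the test suite checks them against each other and
against brute-force partial sums, and checks the resulting defective
densities against closed-form absorption probabilities and against
simulation (below).

### Simulation oracle

The generator integrates the same SDE by Euler–Maruyama. Plain EM
systematically under-detects bound crossings that occur *within* a step
(an O(√dt) bias, visible as absorption probabilities inflated by ~0.7
percentage points at dt = 0.5 ms). Both the path simulator and the
observer therefore apply a diffusion-bridge correction: after each
interior step the crossing probability
exp(−2(a − x_old)(a − x_new)/(c² dt)) (and its lower-bound analogue) is
sampled. With this correction, analytic defective densities and simulated
histograms (1e5 paths, dt = 0.5 ms, 0.1 s bins over 0–5 s) agree to L1 <
0.02 per bound across all tested parameter regimes; the residual L1 is
dominated by Monte-Carlo noise. The histogram bin width is fixed at 0.1 s:
L1 against binned analytic mass is resolution-dependent, and 0.1 s keeps
the Monte-Carlo noise floor at 1e5 paths well below the tolerance.

### Fitting

Continuous maximum likelihood: −Σ log f_bound(rt_i), with the density of
the bound matching the observed choice, evaluated at rt − t0, and a
per-trial floor of 1e−10 so response times the model cannot reach (e.g.
rt < t0) keep the objective finite instead of poisoning the fit. Trials
without a response (rt > 3 s; ~0.1–0.2% under the default generator) are
excluded, mirroring the behavioural exclusions. Eight free quantities: a,
v_weak, v_strong, t0, and z and v_bias per previous-choice context.
Optimisation is bounded L-BFGS-B (bounds a ∈ (0.3, 6), v ∈ (0, 8),
t0 ∈ (0.05, min rt), z ∈ (0.05, 0.95), v_bias ∈ (−4, 4)) from a
moment-based heuristic start (accuracy-matched drift) plus seeded
Latin-hypercube restarts; the likelihood is evaluated vectorised over all
trials at once. Ten restarts are the conservative default; in practice the
heuristic start reaches the global optimum on this likelihood, and the
pipeline uses 3 restarts.

At the per-participant scale of the emulated study (~3,500 trials) all
eight parameters are recovered within 15% or within the parametric
bootstrap 95% interval; the history-shift estimates carry a standard error
of roughly 0.03 (z-shift) and 0.12 (v_bias-shift). At ~500 trials recovery
degrades gracefully — point estimates stay unbiased but shift SEs roughly
triple, so single-session shift estimates should be treated as noisy.

## Synthetic cohort

The generator emulates the study conditions end to end: 19 participants ×
4 sessions crossing drug (placebo vs. atomoxetine) with response mapping,
6 blocks of 160 trials per session (the per-session block count is not
fixed by the emulated design; 6 gives 3,840 trials, inside the reported
3,520–4,320 range), mini-breaks every 40 trials, exact within-block 50/50
signal-side counterbalancing in random order, strengths randomised 50/50,
ITIs uniform on 0.6–1.4 s, feedback 50 ms after the response. Under exact
within-block balancing the expected stimulus repetition probability is
79/159 ≈ 0.497 (sampling without replacement), slightly below 0.5; the
enumeration for 2/2-balanced blocks of length 4 gives exactly 1/3, and the
generated cohort statistic lands at 0.496–0.498.

Per-participant diffusion parameters are drawn from population
distributions chosen to produce realistic behaviour: a ~ N(1.4, 0.12),
v_weak ~ N(0.75, 0.12), v_strong ~ N(1.05, 0.15), t0 ~ N(0.30, 0.03)
(accuracies near 74%/81% for weak/strong), starting-point shift
~ N(−0.03, 0.03) (weakly repelled), drift-bias shift ~ N(+0.30, 0.35)
(~80% repeaters, a 4:1 repeat/alternate split). The drug multiplies the
drift-bias history shift by (1 − shrinkage), default shrinkage 0.5, with a
switch to modulate the starting-point shift instead for falsification
tests. The previous-choice context is the most recent *included* trial's
choice; trials following a miss carry no context and use the neutral
parameter means.

Physiology: pupil traces (100 Hz; well above twice the 6 Hz filter
cut-off) are a session mean (~1,200 raw units, +120 under drug) plus slow
drift, stimulus-locked constriction, a decision-related dilation and a
feedback-locked dilation, all through a canonical gamma pupil response
(shape 10.1, time-to-peak 0.93 s). The decision-related input begins 0.5 s
before the report, so the response peaks shortly after the choice and the
feedback response follows ~0.5 s later — the two-peak structure the tpr
window is designed around. The dilation amplitude is
base − coupling × repeat + noise with coupling 1.5 raw units, planting a
trial-level tpr–repetition correlation of ≈ −0.1 (a realistic pupillometry
effect size). Blink dropouts (Poisson, ~3/min) and saccades (~10/min) add
biphasic artifact responses anchored at blink end / saccade time. ECG is a
Gaussian-bump R-peak train with jittered inter-beat intervals (+5 bpm
under drug).

What the generator does *not* emulate: pixel-level stimuli, gaze-dependent
pupil foreshortening, realistic QRS morphology, slow non-stationarities in
bias, or any coupling between pupil state and the diffusion parameters
within a session (the planted pupil–behaviour link is at the trial level
only). Passing tests therefore certify the analysis machinery — the
estimators recover what was planted under realistic noise — not that real
data satisfy these generative assumptions.

## Staircase

Titration uses a Bayesian adaptive staircase: a grid posterior over the
Weibull threshold (log10 grid, slope/lapse/guess assumed known), each
trial placed at the intensity maximising Fisher information about the log
threshold (the "sweet point", p ≈ 0.89 for slope 3.5, 2AFC), and the final
level read off by inverting the psychometric function at the target
accuracy. After 200 trials the threshold estimate sits at its information
bound (sd ≈ 0.017 log10 units), which maps to a 1σ accuracy error of
~2–2.5 percentage points at the 70%/85% targets; single runs can
therefore miss a ±3 pp window, and the calibration test averages an
ensemble of independent runs instead of asserting one draw.

## Pupil preprocessing

The chain is (i) linear interpolation across missing data, padded 150 ms
on both sides, edges clamped; (ii) zero-phase (forward–backward) 3rd-order
Butterworth low-pass at 6 Hz — zero-phase filtering is chosen to avoid
phase-delaying event-locked averages, at the cost of squaring the
magnitude response; (iii) joint FIR deconvolution of blink-end- and
saccade-locked responses over a 6 s window (sparse normal equations with an
explicit intercept; ridge fallback on singular designs, flagged), then
removal by refitting regressor amplitudes with OLS and subtracting; (iv)
percent signal change around the session mean. Interpolation and PSC are
idempotent; tpr (mean PSC 0–0.65 s from choice minus the 0.25 s pretrial
baseline) is exactly invariant to constant offsets of the PSC trace. An
additive offset of the *raw* trace is not an exact invariance of PSC (it
rescales by m/(m+c)); the scale-invariance of PSC is exact and tested.
Block-wise pupil size is averaged on blink-interpolated raw units over
entire blocks, inter-trial intervals included.

R-peak detection thresholds at half the running 98th percentile of |x|
(10 s segments, interpolated) with a 250 ms refractory period — sensitivity
≥ 0.99 at SNR 10 against planted ground truth.

Pupil-bin analyses use equal-count quantile bins of tpr per participant
(8 by default), exporting a demeaned bin index P for the mixed models.

## Statistics

- Paired t (two-tailed, df = n − 1); zero-variance differences are flagged
  degenerate rather than NaN.
- JZS Bayes factor for the paired t: Cauchy prior on the standardised
  effect size with scale √2⁄2, computed by adaptive quadrature of the
  noncentral-t likelihood over the prior; BF(t = 0.22, n = 19) = 0.243,
  cross-checked against an independent implementation to 0.1%.
- 2×2 repeated-measures ANOVA via the univariate within-subject
  decomposition; each effect is tested against its own subject-by-effect
  interaction with df (1, n − 1). For two-level factors the main-effect F
  equals the squared paired t on collapsed means to 1e−10 (tested).
- Pearson correlations with percentile bootstrap CIs over participant
  resampling (default 5,000 resamples, 68% coverage).
- Regression-to-the-mean control: the observed baseline-vs-change
  correlation is compared against a null built by independently swapping
  each participant's condition labels (which flips that participant's
  change score), preserving regression to the mean while destroying any
  real association. Reported one-sided as the fraction of permuted
  correlations at or below the observed one, with the add-one correction;
  p-values are uniform under exchangeable nulls to within ±3% per decile.
- Difference of dependent correlations (behavioural shift vs. the two
  model shifts): same label-swap null, two-tailed on Δr. The
  implementation takes the per-participant change score and
  condition-averaged predictors; a label swap is then exactly a sign flip
  of the change score.
- Mixed models: y ~ 1, y ~ 1 + P, y ~ 1 + P + P² with participant random
  intercepts. Reported coefficients and variance components come from REML
  fits; model sequencing uses BIC from maximum-likelihood refits, because
  REML criteria are not comparable across fixed-effect structures. Each
  richer model must undercut the current best BIC by more than 10. The
  quadratic step is compared against the current best (not gated on the
  linear step succeeding) so a pure inverted-U — where the linear term adds
  nothing — is still reachable.

## Problem sizes

The default pipeline reproduces the full 19-participant cohort. The test
suite runs the same machinery at sizes chosen for a desk-scale run: density
validation at 1e5 paths × 5 parameter regimes, parameter recovery at one
~3,500-trial session with a 19-draw parametric bootstrap fallback,
drug-selectivity recovery at 10 replicates × 8 participants × 2 conditions
× 800 trials, permutation calibration at 500 simulations × 1,000
permutations, and the pupil round trip on full-length sessions. The
selectivity replicates plant a homogeneous strong repetition bias
(drift-bias shift 0.5 ± 0.15, shrinkage 0.8, starting point untouched):
the property under test is that the planted drug effect loads on the fitted
drift-bias shift and not the starting-point shift, which requires the
per-replicate paired test to be decisively powered; the heterogeneous
default cohort emulates the human study's idiosyncratic biases instead and
is used everywhere else.

## Known limitations

- The likelihood has no contaminant/outlier mixture; the 1e−10 floor is a
  blunt guard, appropriate here because the generator produces no
  contaminants.
- Misses are dropped, not censored; a censored-likelihood treatment would
  matter for datasets with substantial non-response rates.
- Fits are per participant × condition; no hierarchical pooling across
  participants.
- The deconvolution assumes linear superposition of artifact responses and
  fixed kernels within a session.
- Mixed models include random intercepts only (no random slopes), matching
  the analysis they implement.
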