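# Methods

This note documents the generative model, the analysis chain, the defaults
and the numerical choices in `erpmix`, in the order data flow through the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Experimental design

The simulator reproduces a 2 (Type: intact/scrambled) × 2 (Category:
face/house) × 2 (Duration: 33/216 ms) within-subject design delivered in
four 320-trial blocks. Blocks 1–2 ("half 1") contain only 33 ms
presentations — every intact stimulus three times per block, every scrambled
stimulus once. In blocks 3–4 every stimulus appears once at each duration.
Totals per participant: intact 8×33 ms + 2×216 ms, scrambled 4×33 ms +
2×216 ms, over 40 face and 40 house stimuli (ids are shared between the
intact and scrambled versions of an image). `n_stimuli_per_category` scales
the design proportionally while preserving this structure; trial order
within a block is a seeded permutation, with one master seed spawning
per-participant substreams (`numpy.random.SeedSequence`).

## 2. Generative model for single trials

Each trial's epoch (−500…+996 ms at 250 Hz, 375 samples) is

```
x(t) = a_p1 · G(t; 116, 16.5)  −  gain_hemi · amp_n1 · G(t; 172, 16.5)  +  ε(t)
```

with `G` a unit-peak Gaussian in time (centres/SDs in ms, configurable),
`ε(t)` white Gaussian noise per channel and sample (`sd_noise`, default
10 μV), and `gain_hemi` a right-hemisphere scaling of the N1/N170 complex
(default 1.15, reflecting the typically stronger right-lateralized face
response). Channels form two clusters of seven posterior electrodes
(PO7- and PO8-centred labels); all channels of a cluster carry the same
signal plus independent noise, so cluster averaging improves SNR as
1/√n without biasing window means.

The N1/N170 complex amplitude (a positive magnitude, rendered
negative-going) is

```
amp_n1 = base(type) + half2_gain·[intact & half 2] + eff + u_participant + u_stimulus + jitter
```

* `base`: nonspecific N1, 2.0 μV intact / 1.2 μV scrambled;
* `half2_gain` (0.8 μV): a nonspecific increment for all intact stimuli in
  the second half, emulating a practice/familiarity effect that is not
  face-specific;
* `u_participant ~ N(0, 1.0²)`, `u_stimulus ~ N(0, 0.5²)` μV: crossed
  random intercepts; `jitter ~ N(0, 1.0²)` μV: trial-level variability;
* `eff` is the face-specific part and is where the two hypotheses differ.

**All-or-none**: on intact-face trials a Bernoulli draw with probability
`p_detect(category, duration)` gates a full response: `eff ∈ {0,
a_n170_full}` with `a_n170_full = 4 μV`. **Graded**: `eff =
g(duration) · a_n170_full` deterministically, with `g(216) = 1`.
Scrambled trials never carry a category component. The two branches consume
their random draws in the same order, so graded with `g ≡ 1` is
bit-identical to all-or-none with `p_detect ≡ 1` at the same seed — a
useful degenerate-case check.

Detection probabilities are parameterized per (category, duration) rather
than per duration alone: faces and houses have clearly asymmetric detection
at 33 ms (sure-face responses on roughly half of face trials vs. sure-house
on ~15% of house trials), which two duration-only numbers cannot express.
Defaults: faces 0.475/0.99, houses 0.18/0.98 at 33/216 ms.

### Confidence responses

A single signed latent evidence variable (face-positive) produces the 5-key
response: detected (or graded-driven) trials draw evidence at
`±g·mu_evidence` (default 4.0) with SD 1.0; undetected intact trials at 0
with SD 0.8; scrambled trials at 0 with SD 0.5. Two symmetric thresholds
(0.6 and 1.8) cut the scale into Key 1 (sure face) … Key 5 (sure house).
These values were calibrated once against the reported group means of the
response-allocation table: they put the Key-1 share for 33 ms intact faces
at ≈0.47, the 216 ms share at ≈0.98, and P(face | Key 1, 33 ms) at ≈0.99.
The unsure-key (2/4) shares are underpredicted relative to the reported
pattern — a single-evidence-variable model with three free parameters
cannot match all ten key proportions — which is acceptable because only the
Key-1 calibration feeds the screening rule and the high-confidence
analyses. The graded preset uses `g(33) = 0.43`, chosen so the mean 33 ms
evidence sits at the sure threshold and the Key-1 share matches the
all-or-none preset: the two hypotheses are then behaviourally comparable
and differ only neurally, which is the point of the discrimination
experiment. Trials with Key 3 ("no idea") are treated as undetected;
partial awareness on such trials is conceivable but unmodelled.

## 3. Epoch arithmetic

Trigger timestamps from external recordings are shifted later by
`total_delay = amplifier_delay + display_delay` (the canonical values
36 + 14 = 50 ms); simulated data need no shift, the operation exists for
the external-data path. Preprocessing on epochs is: linear detrend (least
squares per trial × channel) on −200…996 ms, subtracted across that span
only, then subtraction of the −200…0 ms baseline mean from every sample.
Window means snap their ms bounds to the nearest sample on the 4 ms grid
and use the closed interval; channels of a hemisphere's cluster are
averaged before the time average (the order is irrelevant by linearity and
fixed for documentation). Single-trial amplitudes are means, not peaks, so
component latency is constant across conditions by construction.

## 4. Component windows

The integration window for each component is found on a condition-blind
grand average over all trials, both hemisphere clusters and all retained
participants. The peak is the polarity-appropriate extremum in a search
range (N170: negative in 100–250 ms; P1: positive in 70–140 ms; earliest
sample wins ties). The window is the contiguous span around the peak where
|waveform| ≥ f·|peak|, with f initialized at 0.5 (FWHM). If the width falls
outside 36–40 ms, f is adjusted by bisection on (0, 1) — width is monotone
non-increasing in f for unimodal waveforms — until the width is inside the
range (inclusive), with tolerance 10⁻⁴ on f and full audit of the f-trace.
Crossing times are linearly interpolated between samples; the 4 ms grid is
otherwise too coarse for a 36–40 ms target. For Gaussian shapes the
implementation satisfies the closed form `width(f) = 2·SD·√(2 ln(1/f))`
within one sample, which the tests exploit at SD 15/16.5/25 ms. The
template defaults (centre 172 ms, SD 16.5 ms) put the noiseless window at
≈152.5–191.5 ms, matching the canonical 152–192 ms window; P1 defaults give
≈96.5–135.5 vs. the canonical 96–136 ms. The two-pass peak-channel
reassessment by scalp inspection is replaced by a deterministic surrogate:
compute candidate-cluster grand averages, keep the cluster with the largest
|peak| (`select_peak_cluster`).

## 5. Behavior and screening

Response allocation and P(face | key) tables are computed within
participant and summarized across participants with normal-approximation
95% CIs (the CI method for such tables is conventionally unstated; the
normal approximation is adequate at these counts). Screening retains
participants whose P(face | Key 1, intact, 33 ms) is ≥ 0.95, inclusive at
the boundary; participants who never pressed Key 1 on those trials are
excluded with the explicit reason `no-usage`, the conservative reading of
the screening intent. Screening pools all 33 ms trials from both halves.
The analysis factors are: Confidence (high/low/guess, defined only for
category-congruent keys), Duration Confidence (33_guess, 33_low, 33_high,
216_high; intact trials only, others NA), and Duration Half (33_half1,
33_half2, 216_half2; high-confidence intact trials only).

## 6. Mixed models

`SingleTrialLMM` fits single-trial window amplitudes with sum-coded fixed
factors (full interactions) and crossed participant/stimulus random
effects, using variance components in `statsmodels.MixedLM` (one group;
participant/stimulus dummy blocks, one variance per term). This
parameterization cannot express correlations between random terms, so the
selection ladder's zero-correlation rung coincides with the maximal model
and the "extended" rung with the reduced one; what remains of the ladder —
convergence fallbacks, dropping non-contributing terms, the final AIC
comparison — is implemented literally and logged rung by rung. A term is
non-contributing when its likelihood-ratio p (ML refits, χ²₁, a
conservative choice given the boundary null) exceeds 0.2 or its variance
falls below 10⁻⁴ of the residual variance; both knobs are arguments.
Fitting is REML; model comparisons use ML log-likelihoods and AIC. If every
random term is dropped the model degenerates to OLS through a small
adapter. Convergence means the optimizer's flag plus finite parameters.

Estimated marginal means are linear combinations of the fixed effects,
averaging uniformly over non-focal factor levels (the design is balanced;
observed-frequency weighting is not needed for the simulated designs).
Contrast SEs come from the coefficient covariance; degrees of freedom are
residual (n − rank), with every contrast tagged `df_method="residual"` — a
Satterthwaite approximation is not available from the backend, and at the
trial counts involved (10³–10⁴ residual df) the t quantiles are
indistinguishable from those at Satterthwaite df in the hundreds. An
independent lme4 fit (via Rscript) cross-checks the fixed effects and SEs
in the test suite.

## 7. NHST, equivalence tests, scenarios

For a contrast b with standard error SE: NHST is the two-sided t test of
b = 0; the equivalence test performs two one-sided tests against the region
[−0.5, +0.5] μV (configurable) and reports the side with the smaller |t|
(the larger p). Bonferroni corrections multiply the reported p by the
family size — 2 for the Duration analyses (one test per hemisphere), 6 for
Duration Confidence (six pairs of four levels), 3 for Duration Half — and
the attached CIs use correspondingly adjusted critical values
(`t_{1−(α/2)/m}` for 95%, `t_{1−α/m}` for 90%), so that corrected
equivalence declaration remains exactly dual to the 90% CI lying inside the
region. The joint outcome is classified into scenarios: S1/S2 (NHST
significant only, split by sign — report NHST only), S3 (equivalence only —
report the ET, smaller-|t| side), S4/S5/S6 (neither — inconclusive, split
by whether the 90% CI spans both bounds or overlaps only the lower/upper
bound; report both). Two corner cases make the classifier total: both tests
significant (a nonzero yet practically equivalent effect) gets its own
flagged label `S_both`, and a CI inside the region whose corrected p still
misses α (possible only with family corrections) is assigned S5/S6 by the
reported side.

## 8. Pipeline and the discrimination experiment

`run_analysis_sequence` chains simulate → preprocess → derive factors →
screen → windows → amplitudes → the three analyses (all-trials
Type×Category×Duration; intact-only Category×Duration-Confidence;
high-confidence Category×Duration-Half, each with Hemisphere as a fixed
factor and contrasts reported per hemisphere), writing tab-delimited
contrast tables stamped with a config hash, window JSONs with f-traces, and
ladder logs. Scrambled trials are excluded from analyses 2–3. The pipeline
is a pure function of (config, seed); reruns are byte-identical.

`discrimination_experiment` replicates the chain under both hypotheses and
tabulates scenario labels for three face-trial contrasts: the all-trials
duration effect, the high-confidence duration effect, and the
within-half-2 high-confidence duration effect. For these fits the two
hemisphere rows of each trial are averaged into one observation (precision
without pseudoreplication) and intercept-only random effects are used. The
default preset runs 8 participants and 16 stimuli per category — chosen so
the standard error of the critical within-half contrast (~0.13–0.16 μV)
matches the precision a full-scale study reports, keeping the equivalence
test adequately powered while one replicate completes in seconds. The
expected pattern, which the acceptance suite verifies over replicates, is:
all-trials contrast significant under *both* hypotheses; within-half
contrast equivalent to zero (S3) under all-or-none and a clear effect
(S1/S2) under graded.

## 9. What the simulator does and does not emulate

It emulates: the block/repetition structure and scaled versions of it;
crossed participant/stimulus variability; detection- or gain-driven
confidence; the half-2 nonspecific gain; component topography reduced to
two labelled clusters with a hemisphere gain; white measurement noise.

It does not emulate: autocorrelated (1/f) EEG noise (an AR(1) option was
considered and left out of the defaults; white noise at 10 μV/sample gives
realistic ~1 μV window-mean noise after cluster averaging but understates
sample-to-sample correlation, so tests passing here say nothing about
filter-induced distortions), ocular or muscle artifacts, realistic scalp
topography or channel interpolation, reaction times, learning curves
beyond the static half-2 gain, or psychometric detection curves (only two
durations exist, so `p_detect` is two free numbers per category).
Consequently, passing tests demonstrate the *logic* of the analysis chain —
dilution, conditioning, equivalence calibration, ladder behavior — not its
robustness to real-data pathologies.

## 10. Numerical conventions

Amplitude magnitudes are stored positive and rendered with component
polarity; contrasts are reported on the signed (negative-going) scale, so
"33 minus 216" on faces is positive when the 33 ms response is weaker.
Times are ms, 0 = stimulus onset. Window bounds snap to samples; peak ties
break to the earliest sample; bisection tolerance on f is 10⁻⁴ with a
200-iteration cap; flat waveforms, plateaued FWHM targets, empty clusters,
degenerate factors, non-positive SEs and mismatched alphas all raise
informative errors rather than propagating NaNs.
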