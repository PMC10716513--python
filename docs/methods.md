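# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `popgaze`. Units throughout: time in seconds (window lengths
quoted in ms), gaze in screen-centered visual degrees (rightward/upward
positive), pupil diameter in millimetres.

## Experiment design and schedule generation

The design is a 56-trial audio-visual face pop-out paradigm. Each trial:
central attention-grabber → auditory cue (or silence) → ISI drawn uniformly
on [80, 400] ms → a 4-image array (face, man-made object, natural object,
geometric shape) for 3 s → 500 ms white screen. The sound inventory holds 6
social (infant-directed speech tokens from two voices) and 6 non-social
(everyday object) recordings with durations spread over 506–989 ms.

Trials come in pairs repeating the same sound at the same volume (the
*repetition* factor). Pairs form two blocks of 14 (12 sound pairs + 2
silent pairs); the blocks share the pair sequence with every volume
assignment exchanged, so each sound occurs once at high and once at low
volume. Volume assignment within a block is balanced within social and
non-social content, making the (content × volume) cells 12/12/12/12 trials.
Silent trials carry volume "none"; consequently the 48 sound trials split
24 high / 24 low. Images (56 per category) are dealt without replacement —
224 unique images per schedule. Positions are the four corners at (±12°,
±6°) from the screen centre; per-trial category→position maps are drawn by
rejection sampling until no category keeps its position across consecutive
trials (a derangement of 4 positions always exists; the retry bound of
1000 is a bug signal, not an expected event).

The geometry places the images at the four corners of the 12°/6°
rectangle; with 11°×11° AOIs this makes the AOIs pairwise disjoint (24°
horizontal, 12° vertical centre separation). A cardinal-point arrangement
would satisfy the same two distances; the corner layout is the package's
choice and the positions are configurable.

## Synthetic sessions

`simulate` produces 600 Hz binocular recordings with known ground truth.
Per trial, time runs from 0 with the sound-onset marker at 0.75 s (silent
trials carry the marker), visual onset at sound + ISI, offset 3 s later,
plus 0.5 s of white screen.

**Pupil.** The cyclopean trace is
`baseline_i + tonic_t + drift(t) + hippus(t) + amp · k(t − sound onset)`:

* `baseline_i`: infant tonic level (4.2 mm at 5 months, 4.4 mm at 10
  months) plus a per-infant random intercept (SD 0.3 mm);
* `tonic_t`: per-trial tonic offset, SD 0.2 mm — slow arousal drift across
  the session, which is what makes baseline pupil size vary within infants;
* `drift`: within-trial linear drift with random slope (SD 0.075 mm/s) and
  `hippus`: a random-frequency (0.15–0.4 Hz) sinusoid of amplitude 0.1 mm;
  together these give the ~0.12 mm window-measurement noise that any
  baseline/response subtraction inherits, on silent trials included;
* `k`: an Erlang-shaped impulse response `(t/nτ)^n e^{n(1−t/nτ)}` with
  n = 10, τ = 0.1 s, peaking 1 s after sound onset — a smooth, causal,
  unimodal kernel consistent with a 2 s response window. Each trial's
  kernel is rescaled so that the *smoothed* kernel's mean over that trial's
  response window is exactly 1. The amplitude `amp` is therefore already in
  "measured dilation" units: on a clean signal, the preprocessing chain
  returns exactly `amp`. `amp = gain(volume) + a_i + ε`, with gains 0.09 mm
  (high), 0.07 mm (low), 0 (silence) — so the injected high–low contrast is
  0.02 mm and both sound conditions exceed silence — a per-infant
  reactivity offset `a_i` (SD 0.03 mm), and trial amplitude noise ε (SD
  0.15 mm). The per-eye traces are the cyclopean trace ± half a constant
  0.3 mm left–right offset, plus independent 0.05 mm sample noise, which
  makes the dynamic-offset binocular mean non-trivial.

**Gaze.** Gaze dwells at the centre (per-sample noise 0.5°), saccades
instantaneously to the chosen image at visual onset + latency, and dwells
there through the presentation. Latency is `μ_age + s_i + ε` with μ = 0.45 s
(5 m) and 0.36 s (10 m) — an injected age effect of exactly −0.09 s — a
per-infant speed offset `s_i` (SD 0.03 s), and ε normal (SD 0.05 s)
truncated symmetrically at ±0.15 s. Symmetric truncation keeps the realized
age contrast equal to −0.09 s exactly, and the bounds keep clean latencies
inside the 0.2–1.0 s validity window so the latency-validity criterion
induces no selection on clean trials. An optional ISI slope (default 0)
supports age × ISI studies.

**Target selection.** The first-look target is drawn from a logistic model:
`logit P(face) = −1.1 + 0.94·[10 m] + 0.44·[high volume ∧ first
presentation] + 0.09·z(amp) + b_lin·(baseline − 4.3) + b_quad·(baseline −
4.3)² + u_i`, with `z(amp)` standardized by the fixed reference scale
(0.08, 0.18 mm), a per-infant random intercept (SD 0.3), and quadratic/
linear baseline terms defaulting to 0 (an inverted-U study injects
b_quad = −1.0 per mm²). Non-face looks pick a distractor uniformly.

**Corruption.** Blinks are binocular Poisson events (0.15/s, duration
150 ± 60 ms) blanking gaze and pupil of both eyes together; monocular
tracking dropouts (0.05/s per eye, ~200 ms) blank one eye; with probability
0.05 per trial an off-screen excursion (0.2–0.6 s) occurs during the
presentation; 3% of trials are "distracted" (gaze wanders between the
images, never entering an AOI) and 2% have latencies outside the validity
bounds. These rates were chosen so that a default cohort yields roughly
47–50 valid trials per infant out of 56, matching the scale of attrition
such experiments report. All corruption is independent of the injected
effects, so trial rejection does not bias effect recovery.

A table-level fast path (`simulate_features_table`) draws the same effect
structure directly at the trial-feature level (dilation = amp + 0.12 mm
window noise; baseline, latency, and face selection from the same models)
without synthesizing signals. It exists for model-stage studies — LRT null
calibration and quadratic recovery need hundreds of replicates where the
signal chain is not the thing under test. The signal path and the table
path share every coefficient; only measurement noise is approximated.

**What the generator does not emulate:** saccade kinematics (saccades are
instantaneous), pupil foreshortening with gaze angle, luminance responses
(room luminance constant in the paradigm), head movement, and
autocorrelated missingness (a distressed infant's missingness is bursty
across trials; here it is independent). Passing tests therefore certify
the pipeline's correctness and calibration under these idealized
conditions, not robustness to every artifact of real infant data.

## Preprocessing

**Gaze:** per-eye, per-channel linear interpolation over gaps *strictly*
shorter than 150 ms (gap duration measured from the last valid to the next
valid sample; leading/trailing gaps never filled) → binocular mean of the
available eyes → binary AOI indicator vectors (closed squares; missing
gaze is in no AOI; at most one image AOI can be active since AOIs are
disjoint) → first-entry latency: the onset of the first maximal run of
in-AOI samples within the presentation window whose length × the nominal
sample period reaches 100 ms; a run broken by a single missing sample is
broken. Raw missingness (neither eye valid, whole trial) and post-
interpolation on-screen proportion (visual window, screen bounds ±21.5°
horizontal, ±12.5° vertical at 65 cm — configurable) are recorded.

**Pupil**, in fixed order: per-eye centred moving average over a 100 ms
window (61 samples at 600 Hz, endpoints inclusive, truncated at edges;
missing stays missing) → dynamic-offset binocular mean: where both eyes are
valid, the plain mean, recording the offset d = L − R; where one eye is
valid, the other is reconstructed from d linearly interpolated
(edge-extrapolated) across both-valid samples; a trial with no both-valid
sample falls back to the available-eye mean and is flagged → validity
recoding in three passes: outside 1.5–9 mm, then beyond ±3 SD of the trial
mean (mean/SD computed once, after range recoding — single-pass, no
iterated trimming), then samples whose gaze is detected off-screen →
linear interpolation over gaps < 150 ms → window means over half-open
intervals: baseline [sound − 0.2 s, sound), response [visual, visual + 2 s),
dilation = response − baseline. Missing fractions per window are kept as
covariates. Pupil features are computed for all trials; the analysis table
retains them for gaze-valid trials, with pupil-specific missingness as
covariates rather than extra rejection rules.

## Trial screening and inclusion

Five criteria (a trial is rejected if any holds):

1. interpolated gaze in the central attention-grabber area (6° square,
   configurable) for ≤ 40% of [sound − 0.5 s, sound);
2. no central-area sample in [visual − 0.2 s, visual);
3. any missing/off-screen sample in [visual, +0.5 s) — strictest reading,
   chosen because the stated purpose of the second clause is to spare
   trials with a valid first shift; `any`/`all`/`proportion` are all
   implemented and configurable — OR > 25% missing/off-screen in
   [+0.5 s, +1.0 s);
4. no qualifying AOI entry during the presentation;
5. first-AOI latency < 0.2 s or > 1.0 s.

Participants with < 70% valid trials are excluded (≥ 0.70 is inclusive).
The analysis table holds one row per valid trial of each included infant:
condition labels, ISI, dilation, baseline, latency, the face indicator
(1 iff the first look hit the face AOI), missingness covariates, and the
infant's valid-trial count. Dilation can be z-scored globally (default,
across all valid trials of included infants) or per infant.

## Models

Gaussian outcomes use a random-intercept LMM fitted by exact profiled
maximum likelihood: given the variance ratio λ = σ_u²/σ_e², β and σ_e² have
closed forms (Woodbury identities per cluster), so the ML problem is a
smooth 1-D search over log λ (Brent, with the λ = 0 boundary checked
explicitly). This is deterministic and accurate to ~1e-10 in λ, which
matters because single-term-deletion LRT statistics are *differences* of
log-likelihoods and inherit any optimizer noise; general-purpose mixed-model
optimizers proved too loose near the variance boundary for calibrated
χ² values. The implementation is cross-checked against statsmodels MixedLM
and OLS in the test suite.

Binary outcomes use a random-intercept logistic GLMM whose marginal
likelihood is integrated by adaptive Gauss–Hermite quadrature (15 nodes,
mode-centred per cluster via Newton steps, vectorized across clusters),
optimized by L-BFGS-B over (β, log σ); standard errors come from the
numerical Hessian at the optimum. The fit is validated against
`lme4::glmer(nAGQ = 15)` in the test suite (coefficients and
log-likelihood to ~1e-3).

Inference: single-term deletions compared by LRT, with the reduced model
refitted on exactly the rows the full model used; χ² is clipped at zero
(boundary/rounding can produce −1e-12 on truly-null terms); dropping a term
that participates in a retained interaction raises. Factors are
deviation (sum-to-zero) coded in the packaged model specs; the LRT is
invariant to that choice (tested). Marginal contrasts build two design rows
differing only in the factor level, covariates at supplied values or sample
means (categoricals at the mode), and use delta-method SEs. Quadratic tests
trim the predictor to its [1st, 99th] percentile range (configurable)
before *both* fits, centre it, and LRT the squared term (1 df). The
power-analysis utility returns central-F upper-tail critical values
(F(55, 2420) at α = 0.05 is 1.339 ≈ 1.34).

Satterthwaite-style denominator-df F tests are deliberately out of scope:
the LRT is the decision procedure implemented, and the primary inference
this package reproduces.

## Multiple imputation

Chained equations with a regression-tree learner (CART-style): each
incomplete column is modelled on the other analysis columns (categoricals
one-hot coded), and missing rows draw a donor uniformly from the observed
values in their terminal leaf — imputations never leave the observed
support. Classic predictive-mean matching (linear prediction, donor drawn
among the 5 nearest observed predictions) is available as an alternative
learner. Initial fill is a random observed draw; visit order is by
increasing missingness; 5 chain iterations (burn-in; unstated upstream,
chosen as a conventional chained-equations depth); m = 100 completed tables
by default. Estimates across imputations are pooled by Rubin's rules:
pooled estimate = mean, total variance T = W + (1 + 1/m)B, reference df
(m − 1)(1 + W/((1 + 1/m)B))². The pooling rule is this package's choice;
identifier and design columns are never imputed.

## Numerical choices and degenerate inputs

* Half-open windows [start, end) everywhere a window mean is taken, so
  boundary samples are never double-counted.
* The 150 ms gap rule is strict (<); the 100 ms dwell rule is inclusive
  (≥ 60 samples at 600 Hz); the 70% inclusion rule is inclusive (≥).
* AOI membership uses closed intervals; ties are impossible (disjoint AOIs).
* Empty analysis windows yield NaN with missing fraction 1, never an
  exception; dilation is NaN if either window is.
* A trial whose eyes never overlap falls back to the plain mean and is
  flagged (`offset_fallback`).
* The ±3 SD recode skips degenerate trials (≤1 valid sample or zero SD).
* GLMM: log σ is box-bounded in [−8, 5]; σ → 0 degrades gracefully to the
  plain GLM likelihood.
* All stochastic components consume explicit seeds; cohort streams spawn
  per-infant `SeedSequence` children so results are independent of
  consumption order.

## Problem sizes used by the test and acceptance suites

Oracle-equivalence suites run 1000 randomized small instances per
primitive. Noise-free fidelity uses a 2-infant cohort (112 trials).
Injected-effect recovery uses 100 replicates of the full 46-infant × 56-
trial design through the complete signal pipeline; LRT null calibration
uses 200 table-level replicates of a 16-infant design; quadratic recovery
uses 40 table-level replicates of the 46-infant design. The acceptance
script defaults to 25 full-pipeline replicates for its recovery summary.

## Known limitations

* The gaussian LMM supports a single random intercept (as the analyses
  require); no random slopes or crossed designs.
* The GLMM's Hessian-based SEs can be slightly optimistic near the σ = 0
  boundary; LRTs, not Wald tests, are the intended inference.
* LRTs for *between-infant* covariates (age, sex) are asymptotic in the
  number of infants and mildly anti-conservative at n = 46 infants; the
  null-calibration suite therefore checks a within-infant term, and
  between-cluster tests should be read with that caveat (as in the
  original analysis framework).
* The imputation chain assumes missingness is ignorable given the analysis
  columns; no sensitivity analysis for non-ignorable mechanisms is
  provided.
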