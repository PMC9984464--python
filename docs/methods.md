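# Methods

## The generative model

A simulated oddball session is a continuous pupil-diameter trace

    d(t) = b
         + a · [g_ISI · sin(2π f_ISI t + φ1) + g_TSI · sin(2π f_TSI t + φ2)]
         + Σ_events  A_cond · K(t − t_event)
         + c_drift · ξ_1/f(t)  +  ε(t)

with baseline `b` (5 mm), dimensionless entrainment gains `g_ISI`, `g_TSI`
scaling a base oscillation amplitude `a` (`osc_amp_mm`, default 0.15 mm) at
the beat frequency f_ISI = 1/1.2 s and the fourth-beat frequency
f_TSI = f_ISI/4, condition-specific evoked responses, a 1/f "slow wander"
component of SD `c_drift` (default 0.30 mm), and white measurement noise
ε (SD 0.15 mm).  Oscillation phases are redrawn per session: entrainment
phase is not assumed stable across sessions, and a fixed phase would let the
sinusoid interfere coherently with the evoked-response train at the same
frequency.

The evoked kernel is the standard pupillary response function of the
pupillometry literature, an Erlang/gamma-family curve
`K(t) = (t/t_max)^n · exp(n (1 − t/t_max))` with shape n = 10.1 and peak
latency t_max = 930 ms, peak-normalized to 1 so `evoked_amp` values read
directly as peak dilations in mm.  Any smooth unimodal ~1 s-lagged kernel
would serve; both parameters are exposed.

Blinks are dropout bursts of 100–400 ms at a Poisson rate (default
15/min) during which the sample is invalid (NaN) — the gap structure the
interpolators must handle.

Amplitude scales were chosen once so that the entrained oscillation is a
small fraction of total signal variance, as in real pupillometry where slow
wander and evoked responses dominate.  This matters for the scoring
statistic: z-scoring power across frequency bins saturates at √(n_bins)
when a single spectral line dominates the variance of the bin distribution,
and in that regime the score stops discriminating gains.  With a ≈ 0.15 mm
oscillation over a 0.30 mm 1/f background, the score is an approximately
monotone function of gain across the full simulated range (g ∈ [0, 2]),
which the recovery tests verify (Spearman > 0.8 over 50 subjects).

The behavioural observer is equal-variance Gaussian signal detection: a
target elicits a press with probability Φ(d′/2 − c), a non-target tone with
probability Φ(−d′/2 − c), presses landing 200–1000 ms after the tone.

A dyad is driven by a latent attention process A(t): an AR(1) on a 1 s
grid (coefficient 0.9, unit variance), upsampled with a cubic spline.  The
speaker's pupil follows A at 120 Hz; the listener mixes A (optionally
lagged; default lag 0, since the warping cost absorbs offsets) with an
independent process B as `coupling·A + (1−coupling)·B` at 30 Hz.
`coupling` ∈ [0, 1] is the ground truth that story-level synchrony must
recover ordinally.

## The task design

Tones every 1200 ms, five blocks of 160; proportions 65/20/10/5% for
standard/target/novel/omission.  Targets and omissions are exactly the
fourth-beat slots (20% + 5% = 25% of tones), randomly interleaved within
them.  Novel tones are drawn log-uniformly from 1320–5280 Hz and placed
randomly on beats 1–3: placing them "anywhere" would be arithmetically
incompatible with targets and omissions filling all fourth-beat slots, so
the design keeps fourth-beat closure and restricts novels to the other
beats.  All per-block condition counts are exact integers by construction;
inconsistent proportions raise a configuration error naming the violated
constraint.

## Preprocessing

Fixed order: interpolate gaps → despike → (detrend, continuous path only)
→ segment.  Two paths differ only in the interpolant: linear for the
trial-level path, cubic spline for the continuous/spectral path.  Leading
and trailing gaps take the nearest valid value.  Despiking is a 5-sample
median filter followed by a zero-phase (forward–backward) order-3
Butterworth low-pass at 10 Hz; at a 30 Hz sampling rate this attenuates a
12 Hz component to ~3% amplitude.  Segmentation cuts 3 s epochs at tone
onset ([onset, onset+3 s), 0-based sample grid), drops any trial with a raw
diameter below 2 mm, z-scores against the whole-session mean/SD (per-epoch
z-scoring would erase the amplitude differences the trial-feature analysis
needs; the scope is configurable, including `zscore="none"` for raw-unit
recovery tests) and subtracts the mean of the 100 ms before onset.  Trials
whose window or baseline leaves the trace are dropped with a recorded
reason, never raised.

QC: a session missing more than 90% of samples, or a listening trace with
more than 25% of samples interpolated, is unusable.  Both thresholds are
strict inequalities — exactly 90% or exactly 25% stays usable.

## Entrainment scoring

Per block (≥ 60 s required): demean, Hamming window, single-segment
periodogram (bin spacing rate/len).  Band power is summarized as the mean
z-score of in-band bins, where the z reference is the mean/SD of power over
all non-DC bins; the mean (not max or sum) keeps the statistic independent
of frequency resolution.  Zero-variance spectra return 0 instead of
dividing by zero.  The session score aggregates per-block (z_ISI + z_TSI)
by the mean — robust to a dropped block — with sum available.  Because both
numerator and reference scale together, the score is invariant to
multiplying the trace by any positive constant.

The z is taken across frequency bins, not across participants: a
cross-participant z could not yield the per-session scores the test–retest
reliability analysis requires.

## Dyadic synchrony

After anti-alias polyphase decimation of the speaker to the listener rate,
trimming to common support and per-story z-scoring, each 3 s window pair
(hop 1.5 s) is split into `n_segments` equal segments (default 10, i.e.
300 ms segments of ~9 samples at 30 Hz).  An alignment path starts at the
first segment pair, advances one segment on either signal or both, ends at
the last pair, and accrues the cosine distance (1 − cosine similarity) of
every segment pair it visits; the window cost is the minimal total penalty,
computed by dynamic programming and verified in the tests against
exhaustive enumeration of all admissible paths.  Costs are averaged within
non-overlapping 6 s bins (grouped by window start), log-transformed with
ε = 1e−6 to admit zero-cost windows, and negated so that larger story
values mean more synchrony and a positive regression slope reads as "more
entrained listeners synchronize more".

One wording choice deserves a note: describing the best-aligned pair as
having the *smallest cosine similarity* is backwards for similar vectors,
so the implementation minimizes cosine *distance*; with that reading,
identical windows cost exactly 0 and antipodal windows cost 2 per compared
segment.  Zero-norm segments are treated as orthogonal to everything
(distance 1) except to another zero segment (distance 0).

## Reliability contrasts

Response curves are per-condition means over kept (and, for targets,
correct) epochs.  Within-participant statistics pair every same-participant
session pair; between-participant statistics pair all cross-participant
session combinations (the larger set).  Curves are compared by Pearson r on
the raw curves (no Fisher transform — group means of r are reported
directly); scores by absolute cross-session differences, which makes
reliable individual differences show up as *smaller* within-participant
values and a negative Cohen's d.  The two sets are contrasted with a
two-sided Mann–Whitney U plus Cohen's d from the pooled SD (the d formula
is not otherwise pinned down by the U test).  Degenerate inputs (all values
identical) return U = n₁n₂/2, p = 1, d = 0 rather than dividing by zero.

Trial-response features are the three quantities entering the
supplementary regressions — amplitude (curve maximum), peak latency, and
width (total time above half-maximum) — the natural three-parameter
description of a unimodal response; width is reported missing for flat or
non-positive curves.

## Inference

The d′-on-entrainment regression standardizes both variables (slope =
standardized β) and reports β, t, p and adjusted R².  The feature
regressions standardize the three features, drop constant columns with a
flag, flag ill-conditioned designs (condition number > 1e3), and
Benjamini–Hochberg-adjust the per-coefficient p-values on request.

Story-level synchrony is modelled with a linear mixed model: fixed effect
of the standardized entrainment score, crossed random intercepts for
participant and story (fit by REML through statsmodels' MixedLM with two
variance components in a single group).  The outcome keeps its own scale so
a known generative coefficient is recovered as-is.  The default p-value
uses a between–within degrees-of-freedom approximation (df =
n_participants − 2, since the predictor varies only between participants);
a normal approximation is selectable.  Designs with a single story, or
fits that go singular, fall back to OLS on participant story-means with a
flag.

The permutation test shuffles the *participant-level* score vector —
every story of a participant keeps that participant's shuffled value, so
within-participant structure is never broken — and refits the mixed model
per shuffle; p = (1 + #{|β*| ≥ |β|}) / (n_perm + 1), two-sided, with floor
1/(n_perm+1).  The per-shuffle refits use a compact profiled-REML solver
for the two-variance-component model (variance ratios optimized by
Nelder–Mead on the log scale; a complete participant × story design is
solved in the joint eigenbasis of the two random-effect Gram matrices,
incomplete designs by dense Cholesky).  The solver is cross-checked against
statsmodels in the test suite — identical fixed-effect estimates on
balanced designs, and a REML objective never above statsmodels' — and
makes 1000-shuffle nulls and the 200-replicate type-I calibration cheap.

## What the simulations do and do not show

The generator reproduces the features the pipeline's correctness depends
on: exact design counts, entrained spectral lines at the task frequencies,
evoked responses with realistic latency, blink-gap structure, 1/f drift,
signal-detection behaviour, and attention-coupled dyads.  It does not
emulate luminance effects, gaze-position artifacts, saccade-related
transients, asymmetric blink edges, nonstationary entrainment, or semantic
story structure; passing tests therefore demonstrate that the *pipeline*
recovers what it claims from signals of this class, not that real pupil
data satisfy the model.  Test–retest reliability in the demo cohort is
built in by stable per-subject parameters, so reliability results there
validate the bookkeeping and statistics, not a psychological claim.

## Problem sizes and numerical choices

Recovery and calibration tests run at the sizes their claims name:
50 subjects for gain recovery, 30 dyads per coupling level, 4000 trials for
d′, 100 cohorts for mixed-model recovery, and 200 replicates × 200
permutations for type-I calibration (24 participants × 4 stories per
cohort).  The demo analysis cohort uses 12 participants × 2 sessions ×
4 stories at the full task design.  Other defaults: ε = 1e−6 in the log
transform; random seeds thread through every generator so all results are
exactly reproducible from (config, seed); all interchange formats are
plain tab-separated text stamped with a hash of the scientific
configuration.

## Known limitations

- The band-z score saturates when a single spectral line dominates the
  bin-power distribution (z → √n_bins); gains far outside the simulated
  range, or nearly noise-free signals, compress toward a ceiling.
- The between–within df approximation is deliberately simple; exact
  Satterthwaite/Kenward–Roger fractional df are out of scope, and p-values
  for small cohorts should lean on the permutation test.
- Press classification assigns each press to the most recent tone slot
  within one ISI and counts at most one press per slot; response-time
  modelling is out of scope.
- The story-level synchrony value weights all 6 s bins equally; no
  emotional-salience or content weighting is attempted.
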