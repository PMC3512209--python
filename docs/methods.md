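# Methods

## The generative model

Sessions emulate steady-state performance on a 40-s peak-interval task:
each session mixes 20 reinforced fixed-interval (FI) trials, 14
non-reinforced probe (PI) trials lasting three criteria (120 s), and 6
probe trials with a 5-s noise distracter starting 5 s into the trial
(PIN), presented in a uniformly random seeded order.

On a trial **with temporal control**, pressing follows a low-high-low
profile: a latent start time s ~ N(f_start·T, (cv_start·f_start·T)²) and
stop time e ~ N(f_stop·T, (cv_stop·f_stop·T)²) (resampled until
0 < s < e < trial duration) gate an inhomogeneous Poisson train with rate
`rate_low` outside [s, e] and `rate_high` inside. The proportional SDs
implement scalar variability, the signature property of interval timing.
With probability `p_no_control` a trial instead presses uniformly at
`rate_low` and carries no latent times — the "trials without temporal
control" that single-trial analyses must screen out.

Defaults: f_start = 0.7, f_stop = 1.4, cv = 0.2, rate_low = 0.1/s,
rate_high = 1.5/s, p_no_control = 0.2. These place fitted peaks near
(slightly above) the criterion with realistic widths, and make roughly a
fifth of trials uninformative, matching the magnitudes such experiments
report. FI trials end at the first press at or after T (the reward time);
if no press occurs within a grace period of one further criterion the
trial times out at 2T un-rewarded — the no-press policy is a convention
of this generator, exposed as `fi_grace`.

**Distracter modes.** In PIN trials both latent times are rigidly
translated — the distracter shifts the timing function without changing
its width — by 0 (`run`), d1 (`stop`), d1 + d2 (`reset`), or
d1 + d2 + X with X ~ Exponential(mean = `salience_lambda`)
(`over_reset`). The exponential extra delay embodies a resource-sharing
account in which attentional/working-memory resources return to timing
only some time after a salient distracter ends; λ scales with the
distracter's salience. Shifted stops are truncated at the trial end and
flagged.

**Freezing.** Conditioned fear is generated as independent Bernoulli
2.5-s bins: probability `p_base` before the noise in both groups
(default 0.05); for the FEAR group `p_high` (default 0.875) during the
noise, decaying exponentially after its offset with time constant
`tau_decay` (default 90 s) back to baseline. The defaults mirror the
magnitudes reported for such preparations (high during-noise freezing
persisting for minutes). Bins are independent given the rate profile —
real freezing bouts are autocorrelated, so agreement and variance
figures on synthetic data are optimistic in that respect.

## Response-curve fitting

Presses from probe trials are counted in half-open 4-s bins (the last
bin closed) over (0, 100) s for PI and (20, 120) s for PIN trials and
divided by n_trials × bin width to give a mean rate function. The model

R(t) = a·exp(−(t − t0)²/(2b²)) + c·t + d0

is fit by bounded nonlinear least squares (scipy's trust-region
reflective solver; tolerances 1e-12). Initialization: t0 at the argmax
bin, a at the rate range, b at one sixth of the window, c = 0, d0 at the
minimum rate; if that start fails, a 3 × 3 grid over (t0, b) is tried
and the best SSE kept. Failure is reported as `converged = False` with a
reason, never raised.

Two constraints are part of the model, not conveniences: a ≥ 0 and
d0 ≥ 0, because the response rate is non-negative and the Gaussian
component represents a peak. Without them the global SSE optimum on
weak-peaked curves (few trials, several without temporal control) is a
degenerate "shoulder" — t0 at the window bound, b wider than the window,
a large negative intercept — which is not a peak-time estimate at all.

A fit additionally carries `peak_resolved`: the ±1 SD core of the
Gaussian must lie inside the analysis window (t0 ± b within it) and
b must exceed half a bin. Fits failing this describe a monotone shoulder
or a sub-bin spike; delay computation drops such subjects with a logged
reason. Width is reported as the Gaussian SD b, with FWHM = 2.3548 b as
a derived field. Max-percent normalization (maximum bin scaled to 100)
is presentation-only; fitting is done on raw rates, and the peak-time
estimate is invariant to the scaling.

## Single-trial start/stop extraction

Within a window of length T′ the index

I(t1, t2) = t1′(r − r1) + (t2 − t1)(r2 − r) + (T′ − t2′)(r − r3)

(primes: times from window start; r the overall window rate; r1/r2/r3
the segment rates) is maximized exhaustively over ordered pairs of
candidates — the in-window press times plus the window edges. Presses at
t1 or t2 count toward the middle segment; ties break to the earliest
start, then earliest stop, making the output deterministic. The search
is exact: the index decomposes into separate t1 and t2 terms, evaluated
over all pairs.

A trial has temporal control iff r2 exceeds the overall rate, the
flanking rates are at most f·r2 (default f = 0.5), and the estimated
start/stop straddle the criterion (start < T < stop). For PIN trials in
the FEAR group, where the distracter disrupts early responding, the
analysis window is the post-noise (20, 120) s and the start-related
clauses are skipped. The thresholds are a configurable stand-in for the
conservative published criteria (which are not printed in full anywhere);
with the generator defaults they exclude ≈ 20% of trials, consistent
with the mixture proportion that generated them. Summaries report per
subject × drug × trial type the mean start/stop and their coefficients
of variation (sample SD / mean over valid trials; absent with < 2 valid
trials).

## Delay classification

Per subject, delay = t0(PIN) − t0(PI) from converged, peak-resolved
fits. Against benchmarks {run: 0, stop: d1, reset: d1 + d2}, a sample of
delays is labeled by one-sample t-tests at α = 0.05: `over_reset` if
one-sidedly greater than the reset benchmark; `run` if not reliably
different from 0; otherwise the nearest benchmark whose two-sided test
is not rejected; `indeterminate` otherwise. A single subject falls back
to the nearest benchmark within a 2-s tolerance. Testing the delay
sample against each analytic benchmark is the field's usual logic; the
single-subject rule and the precedence order are this package's choices.

## Mixed ANOVA

The split-plot decomposition is computed from classical raw sums of
squares R(C) = Σ cells (total²/size) with subject as a random block
nested in group: the group effect is tested against subjects-within-
groups; each within effect and its interaction with group against its
own factor × subject stratum. Designs must be balanced (every subject in
every within cell exactly once; missing cells are reported by subject).
Within factors are limited to two levels — the designs used here — so
sphericity corrections are unnecessary; factors with more levels are
refused rather than silently uncorrected. Planned comparisons test a
two-cell contrast against either the pooled ANOVA error stratum
(default) or a cell-wise error. Zero-variance t-tests report a
machine-epsilon p with a flag rather than dividing by zero.

## Validation scales and what they show

The test suite validates each stage against independent oracles:
brute-force enumeration for the change-point index, a 4-D parameter grid
for the fit SSE, binomial/Poisson standard errors for the generator's
rates, an independently coded textbook split-plot computation and
pingouin's mixed ANOVA for the statistics, and a 2,000-replicate null
simulation for the type-I error rate. End-to-end, cohorts of 12 subjects
(20 PI + 6 PIN trials each) recover mean delays within ±1.5 s of the
0 / 5 / 10 s benchmarks, and over-reset cohorts (λ = 5 s) are labeled
as such in ≥ 90% of 50 replicates. The benchmark-recovery script
averages 10 replicate cohorts per mode (120 subjects) to keep the
Monte-Carlo error of the reported mean well inside that tolerance;
single cohorts of 12 have a mean-delay SD of about 1 s.

Passing these tests shows the analysis recovers what this generative
model encodes. Real operant data differ in ways the generator does not
model: acquisition and motivation dynamics across a session, bout
structure in pressing (non-Poisson inter-press intervals), partial or
per-trial mixtures of clock responses to a distracter, and reward
interactions in FI trials. Conclusions about the analysis code transfer;
conclusions about effect sizes in real data do not.

## Known limitations

- Only trained steady-state behavior is generated; no
  learning/pharmacokinetic dynamics (drug conditions differ only through
  the configured distracter mode and salience).
- The distracter acts as a rigid translation of the latent times; the
  generator does not model within-subject mixtures of run/stop/reset
  responses across trials.
- The ANOVA layer intentionally refuses > 2-level within factors.
- Inter-trial intervals are configured but not placed on a session
  clock; all analyses are in trial-relative time.
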