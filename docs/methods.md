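# Methods

## The measurement problem

The package operationalises a simple idea: on a task whose binary outcome
sequence is genuinely random, the *reach into the past* of a subject's
predictions identifies their learning rate.  A delta-rule learner with
rate R holds strength

    W_t = R · Σ_{k≥0} (1−R)^k · S_{t−1−k} + (1−R)^{t−1} · w0,

an exponentially weighted history of stimuli, so the correlation of the
current prediction with the stimulus n trials back decays geometrically
at (1−R) per lag.  R = 1 yields perfect lag-1 correlation and none
beyond; R → 0 yields weak but long-reaching influence.  The influence
profile (phi per lag, 1..10) is therefore a non-parametric learning-rate
read-out, and the grid fit a parametric one.

## Model and simulation semantics

Two processes run per trial on S ∈ {0, 1} (1 = right):

- Rescorla–Wagner: `W ← W + R·(S − W)`; the prediction error is S − W
  (the delta rule's convex form).
- Gambler's fallacy: `G ← R_gf·(1−S) + (1−R_gf)·G`, pulled toward the
  *opposite* of the last outcome.  Algebraically this is the delta rule
  applied to the flipped sequence 1−S, an identity the tests assert
  exactly.
- Mixture: `T = p·W + (1−p)·G`.

Both updates are convex combinations, so W, G, T ∈ [0, 1] for any
parameters in [0, 1] (property-tested).  A single always-on context unit
drives the learner; tone/no-tone context is *not* modelled as separate
associative cues — context sensitivity is examined only through filtered
influence profiles.

Within a trial the simulated agent responds from the current T and only
then observes the stimulus and updates: the prediction precedes the
outcome in the task, which forces this order.  Initial strengths default
to w0 = g0 = 0.5 (neutral ignorance); both are exposed as parameters.

Response policies: `threshold` (1 if T > 0.5, 0 if T < 0.5, seeded fair
coin at exactly 0.5 — unbiased and reproducible) and `probabilistic`
(Bernoulli(T)).  Thresholding makes moderate-rate agents respond almost
deterministically (any T > 0.5 maps to the same response), which
collapses the profile differences between rates; cohort simulations
therefore default to the probabilistic policy, whose phi magnitudes also
sit closer to human scale.

## Influence profile

Phi at lag k is the Pearson correlation over pairs (response_t,
stimulus_{t−k}) for all current trials t > k that pass the filter.  It is
computed from integer sums, so perfectly (anti-)aligned vectors give
exactly ±1, and it equals the 2×2 contingency-table coefficient
(ad−bc)/√((a+b)(c+d)(a+c)(b+d)) wherever both are defined — asserted
against that independent formula in the tests.  A constant response or
stimulus column makes phi undefined; undefined values propagate as NaN,
are excluded from per-subject summaries, and subjects undefined on a
measure are dropped from that group analysis.

Filters (context, attribution) condition on the **current trial only**:
the tone/no-tone split classifies the trial on which the prediction is
made, while the past trial may be of either type.  This is a documented
reading choice; conditioning the past trial's context as well is a
different analysis that the package does not implement.

Summaries are unweighted means of the defined member lags — recent =
lags 1–2, distant = lags 4–10, overall = 1–10 — never pair-count
weighted.  Lag 3 enters no summary (gambler's-fallacy predominance).

## Grid fit

`DualProcessGridSearch` evaluates the MSE between T and the 0/1 responses
at every lattice point (11³ at step 0.1, endpoints included), driving the
strengths with the stimulus sequence only (never the subject's own
responses) and averaging over **all** trials, including trial 1 where T
comes from the initial strengths.  The implementation vectorises over the
lattice; a per-trial Python loop oracle must agree to 1e−12 at every
point (tested).  Ties within 1e−12 of the minimum are all recorded;
the reported triple is the tie with the lowest r_learn, then r_gf, then
p_mix — a deterministic, reproducible convention, not a claim about the
original analysts' rule.  On random sequences the error surface is flat
around its minimum, so recovery is assessed on cohort means: at true
rates 0.2/0.5/0.8 (100 sessions each) mean fitted rates are strictly
increasing and within 0.15 of truth.

## Inference layer

t tests (one-sample, paired, Welch/pooled two-sample) delegate to scipy
and report t, df, two-sided p, a 95% CI, and pooled-SD Cohen's d (dz for
within-subject contrasts); results are verified against textbook formulas
to 1e−10.  Identical paired samples return the degenerate t = 0, dz = 0
rather than an error.  No multiple-testing correction is applied
anywhere, matching the analysis style the package reproduces; directional
hypotheses are handled by the Bayes factor, not one-tailed p values.

The half-normal Bayes factor treats the data likelihood as normal in the
observed effect (the reproduction-critical choice; a t likelihood would
give slightly different values) and the directional theory as a
half-normal on θ ≥ 0 with scale set a priori — here from pilot means:
0.10 for recent influences, 0.01 for distant.  Primary computation is
adaptive quadrature on [0, 5·max(prior_sd, se + |obs|)] with breakpoints
at multiples of both scales (so a prior much narrower than the likelihood
is still resolved), relative tolerance 1e−6; a Gaussian-product closed
form (scaled normal density × normal CDF) serves as an independent
cross-check to 1e−6 relative error.  The quadrature route is kept primary
because it extends transparently to non-normal priors.

## Synthetic cohorts

`simulate_group` draws each subject's (r_learn, r_gf, p_mix) from
truncated normals on [0, 1] — exact truncated sampling, not clipping,
which would distort the means — runs a fresh seeded sequence, and
simulates the responder.  Preset means/SDs for the two rates are the
published model-based group estimates (controls .63/.32 and .43/.35,
amnesic-like .80/.14 and .46/.40, happy .51/.34 and .58/.32, sad .63/.33
and .46/.37).  No group p value is published; all presets share
p ~ TN(0.70, 0.20), a free choice fixed once.

Attribution labels (guess vs confident) are a **synthetic stand-in**:
there is no published generative account linking confidence to strength,
so a trial is labelled confident when |T − 0.5| exceeds a threshold δ,
and δ is calibrated as the pooled conviction quantile that yields a
target guess fraction (default 0.66).  Passing attribution tests shows
the analysis path works, not that this confidence mechanism is the human
one.

What the generator emulates: session length (300 trials), iid
Bernoulli(0.5) stimuli, the tone (every fourth trial silent), probability-
block (p_right .40×120, .50×40, .60×120, counterbalanced order) and mood
(half of trials, randomly intermixed) schedules, and between-subject
parameter heterogeneity.  What it does not: reaction times, fatigue or
drift within a session, mood-rating data, response biases beyond the two
processes, and any context-specific associative weighting.  Human phi
magnitudes are smaller than the Bernoulli(T) responder's, so synthetic
group contrasts replicate the *directions* and orderings of the human
results, not their numerical values.

## Experiment replicas and problem sizes

`run_experiment_replica` wires the cohorts through the analysis paths
with default group sizes mirroring the human studies (34; 60; 50; 40/40;
27/29).  Test problem sizes were chosen so each check's Monte-Carlo error
is comfortably below the tested effect: 200 agents for the rate-1 and
null signatures, 500 sessions for the geometric-decay ratio (at r = 0.3
the lag-(n+1)/lag-n mean-phi ratio approaches 0.7), 100 sessions per
level for recovery, and 12 replicate 40/40 runs for the synthetic
amnesic-vs-controls contrast.  The last is aggregated across replicate
runs because the preset effect size (d ≈ 0.4 per contrast, a consequence
of the published between-subject rate SDs) puts single-run power near
40%; the aggregate tests the direction of the run-level differences at
conventional significance.  For partial probability-block tracking, the
post-switch transient lasts ~1/R trials, so the test uses a slow learner
(R = .05) and 300-trial blocks where that transient is resolvable against
Monte-Carlo noise.

## Known limitations

- Grid estimates are lattice-resolution bounded (±0.05 at best) and
  noisy per session on random sequences; use cohort means.
- The influence profile assumes iid schedules; for non-iid (block)
  schedules inter-trial dependence is not partialed out, and the package
  reports only the block response-shift summary there.
- The normal-likelihood Bayes factor ignores small-sample t-tail
  corrections; with the df involved here the effect is negligible
  relative to the prior-scale choice, but it is a convention, not a
  theorem.
- Phi is undefined on constant columns; heavily filtered profiles (e.g.
  rare attribution labels) can lose subjects from group summaries, which
  the t tests handle by dropping NaN subjects and reporting reduced df.
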