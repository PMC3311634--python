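# implearn

Tools for measuring the **rate of implicit learning** from a rapid binary
prediction task, for cognitive and clinical researchers who want a
trial-cheap learning-rate assay: simulate the task and model responders,
compute the lag-correlation *influence profile*, fit the dual-process
trial-by-trial model by exhaustive grid search, and run the group-level
inference (t tests, effect sizes, half-normal Bayes factors).

## The method

A subject predicts, on each of ~300 trials, whether a square will appear
on the left or right; the sequence is in fact iid Bernoulli(0.5), coded
S = 1 for right, 0 for left.  Because the structure is random, any
sensitivity of the current prediction to past stimuli is learning — and
*how far back* that sensitivity reaches identifies the learning rate.

**Influence profile.** For each lag n = 1..10, compute the phi (Pearson)
correlation between the current response and the stimulus n trials back.
A learner with rate R = 1 copies the last trial: phi = 1 at lag 1 and 0
beyond.  Smaller R spreads influence geometrically (ratio 1 − R per lag).
Summaries: *recent* influence = mean of lags 1–2, *distant* = mean of
lags 4–10; lag 3 is excluded from both because the gambler's fallacy
predominates there.

**Dual-process model.** Two strength processes for predicting "right" run
in parallel and are fitted jointly so the gambler's fallacy cannot
masquerade as (negative) learning:

- Rescorla–Wagner / delta rule: `W ← W + R·(S − W)`
- gambler's fallacy: `G ← R_gf·(1 − S) + (1 − R_gf)·G`
- overall strength: `T = p·W + (1 − p)·G`

All three parameters take values 0, 0.1, …, 1; the 11×11×11 lattice is
searched exhaustively for the combination minimising the mean squared
error between T and the subject's 0/1 responses over all trials.

**Inference.** Directional theories are evaluated with half-normal-prior
Bayes factors: `B = [∫₀^∞ 2·N(θ; 0, σ_prior)·N(d_obs; θ, SE) dθ] /
N(d_obs; 0, SE)`, with the prior SD set from pilot effect sizes (0.10 for
recent influences, 0.01 for distant).  Independent B's multiply.

## Worked example

```python
import implearn as il

seq = il.generate_random_sequence(300, p_right=0.5, seed=7)
agent = il.AgentParams(r_learn=0.6, r_gf=0.3, p_mix=0.8,
                       policy="probabilistic", seed=11)
session = il.simulate_session(seq, agent)

prof = il.lag_profile(session)
print(prof.correlations.round(3))
# [ 0.397  0.153  0.029  0.019 -0.019 -0.049 -0.128 -0.07  -0.053 -0.008]
print(f"recent {prof.recent:.3f}  distant {prof.distant:.3f}")
# recent 0.275  distant -0.044

fit = il.grid_fit(session)
print(fit.r_learn, fit.r_gf, fit.p_mix, round(fit.mse, 4))
# 0.7 0.1 0.6 0.2042
```

The profile shows the moderate-rate signature: strong influence at lag 1
(0.397) decaying over the next few lags toward zero, with recent
influence (0.275) far exceeding distant (−0.044).  The grid fit recovers
the generating parameters (0.6, 0.3, 0.8) up to the lattice resolution
and the flatness of the error surface on random sequences — single-session
estimates are noisy by design; group means are the meaningful quantity.

The `DualProcessGridSearch` estimator behind `grid_fit` follows the
scikit-learn protocol (`fit(stimuli, responses)`, fitted attributes
`r_learn_`, `r_gf_`, `p_mix_`, `mse_`, `ties_`) and composes with sklearn
tooling.

A Bayes factor for a recent-influence group difference of 0.10 with
t = 2.54 under the 0.10 pilot prior:

```python
il.bayes_factor_halfnormal(0.10, 0.10 / 2.54, 0.10).b   # 11.85
```

Synthetic cohorts emulating the task's study designs (tone context,
probability blocks, guess attribution, amnesic vs controls, mood
induction) are available via `implearn.make_cohort_spec`,
`implearn.simulate_group` and `implearn.run_experiment_replica`, and from
the command line:

```bash
implearn simulate --preset controls --n-subjects 50 --seed 1 --out cohort/
implearn fit cohort/controls_000.csv
implearn replica exp3_amnesic --seed 1
implearn bf --obs-diff 0.10 --t 2.54 --prior-sd 0.10
```

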