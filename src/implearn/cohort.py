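"""Synthetic cohorts of simulated subjects and experiment replicas.

Each subject draws their three model parameters from truncated normals on
[0, 1] (so group means are respected without clipping artefacts), runs a
fresh 300-trial random sequence, and responds through the dual-process
model.  The preset group means and SDs for the learning and
gambler's-fallacy rates are the published model-based estimates for the
corresponding populations:

===========  =================  ================
preset       r_learn (mean/SD)  r_gf (mean/SD)
===========  =================  ================
controls     .63 / .32          .43 / .35
amnesic      .80 / .14          .46 / .40
happy        .51 / .34          .58 / .32
sad          .63 / .33          .46 / .37
===========  =================  ================

No group-level mixture weight p is published; all presets share
p ~ TN(0.70, 0.20), a free modelling choice documented in the methods
note.  The experiment replicas wire these cohorts through the profile and
inference layers and report the same statistics the human analyses use.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import stats

from .agents import CONFIDENT, GUESS, AgentParams, Session, simulate_session
from .inference import (
    TTestResult,
    bayes_factor_halfnormal,
    combine_bfs,
    one_sample_t,
    paired_t,
    two_sample_t,
)
from .profile import (
    attribution_split,
    block_response_shift,
    by_context,
    lag_profile,
)
from .sequences import (
    MOOD,
    NEUTRAL,
    NO_TONE,
    TONE,
    BlockSpec,
    generate_block_sequence,
    generate_mood_schedule,
    generate_random_sequence,
    generate_tone_schedule,
)

__all__ = [
    "ParamDist",
    "CohortSpec",
    "PRESETS",
    "EXPERIMENT_NAMES",
    "make_cohort_spec",
    "simulate_group",
    "assign_attributions",
    "calibrate_attribution_delta",
    "run_experiment_replica",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal parameter distribution on [0, 1]."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("mean must lie in [0, 1]")
        if self.sd < 0.0:
            raise ValueError("sd must be non-negative")

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(size, self.mean)
        a = (0.0 - self.mean) / self.sd
        b = (1.0 - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class CohortSpec:
    """A seeded group of simulated subjects.

    ``design`` selects the sequence/context generator: "plain" (random
    stimuli, no context), "tone" (random stimuli, silent every fourth
    trial), "mood" (random stimuli, half mood-inducing trials) or
    "blocks" (drifting stimulus probability; block order alternates
    between subjects, emulating counterbalancing).
    """

    n_subjects: int
    r_learn: ParamDist
    r_gf: ParamDist
    p_mix: ParamDist = ParamDist(0.70, 0.20)
    design: str = "plain"
    n_trials: int = 300
    blocks: BlockSpec | None = None
    first_no_tone: int = 4
    policy: str = "probabilistic"
    condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")
        if self.design not in ("plain", "tone", "mood", "blocks"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "blocks" and self.blocks is None:
            raise ValueError("blocks design requires a BlockSpec")


PRESETS: dict[str, dict[str, ParamDist]] = {
    "controls": {"r_learn": ParamDist(0.63, 0.32), "r_gf": ParamDist(0.43, 0.35)},
    "amnesic": {"r_learn": ParamDist(0.80, 0.14), "r_gf": ParamDist(0.46, 0.40)},
    "happy": {"r_learn": ParamDist(0.51, 0.34), "r_gf": ParamDist(0.58, 0.32)},
    "sad": {"r_learn": ParamDist(0.63, 0.33), "r_gf": ParamDist(0.46, 0.37)},
}


def make_cohort_spec(preset: str, n_subjects: int, seed: int, **overrides) -> CohortSpec:
    """Build a :class:`CohortSpec` from a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; use one of {sorted(PRESETS)}")
    kwargs: dict = dict(PRESETS[preset])
    kwargs.update(n_subjects=n_subjects, seed=seed, condition=preset)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _make_sequence(spec: CohortSpec, subject_index: int, seq_seed: int):
    if spec.design == "blocks":
        reverse = bool(subject_index % 2)  # counterbalance block order
        seq = generate_block_sequence(spec.blocks, reverse=reverse, seed=seq_seed)
        return seq, None, reverse
    seq = generate_random_sequence(spec.n_trials, 0.5, seq_seed)
    if spec.design == "tone":
        return seq, generate_tone_schedule(spec.n_trials, spec.first_no_tone), False
    if spec.design == "mood":
        return seq, generate_mood_schedule(spec.n_trials, seq_seed + 1), False
    return seq, None, False


def simulate_group(
    spec: CohortSpec, return_params: bool = False
) -> list[Session] | tuple[list[Session], list[AgentParams]]:
    """Simulate every subject of a cohort, fully seed-deterministically."""
    rng = np.random.default_rng(spec.seed)
    r_learns = spec.r_learn.draw(spec.n_subjects, rng)
    r_gfs = spec.r_gf.draw(spec.n_subjects, rng)
    p_mixes = spec.p_mix.draw(spec.n_subjects, rng)
    child_seeds = rng.integers(0, _MAX_SEED, size=(spec.n_subjects, 2))
    sessions: list[Session] = []
    drawn: list[AgentParams] = []
    for i in range(spec.n_subjects):
        params = AgentParams(
            r_learn=float(r_learns[i]),
            r_gf=float(r_gfs[i]),
            p_mix=float(p_mixes[i]),
            policy=spec.policy,
            seed=int(child_seeds[i, 0]),
        )
        seq, ctx, _ = _make_sequence(spec, i, int(child_seeds[i, 1]))
        label = f"{spec.condition or 'sim'}_{i:03d}"
        sessions.append(
            simulate_session(seq, params, ctx, subject_id=label, condition=spec.condition)
        )
        drawn.append(params)
    return (sessions, drawn) if return_params else sessions


def assign_attributions(session: Session, delta: float) -> Session:
    """Label trials guess/confident from the recorded strength.

    A trial is labelled confident when the model's conviction |T - 0.5|
    exceeds ``delta``, otherwise guess.  This is a synthetic stand-in for
    human metacognitive reports — the underlying data give no generative
    account of confidence — used to exercise the attribution analyses.
    """
    if session.strength is None:
        raise ValueError("session has no recorded strengths")
    if not 0.0 <= delta <= 0.5:
        raise ValueError("delta must lie in [0, 0.5]")
    conviction = np.abs(session.strength - 0.5)
    labels = np.where(conviction > delta, CONFIDENT, GUESS).astype(object)
    return session.with_attribution(labels)


def calibrate_attribution_delta(
    sessions: list[Session], target_guess_fraction: float = 0.66
) -> float:
    """Delta such that the cohort's pooled guess fraction hits the target.

    Since guess <=> |T - 0.5| <= delta, the calibrated delta is the
    target-quantile of the pooled conviction distribution.
    """
    if not 0.0 < target_guess_fraction < 1.0:
        raise ValueError("target_guess_fraction must lie in (0, 1)")
    conviction = np.concatenate(
        [np.abs(s.strength - 0.5) for s in sessions if s.strength is not None]
    )
    if conviction.size == 0:
        raise ValueError("no session has recorded strengths")
    return float(np.quantile(conviction, target_guess_fraction))


EXPERIMENT_NAMES = (
    "exp1_tone",
    "exp1_blocks",
    "exp2_guess",
    "exp3_amnesic",
    "exp4_mood",
)

# half-normal prior scales from the pilot study: mean recent influence .10,
# mean distant influence .01
PRIOR_SD_RECENT = 0.10
PRIOR_SD_DISTANT = 0.01


def _t_dict(res: TTestResult) -> dict:
    d = asdict(res)
    d["ci"] = list(d["ci"])
    return d


def _recent_distant(sessions: list[Session]) -> tuple[np.ndarray, np.ndarray]:
    profiles = [lag_profile(s) for s in sessions]
    return (
        np.array([p.recent for p in profiles]),
        np.array([p.distant for p in profiles]),
    )


def _replica_exp1_tone(seed: int, n_subjects: int) -> dict:
    spec = make_cohort_spec("controls", n_subjects, seed, design="tone")
    sessions = simulate_group(spec)
    tone = np.array(
        [lag_profile(s, trial_filter=by_context(TONE)).overall for s in sessions]
    )
    no_tone = np.array(
        [lag_profile(s, trial_filter=by_context(NO_TONE)).overall for s in sessions]
    )
    return {
        "experiment": "exp1_tone",
        "n_subjects": n_subjects,
        "mean_overall_tone": float(np.nanmean(tone)),
        "mean_overall_no_tone": float(np.nanmean(no_tone)),
        "tone_vs_no_tone": _t_dict(paired_t(tone, no_tone)),
        "tone_vs_zero": _t_dict(one_sample_t(tone)),
        "no_tone_vs_zero": _t_dict(one_sample_t(no_tone)),
    }


def _replica_exp1_blocks(seed: int, n_subjects: int) -> dict:
    # p_left runs .60 -> .50 -> .40, i.e. p_right .40 -> .50 -> .60
    blocks = BlockSpec(((120, 0.40), (40, 0.50), (120, 0.60)))
    spec = make_cohort_spec(
        "controls", n_subjects, seed, design="blocks", blocks=blocks, n_trials=280
    )
    sessions = simulate_group(spec)
    stim_shifts, resp_shifts = [], []
    for i, session in enumerate(sessions):
        subject_blocks = blocks.reversed() if i % 2 else blocks
        stim, resp = block_response_shift(session, subject_blocks)
        sign = -1.0 if i % 2 else 1.0  # align the counterbalanced halves
        stim_shifts.append(sign * stim)
        resp_shifts.append(sign * resp)
    return {
        "experiment": "exp1_blocks",
        "n_subjects": n_subjects,
        "mean_stimulus_shift": float(np.mean(stim_shifts)),
        "mean_response_shift": float(np.mean(resp_shifts)),
        "response_shift_vs_zero": _t_dict(one_sample_t(resp_shifts)),
    }


def _replica_exp2_guess(seed: int, n_subjects: int) -> dict:
    spec = make_cohort_spec("controls", n_subjects, seed)
    sessions = simulate_group(spec)
    delta = calibrate_attribution_delta(sessions, 0.66)
    sessions = [assign_attributions(s, delta) for s in sessions]
    guess_frac = float(
        np.mean([np.mean(s.attribution == GUESS) for s in sessions])
    )
    guess_overall, sure_overall = [], []
    for s in sessions:
        guess_prof, sure_prof = attribution_split(s)
        guess_overall.append(guess_prof.overall)
        sure_overall.append(sure_prof.overall)
    return {
        "experiment": "exp2_guess",
        "n_subjects": n_subjects,
        "attribution_delta": delta,
        "guess_fraction": guess_frac,
        "mean_overall_guess": float(np.nanmean(guess_overall)),
        "mean_overall_sure": float(np.nanmean(sure_overall)),
        "guess_vs_zero": _t_dict(one_sample_t(guess_overall)),
    }


def _replica_exp3_amnesic(seed: int, n_subjects: int) -> dict:
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, _MAX_SEED, size=2)
    amn = simulate_group(make_cohort_spec("amnesic", n_subjects, int(seeds[0])))
    con = simulate_group(make_cohort_spec("controls", n_subjects, int(seeds[1])))
    amn_rec, amn_dis = _recent_distant(amn)
    con_rec, con_dis = _recent_distant(con)
    return {
        "experiment": "exp3_amnesic",
        "n_per_group": n_subjects,
        "mean_recent_amnesic": float(np.nanmean(amn_rec)),
        "mean_recent_controls": float(np.nanmean(con_rec)),
        "mean_distant_amnesic": float(np.nanmean(amn_dis)),
        "mean_distant_controls": float(np.nanmean(con_dis)),
        "recent_amnesic_vs_controls": _t_dict(
            two_sample_t(amn_rec, con_rec, unequal_var=True)
        ),
        "distant_controls_vs_amnesic": _t_dict(
            two_sample_t(con_dis, amn_dis, unequal_var=True)
        ),
    }


def _replica_exp4_mood(seed: int, n_subjects: int | None) -> dict:
    n_sad, n_happy = (n_subjects, n_subjects) if n_subjects else (27, 29)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, _MAX_SEED, size=2)
    sad = simulate_group(make_cohort_spec("sad", n_sad, int(seeds[0]), design="mood"))
    happy = simulate_group(
        make_cohort_spec("happy", n_happy, int(seeds[1]), design="mood")
    )
    sad_rec, sad_dis = _recent_distant(sad)
    hap_rec, hap_dis = _recent_distant(happy)
    rec_test = two_sample_t(sad_rec, hap_rec, unequal_var=False)
    dis_test = two_sample_t(sad_dis, hap_dis, unequal_var=False)
    bf_rec = bayes_factor_halfnormal(rec_test.mean, rec_test.se, PRIOR_SD_RECENT)
    bf_dis = bayes_factor_halfnormal(dis_test.mean, dis_test.se, PRIOR_SD_DISTANT)
    return {
        "experiment": "exp4_mood",
        "n_sad": n_sad,
        "n_happy": n_happy,
        "mean_recent_sad": float(np.nanmean(sad_rec)),
        "mean_recent_happy": float(np.nanmean(hap_rec)),
        "mean_distant_sad": float(np.nanmean(sad_dis)),
        "mean_distant_happy": float(np.nanmean(hap_dis)),
        "recent_sad_vs_happy": _t_dict(rec_test),
        "distant_sad_vs_happy": _t_dict(dis_test),
        "bf_recent": bf_rec.b,
        "bf_distant": bf_dis.b,
        "bf_overall": combine_bfs([bf_rec.b, bf_dis.b]),
    }


def run_experiment_replica(
    name: str, seed: int = 0, n_subjects: int | None = None
) -> dict:
    """Generate a synthetic cohort for one experiment design and run its
    analysis path end-to-end, returning a JSON-serialisable report.

    Default cohort sizes mirror the human studies (34, 60, 50, 40/40,
    27/29); pass ``n_subjects`` to override (per group where grouped).
    """
    if name == "exp1_tone":
        return _replica_exp1_tone(seed, n_subjects or 34)
    if name == "exp1_blocks":
        return _replica_exp1_blocks(seed, n_subjects or 60)
    if name == "exp2_guess":
        return _replica_exp2_guess(seed, n_subjects or 50)
    if name == "exp3_amnesic":
        return _replica_exp3_amnesic(seed, n_subjects or 40)
    if name == "exp4_mood":
        return _replica_exp4_mood(seed, n_subjects)
    raise ValueError(f"unknown experiment {name!r}; use one of {EXPERIMENT_NAMES}")
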