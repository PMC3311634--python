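"""Dual-process trial-by-trial responders.

Two strength processes run in parallel over a binary stimulus stream S
(1 = right, 0 = left):

* a Rescorla-Wagner (delta-rule) learner, ``W <- W + R*(S - W)``, driven by
  a single always-on context unit, which moves its prediction strength for
  "right" toward whatever just happened;
* a gambler's-fallacy process, ``G <- R*(1 - S) + (1 - R)*G``, which moves
  toward predicting the *opposite* of the last stimulus.

The overall prediction strength is the mixture ``T = p*W + (1-p)*G``.
Within a trial the agent first responds from the current T, then observes
the stimulus and updates both processes; the prediction necessarily
precedes the outcome in the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .sequences import ContextSchedule, StimulusSequence

__all__ = [
    "GUESS",
    "CONFIDENT",
    "RULE_RECOLLECTION",
    "AgentParams",
    "AgentState",
    "TrialRecord",
    "Session",
    "rw_update",
    "gf_update",
    "combined_strength",
    "respond",
    "simulate_session",
]

GUESS = "guess"
CONFIDENT = "confident"
RULE_RECOLLECTION = "rule_recollection"

_POLICIES = ("threshold", "probabilistic")


def _check_unit(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the dual-process responder.

    Attributes
    ----------
    r_learn : float
        Learning rate R of the Rescorla-Wagner process, in [0, 1].  Large
        values mean recent trials dominate (short memory).
    r_gf : float
        Rate of the gambler's-fallacy process, in [0, 1].
    p_mix : float
        Mixture weight p on the Rescorla-Wagner output (1-p on the
        gambler's fallacy).
    w0, g0 : float
        Initial strengths; 0.5 encodes neutral ignorance.
    policy : {"threshold", "probabilistic"}
        How a response is emitted from the mixed strength T: deterministic
        thresholding at 0.5 (seeded fair coin on a tie) or Bernoulli(T).
    seed : int
        Seed for the response randomness.
    """

    r_learn: float
    r_gf: float = 0.0
    p_mix: float = 1.0
    w0: float = 0.5
    g0: float = 0.5
    policy: str = "threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_learn", "r_gf", "p_mix", "w0", "g0"):
            _check_unit(name, getattr(self, name))
        if self.policy not in _POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; use one of {_POLICIES}")


@dataclass
class AgentState:
    """Current strengths of prediction for 'right' of the two processes."""

    w: float = 0.5
    g: float = 0.5


@dataclass(frozen=True)
class TrialRecord:
    """One task trial; ``strength`` is the model's T (absent for humans)."""

    index: int
    stimulus: int
    response: int
    context: str | None = None
    attribution: str | None = None
    strength: float | None = None


@dataclass(frozen=True)
class Session:
    """Ordered trials of one subject/run, stored columnwise.

    ``stimuli`` and ``responses`` are 0/1 arrays; ``context``,
    ``attribution`` and ``strength`` are optional per-trial columns
    (``strength`` is recorded for simulated agents and absent for
    imported human data).
    """

    stimuli: np.ndarray
    responses: np.ndarray
    context: np.ndarray | None = None
    attribution: np.ndarray | None = None
    strength: np.ndarray | None = None
    subject_id: str = "s0"
    condition: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        stim = np.asarray(self.stimuli, dtype=np.int64)
        resp = np.asarray(self.responses, dtype=np.int64)
        if stim.ndim != 1 or stim.size < 1:
            raise ValueError("session must contain at least one trial")
        if resp.shape != stim.shape:
            raise ValueError("stimuli and responses must have equal length")
        for arr in (stim, resp):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("stimulus/response codes must be 0 or 1")
        object.__setattr__(self, "stimuli", stim)
        object.__setattr__(self, "responses", resp)
        for name, dtype in (("context", object), ("attribution", object), ("strength", float)):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=dtype)
                if col.shape != stim.shape:
                    raise ValueError(f"{name} must have one entry per trial")
                object.__setattr__(self, name, col)

    @property
    def n_trials(self) -> int:
        return int(self.stimuli.size)

    def __len__(self) -> int:
        return self.n_trials

    def records(self) -> Iterator[TrialRecord]:
        """Iterate trials as :class:`TrialRecord` (1-based indices)."""
        for i in range(self.n_trials):
            yield TrialRecord(
                index=i + 1,
                stimulus=int(self.stimuli[i]),
                response=int(self.responses[i]),
                context=None if self.context is None else self.context[i],
                attribution=None if self.attribution is None else self.attribution[i],
                strength=None if self.strength is None else float(self.strength[i]),
            )

    def with_attribution(self, attribution: np.ndarray) -> "Session":
        return replace(self, attribution=np.asarray(attribution, dtype=object))


def rw_update(w: float, s: int, r_learn: float) -> float:
    """Delta-rule step: convex move of W toward the observed side S."""
    _check_unit("w", w)
    _check_unit("r_learn", r_learn)
    if s not in (0, 1):
        raise ValueError("stimulus must be 0 or 1")
    return (1.0 - r_learn) * w + r_learn * s


def gf_update(g: float, s: int, r_gf: float) -> float:
    """Gambler's-fallacy step: convex move of G toward 1-S (the other side)."""
    _check_unit("g", g)
    _check_unit("r_gf", r_gf)
    if s not in (0, 1):
        raise ValueError("stimulus must be 0 or 1")
    return r_gf * (1.0 - s) + (1.0 - r_gf) * g


def combined_strength(w: float, g: float, p_mix: float) -> float:
    """Mixture T = p*W + (1-p)*G, the overall strength of predicting right."""
    _check_unit("w", w)
    _check_unit("g", g)
    _check_unit("p_mix", p_mix)
    return p_mix * w + (1.0 - p_mix) * g


def respond(t_strength: float, policy: str, rng: np.random.Generator) -> int:
    """Emit a 0/1 response from strength T under the given policy."""
    _check_unit("t_strength", t_strength)
    if policy == "threshold":
        if t_strength > 0.5:
            return 1
        if t_strength < 0.5:
            return 0
        return int(rng.random() < 0.5)
    if policy == "probabilistic":
        return int(rng.random() < t_strength)
    raise ValueError(f"unknown policy {policy!r}; use one of {_POLICIES}")


def simulate_session(
    seq: StimulusSequence,
    params: AgentParams,
    ctx: ContextSchedule | None = None,
    subject_id: str = "sim",
    condition: str | None = None,
) -> Session:
    """Run the dual-process agent over a stimulus sequence.

    Per trial: T is computed from the current (w, g); a response is emitted;
    only then is the stimulus observed and both strengths updated.  The
    run is fully deterministic given ``params.seed``.
    """
    if ctx is not None and len(ctx) != len(seq):
        raise ValueError("context schedule length must match the sequence")
    rng = np.random.default_rng(params.seed)
    n = len(seq)
    s = seq.sides
    w, g = params.w0, params.g0
    responses = np.empty(n, dtype=np.int64)
    strength = np.empty(n, dtype=float)
    for t in range(n):
        T = combined_strength(w, g, params.p_mix)
        strength[t] = T
        responses[t] = respond(T, params.policy, rng)
        w = rw_update(w, int(s[t]), params.r_learn)
        g = gf_update(g, int(s[t]), params.r_gf)
    return Session(
        stimuli=s,
        responses=responses,
        context=None if ctx is None else ctx.labels,
        strength=strength,
        subject_id=subject_id,
        condition=condition,
        seed=params.seed,
    )
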