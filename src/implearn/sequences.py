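"""Stimulus sequences and context schedules for the binary prediction task.

The task presents a square on the left or right of a screen; the subject
predicts the side before each presentation.  Sides are coded globally as
1 = right, 0 = left, and trial positions are 1-based (trial 1 is the first
trial).  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as _Seq

import numpy as np

__all__ = [
    "TONE",
    "NO_TONE",
    "MOOD",
    "NEUTRAL",
    "StimulusSequence",
    "ContextSchedule",
    "BlockSpec",
    "generate_random_sequence",
    "generate_tone_schedule",
    "generate_block_sequence",
    "generate_mood_schedule",
]

TONE = "tone"
NO_TONE = "no_tone"
MOOD = "mood"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class StimulusSequence:
    """A binary left/right stimulus sequence with its generating schedule.

    Attributes
    ----------
    sides : ndarray of int
        Stimulus side per trial, 1 = right, 0 = left.
    p_right_schedule : ndarray of float
        Probability of "right" used to draw each trial.
    seed : int or None
        RNG seed the sequence was drawn with.
    """

    sides: np.ndarray
    p_right_schedule: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        sides = np.asarray(self.sides, dtype=np.int64)
        sched = np.asarray(self.p_right_schedule, dtype=float)
        if sides.ndim != 1 or sides.size < 1:
            raise ValueError("sequence must be a non-empty 1-D array")
        if not np.isin(sides, (0, 1)).all():
            raise ValueError("stimulus codes must be 0 (left) or 1 (right)")
        if sched.shape != sides.shape:
            raise ValueError("schedule length must equal sequence length")
        if ((sched < 0) | (sched > 1)).any():
            raise ValueError("schedule probabilities must lie in [0, 1]")
        object.__setattr__(self, "sides", sides)
        object.__setattr__(self, "p_right_schedule", sched)

    def __len__(self) -> int:
        return int(self.sides.size)


@dataclass(frozen=True)
class ContextSchedule:
    """Per-trial context labels (e.g. tone/no_tone or mood/neutral)."""

    labels: np.ndarray
    design_name: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("schedule must be a non-empty 1-D array")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class BlockSpec:
    """Ordered probability blocks: (n_trials, p_right) per block."""

    blocks: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        blocks = tuple((int(n), float(p)) for n, p in self.blocks)
        if not blocks:
            raise ValueError("block spec must contain at least one block")
        for n, p in blocks:
            if n < 1:
                raise ValueError("each block needs at least one trial")
            if not 0.0 <= p <= 1.0:
                raise ValueError("block probabilities must lie in [0, 1]")
        object.__setattr__(self, "blocks", blocks)

    @property
    def n_trials(self) -> int:
        return sum(n for n, _ in self.blocks)

    def reversed(self) -> "BlockSpec":
        return BlockSpec(tuple(self.blocks[::-1]))

    def schedule(self) -> np.ndarray:
        """Per-trial p_right implied by the blocks."""
        return np.concatenate([np.full(n, p) for n, p in self.blocks])


def generate_random_sequence(n: int, p_right: float, seed: int) -> StimulusSequence:
    """Draw ``n`` iid Bernoulli(``p_right``) stimulus sides.

    The experimental sequences are genuinely random: any sensitivity of
    predictions to past trials reflects (spurious) learning, not structure.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not 0.0 <= p_right <= 1.0:
        raise ValueError("p_right must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sides = (rng.random(n) < p_right).astype(np.int64)
    return StimulusSequence(sides, np.full(n, p_right), seed=seed)


def generate_tone_schedule(n: int, first_no_tone: int = 4) -> ContextSchedule:
    """Tone on every trial except every fourth, which is silent.

    ``first_no_tone`` (1..4) positions the first silent trial; subsequent
    silent trials follow every 4 trials, so there are always three tone
    trials between consecutive no-tone trials.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not 1 <= first_no_tone <= 4:
        raise ValueError("first_no_tone must lie in 1..4")
    labels = np.full(n, TONE, dtype=object)
    labels[first_no_tone - 1 :: 4] = NO_TONE
    return ContextSchedule(labels, design_name="tone")


def generate_block_sequence(
    spec: BlockSpec, reverse: bool = False, seed: int = 0
) -> StimulusSequence:
    """Concatenated Bernoulli blocks with per-block p_right.

    With ``reverse`` the block order is flipped (the counterbalanced half
    of the probability-block design).
    """
    if reverse:
        spec = spec.reversed()
    sched = spec.schedule()
    rng = np.random.default_rng(seed)
    sides = (rng.random(sched.size) < sched).astype(np.int64)
    return StimulusSequence(sides, sched, seed=seed)


def generate_mood_schedule(n: int, seed: int) -> ContextSchedule:
    """Exactly half mood-inducing, half neutral trials, randomly intermixed."""
    if n < 1 or n % 2:
        raise ValueError("n must be a positive even number")
    labels = np.array([MOOD] * (n // 2) + [NEUTRAL] * (n // 2), dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return ContextSchedule(labels, design_name="mood")
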