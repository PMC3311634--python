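"""Trial-log CSV and JSON serialisation.

The trial-log format is one row per trial with columns
``trial, stimulus, response, context, attribution, strength`` (1-based
trial index; optional columns empty where unknown).  Human data imports
use the same format with ``strength`` empty.  Sequences additionally
round-trip through a small JSON spec (generator name + arguments + seed)
that regenerates them exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import Session
from .sequences import (
    BlockSpec,
    StimulusSequence,
    generate_block_sequence,
    generate_random_sequence,
)

__all__ = [
    "session_to_frame",
    "frame_to_session",
    "write_session_csv",
    "read_session_csv",
    "sequence_to_json",
    "sequence_from_json",
    "write_cohort",
    "read_cohort",
]

_COLUMNS = ["trial", "stimulus", "response", "context", "attribution", "strength"]


def session_to_frame(session: Session) -> pd.DataFrame:
    n = session.n_trials
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "stimulus": session.stimuli,
            "response": session.responses,
            "context": session.context if session.context is not None else [None] * n,
            "attribution": (
                session.attribution if session.attribution is not None else [None] * n
            ),
            "strength": (
                session.strength if session.strength is not None else [np.nan] * n
            ),
        }
    )


def frame_to_session(
    frame: pd.DataFrame,
    subject_id: str = "s0",
    condition: str | None = None,
    seed: int | None = None,
) -> Session:
    missing = [c for c in ("trial", "stimulus", "response") if c not in frame.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    frame = frame.sort_values("trial")
    expected = np.arange(1, len(frame) + 1)
    if not np.array_equal(frame["trial"].to_numpy(), expected):
        raise ValueError("trial indices must be consecutive from 1")

    def _opt(col: str):
        if col not in frame.columns or frame[col].isna().all():
            return None
        return frame[col].to_numpy()

    return Session(
        stimuli=frame["stimulus"].to_numpy(),
        responses=frame["response"].to_numpy(),
        context=_opt("context"),
        attribution=_opt("attribution"),
        strength=_opt("strength"),
        subject_id=subject_id,
        condition=condition,
        seed=seed,
    )


def write_session_csv(session: Session, path: str | Path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def read_session_csv(
    path: str | Path, subject_id: str | None = None, condition: str | None = None
) -> Session:
    path = Path(path)
    frame = pd.read_csv(path)
    return frame_to_session(
        frame, subject_id=subject_id or path.stem, condition=condition
    )


def sequence_to_json(seq: StimulusSequence) -> str:
    """Serialise a sequence as its regeneration spec (constant-p or blocks)."""
    sched = seq.p_right_schedule
    if np.unique(sched).size == 1:
        spec = {"design": "random", "n": len(seq), "p_right": float(sched[0])}
    else:
        change = np.flatnonzero(np.diff(sched)) + 1
        bounds = np.concatenate(([0], change, [sched.size]))
        blocks = [
            [int(b - a), float(sched[a])] for a, b in zip(bounds[:-1], bounds[1:])
        ]
        spec = {"design": "blocks", "blocks": blocks}
    spec["seed"] = seq.seed
    return json.dumps(spec)


def sequence_from_json(text: str) -> StimulusSequence:
    spec = json.loads(text)
    if spec["design"] == "random":
        return generate_random_sequence(spec["n"], spec["p_right"], spec["seed"])
    if spec["design"] == "blocks":
        blocks = BlockSpec(tuple((n, p) for n, p in spec["blocks"]))
        return generate_block_sequence(blocks, seed=spec["seed"])
    raise ValueError(f"unknown sequence design {spec['design']!r}")


def write_cohort(sessions: list[Session], out_dir: str | Path) -> Path:
    """Write one trial-log CSV per session plus a manifest JSON; returns
    the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for session in sessions:
        fname = f"{session.subject_id}.csv"
        write_session_csv(session, out_dir / fname)
        manifest.append(
            {
                "subject_id": session.subject_id,
                "condition": session.condition,
                "seed": session.seed,
                "file": fname,
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"sessions": manifest}, indent=2))
    return manifest_path


def read_cohort(out_dir: str | Path) -> list[Session]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    sessions = []
    for entry in manifest["sessions"]:
        session = read_session_csv(
            out_dir / entry["file"],
            subject_id=entry["subject_id"],
            condition=entry["condition"],
        )
        sessions.append(session)
    return sessions
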