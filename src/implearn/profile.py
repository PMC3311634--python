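"""The influence profile: phi correlations of prediction with past stimuli.

For each lag k, the phi (Pearson) correlation is computed between the
current response and the stimulus k trials back, over all trials with at
least k predecessors.  The shape of this profile over lags 1..10 carries
the learning rate: a rate-1 learner correlates perfectly with lag 1 and
not at all further back, while small rates spread influence over many
lags (geometric decay at 1 - R).

Summaries follow the field's division: *recent* influence is the mean of
lags 1-2, *distant* the mean of lags 4-10; lag 3 is excluded from both
because the gambler's fallacy predominates there.  Trial filters (by
context or attribution) condition on the CURRENT trial only — the past
trial may be of either type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .agents import CONFIDENT, GUESS, RULE_RECOLLECTION, Session
from .sequences import BlockSpec

__all__ = [
    "RECENT_LAGS",
    "DISTANT_LAGS",
    "LagProfile",
    "by_context",
    "by_attribution",
    "lag_correlation",
    "lag_profile",
    "attribution_split",
    "block_response_shift",
]

RECENT_LAGS = (1, 2)
DISTANT_LAGS = (4, 5, 6, 7, 8, 9, 10)

TrialFilter = Callable[[Session], np.ndarray]


def by_context(*labels: str) -> TrialFilter:
    """Keep trials whose (current-trial) context is one of ``labels``."""

    def _filter(session: Session) -> np.ndarray:
        if session.context is None:
            raise ValueError("session has no context labels")
        return np.isin(session.context, labels)

    return _filter


def by_attribution(*labels: str) -> TrialFilter:
    """Keep trials whose (current-trial) attribution is one of ``labels``."""

    def _filter(session: Session) -> np.ndarray:
        if session.attribution is None:
            raise ValueError("session has no attribution labels")
        return np.isin(session.attribution, labels)

    return _filter


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    # Pearson correlation of two binary vectors, via integer sums so that
    # perfectly (anti-)aligned vectors give exactly +/-1.0; NaN when either
    # vector is constant.
    n = x.size
    if n < 2:
        return float("nan")
    sx = int(x.sum())
    sy = int(y.sum())
    sxy = int((x * y).sum())
    var_x = n * sx - sx * sx
    var_y = n * sy - sy * sy
    if var_x == 0 or var_y == 0:
        return float("nan")
    return float((n * sxy - sx * sy) / np.sqrt(var_x * var_y))


def _lag_pairs(
    session: Session, lag: int, trial_filter: TrialFilter | None
) -> tuple[np.ndarray, np.ndarray]:
    if lag < 1:
        raise ValueError("lag must be at least 1")
    if lag >= session.n_trials:
        raise ValueError("lag must be smaller than the session length")
    keep = np.ones(session.n_trials, dtype=bool)
    if trial_filter is not None:
        keep = np.asarray(trial_filter(session), dtype=bool)
    keep = keep[lag:]  # current trials t with t - lag >= 1
    return session.responses[lag:][keep], session.stimuli[:-lag][keep]


def lag_correlation(
    session: Session, lag: int, trial_filter: TrialFilter | None = None
) -> float:
    """Phi correlation of response_t with stimulus_{t-lag}; NaN if undefined."""
    resp, stim = _lag_pairs(session, lag, trial_filter)
    return _phi(resp, stim)


@dataclass(frozen=True)
class LagProfile:
    """Influence profile over lags 1..max_lag with its standard summaries.

    ``correlations[k-1]`` is the phi at lag k (NaN where undefined, e.g.
    constant responses), ``n_pairs[k-1]`` the number of contributing trial
    pairs.  ``recent``/``distant``/``overall`` are unweighted means over the
    defined member lags (1-2, 4-10 and 1-10 respectively; NaN when every
    member lag is undefined).
    """

    lags: np.ndarray
    correlations: np.ndarray
    n_pairs: np.ndarray
    recent: float
    distant: float
    overall: float
    filter_spec: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag": self.lags, "phi": self.correlations, "n_pairs": self.n_pairs}
        )

    def to_dict(self) -> dict:
        return {
            "lags": self.lags.tolist(),
            "correlations": [None if np.isnan(c) else c for c in self.correlations],
            "n_pairs": self.n_pairs.tolist(),
            "recent": None if np.isnan(self.recent) else self.recent,
            "distant": None if np.isnan(self.distant) else self.distant,
            "overall": None if np.isnan(self.overall) else self.overall,
            "filter_spec": self.filter_spec,
        }


def _mean_defined(values: np.ndarray) -> float:
    defined = values[~np.isnan(values)]
    return float(defined.mean()) if defined.size else float("nan")


def lag_profile(
    session: Session,
    max_lag: int = 10,
    trial_filter: TrialFilter | None = None,
    filter_spec: str = "",
) -> LagProfile:
    """Compute the influence profile of a session over lags 1..max_lag."""
    if session.n_trials <= max_lag:
        raise ValueError("session must be longer than max_lag")
    lags = np.arange(1, max_lag + 1)
    correlations = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for i, lag in enumerate(lags):
        resp, stim = _lag_pairs(session, int(lag), trial_filter)
        correlations[i] = _phi(resp, stim)
        n_pairs[i] = resp.size
    by_lag = dict(zip(lags.tolist(), correlations))
    recent = _mean_defined(np.array([by_lag[k] for k in RECENT_LAGS if k <= max_lag]))
    distant = _mean_defined(np.array([by_lag[k] for k in DISTANT_LAGS if k <= max_lag]))
    overall = _mean_defined(correlations)
    return LagProfile(lags, correlations, n_pairs, recent, distant, overall, filter_spec)


def attribution_split(
    session: Session, max_lag: int = 10
) -> tuple[LagProfile, LagProfile]:
    """Profiles restricted to guess trials and to confident/rule trials.

    The guess profile keeps trials the subject attributed to pure guessing;
    the sure profile keeps trials attributed to confidence or to conscious
    rules/recollection.  Filters apply to the current trial only.
    """
    if session.attribution is None:
        raise ValueError("session has no attribution labels")
    guess = lag_profile(
        session, max_lag, by_attribution(GUESS), filter_spec="attribution in {guess}"
    )
    sure = lag_profile(
        session,
        max_lag,
        by_attribution(CONFIDENT, RULE_RECOLLECTION),
        filter_spec="attribution in {confident, rule_recollection}",
    )
    return guess, sure


def block_response_shift(
    session: Session, spec: BlockSpec
) -> tuple[float, float]:
    """(stimulus_shift, response_shift): final-block minus first-block
    right-fraction, for the stimuli and for the subject's responses.

    A learner tracking the drifting stimulus probability shows a response
    shift of the same sign as the stimulus shift; perfect probability
    matching would equate the two.
    """
    if spec.n_trials != session.n_trials:
        raise ValueError("block spec does not partition the session")
    n_first = spec.blocks[0][0]
    n_final = spec.blocks[-1][0]
    stim_shift = session.stimuli[-n_final:].mean() - session.stimuli[:n_first].mean()
    resp_shift = session.responses[-n_final:].mean() - session.responses[:n_first].mean()
    return float(stim_shift), float(resp_shift)
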