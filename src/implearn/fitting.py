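"""Grid-search fitting of the dual-process model to a session.

The three parameters (Rescorla-Wagner rate R, gambler's-fallacy rate, and
mixture weight p) are estimated by exhaustive search over an
(1/step + 1)^3 lattice — 11 x 11 x 11 at the default step of 0.1 —
minimising the mean squared error between the subject's 0/1 responses and
the model's trial-by-trial strength T.  Strength trajectories are driven
by the stimulus sequence only (standard delta rule), never by the
subject's responses, and T on each trial is the pre-update value, so the
model predicts before it sees the outcome.  The MSE averages over ALL
trials including trial 1 (where T comes from the initial strengths).

Because the sequences are random and the two processes oppose each other,
the error surface is relatively flat around its minimum; single-session
estimates are noisy and group means are the meaningful quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .agents import AgentParams, Session

__all__ = [
    "FitResult",
    "strength_trajectory",
    "model_mse",
    "DualProcessGridSearch",
    "grid_fit",
]


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim == 2 and arr.shape[1] == 1:  # sklearn-style column vector
        arr = arr.ravel()
    arr = arr.astype(np.int64)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D binary array")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 codes")
    return arr


def _strength_grid(
    stimuli: np.ndarray, rates: np.ndarray, init: float, toward_opposite: bool
) -> np.ndarray:
    """Pre-update strengths V[i, t] for every rate, vectorised over rates."""
    n = stimuli.size
    target = (1 - stimuli) if toward_opposite else stimuli
    V = np.empty((rates.size, n))
    V[:, 0] = init
    for t in range(1, n):
        V[:, t] = (1.0 - rates) * V[:, t - 1] + rates * target[t - 1]
    return V


def strength_trajectory(stimuli: np.ndarray, params: AgentParams) -> np.ndarray:
    """Per-trial mixed strength T (pre-update) along a stimulus sequence."""
    s = _as_binary(stimuli, "stimuli")
    w = _strength_grid(s, np.array([params.r_learn]), params.w0, False)[0]
    g = _strength_grid(s, np.array([params.r_gf]), params.g0, True)[0]
    return params.p_mix * w + (1.0 - params.p_mix) * g


def model_mse(session: Session, params: AgentParams) -> float:
    """Mean over all trials of (response_t - T_t)^2."""
    T = strength_trajectory(session.stimuli, params)
    return float(np.mean((session.responses - T) ** 2))


@dataclass(frozen=True)
class FitResult:
    """Best-fitting lattice triple with its achieved MSE and tie set."""

    r_learn: float
    r_gf: float
    p_mix: float
    mse: float
    ties: tuple[tuple[float, float, float], ...]
    grid_step: float


class DualProcessGridSearch(BaseEstimator):
    """Exhaustive-lattice estimator of the dual-process model.

    Scikit-learn style: ``fit(X, y)`` takes the stimulus sequence as ``X``
    (shape ``(n_trials,)`` or ``(n_trials, 1)``, codes 1 = right / 0 = left)
    and the subject's responses as ``y``, evaluates the model MSE on the
    full parameter lattice and stores the minimiser.

    Parameters
    ----------
    grid_step : float, default 0.1
        Lattice resolution; must divide 1 evenly.  Both endpoints 0 and 1
        are included (11 points per axis at the default).
    w0, g0 : float, default 0.5
        Initial strengths of the two processes (neutral ignorance).
    tie_tol : float, default 1e-12
        Absolute slack within which lattice points count as tied for the
        minimum.

    Attributes
    ----------
    grid_ : ndarray
        The lattice values shared by all three axes.
    mse_surface_ : ndarray, shape (m, m, m)
        Full error surface, indexed (r_learn, r_gf, p_mix).
    r_learn_, r_gf_, p_mix_ : float
        The minimising triple under the tie-break (lowest r_learn, then
        lowest r_gf, then lowest p_mix).
    mse_ : float
        The achieved minimum mean squared error.
    ties_ : tuple of triples
        Every lattice triple within ``tie_tol`` of the minimum (includes
        the reported triple).
    n_trials_ : int
        Number of trials fitted.
    """

    def __init__(
        self,
        grid_step: float = 0.1,
        w0: float = 0.5,
        g0: float = 0.5,
        tie_tol: float = 1e-12,
    ):
        self.grid_step = grid_step
        self.w0 = w0
        self.g0 = g0
        self.tie_tol = tie_tol

    def _grid(self) -> np.ndarray:
        if not 0.0 < self.grid_step <= 1.0:
            raise ValueError("grid_step must lie in (0, 1]")
        n_steps = round(1.0 / self.grid_step)
        if abs(n_steps * self.grid_step - 1.0) > 1e-9:
            raise ValueError("grid_step must divide 1 evenly")
        return np.linspace(0.0, 1.0, n_steps + 1)

    def fit(self, X, y):
        """Fit to one session: X = stimuli, y = responses."""
        stimuli = _as_binary(X, "X (stimuli)")
        responses = _as_binary(y, "y (responses)")
        if responses.shape != stimuli.shape:
            raise ValueError("stimuli and responses must have equal length")
        grid = self._grid()
        W = _strength_grid(stimuli, grid, self.w0, False)  # (m, n)
        G = _strength_grid(stimuli, grid, self.g0, True)
        p = grid[None, None, :, None]
        # T over the full lattice: axes (r_learn, r_gf, p_mix, trial)
        T = p * W[:, None, None, :] + (1.0 - p) * G[None, :, None, :]
        surface = ((responses - T) ** 2).mean(axis=-1)

        self.grid_ = grid
        self.mse_surface_ = surface
        self.mse_ = float(surface.min())
        tied = np.argwhere(surface <= self.mse_ + self.tie_tol)
        # row-sorted = lexicographic (r_learn, r_gf, p_mix): tie-break order
        tied = tied[np.lexsort((tied[:, 2], tied[:, 1], tied[:, 0]))]
        self.ties_ = tuple(
            (float(grid[i]), float(grid[j]), float(grid[k])) for i, j, k in tied
        )
        self.r_learn_, self.r_gf_, self.p_mix_ = self.ties_[0]
        self.mse_ = float(surface[tuple(tied[0])])
        self.n_trials_ = int(stimuli.size)
        return self

    def _fitted_params(self) -> AgentParams:
        check_is_fitted(self, "r_learn_")
        return AgentParams(
            r_learn=self.r_learn_,
            r_gf=self.r_gf_,
            p_mix=self.p_mix_,
            w0=self.w0,
            g0=self.g0,
        )

    def predict_strength(self, X) -> np.ndarray:
        """Trial-by-trial T along ``X`` under the fitted parameters."""
        return strength_trajectory(np.asarray(X), self._fitted_params())

    def predict(self, X) -> np.ndarray:
        """Thresholded (T > 0.5) response prediction along ``X``."""
        return (self.predict_strength(X) > 0.5).astype(np.int64)

    def score(self, X, y) -> float:
        """Negative model MSE (higher is better, for model selection)."""
        responses = _as_binary(y, "y (responses)")
        T = self.predict_strength(X)
        return -float(np.mean((responses - T) ** 2))

    def result_(self) -> FitResult:
        check_is_fitted(self, "r_learn_")
        return FitResult(
            r_learn=self.r_learn_,
            r_gf=self.r_gf_,
            p_mix=self.p_mix_,
            mse=self.mse_,
            ties=self.ties_,
            grid_step=self.grid_step,
        )


def grid_fit(session: Session, grid_step: float = 0.1, w0: float = 0.5, g0: float = 0.5) -> FitResult:
    """Convenience wrapper: fit :class:`DualProcessGridSearch` to a session."""
    est = DualProcessGridSearch(grid_step=grid_step, w0=w0, g0=g0)
    est.fit(session.stimuli, session.responses)
    return est.result_()
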