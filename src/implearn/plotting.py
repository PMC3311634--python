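"""Influence-profile charts in the style of the task's figures."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .profile import LagProfile

__all__ = ["plot_profile"]


def plot_profile(
    profiles: LagProfile | Sequence[LagProfile],
    ax=None,
    label: str | None = None,
    color=None,
):
    """Plot phi against trials into the past.

    A single profile is drawn as a line with markers; a collection of
    per-subject profiles is drawn as the cross-subject mean with 95%
    confidence-interval error bars.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if isinstance(profiles, LagProfile):
        ax.plot(profiles.lags, profiles.correlations, "o-", label=label, color=color)
    else:
        mat = np.vstack([p.correlations for p in profiles])
        lags = profiles[0].lags
        mean = np.nanmean(mat, axis=0)
        n = np.sum(~np.isnan(mat), axis=0)
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        ax.errorbar(
            lags, mean, yerr=1.96 * sem, fmt="o-", capsize=3, label=label, color=color
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Trials into the past (n)")
    ax.set_ylabel("Correlation of prediction with stimulus n back")
    if label:
        ax.legend()
    return ax
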