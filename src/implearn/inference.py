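"""Group-level inference: t tests, effect sizes, and half-normal Bayes factors.

The t tests are thin wrappers over scipy with the quantities the task's
analyses report: the statistic, (possibly fractional) degrees of freedom,
two-sided p, a Cohen-style effect size, a 95% CI on the mean (difference),
and the standard error of the effect — the last being what the Bayes
factor needs.

The Bayes factor follows the half-normal recipe: the directional theory
predicts an effect theta >= 0 with smaller values more likely than larger,
modelled as a half-normal with a scale chosen a priori (here, from pilot
data); the data likelihood is treated as normal in the observed effect.

    B = [ integral_0^inf 2 N(theta; 0, prior_sd) N(obs; theta, se) dtheta ]
        / N(obs; 0, se)

B > 3 is conventionally substantial evidence for the theory, B < 1/3 for
the null, and values near 1 are uninformative.  Independent Bayes factors
multiply.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod, sqrt
from typing import Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "TTestResult",
    "BayesFactorResult",
    "one_sample_t",
    "paired_t",
    "two_sample_t",
    "cohens_d_group",
    "cohens_dz",
    "cohens_d_from_summary",
    "bayes_factor_halfnormal",
    "bayes_factor_halfnormal_closed_form",
    "combine_bfs",
]


@dataclass(frozen=True)
class TTestResult:
    """t statistic with df, two-sided p, effect size, 95% CI and SE."""

    t: float
    df: float
    p: float
    effect: float
    ci: tuple[float, float]
    mean: float
    se: float


def _clean(values, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values")
    if np.isnan(arr).any():
        arr = arr[~np.isnan(arr)]
        if arr.size < min_n:
            raise ValueError(f"{name} has fewer than {min_n} defined values")
    return arr


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """One-sample t test of mean(values) against mu0; d = (mean-mu0)/SD.

    NaN entries (e.g. subjects whose profile was undefined for the
    measure) are dropped before testing.
    """
    arr = _clean(values, "values")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("values have zero variance")
    res = stats.ttest_1samp(arr, mu0)
    ci = res.confidence_interval(0.95)
    return TTestResult(
        t=float(res.statistic),
        df=float(arr.size - 1),
        p=float(res.pvalue),
        effect=float((arr.mean() - mu0) / sd),
        ci=(float(ci.low), float(ci.high)),
        mean=float(arr.mean()),
        se=float(sd / sqrt(arr.size)),
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired t test of a - b; effect is dz = mean(diff)/SD(diff).

    Identical samples (every difference exactly zero) return the
    degenerate no-effect result t = 0, dz = 0, p = 1 rather than a
    zero-variance error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if diffs.size >= 2 and np.all(diffs == 0.0):
        return TTestResult(
            t=0.0, df=float(diffs.size - 1), p=1.0, effect=0.0,
            ci=(0.0, 0.0), mean=0.0, se=0.0,
        )
    return one_sample_t(diffs, 0.0)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], unequal_var: bool = False
) -> TTestResult:
    """Independent-groups t test of mean(a) - mean(b).

    With ``unequal_var`` the Welch statistic and Satterthwaite df are used
    ("df adjusted for unequal variances"); the effect size d uses the
    pooled SD in either case.
    """
    a = _clean(a, "a")
    b = _clean(b, "b")
    res = stats.ttest_ind(a, b, equal_var=not unequal_var)
    ci = res.confidence_interval(0.95)
    diff = a.mean() - b.mean()
    if unequal_var:
        se = sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    else:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        se = sqrt(sp2 * (1 / a.size + 1 / b.size))
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        effect=cohens_d_group(a, b),
        ci=(float(ci.low), float(ci.high)),
        mean=float(diff),
        se=float(se),
    )


def cohens_d_group(a: Sequence[float], b: Sequence[float]) -> float:
    """Pooled-SD Cohen's d for two independent groups."""
    a = _clean(a, "a")
    b = _clean(b, "b")
    return cohens_d_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def cohens_dz(diffs: Sequence[float]) -> float:
    """Within-subject effect size: mean of differences over their SD."""
    diffs = _clean(diffs, "diffs")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        raise ValueError("differences have zero variance")
    return float(diffs.mean() / sd)


def cohens_d_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Pooled-SD d from group summaries (handy for published tables)."""
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 == 0.0:
        raise ValueError("pooled variance is zero")
    return float((mean_a - mean_b) / sqrt(sp2))


@dataclass(frozen=True)
class BayesFactorResult:
    """Half-normal Bayes factor with the inputs and integration record."""

    b: float
    obs_diff: float
    se: float
    prior_sd: float
    integration: tuple[float, int]  # (upper limit, function evaluations)


def bayes_factor_halfnormal(
    obs_diff: float, se: float, prior_sd: float, upper_mult: float = 5.0
) -> BayesFactorResult:
    """Half-normal-prior Bayes factor by adaptive quadrature.

    The marginal likelihood of the observed effect under the directional
    half-normal prior (scale ``prior_sd``) is integrated over
    theta in [0, upper_mult * max(prior_sd, se + obs_diff)] and divided by
    the likelihood under the point null.  The ratio is invariant under a
    common rescaling of all three inputs.
    """
    if se <= 0 or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    upper = upper_mult * max(prior_sd, se + abs(obs_diff))

    def integrand(theta: float) -> float:
        return 2.0 * stats.norm.pdf(theta, 0.0, prior_sd) * stats.norm.pdf(
            obs_diff, theta, se
        )

    # breakpoints at multiples of the prior and likelihood scales keep the
    # adaptive subdivision from stepping over a sharply peaked integrand
    breaks = sorted(
        {
            scale * mult
            for scale in (prior_sd, se)
            for mult in (0.5, 1.0, 2.0, 4.0, 8.0)
            if 0.0 < scale * mult < upper
        }
    )
    marginal, _, info = integrate.quad(
        integrand, 0.0, upper, epsrel=1e-6, full_output=True, points=breaks
    )[:3]
    b = marginal / stats.norm.pdf(obs_diff, 0.0, se)
    return BayesFactorResult(
        b=float(b),
        obs_diff=float(obs_diff),
        se=float(se),
        prior_sd=float(prior_sd),
        integration=(float(upper), int(info["neval"])),
    )


def bayes_factor_halfnormal_closed_form(
    obs_diff: float, se: float, prior_sd: float
) -> float:
    """Gaussian-product closed form of the half-normal Bayes factor.

    N(theta; 0, tau) N(x; theta, sigma) = N(x; 0, sqrt(sigma^2+tau^2))
    N(theta; m, sqrt(v)) with v = tau^2 sigma^2/(sigma^2+tau^2) and
    m = x tau^2/(sigma^2+tau^2), so the half-line integral reduces to a
    normal CDF.  Used as an independent cross-check of the quadrature.
    """
    if se <= 0 or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    s2, t2 = se**2, prior_sd**2
    v = t2 * s2 / (s2 + t2)
    m = obs_diff * t2 / (s2 + t2)
    marginal = (
        2.0
        * stats.norm.pdf(obs_diff, 0.0, sqrt(s2 + t2))
        * stats.norm.cdf(m / sqrt(v))
    )
    return float(marginal / stats.norm.pdf(obs_diff, 0.0, se))


def combine_bfs(bs: Sequence[float]) -> float:
    """Product of independent Bayes factors."""
    bs = list(bs)
    if not bs or any(b <= 0 for b in bs):
        raise ValueError("Bayes factors must be positive")
    return float(prod(bs))
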