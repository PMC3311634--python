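"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: contingency-table phi, per-trial
Python loops for strengths and MSE, and textbook t-test formulas — no
code shared with the package's vectorised paths.
"""

from math import sqrt

import numpy as np


def phi_contingency(x, y) -> float:
    """Phi from the 2x2 table: (ad - bc)/sqrt((a+b)(c+d)(a+c)(b+d))."""
    x = np.asarray(x)
    y = np.asarray(y)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return (a * d - b * c) / sqrt(denom)


def rw_closed_form(stimuli, r: float, w0: float, t: int) -> float:
    """W before 1-based trial t: geometric sum over past stimuli."""
    total = (1 - r) ** (t - 1) * w0
    for k in range(t - 1):  # k trials further back than t-1
        total += r * (1 - r) ** k * stimuli[t - 2 - k]
    return total


def naive_mse(stimuli, responses, r_learn, r_gf, p_mix, w0=0.5, g0=0.5) -> float:
    """Per-trial loop: T before update, squared error vs response, mean."""
    w, g = w0, g0
    total = 0.0
    for s, resp in zip(stimuli, responses):
        T = p_mix * w + (1 - p_mix) * g
        total += (resp - T) ** 2
        w = w + r_learn * (s - w)
        g = r_gf * (1 - s) + (1 - r_gf) * g
    return total / len(stimuli)


def t_one_sample(values, mu0: float = 0.0) -> tuple[float, float]:
    """(t, df) from the textbook formula."""
    values = np.asarray(values, dtype=float)
    n = values.size
    se = values.std(ddof=1) / sqrt(n)
    return (values.mean() - mu0) / se, float(n - 1)


def t_two_sample_pooled(a, b) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / sqrt(sp2 * (1 / na + 1 / nb))
    return t, float(na + nb - 2)


def t_two_sample_welch(a, b) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df
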