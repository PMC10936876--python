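"""Independent brute-force reference implementations used by the
acceptance checks. Deliberately written as literal loops over the
definitions, sharing no code with the package."""

import numpy as np


def bh_step_up(pvals):
    """Benjamini-Hochberg step-up: adjusted_i = min over ranks j >= rank(i)
    of p_(j) * m / j, capped at 1."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def rolling_mean_loop(values, window, centering="left"):
    """Clipped centered rolling mean, one position at a time."""
    n = len(values)
    if centering == "left":
        left = window // 2
    else:
        left = window - window // 2 - 1
    right = window - left - 1
    out = np.empty(n)
    for i in range(n):
        lo = max(i - left, 0)
        hi = min(i + right + 1, n)
        out[i] = sum(values[lo:hi]) / (hi - lo)
    return out
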