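"""Independent brute-force references used to check the fast implementations."""

import itertools

import numpy as np


def brute_force_fpt(x, y, t, i, radius):
    """First passage time at path index i by walking every segment.

    Finds the first forward segment whose endpoint leaves the circle and
    the first backward one likewise, interpolating the crossing time
    linearly on the distance-to-centre function. Returns NaN when the path
    starts or ends inside the circle.
    """
    d = np.hypot(x - x[i], y - y[i])

    def first_crossing(indices):
        prev = indices[0]
        for j in indices[1:]:
            if d[j] > radius:
                frac = (radius - d[prev]) / (d[j] - d[prev])
                return t[prev] + frac * (t[j] - t[prev])
            prev = j
        return np.nan

    t_exit = first_crossing(range(i, len(x)))
    t_entry = first_crossing(range(i, -1, -1))
    return t_exit - t_entry


def exact_multinomial_tail(observed, p):
    """P(chi2 >= chi2_obs) under multinomial(n, p) by full enumeration."""
    obs = np.asarray(observed, dtype=int)
    p = np.asarray(p, dtype=float)
    n = int(obs.sum())
    exp = n * p
    chi2_obs = float(((obs - exp) ** 2 / exp).sum())
    from math import factorial

    total = 0.0
    k = len(p)
    for counts in itertools.product(range(n + 1), repeat=k - 1):
        if sum(counts) > n:
            continue
        full = counts + (n - sum(counts),)
        chi2 = float(((np.array(full) - exp) ** 2 / exp).sum())
        if chi2 >= chi2_obs - 1e-12:
            prob = factorial(n)
            for c, pi in zip(full, p):
                prob = prob / factorial(c) * pi ** c
            total += prob
    return total
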