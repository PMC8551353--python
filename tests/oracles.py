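"""Independent brute-force reference implementations used only by tests.

Deliberately written as plain Python loops over lists, with no shared code
with the package's vectorised implementations.
"""

import math


def gradient_oracle(j):
    """Loop version of the gradient quantities; None marks undefined."""
    n = len(j)
    d = [None] * n
    v1 = [None] * n
    v2 = [None] * n
    e = [None] * n
    for i in range(n):
        if i + 1 < n and j[i] is not None and j[i + 1] is not None:
            d[i] = j[i + 1] - j[i]
            v1[i] = (j[i + 1] - j[i]) / j[i]
        if i > 0 and j[i] is not None and j[i - 1] is not None:
            v2[i] = (j[i] - j[i - 1]) / j[i - 1]
    for i in range(n):
        sides = [abs(v) for v in (v1[i], v2[i]) if v is not None]
        e[i] = max(sides) if sides else None
    return d, v1, v2, e


def quantile_oracle(values, q):
    """NumPy 'linear' empirical quantile, recomputed by hand."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = q * (len(xs) - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def association_oracle(positions, flagged_by_position):
    """Fraction of 1-based positions that are flagged (dict lookup)."""
    hits = sum(1 for p in positions if flagged_by_position[p])
    return hits / len(positions)
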