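"""Sliding-window sample/fuzzy entropy kernels (numba-compiled).

Both statistics use embedding dimension 2, Chebyshev distance, and a
tolerance tied to the standard deviation of the current window, so they are
O(W^2) per sample; the JIT keeps full-trial evaluation fast.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_sliding(x: np.ndarray, w: int, rho: float, cap: float) -> np.ndarray:
    """SampEn(m=2, r=rho*SD) of each trailing window of length ``w``.

    Windows with no template matches at either length return ``cap``.
    Output is 0 for the first ``w - 1`` samples.
    """
    n = x.size
    g = np.zeros(n)
    for end in range(w - 1, n):
        start = end - w + 1
        mean = 0.0
        for i in range(start, end + 1):
            mean += x[i]
        mean /= w
        var = 0.0
        for i in range(start, end + 1):
            var += (x[i] - mean) ** 2
        var /= w - 1
        r = rho * math.sqrt(var)
        nt = w - 2  # templates of length 2 that extend to length 3
        b_count = 0
        a_count = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                xi = start + i
                xj = start + j
                d2 = abs(x[xi] - x[xj])
                d2b = abs(x[xi + 1] - x[xj + 1])
                if d2b > d2:
                    d2 = d2b
                if d2 <= r:
                    b_count += 1
                    d3 = abs(x[xi + 2] - x[xj + 2])
                    if d3 < d2:
                        d3 = d2
                    if d3 <= r:
                        a_count += 1
        if a_count == 0 or b_count == 0:
            g[end] = cap
        else:
            g[end] = -math.log(a_count / b_count)
    return g


@njit(cache=True)
def fuzzyen_sliding(x: np.ndarray, w: int, r: float, saturation: float) -> np.ndarray:
    """FuzzyEn(m=2, exp(-d^2 / r)) of each trailing window, fixed tolerance r.

    The tolerance is calibrated once per trial (0.2 x baseline SD), which
    keeps the statistic causal yet sensitive to amplitude changes.
    Templates are mean-subtracted before the Chebyshev distance; both
    membership sums use the ``w - 2`` templates that exist at both lengths.
    Degenerate tolerance / fully underflowed memberships return
    0 / ``saturation`` respectively.
    """
    n = x.size
    g = np.zeros(n)
    tm2 = np.empty((w, 2))
    tm3 = np.empty((w, 3))
    if r <= 0.0:
        return g
    for end in range(w - 1, n):
        start = end - w + 1
        nt = w - 2
        for i in range(nt):
            m2 = 0.5 * (x[start + i] + x[start + i + 1])
            tm2[i, 0] = x[start + i] - m2
            tm2[i, 1] = x[start + i + 1] - m2
            m3 = (x[start + i] + x[start + i + 1] + x[start + i + 2]) / 3.0
            for k in range(3):
                tm3[i, k] = x[start + i + k] - m3
        phi2 = 0.0
        phi3 = 0.0
        for i in range(nt):
            for j in range(i + 1, nt):
                d2 = abs(tm2[i, 0] - tm2[j, 0])
                d2b = abs(tm2[i, 1] - tm2[j, 1])
                if d2b > d2:
                    d2 = d2b
                phi2 += math.exp(-(d2 * d2) / r)
                d3 = abs(tm3[i, 0] - tm3[j, 0])
                for k in range(1, 3):
                    d3b = abs(tm3[i, k] - tm3[j, k])
                    if d3b > d3:
                        d3 = d3b
                phi3 += math.exp(-(d3 * d3) / r)
        if phi3 <= 0.0 or phi2 <= 0.0:
            g[end] = saturation
        else:
            g[end] = -math.log(phi3 / phi2)
    return g
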