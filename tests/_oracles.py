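"""Independent brute-force oracles used to cross-check the test functions.

Everything here is deliberately naive (explicit python loops, O(W^2)
pair counting, direct convolution sums) and shares no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def mav_oracle(x, w):
    """Trailing moving average by explicit window sums (zero-padded past)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for n in range(x.size):
        lo = max(0, n - w + 1)
        out[n] = sum(x[lo : n + 1]) / w
    return out


def tkeo_oracle(x):
    """psi(n) = x(n-1)^2 - x(n-2)*x(n) by direct evaluation."""
    x = np.asarray(x, dtype=float)
    psi = np.zeros_like(x)
    for n in range(2, x.size):
        psi[n] = x[n - 1] ** 2 - x[n - 2] * x[n]
    return psi


def rms_window_oracle(window):
    """RMS of one window by explicit sum."""
    return math.sqrt(sum(v * v for v in window) / len(window))


def aglr_gauss_oracle(window, sigma0_sq):
    """Gaussian variance-change log-likelihood ratio computed from densities.

    Maximized log likelihood under the window's MLE variance minus the log
    likelihood under the baseline variance, using explicit normal log-pdfs.
    """
    window = np.asarray(window, dtype=float)
    w = window.size
    s2 = float(np.sum(window**2)) / w

    def loglik(var):
        return sum(
            -0.5 * math.log(2 * math.pi * var) - v * v / (2 * var) for v in window
        )

    return loglik(s2) - loglik(sigma0_sq)


def aglr_lap_oracle(window, b0):
    """Laplacian scale-change log-likelihood ratio from explicit log-pdfs."""
    window = np.asarray(window, dtype=float)
    w = window.size
    b_hat = float(np.sum(np.abs(window))) / w

    def loglik(b):
        return sum(-math.log(2 * b) - abs(v) / b for v in window)

    return loglik(b_hat) - loglik(b0)


def sampen_oracle(window, rho, cap):
    """SampEn(m=2, Chebyshev, r=rho*sample SD) by O(W^2) pair counting."""
    w = list(map(float, window))
    n = len(w)
    mean = sum(w) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in w) / (n - 1))
    r = rho * sd
    nt = n - 2
    b_count = 0
    a_count = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d2 = max(abs(w[i] - w[j]), abs(w[i + 1] - w[j + 1]))
            if d2 <= r:
                b_count += 1
                d3 = max(d2, abs(w[i + 2] - w[j + 2]))
                if d3 <= r:
                    a_count += 1
    if a_count == 0 or b_count == 0:
        return cap
    return -math.log(a_count / b_count)


def fuzzyen_oracle(window, r):
    """FuzzyEn(m=2, exp(-d^2/r)) with mean-subtracted templates, brute force."""
    w = list(map(float, window))
    n = len(w)
    nt = n - 2

    def template(i, m):
        seg = w[i : i + m]
        mu = sum(seg) / m
        return [v - mu for v in seg]

    def chebyshev(a, b):
        return max(abs(u - v) for u, v in zip(a, b))

    phi2 = 0.0
    phi3 = 0.0
    for i in range(nt):
        for j in range(i + 1, nt):
            phi2 += math.exp(-chebyshev(template(i, 2), template(j, 2)) ** 2 / r)
            phi3 += math.exp(-chebyshev(template(i, 3), template(j, 3)) ** 2 / r)
    return -math.log(phi3 / phi2)


def causal_convolution_oracle(x, kernel):
    """g(n) = |sum_k kernel(k) * x(n-k)| by direct summation."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for n in range(x.size):
        acc = 0.0
        for k, c in enumerate(kernel):
            if n - k >= 0:
                acc += c * x[n - k]
        out[n] = abs(acc)
    return out


def cost_checker_oracle(y, n_rest, fs):
    """Acceptability of a detector output by first principles.

    Returns (cost, acceptable) where acceptable applies the three explicit
    bounds rFP <= 0.2, rFN <= 0.2, dt <= 50 ms directly.
    """
    y = np.asarray(y)
    rest = y[int(3 * fs) : n_rest]
    move = y[n_rest:]
    r_fp = float(np.sum(rest == 1)) / rest.size
    r_fn = float(np.sum(move == 0)) / move.size
    ones = np.flatnonzero(move == 1)
    dt = None if ones.size == 0 else ones[0] * 1000.0 / fs
    if dt is None:
        f = 1.0
    elif dt >= 250.0:
        f = 1.0
    else:
        f = dt / 250.0
    acceptable = (r_fp <= 0.2) and (r_fn <= 0.2) and (dt is not None and dt <= 50.0)
    return max(r_fp, r_fn, f), acceptable
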