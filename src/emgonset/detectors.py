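"""Causal real-time sEMG onset detectors.

Every detector follows the same three-stage structure: causal signal
conditioning, a scalar test function g(n) computed over past samples only,
and a threshold decision rule producing a binary output y(n).  The
threshold is adaptive per trial,

    h = mean(g) + alpha * SD(g)

over the first 3 s of the trial (the baseline phase), excluding warm-up
samples where g is undefined.  Decision rules are either a single strict
comparison y(n) = [g(n) > h] or a Bonato-style double threshold requiring
at least m supra-threshold samples within the trailing T1 samples.

Thirteen detectors are registered under their conventional names:

========================  =============================================
name                      parameters (W, m, T1, p in ms; fc in Hz)
========================  =============================================
``Modified Hodges``       alpha, fc
``Hodges``                alpha, fc, W
``Modified Lidierth``     alpha, fc, m, T1
``Lidierth``              alpha, W, m, T1
``RMS``                   alpha, W, p (window shift), m (persistence)
``TKEO``                  alpha, fc (high-pass), W, T1 (m fixed at 1)
``Bonato``                alpha, m, T1 (whitened, paired-sample statistic)
``AGLR-G``                alpha, W (Gaussian variance-change LLR)
``AGLR-L``                alpha, W (Laplacian scale-change LLR)
``Sample Entropy``        alpha, W, rho (tolerance, units of local SD)
``Fuzzy Entropy``         alpha, W
``CWT``                   alpha, a (wavelet scale, ms)
``SSA``                   W (threshold weight fixed at 1)
========================  =============================================

All window-type parameters are given in milliseconds and converted to
samples with the trial's sampling rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from ._entropy import fuzzyen_sliding, sampen_sliding
from .signal_models import SimulatedTrial

__all__ = [
    "DETECTOR_NAMES",
    "PARAM_SCHEMAS",
    "DetectorParams",
    "DetectorOutput",
    "estimate_threshold",
    "apply_single_threshold",
    "apply_double_threshold",
    "whiten",
    "detect",
]

logger = logging.getLogger(__name__)

BASELINE_S = 3.0  # threshold-estimation segment at the start of each trial
WHITEN_ORDER = 6  # AR order for the adaptive whitening filter
FUZZY_R_FRAC = 0.2  # FuzzyEn tolerance as a fraction of the local SD
FUZZY_SATURATION = 700.0  # -log of the smallest normal double, effectively
SSA_ENERGY = 0.9  # baseline-subspace rank: smallest k capturing this energy

DETECTOR_NAMES = (
    "Modified Hodges",
    "AGLR-G",
    "AGLR-L",
    "Fuzzy Entropy",
    "Modified Lidierth",
    "Hodges",
    "RMS",
    "Lidierth",
    "TKEO",
    "Bonato",
    "Sample Entropy",
    "CWT",
    "SSA",
)

PARAM_SCHEMAS: dict[str, frozenset[str]] = {
    "Modified Hodges": frozenset({"alpha", "fc"}),
    "Hodges": frozenset({"alpha", "fc", "W"}),
    "Modified Lidierth": frozenset({"alpha", "fc", "m", "T1"}),
    "Lidierth": frozenset({"alpha", "W", "m", "T1"}),
    "RMS": frozenset({"alpha", "W", "p", "m"}),
    "TKEO": frozenset({"alpha", "fc", "W", "T1"}),
    "Bonato": frozenset({"alpha", "m", "T1"}),
    "AGLR-G": frozenset({"alpha", "W"}),
    "AGLR-L": frozenset({"alpha", "W"}),
    "Sample Entropy": frozenset({"alpha", "W", "rho"}),
    "Fuzzy Entropy": frozenset({"alpha", "W"}),
    "CWT": frozenset({"alpha", "a"}),
    "SSA": frozenset({"W"}),
}


@dataclass(frozen=True)
class DetectorParams:
    """A named, schema-checked parameter set for one detector type."""

    detector_type: str
    values: dict

    def __post_init__(self) -> None:
        if self.detector_type not in PARAM_SCHEMAS:
            raise ValueError(f"unknown detector type {self.detector_type!r}")
        legal = PARAM_SCHEMAS[self.detector_type]
        given = set(self.values)
        if given != legal:
            raise ValueError(
                f"{self.detector_type}: parameters must be exactly "
                f"{sorted(legal)}, got {sorted(given)}"
            )
        if "alpha" in self.values and self.values["alpha"] < 0:
            raise ValueError("alpha must be non-negative")

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass(frozen=True)
class DetectorOutput:
    """Per-sample test function g(n), threshold h, and binary output y(n)."""

    g: np.ndarray
    h: float
    y: np.ndarray
    warmup: int = 0


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------


def _ms_to_samples(ms: float, fs: float) -> int:
    n = int(round(ms * fs / 1000.0))
    if n < 1:
        raise ValueError(f"window of {ms} ms is shorter than one sample at fs={fs}")
    return n


def estimate_threshold(
    g: np.ndarray, alpha: float, *, warmup: int = 0, baseline_n: int = 3000
) -> float:
    """Adaptive threshold h = mean + alpha * sample SD of the baseline g.

    Warm-up samples (where g is identically zero by convention) are
    excluded so they cannot bias the estimate.
    """
    seg = np.asarray(g[warmup:baseline_n], dtype=float)
    if seg.size < 2:
        raise ValueError("baseline segment too short for threshold estimation")
    mu = float(seg.mean())
    sd = float(seg.std(ddof=1))
    if sd == 0.0:
        logger.warning("degenerate baseline: SD of test function is 0; h = mean")
        return mu
    return mu + alpha * sd


def apply_single_threshold(g: np.ndarray, h: float) -> np.ndarray:
    """y(n) = 1 iff g(n) > h (strict; ties give 0)."""
    return (np.asarray(g) > h).astype(np.int8)


def apply_double_threshold(b: np.ndarray, m: int, t1: int) -> np.ndarray:
    """y(n) = 1 iff >= m of the trailing t1 samples of b are 1."""
    if not 1 <= m <= t1:
        raise ValueError(f"double threshold requires 1 <= m <= T1, got m={m}, T1={t1}")
    b = np.asarray(b, dtype=float)
    counts = signal.lfilter(np.ones(t1), [1.0], b)
    # counts are integer-valued sums; compare against m - 1/2 to dodge
    # floating-point equality
    return (counts > m - 0.5).astype(np.int8)


def _causal_mav(x: np.ndarray, w: int) -> np.ndarray:
    """Trailing moving average over w samples (causal; ramp-up zeroed later)."""
    return signal.lfilter(np.ones(w) / w, [1.0], x)


def whiten(
    x: np.ndarray,
    *,
    baseline_n: int = 3000,
    order: int = WHITEN_ORDER,
) -> np.ndarray:
    """Adaptive whitening: AR(order) fit on the baseline, inverse filter applied.

    The AR model is estimated from the first ``baseline_n`` samples by
    Yule-Walker and its prediction-error filter is run causally over the
    whole record, flattening the shaping-filter colour so that
    variance-change statistics behave like white-noise statistics.
    """
    x = np.asarray(x, dtype=float)
    base = x[:baseline_n] - x[:baseline_n].mean()
    n = base.size
    acov = np.array(
        [np.dot(base[: n - k], base[k:]) / n for k in range(order + 1)]
    )
    if acov[0] <= 0.0:
        logger.warning("degenerate whitening fit (constant baseline); passthrough")
        return x.copy()
    # ridge regularization keeps the Toeplitz solve stable for near-
    # deterministic baselines
    r0 = acov[0] * (1.0 + 1e-8)
    coeffs = linalg.solve_toeplitz(
        (np.r_[r0, acov[1:order]], np.r_[r0, acov[1:order]]), acov[1 : order + 1]
    )
    return signal.lfilter(np.r_[1.0, -coeffs], [1.0], x)


def _rectified_lpf(x: np.ndarray, fc: float, fs: float) -> tuple[np.ndarray, int]:
    """Causal 2nd-order Butterworth low-pass of |x|; warm-up = filter order."""
    if not 0 < fc < fs / 2:
        raise ValueError(f"invalid low-pass cutoff {fc} Hz at fs={fs}")
    b, a = signal.butter(2, fc, btype="low", fs=fs)
    env = signal.lfilter(b, a, np.abs(x))
    env[:2] = 0.0
    return env, 2


# ---------------------------------------------------------------------------
# test functions
# ---------------------------------------------------------------------------


def tf_modified_hodges(x: np.ndarray, fs: float, fc: float) -> tuple[np.ndarray, int]:
    """Rectify-and-smooth amplitude envelope: g = LPF(|x|)."""
    return _rectified_lpf(x, fc, fs)


def tf_hodges(
    x: np.ndarray, fs: float, fc: float, w_ms: float, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int]:
    """Baseline-standardized moving average of the rectified, low-passed signal."""
    w = _ms_to_samples(w_ms, fs)
    env, warm = _rectified_lpf(x, fc, fs)
    hat = _causal_mav(env, w)
    warm += w - 1
    mu0 = hat[warm:baseline_n].mean()
    sd0 = hat[warm:baseline_n].std(ddof=1)
    if sd0 == 0.0:
        logger.warning("Hodges: zero baseline SD; standardizing by 1")
        sd0 = 1.0
    g = (hat - mu0) / sd0
    g[:warm] = 0.0
    return g, warm


def tf_lidierth(
    x: np.ndarray, fs: float, w_ms: float, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int]:
    """As Hodges but on the raw rectified signal (no low-pass stage)."""
    w = _ms_to_samples(w_ms, fs)
    hat = _causal_mav(np.abs(x), w)
    warm = w - 1
    mu0 = hat[warm:baseline_n].mean()
    sd0 = hat[warm:baseline_n].std(ddof=1)
    if sd0 == 0.0:
        logger.warning("Lidierth: zero baseline SD; standardizing by 1")
        sd0 = 1.0
    g = (hat - mu0) / sd0
    g[:warm] = 0.0
    return g, warm


def tf_rms(
    x: np.ndarray, fs: float, w_ms: float, p_ms: float
) -> tuple[np.ndarray, int, np.ndarray]:
    """Block-updated RMS of the bandpass-conditioned signal.

    g is recomputed every p ms over the trailing W ms and held constant
    between updates.  Returns (g, warmup, update_indices).
    """
    w = _ms_to_samples(w_ms, fs)
    p = _ms_to_samples(p_ms, fs)
    high = min(450.0, 0.45 * fs)
    b, a = signal.butter(4, [10.0, high], btype="bandpass", fs=fs)
    xc = signal.lfilter(b, a, x)
    ms = _causal_mav(xc**2, w)
    updates = np.arange(w - 1, x.size, p)
    g = np.zeros(x.size)
    vals = np.sqrt(np.maximum(ms[updates], 0.0))
    for k, n in enumerate(updates):
        end = updates[k + 1] if k + 1 < updates.size else x.size
        g[n:end] = vals[k]
    return g, w - 1, updates


def tf_tkeo(
    x: np.ndarray, fs: float, fc: float, w_ms: float
) -> tuple[np.ndarray, int]:
    """Moving average of the causal Teager-Kaiser energy of the high-passed signal.

    psi(n) = x~(n-1)^2 - x~(n-2) * x~(n), the one-sample-delayed energy
    operator, so the statistic uses past samples only.
    """
    if not 0 < fc < fs / 2:
        raise ValueError(f"invalid high-pass cutoff {fc} Hz at fs={fs}")
    w = _ms_to_samples(w_ms, fs)
    b, a = signal.butter(2, fc, btype="high", fs=fs)
    xt = signal.lfilter(b, a, x)
    psi = np.zeros_like(xt)
    psi[2:] = xt[1:-1] ** 2 - xt[:-2] * xt[2:]
    g = _causal_mav(psi, w)
    warm = 2 + (w - 1) + 2
    g[:warm] = 0.0
    return g, warm


def tf_bonato(
    x: np.ndarray, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int, np.ndarray, int]:
    """Paired-sample variance statistic on the whitened signal (half time base).

    g(k) = (x~(2k)^2 + x~(2k+1)^2) / sigma0^2 over successive non-overlapping
    pairs; on the full timeline the value is held from the completing (odd)
    sample.  Returns (g_full, warmup, g_half, pair_offset).
    """
    xt = whiten(x, baseline_n=baseline_n)
    warm = WHITEN_ORDER
    sigma0_sq = xt[warm:baseline_n].var(ddof=1)
    if sigma0_sq == 0.0:
        logger.warning("Bonato: zero baseline variance; using 1")
        sigma0_sq = 1.0
    n = xt.size
    n_pairs = n // 2
    pairs = xt[: 2 * n_pairs].reshape(n_pairs, 2)
    g_half = (pairs[:, 0] ** 2 + pairs[:, 1] ** 2) / sigma0_sq
    g = np.zeros(n)
    odd = 2 * np.arange(n_pairs) + 1
    g[odd] = g_half
    g[odd[:-1] + 1] = g_half[:-1]  # hold until the next pair completes
    if 2 * n_pairs < n:
        g[-1] = g_half[-1]
    warm_full = warm + 2
    g[:warm_full] = 0.0
    return g, warm_full, g_half, warm_full // 2


def _trailing_mean(x: np.ndarray, w: int) -> np.ndarray:
    return _causal_mav(x, w)


def tf_aglr_gauss(
    x: np.ndarray, fs: float, w_ms: float, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int]:
    """Approximate GLR for a Gaussian variance change after whitening.

    With sigma_hat^2 the trailing-window mean square and sigma0^2 the
    baseline variance of the whitened signal,

        g(n) = (W/2) * (ratio - ln(ratio) - 1),  ratio = sigma_hat^2/sigma0^2,

    which is >= 0 and 0 exactly when the window matches the baseline.
    """
    w = _ms_to_samples(w_ms, fs)
    xt = whiten(x, baseline_n=baseline_n)
    sigma0_sq = xt[WHITEN_ORDER:baseline_n].var(ddof=1)
    if sigma0_sq == 0.0:
        logger.warning("AGLR-G: zero baseline variance; using 1")
        sigma0_sq = 1.0
    s2 = _trailing_mean(xt**2, w)
    ratio = np.maximum(s2 / sigma0_sq, 1e-300)
    g = 0.5 * w * (ratio - np.log(ratio) - 1.0)
    warm = WHITEN_ORDER + w - 1
    g[:warm] = 0.0
    return g, warm


def tf_aglr_laplace(
    x: np.ndarray, fs: float, w_ms: float, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int]:
    """Approximate GLR for a Laplacian scale change after whitening.

    g(n) = W * (b_hat/b0 - ln(b_hat/b0) - 1) with b_hat the trailing-window
    mean absolute value and b0 its baseline value.
    """
    w = _ms_to_samples(w_ms, fs)
    xt = whiten(x, baseline_n=baseline_n)
    b0 = np.abs(xt[WHITEN_ORDER:baseline_n]).mean()
    if b0 == 0.0:
        logger.warning("AGLR-L: zero baseline scale; using 1")
        b0 = 1.0
    bh = _trailing_mean(np.abs(xt), w)
    ratio = np.maximum(bh / b0, 1e-300)
    g = w * (ratio - np.log(ratio) - 1.0)
    warm = WHITEN_ORDER + w - 1
    g[:warm] = 0.0
    return g, warm


def sampen_cap(w: int) -> float:
    """Cap for undefined sample-entropy values: ln(W*(W-1))."""
    return math.log(w * (w - 1))


def tf_sample_entropy(
    x: np.ndarray, fs: float, w_ms: float, rho: float
) -> tuple[np.ndarray, int]:
    """SampEn(m=2, Chebyshev, r = rho * local SD) over the trailing window."""
    w = _ms_to_samples(w_ms, fs)
    if w < 5:
        raise ValueError("sample entropy needs a window of at least 5 samples")
    g = sampen_sliding(np.ascontiguousarray(x, dtype=np.float64), w, rho, sampen_cap(w))
    return g, w - 1


def tf_fuzzy_entropy(
    x: np.ndarray, fs: float, w_ms: float, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int]:
    """FuzzyEn(m=2, exp(-d^2/r)) over the trailing window.

    The tolerance r = 0.2 * SD(baseline) is calibrated once per trial from
    the first 3 s, so the statistic stays causal while responding to
    amplitude changes (a sliding-window tolerance would make it nearly
    scale-invariant and blind to a pure variance step).
    """
    w = _ms_to_samples(w_ms, fs)
    if w < 5:
        raise ValueError("fuzzy entropy needs a window of at least 5 samples")
    r = FUZZY_R_FRAC * float(np.std(x[:baseline_n], ddof=1))
    if r <= 0.0:
        logger.warning("Fuzzy Entropy: zero baseline SD; test function is 0")
    g = fuzzyen_sliding(
        np.ascontiguousarray(x, dtype=np.float64), w, r, FUZZY_SATURATION
    )
    return g, w - 1


def ricker_wavelet(scale: float, n_points: int | None = None) -> np.ndarray:
    """Second derivative of a Gaussian (Mexican hat), scale in samples."""
    if scale <= 0:
        raise ValueError("wavelet scale must be positive")
    if n_points is None:
        n_points = 2 * int(math.ceil(5 * scale)) + 1
    t = np.arange(n_points) - (n_points - 1) / 2.0
    a2 = scale**2
    norm = 2.0 / (math.sqrt(3.0 * scale) * math.pi**0.25)
    taps = norm * (1.0 - t**2 / a2) * np.exp(-(t**2) / (2.0 * a2))
    # remove the discretization residual so the DC gain is exactly zero
    return taps - taps.mean()


def tf_cwt(x: np.ndarray, fs: float, a_ms: float) -> tuple[np.ndarray, int]:
    """|correlation of x with a MUAP-shaped (Mexican-hat) wavelet| at one scale.

    The kernel is applied as a causal FIR (delayed by half its support), so
    g(n) is the magnitude of the wavelet coefficient centred (a_ms * 5) ms
    in the past.
    """
    scale = a_ms * fs / 1000.0
    kernel = ricker_wavelet(scale)
    g = np.abs(signal.lfilter(kernel, [1.0], x))
    warm = kernel.size - 1
    g[:warm] = 0.0
    return g, warm


def tf_ssa(
    x: np.ndarray, fs: float, w_ms: float, *, baseline_n: int = 3000
) -> tuple[np.ndarray, int]:
    """Distance of the current lagged vector from the baseline signal subspace.

    A lag-l trajectory matrix (l = W/2 samples) is built from the baseline;
    the top left-singular subspace capturing 90% of its energy defines the
    "normal" signal.  g(n) is the squared residual of the current lagged
    vector after projection, normalized by the vector's own energy, so
    g in [0, 1].
    """
    w = _ms_to_samples(w_ms, fs)
    lag = max(2, w // 2)
    if baseline_n <= lag:
        raise ValueError("baseline too short for the requested SSA lag")
    base = np.lib.stride_tricks.sliding_window_view(x[:baseline_n], lag)
    # eigendecomposition of the l x l second-moment matrix (economy SVD)
    cov = base.T @ base
    evals, evecs = np.linalg.eigh(cov)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    total = evals.sum()
    if total <= 0.0:
        logger.warning("SSA: zero-energy baseline; empty subspace")
        k = 0
    else:
        k = int(np.searchsorted(np.cumsum(evals) / total, SSA_ENERGY) + 1)
    u = evecs[:, :k]
    vecs = np.lib.stride_tricks.sliding_window_view(x, lag)
    resid = vecs - (vecs @ u) @ u.T
    num = np.einsum("ij,ij->i", resid, resid)
    den = np.einsum("ij,ij->i", vecs, vecs)
    gv = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    g = np.zeros(x.size)
    g[lag - 1 :] = gv
    return g, lag - 1


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def _single(g: np.ndarray, h: float) -> np.ndarray:
    return apply_single_threshold(g, h)


def _double(g: np.ndarray, h: float, m: int, t1: int) -> np.ndarray:
    return apply_double_threshold(apply_single_threshold(g, h), m, t1)


def detect(trial: SimulatedTrial, params: DetectorParams) -> DetectorOutput:
    """Run one detector on one trial.

    Computes the test function, estimates the adaptive threshold from the
    first 3 s, applies the detector's decision rule, and returns the full
    per-sample output.  g(n) depends only on x(0..n) for every detector.
    """
    if not isinstance(params, DetectorParams):
        params = DetectorParams(*params)
    x = trial.samples
    fs = trial.fs
    baseline_n = int(round(BASELINE_S * fs))
    name = params.detector_type
    v = params.values

    if x.size <= baseline_n:
        raise ValueError("trial shorter than the threshold-baseline phase")

    if name == "Modified Hodges":
        g, warm = tf_modified_hodges(x, fs, v["fc"])
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "Hodges":
        g, warm = tf_hodges(x, fs, v["fc"], v["W"], baseline_n=baseline_n)
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "Modified Lidierth":
        g, warm = tf_modified_hodges(x, fs, v["fc"])
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _double(g, h, _ms_to_samples(v["m"], fs), _ms_to_samples(v["T1"], fs))
    elif name == "Lidierth":
        g, warm = tf_lidierth(x, fs, v["W"], baseline_n=baseline_n)
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _double(g, h, _ms_to_samples(v["m"], fs), _ms_to_samples(v["T1"], fs))
    elif name == "RMS":
        g, warm, updates = tf_rms(x, fs, v["W"], v["p"])
        base_updates = updates[updates < baseline_n]
        seg = g[base_updates]
        mu, sd = seg.mean(), seg.std(ddof=1)
        h = mu if sd == 0.0 else mu + v["alpha"] * sd
        required = max(1, math.ceil(v["m"] / v["p"]))
        supra = g[updates] > h
        run = 0
        y_updates = np.zeros(updates.size, dtype=np.int8)
        for k, s in enumerate(supra):
            run = run + 1 if s else 0
            y_updates[k] = 1 if run >= required else 0
        y = np.zeros(x.size, dtype=np.int8)
        for k, n in enumerate(updates):
            end = updates[k + 1] if k + 1 < updates.size else x.size
            y[n:end] = y_updates[k]
    elif name == "TKEO":
        g, warm = tf_tkeo(x, fs, v["fc"], v["W"])
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _double(g, h, 1, _ms_to_samples(v["T1"], fs))
    elif name == "Bonato":
        g, warm, g_half, pair_warm = tf_bonato(x, baseline_n=baseline_n)
        half_base = baseline_n // 2
        seg = g_half[pair_warm:half_base]
        mu, sd = seg.mean(), seg.std(ddof=1)
        h = mu if sd == 0.0 else mu + v["alpha"] * sd
        m_half = max(1, int(round(_ms_to_samples(v["m"], fs) / 2)))
        t1_half = max(m_half, int(round(_ms_to_samples(v["T1"], fs) / 2)))
        y_half = apply_double_threshold(g_half > h, m_half, t1_half)
        y = np.zeros(x.size, dtype=np.int8)
        n_pairs = g_half.size
        odd = 2 * np.arange(n_pairs) + 1
        y[odd] = y_half
        y[odd[:-1] + 1] = y_half[:-1]
        if 2 * n_pairs < x.size:
            y[-1] = y_half[-1]
    elif name == "AGLR-G":
        g, warm = tf_aglr_gauss(x, fs, v["W"], baseline_n=baseline_n)
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "AGLR-L":
        g, warm = tf_aglr_laplace(x, fs, v["W"], baseline_n=baseline_n)
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "Sample Entropy":
        g, warm = tf_sample_entropy(x, fs, v["W"], v["rho"])
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "Fuzzy Entropy":
        g, warm = tf_fuzzy_entropy(x, fs, v["W"], baseline_n=baseline_n)
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "CWT":
        g, warm = tf_cwt(x, fs, v["a"])
        h = estimate_threshold(g, v["alpha"], warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    elif name == "SSA":
        g, warm = tf_ssa(x, fs, v["W"], baseline_n=baseline_n)
        h = estimate_threshold(g, 1.0, warmup=warm, baseline_n=baseline_n)
        y = _single(g, h)
    else:  # pragma: no cover - schema check precludes this
        raise ValueError(f"unknown detector type {name!r}")

    return DetectorOutput(g=g, h=float(h), y=np.asarray(y, dtype=np.int8), warmup=warm)
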