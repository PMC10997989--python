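"""Simulators for surface-EMG trials with a rest/move variance step.

Three signal models are provided, all producing 13 s trials sampled at
1 kHz (8 s rest, 5 s move):

* ``gaussian`` / ``laplacian`` — phenomenological models: zero-mean
  unit-variance white noise whose variance steps from ``sigma0**2`` (rest)
  to ``sigma0**2 + sigma1**2`` (move), shaped by an 8th-order FIR bandpass
  (10–450 Hz) applied zero-phase.  ``sigma0**2`` is fixed at 1 and
  ``sigma1**2 = 10**(snr_db / 10)``.
* ``biophysical`` — a motor-unit train model: each motor unit fires a
  jittered impulse train whose rate follows the requested force level,
  convolved with a bipolar-electrode motor-unit action potential (MUAP);
  white Gaussian noise is added with variance calibrated so the move-phase
  signal-to-noise ratio matches the request, then the same bandpass is
  applied.

Zero-phase filtering is used only here, at generation time; detectors must
remain causal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "SimulatedTrial",
    "BiophysicalConfig",
    "make_shaping_filter",
    "generate_phenomenological",
    "generate_biophysical",
    "generate_trials",
    "motor_unit_firing",
    "muap_waveform",
    "write_trialset_csv",
    "read_trialset_csv",
    "trialset_filename",
]

#: default trial geometry (samples at 1 kHz)
FS_DEFAULT = 1000.0
N_REST_DEFAULT = 8000
N_MOVE_DEFAULT = 5000

MODEL_TAGS = {"gaussian": "gauss", "laplacian": "lap", "biophysical": "biophy"}


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated sEMG trial.

    ``samples[:n_rest]`` is the rest phase, ``samples[n_rest:]`` the move
    phase; ``n_rest`` is the index of the first move-phase sample.
    """

    samples: np.ndarray
    fs: float
    n_rest: int
    model: str
    snr_db: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("trial samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trial samples must be finite")
        if not 0 < self.n_rest < samples.size:
            raise ValueError("n_rest must split the trial into two non-empty phases")
        object.__setattr__(self, "samples", samples)

    @property
    def n_total(self) -> int:
        return self.samples.size

    @property
    def n_move(self) -> int:
        return self.n_total - self.n_rest

    @property
    def rest(self) -> np.ndarray:
        return self.samples[: self.n_rest]

    @property
    def move(self) -> np.ndarray:
        return self.samples[self.n_rest :]


def make_shaping_filter(
    fs: float = FS_DEFAULT,
    band: tuple[float, float] = (10.0, 450.0),
    order: int = 8,
) -> np.ndarray:
    """Linear-phase FIR bandpass used to shape white noise into sEMG.

    Returns the ``order + 1`` filter taps (Hamming-windowed sinc design).
    The DC gain is exactly zero.  At generation time the filter is applied
    forward-backward (zero phase).
    """
    low, high = band
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(f"invalid band {band!r} for fs={fs}")
    if order < 2:
        raise ValueError("filter order must be >= 2")
    return signal.firwin(order + 1, [low, high], pass_zero=False, fs=fs)


def _shape(x: np.ndarray, fs: float) -> np.ndarray:
    taps = make_shaping_filter(fs)
    return signal.filtfilt(taps, [1.0], x)


def _trial_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based Philox stream keyed on (seed, trial index): independent,
    # reproducible trials
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), int(index)])))


def generate_phenomenological(
    distribution: str,
    snr_db: float,
    n_trials: int,
    seed: int,
    *,
    fs: float = FS_DEFAULT,
    n_rest: int = N_REST_DEFAULT,
    n_move: int = N_MOVE_DEFAULT,
    filtered: bool = True,
) -> list[SimulatedTrial]:
    """Generate trials from the Gaussian or Laplacian phenomenological model.

    White unit-variance noise is scaled by ``sigma(n)`` — ``sigma0 = 1`` in
    rest, ``sqrt(sigma0**2 + sigma1**2)`` in move with
    ``sigma1**2 = 10**(snr_db/10)`` — then zero-phase bandpass filtered.
    ``filtered=False`` returns the pre-filter variance-step noise (used for
    calibration checks).
    """
    if distribution not in ("gaussian", "laplacian"):
        raise ValueError(f"unknown distribution {distribution!r}")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    n_total = n_rest + n_move
    sigma1_sq = 10.0 ** (snr_db / 10.0)
    scale = np.ones(n_total)
    scale[n_rest:] = math.sqrt(1.0 + sigma1_sq)

    trials = []
    for i in range(n_trials):
        rng = _trial_rng(seed, i)
        if distribution == "gaussian":
            e = rng.standard_normal(n_total)
        else:
            # Laplace(0, b) with b = 1/sqrt(2) has unit variance
            e = rng.laplace(0.0, 1.0 / math.sqrt(2.0), n_total)
        x = e * scale
        if filtered:
            x = _shape(x, fs)
        trials.append(SimulatedTrial(x, fs, n_rest, distribution, snr_db))
    return trials


# ---------------------------------------------------------------------------
# biophysical model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiophysicalConfig:
    """Motor-unit pool and electrode geometry for the biophysical model.

    The pool follows the size principle: recruitment thresholds spread
    exponentially over ``[0, recruitment_max_force]`` and all units are
    recruited at the move-phase force.  The rate-vs-force gain is solved in
    closed form so the pool's mean firing rate at ``force_move`` equals
    ``target_mean_rate_hz``.  The single-fibre action potential is a
    biphasic (first-derivative-of-Gaussian) wave; the bipolar electrode is a
    spatial difference with ``electrode_distance_mm`` spacing travelling at
    ``conduction_velocity_m_s``.
    """

    n_motor_units: int = 100
    fibers_mean: float = 80.0
    fiber_amplitude_mv: float = 0.001  # per-fibre contribution to the surface MUAP peak
    force_rest: float = 0.0
    force_move: float = 10.0
    target_mean_rate_hz: float = 16.4
    min_rate_hz: float = 8.0
    recruitment_max_force: float = 8.0
    isi_cv: float = 0.15
    sfap_time_constant_ms: float = 2.0
    dispersion_ms: float = 3.0
    electrode_distance_mm: float = 10.0
    conduction_velocity_m_s: float = 4.0

    def recruitment_thresholds(self) -> np.ndarray:
        """Exponentially spaced recruitment thresholds in [0, max_force)."""
        q = np.arange(self.n_motor_units)
        frac = (np.exp(np.log(101.0) * q / self.n_motor_units) - 1.0) / 100.0
        return self.recruitment_max_force * frac

    def rate_gain(self) -> float:
        """Hz/N slope making the mean pool rate hit the calibration target."""
        thr = self.recruitment_thresholds()
        excess = np.mean(self.force_move - thr)
        if excess <= 0:
            raise ValueError("force_move must recruit the whole pool")
        return (self.target_mean_rate_hz - self.min_rate_hz) / excess

    def firing_rates(self, force: float) -> np.ndarray:
        """Per-unit firing rate (Hz) at a given force; 0 for unrecruited units."""
        thr = self.recruitment_thresholds()
        rates = np.where(
            force > thr, self.min_rate_hz + self.rate_gain() * (force - thr), 0.0
        )
        if force <= 0:
            rates = np.zeros_like(rates)
        return rates


def motor_unit_firing(
    force: float,
    config: BiophysicalConfig,
    duration: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Spike times (s) for each motor unit at a constant force level.

    Inter-spike intervals are Gaussian-jittered around 1/rate with
    coefficient of variation ``config.isi_cv``; zero force produces empty
    trains for every unit.
    """
    if force < 0:
        raise ValueError("force must be non-negative")
    rates = config.firing_rates(force)
    trains: list[np.ndarray] = []
    for rate in rates:
        if rate <= 0 or duration <= 0:
            trains.append(np.empty(0))
            continue
        mean_isi = 1.0 / rate
        n_max = int(duration * rate * 2 + 20)
        isi = rng.normal(mean_isi, config.isi_cv * mean_isi, n_max)
        isi = np.clip(isi, 0.1 * mean_isi, None)
        t = rng.uniform(0.0, mean_isi) + np.cumsum(isi) - isi[0]
        trains.append(t[t < duration])
    return trains


def muap_waveform(config: BiophysicalConfig, fs: float) -> np.ndarray:
    """Bipolar-electrode MUAP template (unit peak amplitude).

    The single-fibre potential p(t) = t*exp(-(t/tau)^2) is broadened by a
    Gaussian kernel modelling intra-unit temporal dispersion (endplate
    scatter and per-fibre conduction differences), which gives the unit
    potential its realistic 10-15 ms width and low-frequency-dominated
    spectrum; the bipolar montage then subtracts a copy delayed by the
    inter-electrode travel time.
    """
    tau = config.sfap_time_constant_ms / 1000.0
    disp = config.dispersion_ms / 1000.0
    delay = config.electrode_distance_mm / 1000.0 / config.conduction_velocity_m_s
    support = 5.0 * tau + 4.0 * disp + delay
    t = np.arange(0.0, support, 1.0 / fs)
    sfap = t * np.exp(-((t / tau) ** 2))
    if disp > 0:
        k = np.exp(-0.5 * ((np.arange(-4.0 * disp, 4.0 * disp, 1.0 / fs)) / disp) ** 2)
        sfap = signal.fftconvolve(sfap, k / k.sum())[: t.size]
    n_delay = int(round(delay * fs))
    wave = sfap.copy()
    if n_delay > 0:
        wave[n_delay:] -= sfap[:-n_delay]
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def _pure_emg(
    config: BiophysicalConfig,
    fs: float,
    n_rest: int,
    n_move: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free bipolar sEMG: zero in rest, MUAP trains in move."""
    n_total = n_rest + n_move
    duration = n_move / fs
    trains = motor_unit_firing(config.force_move, config, duration, rng)
    wave = muap_waveform(config, fs)
    # unit amplitudes in mV ~ fibre count x per-fibre surface contribution;
    # lognormal scatter around fibers_mean models the motor-unit size spread
    amps = rng.lognormal(mean=0.0, sigma=0.5, size=len(trains))
    amps *= config.fibers_mean * config.fiber_amplitude_mv / np.mean(amps)
    impulse = np.zeros(n_move + wave.size)
    x = np.zeros(n_total + wave.size)
    for train, amp in zip(trains, amps):
        impulse[:] = 0.0
        idx = np.round(train * fs).astype(int)
        idx = idx[idx < n_move]
        np.add.at(impulse, idx, amp)
        conv = signal.fftconvolve(impulse[:n_move], wave)
        x[n_rest : n_rest + conv.size] += conv
    return x[:n_total]


def generate_biophysical(
    snr_db: float,
    n_trials: int,
    seed: int,
    config: BiophysicalConfig | None = None,
    *,
    fs: float = FS_DEFAULT,
    n_rest: int = N_REST_DEFAULT,
    n_move: int = N_MOVE_DEFAULT,
    add_noise: bool = True,
    filtered: bool = True,
) -> list[SimulatedTrial]:
    """Generate trials from the motor-unit biophysical model.

    The move-phase power of the pure signal defines ``sigma1**2``; additive
    white Gaussian noise with ``sigma0**2 = sigma1**2 / 10**(snr_db/10)`` is
    then mixed in and the sum bandpass filtered (10–450 Hz, zero phase).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if config is None:
        config = BiophysicalConfig()
    snr_linear = 10.0 ** (snr_db / 10.0)
    trials = []
    for i in range(n_trials):
        rng = _trial_rng(seed, i)
        pure = _pure_emg(config, fs, n_rest, n_move, rng)
        sigma1_sq = float(np.mean(pure[n_rest:] ** 2))
        if sigma1_sq == 0.0:
            raise ValueError("move-phase signal power is zero; cannot calibrate noise")
        x = pure
        if add_noise:
            sigma0_sq = sigma1_sq / snr_linear
            x = pure + rng.normal(0.0, math.sqrt(sigma0_sq), pure.size)
        if filtered:
            x = _shape(x, fs)
        trials.append(SimulatedTrial(x, fs, n_rest, "biophysical", snr_db))
    return trials


def generate_trials(
    model: str,
    snr_db: float,
    n_trials: int,
    seed: int,
    config: BiophysicalConfig | None = None,
    **kwargs,
) -> list[SimulatedTrial]:
    """Dispatch to the phenomenological or biophysical generator by name."""
    if model in ("gaussian", "laplacian"):
        return generate_phenomenological(model, snr_db, n_trials, seed, **kwargs)
    if model == "biophysical":
        return generate_biophysical(snr_db, n_trials, seed, config, **kwargs)
    raise ValueError(f"unknown signal model {model!r}")


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def trialset_filename(model: str, snr_db: float, n_trials: int, duration_s: int = 13) -> str:
    """Deposited-convention file name, e.g. ``EMGDataSNR0trail50dur13biophy.csv``."""
    tag = MODEL_TAGS.get(model)
    if tag is None:
        raise ValueError(f"unknown signal model {model!r}")
    snr = int(snr_db) if float(snr_db).is_integer() else snr_db
    return f"EMGDataSNR{snr}trail{n_trials}dur{duration_s}{tag}.csv"


def write_trialset_csv(trials: list[SimulatedTrial], path: str | Path) -> None:
    """Write a trial set as decimal text, one column per trial.

    Metadata (fs, n_rest, model, snr_db) goes to a ``<path>.meta.json``
    companion so the matrix stays plain CSV.
    """
    if not trials:
        raise ValueError("empty trial set")
    first = trials[0]
    for t in trials:
        if (t.n_total, t.n_rest, t.fs, t.model, t.snr_db) != (
            first.n_total,
            first.n_rest,
            first.fs,
            first.model,
            first.snr_db,
        ):
            raise ValueError("trials in one set must share geometry and metadata")
    path = Path(path)
    matrix = np.column_stack([t.samples for t in trials])
    header = ",".join(f"trial{i}" for i in range(len(trials)))
    np.savetxt(path, matrix, delimiter=",", fmt="%.17g", header=header, comments="")
    meta = {
        "fs": first.fs,
        "n_rest": first.n_rest,
        "n_total": first.n_total,
        "model": first.model,
        "snr_db": first.snr_db,
        "n_trials": len(trials),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trialset_csv(path: str | Path) -> list[SimulatedTrial]:
    """Read a trial set written by :func:`write_trialset_csv`."""
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata companion {meta_path}")
    meta = json.loads(meta_path.read_text())
    try:
        matrix = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed trial CSV {path}: {exc}") from exc
    if matrix.shape[0] != meta["n_total"]:
        raise ValueError(
            f"{path}: expected {meta['n_total']} rows, found {matrix.shape[0]}"
        )
    if matrix.shape[1] != meta["n_trials"]:
        raise ValueError(
            f"{path}: expected {meta['n_trials']} columns, found {matrix.shape[1]}"
        )
    return [
        SimulatedTrial(matrix[:, j], meta["fs"], meta["n_rest"], meta["model"], meta["snr_db"])
        for j in range(matrix.shape[1])
    ]
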