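"""Detector tests: thresholds, per-detector oracles, causality, invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import signal as sp_signal

from emgonset.detectors import (
    DETECTOR_NAMES,
    DetectorParams,
    apply_double_threshold,
    apply_single_threshold,
    detect,
    estimate_threshold,
    ricker_wavelet,
    sampen_cap,
    tf_aglr_gauss,
    tf_aglr_laplace,
    tf_bonato,
    tf_cwt,
    tf_hodges,
    tf_lidierth,
    tf_modified_hodges,
    tf_rms,
    tf_sample_entropy,
    tf_ssa,
    tf_tkeo,
    whiten,
)
from emgonset._entropy import fuzzyen_sliding, sampen_sliding
from emgonset.signal_models import SimulatedTrial

from _oracles import (
    aglr_gauss_oracle,
    aglr_lap_oracle,
    causal_convolution_oracle,
    fuzzyen_oracle,
    mav_oracle,
    rms_window_oracle,
    sampen_oracle,
    tkeo_oracle,
)

# parameter sets that are legal for every detector at fs = 1 kHz
SMOKE_PARAMS = {
    "Modified Hodges": {"alpha": 1, "fc": 7.5},
    "Hodges": {"alpha": 1, "fc": 9.5, "W": 100},
    "Modified Lidierth": {"alpha": 1, "fc": 9.5, "m": 20, "T1": 30},
    "Lidierth": {"alpha": 1, "W": 100, "m": 10, "T1": 30},
    "RMS": {"alpha": 1, "W": 120, "p": 40, "m": 40},
    "TKEO": {"alpha": 1, "fc": 5, "W": 100, "T1": 30},
    "Bonato": {"alpha": 1, "m": 10, "T1": 30},
    "AGLR-G": {"alpha": 2, "W": 100},
    "AGLR-L": {"alpha": 1, "W": 100},
    "Sample Entropy": {"alpha": 1, "W": 50, "rho": 0.5},
    "Fuzzy Entropy": {"alpha": 1, "W": 60},
    "CWT": {"alpha": 1.1, "a": 16},
    "SSA": {"W": 52},
}


class TestThreshold:
    def test_constant_baseline_gives_mean(self):
        g = np.full(4000, 2.5)
        assert estimate_threshold(g, alpha=3.0) == 2.5

    def test_hand_computed_example(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = np.std(g, ddof=1)
        assert estimate_threshold(g, alpha=2.0, baseline_n=5) == pytest.approx(
            3.0 + 2.0 * sd
        )

    def test_standard_normal_alpha_one(self, rng):
        g = rng.standard_normal(100_000)
        assert estimate_threshold(g, alpha=1.0, baseline_n=100_000) == pytest.approx(
            1.0, abs=0.02
        )

    def test_warmup_exclusion(self):
        g = np.r_[np.zeros(100), np.ones(2900)]
        assert estimate_threshold(g, alpha=5.0, warmup=100) == 1.0


class TestDecisionRules:
    def test_single_threshold_strict(self):
        g = np.array([1.0, 1.0, 1.0 + 1e-12, 0.5])
        np.testing.assert_array_equal(apply_single_threshold(g, 1.0), [0, 0, 1, 0])

    def test_double_threshold_all_ones_starts_at_m_minus_1(self):
        y = apply_double_threshold(np.ones(20), m=3, t1=5)
        np.testing.assert_array_equal(y[:2], 0)
        np.testing.assert_array_equal(y[2:], 1)

    def test_double_threshold_m1_stretches_pulses(self):
        b = np.zeros(15)
        b[4] = 1
        y = apply_double_threshold(b, m=1, t1=5)
        np.testing.assert_array_equal(np.flatnonzero(y), np.arange(4, 9))

    def test_isolated_one_never_reaches_m2(self):
        b = np.zeros(30)
        b[10] = 1
        assert apply_double_threshold(b, m=2, t1=6).sum() == 0

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            apply_double_threshold(np.zeros(5), m=4, t1=3)

    def test_brute_force_window_counts(self, rng):
        b = (rng.random(300) < 0.3).astype(int)
        y = apply_double_threshold(b, m=4, t1=10)
        for n in range(300):
            lo = max(0, n - 9)
            assert y[n] == (b[lo : n + 1].sum() >= 4)


class TestWhitening:
    def test_ar1_coefficient_recovered_and_flattened(self, rng):
        e = rng.standard_normal(20_000)
        x = sp_signal.lfilter([1.0], [1.0, -0.8], e)
        xt = whiten(x, baseline_n=10_000)
        tail = xt[6:]
        r1 = np.corrcoef(tail[:-1], tail[1:])[0, 1]
        assert abs(r1) < 3.0 / np.sqrt(tail.size)

    def test_white_input_passthrough(self, rng):
        x = rng.standard_normal(8000)
        xt = whiten(x, baseline_n=4000)
        assert np.corrcoef(x[6:], xt[6:])[0, 1] > 0.99

    def test_constant_input_degenerates_gracefully(self):
        xt = whiten(np.full(5000, 1.5), baseline_n=3000)
        assert np.all(np.isfinite(xt))


class TestTestFunctionOracles:
    def test_modified_hodges_matches_difference_equation(self, rng):
        x = rng.standard_normal(200)
        g, warm = tf_modified_hodges(x, 1000.0, 7.5)
        b, a = sp_signal.butter(2, 7.5, fs=1000.0)
        ref = np.zeros(200)
        xr = np.abs(x)
        for n in range(200):  # direct recursion of the difference equation
            acc = sum(b[k] * xr[n - k] for k in range(3) if n - k >= 0)
            acc -= sum(a[k] * ref[n - k] for k in range(1, 3) if n - k >= 0)
            ref[n] = acc / a[0]
        ref[:warm] = 0.0
        np.testing.assert_allclose(g, ref, rtol=1e-9, atol=1e-12)

    def test_modified_hodges_dc_gain_unity(self):
        g, _ = tf_modified_hodges(np.full(5000, 2.0), 1000.0, 7.5)
        assert g[-1] == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_hodges_mav_stage_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(400)
        w = 25
        g, warm = tf_lidierth(x, 1000.0, w, baseline_n=300)
        hat = mav_oracle(np.abs(x), w)
        mu = hat[warm:300].mean()
        sd = hat[warm:300].std(ddof=1)
        ref = (hat - mu) / sd
        ref[:warm] = 0.0
        np.testing.assert_allclose(g, ref, rtol=1e-9, atol=1e-12)

    def test_hodges_baseline_standardized(self, gaussian_trial):
        g, warm = tf_hodges(gaussian_trial.samples, 1000.0, 9.5, 100)
        base = g[warm:3000]
        assert base.mean() == pytest.approx(0.0, abs=1e-9)
        assert base.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_rms_hand_example_and_hold(self):
        x = np.array([1.0, 2.0, 2.0, 0.0, 0.0, 0.0])
        w = [1.0, 2.0, 2.0]
        assert rms_window_oracle(w) == pytest.approx(math.sqrt(3.0))
        # constant input: steady-state RMS equals |c| (conditioning disabled
        # by construction: feed the already-conditioned value through MAV)
        from emgonset.detectors import _causal_mav

        ms = _causal_mav(np.full(1000, 4.0) ** 2, 10)
        assert np.sqrt(ms[-1]) == pytest.approx(4.0)

    def test_rms_block_update_and_hold(self, rng):
        x = rng.standard_normal(300)
        g, warm, updates = tf_rms(x, 1000.0, 50, 20)
        b, a = sp_signal.butter(4, [10.0, 450.0], btype="bandpass", fs=1000.0)
        xc = sp_signal.lfilter(b, a, x)
        for n in updates:
            assert g[n] == pytest.approx(rms_window_oracle(xc[max(0, n - 49) : n + 1]),
                                         rel=1e-9)
        # held constant between updates
        for k in range(len(updates) - 1):
            seg = g[updates[k] : updates[k + 1]]
            assert np.all(seg == seg[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_tkeo_recurrence_matches_direct_evaluation(self, seed):
        rng = np.random.default_rng(10 + seed)
        x = rng.standard_normal(6)
        from emgonset.detectors import _causal_mav

        # isolate the psi stage by applying the implementation to a signal
        # and comparing MAV(psi_oracle) after identical high-pass filtering
        xfull = rng.standard_normal(200)
        g, warm = tf_tkeo(xfull, 1000.0, 5.0, 20)
        b, a = sp_signal.butter(2, 5.0, btype="high", fs=1000.0)
        xt = sp_signal.lfilter(b, a, xfull)
        ref = mav_oracle(tkeo_oracle(xt), 20)
        ref[:warm] = 0.0
        np.testing.assert_allclose(g, ref, rtol=1e-9, atol=1e-12)

    def test_tkeo_constant_and_sinusoid_identities(self):
        psi = tkeo_oracle(np.full(50, 3.0))
        np.testing.assert_allclose(psi[2:], 0.0, atol=1e-12)
        n = np.arange(500)
        omega = 0.3
        x = 2.0 * np.sin(omega * n)
        psi = tkeo_oracle(x)[10:]
        np.testing.assert_allclose(psi, 4.0 * np.sin(omega) ** 2, atol=1e-9)

    def test_aglr_gauss_closed_form_and_numeric_oracle(self, rng):
        # baseline sigma0^2 = 1, window with mean square exactly 2 -> the
        # published closed-form value 50*(2 - ln 2 - 1)
        w = 100
        window = rng.standard_normal(w)
        window *= math.sqrt(2.0 * w / np.sum(window**2))
        expected = 0.5 * w * (2.0 - math.log(2.0) - 1.0)
        assert expected == pytest.approx(15.3426409720027, abs=1e-10)
        assert aglr_gauss_oracle(window, 1.0) == pytest.approx(expected, abs=1e-9)

    def test_aglr_lap_closed_form_and_numeric_oracle(self, rng):
        w = 100
        window = rng.laplace(0.0, 1.0, w)
        window *= 2.0 * w / np.sum(np.abs(window))  # b_hat = 2, b0 = 1
        expected = w * (2.0 - math.log(2.0) - 1.0)
        assert expected == pytest.approx(30.6852819440055, abs=1e-10)
        assert aglr_lap_oracle(window, 1.0) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("tf,oracle", [(tf_aglr_gauss, aglr_gauss_oracle),
                                           (tf_aglr_laplace, aglr_lap_oracle)])
    def test_aglr_statistics_match_likelihood_oracle(self, tf, oracle, rng):
        # the whitened path's statistic must equal the explicit LLR of its
        # own trailing window against its own baseline estimate
        x = rng.standard_normal(4000)
        x[3500:] *= 2.0
        w_ms = 50
        g, warm = tf(x, 1000.0, w_ms, baseline_n=3000)
        xt = whiten(x, baseline_n=3000)
        w = 50
        if tf is tf_aglr_gauss:
            base = xt[6:3000].var(ddof=1)
        else:
            base = np.abs(xt[6:3000]).mean()
        for n in [3100, 3600, 3999]:
            ref = oracle(xt[n - w + 1 : n + 1], base)
            assert g[n] == pytest.approx(ref, rel=1e-9)

    def test_aglr_nonnegative_zero_at_baseline_match(self):
        w = 100
        assert 0.5 * w * (1.0 - math.log(1.0) - 1.0) == 0.0
        g, warm = tf_aglr_gauss(np.random.default_rng(3).standard_normal(5000), 1000.0, 100)
        assert np.all(g >= 0.0)

    def test_bonato_pair_statistic(self, rng):
        x = rng.standard_normal(8000)
        g, warm, g_half, pair_warm = tf_bonato(x, baseline_n=3000)
        xt = whiten(x, baseline_n=3000)
        s0 = xt[6:3000].var(ddof=1)
        for k in [10, 100, 3000]:
            ref = (xt[2 * k] ** 2 + xt[2 * k + 1] ** 2) / s0
            assert g_half[k] == pytest.approx(ref, rel=1e-12)
        # white baseline: chi-square(2)-like statistic with mean ~2
        assert g_half[pair_warm:1500].mean() == pytest.approx(2.0, abs=0.15)
        # full-timeline signal holds the last completed pair (causality)
        assert g[21] == g_half[10]
        assert g[22] == g_half[10]

    @pytest.mark.parametrize("seed", range(3))
    def test_sample_entropy_matches_brute_force(self, seed):
        rng = np.random.default_rng(30 + seed)
        x = rng.standard_normal(120)
        w, rho = 50, 0.5
        g, warm = tf_sample_entropy(x, 1000.0, w, rho)
        cap = sampen_cap(w)
        for n in [49, 80, 119]:
            ref = sampen_oracle(x[n - w + 1 : n + 1], rho, cap)
            assert g[n] == pytest.approx(ref, rel=1e-9)

    def test_sample_entropy_degenerate_windows(self):
        w = 20
        const = np.full(60, 1.0)
        g = sampen_sliding(const, w, 0.5, sampen_cap(w))
        np.testing.assert_allclose(g[w - 1 :], 0.0)  # all templates match
        ramp = np.arange(60.0)
        g = sampen_sliding(ramp, w, 1e-6, sampen_cap(w))
        np.testing.assert_allclose(g[w - 1 :], sampen_cap(w))  # no matches

    @pytest.mark.parametrize("seed", range(3))
    def test_fuzzy_entropy_matches_brute_force(self, seed):
        rng = np.random.default_rng(60 + seed)
        x = rng.standard_normal(100)
        w, r = 50, 0.3
        g = fuzzyen_sliding(x, w, r, 700.0)
        for n in [49, 70, 99]:
            ref = fuzzyen_oracle(x[n - w + 1 : n + 1], r)
            assert g[n] == pytest.approx(ref, rel=1e-9)

    def test_fuzzy_entropy_constant_window_is_zero(self):
        g = fuzzyen_sliding(np.full(60, 2.0), 20, 0.5, 700.0)
        np.testing.assert_allclose(g[19:], 0.0, atol=1e-12)

    def test_fuzzy_membership_monotone_in_distance(self):
        r = 0.4
        d = np.linspace(0, 3, 50)
        mem = np.exp(-(d**2) / r)
        assert np.all(np.diff(mem) < 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_cwt_matches_direct_convolution(self, seed):
        rng = np.random.default_rng(90 + seed)
        x = rng.standard_normal(16)
        g, warm = tf_cwt(x, 1000.0, 2.0)
        kernel = ricker_wavelet(2.0)
        ref = causal_convolution_oracle(x, kernel)
        ref[:warm] = 0.0
        np.testing.assert_allclose(g, ref, rtol=1e-9, atol=1e-12)

    def test_cwt_rejects_constants_and_peaks_on_matched_shape(self):
        g, _ = tf_cwt(np.full(600, 5.0), 1000.0, 8.0)
        assert np.max(g[400:]) < 1e-9
        kernel = ricker_wavelet(8.0 * 1.0)
        x = np.zeros(600)
        x[300 : 300 + kernel.size] = kernel
        g, _ = tf_cwt(x, 1000.0, 8.0)
        assert np.argmax(g) == 300 + kernel.size - 1  # alignment at full overlap

    def test_ssa_projection_identities(self, rng):
        # baseline = pure sinusoid: its continuation lies in the baseline
        # subspace (g ~ 0); an orthogonal-frequency burst does not
        n = np.arange(4000)
        x = np.sin(2 * np.pi * 0.01 * n)
        x[3500:] = np.sign(np.sin(2 * np.pi * 0.25 * n[3500:]))
        g, warm = tf_ssa(x, 1000.0, 52, baseline_n=3000)
        assert np.max(g[warm:3000]) < 1e-6
        assert np.median(g[3600:]) > 0.1
        assert np.all((g >= 0) & (g <= 1.0 + 1e-9))

    def test_ssa_matches_explicit_projector(self, rng):
        x = rng.standard_normal(3500)
        w_ms = 40
        lag = 20
        g, warm = tf_ssa(x, 1000.0, w_ms, baseline_n=3000)
        base = np.lib.stride_tricks.sliding_window_view(x[:3000], lag)
        u, s, vt = np.linalg.svd(base.T @ base)
        energy = np.cumsum(s) / np.sum(s)
        k = int(np.searchsorted(energy, 0.9) + 1)
        proj = np.eye(lag) - u[:, :k] @ u[:, :k].T
        for n in [3100, 3499]:
            v = x[n - lag + 1 : n + 1]
            ref = float(v @ proj @ v) / float(v @ v)
            assert g[n] == pytest.approx(ref, rel=1e-6, abs=1e-9)


class TestDetectInvariants:
    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_output_contract(self, name, short_trial):
        out = detect(short_trial, DetectorParams(name, SMOKE_PARAMS[name]))
        assert out.g.size == short_trial.n_total
        assert out.y.size == short_trial.n_total
        assert np.all(np.isfinite(out.g))
        np.testing.assert_array_equal(out.g[: out.warmup], 0.0)
        assert set(np.unique(out.y)) <= {0, 1}
        assert np.isfinite(out.h)

    @pytest.mark.parametrize("name", DETECTOR_NAMES)
    def test_causality_prefix_invariance(self, name, short_trial):
        """Truncating the future never changes the past decisions."""
        params = DetectorParams(name, SMOKE_PARAMS[name])
        full = detect(short_trial, params)
        cut = 3900
        truncated = SimulatedTrial(
            short_trial.samples[:cut],
            short_trial.fs,
            short_trial.n_rest,
            short_trial.model,
            short_trial.snr_db,
        )
        part = detect(truncated, params)
        np.testing.assert_array_equal(part.y, full.y[:cut])
        np.testing.assert_allclose(part.g, full.g[:cut], rtol=1e-12, atol=1e-12)

    def test_modified_lidierth_degenerates_to_modified_hodges(self, short_trial):
        ml = detect(
            short_trial,
            DetectorParams("Modified Lidierth", {"alpha": 1, "fc": 7.5, "m": 1, "T1": 1}),
        )
        mh = detect(short_trial, DetectorParams("Modified Hodges", {"alpha": 1, "fc": 7.5}))
        np.testing.assert_array_equal(ml.y, mh.y)

    @pytest.mark.parametrize("name", ["Modified Hodges", "AGLR-G", "Lidierth", "Bonato"])
    def test_false_positives_monotone_in_alpha(self, name, short_trial):
        from emgonset.evaluation import false_positive_rate

        rates = []
        for alpha in [0.5, 1, 2, 4]:
            values = dict(SMOKE_PARAMS[name], alpha=alpha)
            out = detect(short_trial, DetectorParams(name, values))
            rates.append(false_positive_rate(out.y, short_trial.n_rest, short_trial.fs))
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_short_trial_rejected(self):
        t = SimulatedTrial(np.random.default_rng(0).standard_normal(2000), 1000.0, 1500,
                           "gaussian", 0.0)
        with pytest.raises(ValueError):
            detect(t, DetectorParams("Modified Hodges", {"alpha": 1, "fc": 7.5}))

    def test_illegal_params_rejected(self):
        with pytest.raises(ValueError):
            DetectorParams("Modified Hodges", {"alpha": 1})
        with pytest.raises(ValueError):
            DetectorParams("Modified Hodges", {"alpha": 1, "fc": 7.5, "W": 100})
        with pytest.raises(ValueError):
            DetectorParams("AGLR-G", {"alpha": -1, "W": 100})
        with pytest.raises(ValueError):
            DetectorParams("nonsense", {})
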