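"""Moment features, dispersion entropy (with brute-force oracle), ECG features."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import norm

from sleepsig.features import (DEParams, dispersion_entropy, ecg_feature_vector,
                               emg_feature_vector, moment_features,
                               resp_amplitude_features, resp_if_features,
                               respiratory_modulation, rpeak_timing_features,
                               RespModulation)
from sleepsig.rpeak import RPeakSet, iterative_rpeak_detect
from sleepsig.synthetic import GroupProfile, gen_ecg, gen_emg
from sleepsig.tfa import SignalSegment


def de_oracle(x, m, c, d):
    """Independent dispersion entropy: explicit tuple patterns via a Counter."""
    x = np.asarray(x, dtype=float)
    y = norm.cdf(x, loc=x.mean(), scale=x.std())
    z = [min(max(int(math.floor(c * yi + 1.0)), 1), c) for yi in y]
    n_words = len(x) - (m - 1) * d
    words = Counter(tuple(z[i + k * d] for k in range(m)) for i in range(n_words))
    return -sum((n / n_words) * math.log(n / n_words) for n in words.values())


class TestMoments:
    def test_simple_worked_example(self):
        # {1, 2, 3}: mean 2, population var 2/3, symmetric, platykurtic
        mean, sd, skew, kurt = moment_features([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.5)

    def test_alternating_sequence(self):
        # {-1, 1, -1, 1}: two-point distribution, kurtosis exactly 1
        mean, sd, skew, kurt = moment_features([-1.0, 1.0, -1.0, 1.0])
        assert mean == 0.0 and sd == 1.0 and skew == 0.0 and kurt == 1.0

    def test_matches_four_pass_oracle(self, rng):
        x = rng.gamma(2.0, 1.5, size=500)  # skewed on purpose
        mean, sd, skew, kurt = moment_features(x)
        mu = sum(x) / len(x)
        m2 = sum((v - mu) ** 2 for v in x) / len(x)
        m3 = sum((v - mu) ** 3 for v in x) / len(x)
        m4 = sum((v - mu) ** 4 for v in x) / len(x)
        assert mean == pytest.approx(mu, rel=1e-12)
        assert sd == pytest.approx(math.sqrt(m2), rel=1e-12)
        assert skew == pytest.approx(m3 / m2 ** 1.5, rel=1e-9)
        assert kurt == pytest.approx(m4 / m2 ** 2, rel=1e-9)

    def test_constant_signal_shape_moments_zero(self):
        mean, sd, skew, kurt = moment_features(np.full(10, 3.7))
        assert (mean, sd, skew, kurt) == (3.7, 0.0, 0.0, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            moment_features([1.0])


class TestDispersionEntropy:
    def test_matches_oracle_on_random_signals(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(20, 200))
            x = r.standard_normal(n)
            p = DEParams(m=int(r.integers(2, 4)), c=int(r.integers(3, 7)),
                         d=int(r.integers(1, 3)))
            assert dispersion_entropy(x, p) == pytest.approx(
                de_oracle(x, p.m, p.c, p.d), abs=1e-12), f"seed={seed}"

    def test_alternating_signal_two_patterns(self):
        # strictly alternating values -> only the words (1,2) and (2,1), DE=ln 2
        x = np.tile([-1.0, 1.0], 200)
        x += np.linspace(0, 1e-9, x.size)  # break exact ties, keep ordering
        de = dispersion_entropy(x, DEParams(m=2, c=2, d=1))
        assert de == pytest.approx(np.log(2), abs=1e-4)
        assert de == pytest.approx(de_oracle(x, 2, 2, 1), abs=1e-12)

    def test_single_word_gives_zero(self):
        # n = (m-1)d + 1 leaves exactly one embedded word: zero entropy
        assert dispersion_entropy(np.array([0.0, 1.0]),
                                  DEParams(m=2, c=2, d=1)) == 0.0

    def test_lower_bound_zero(self):
        # a monotone ramp mapped to c=2 classes yields long constant runs;
        # entropy is small but never below zero
        x = np.linspace(-10, 10, 500)
        de = dispersion_entropy(x, DEParams(m=2, c=2, d=1))
        assert de >= 0.0

    def test_upper_bound_m_ln_c(self, rng):
        p = DEParams(m=2, c=5, d=1)
        for _ in range(20):
            de = dispersion_entropy(rng.standard_normal(4000), p)
            assert de <= p.m * np.log(p.c) + 1e-12
        # white noise should come close to the bound
        assert de > 0.9 * p.m * np.log(p.c)

    def test_uniform_pattern_distribution_achieves_maximum(self):
        # craft a class sequence visiting all c^m = 4 patterns equally (m=2,c=2)
        # low/high values straddling the median map to classes 1/2
        base = [-1.0, -1.0, 1.0, 1.0]  # words: 11,12,22,21 cyclically
        x = np.array(base * 100 + [-1.0])  # 401 samples -> 400 words, 100 each
        x += np.linspace(0, 1e-9, x.size)
        de = dispersion_entropy(x, DEParams(m=2, c=2, d=1))
        assert de == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(300)
        p = DEParams()
        assert dispersion_entropy(3.2 * x + 17.0, p) == pytest.approx(
            dispersion_entropy(x, p), abs=1e-12)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            dispersion_entropy(np.ones(100))

    def test_too_short_for_embedding_rejected(self):
        with pytest.raises(ValueError):
            dispersion_entropy(np.array([1.0, 2.0]), DEParams(m=3, c=3, d=2))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DEParams(m=1)
        with pytest.raises(ValueError):
            DEParams(c=1)
        with pytest.raises(ValueError):
            DEParams(d=0)


class TestEMGVector:
    def test_five_features_fixed_order(self, rng):
        win = SignalSegment(rng.standard_normal(4000), 200.0)
        v = emg_feature_vector(win)
        arr = v.as_array()
        assert arr.shape == (5,)
        mean, sd, skew, kurt = moment_features(win.samples)
        np.testing.assert_allclose(
            arr, [mean, sd, skew, kurt, dispersion_entropy(win.samples)])

    def test_burst_emg_has_higher_kurtosis_than_tonic(self):
        tonic, _ = gen_emg(GroupProfile(), 20.0, seed=0)
        burst, _ = gen_emg(GroupProfile(burst_gain=4.0), 20.0, seed=0)
        kt = emg_feature_vector(tonic).kurtosis
        kb = emg_feature_vector(burst).kurtosis
        assert kb > kt + 1.0

    def test_constant_window_marked_degenerate(self):
        v = emg_feature_vector(SignalSegment(np.full(4000, 0.3), 200.0))
        assert v.degenerate and v.de == 0.0


class TestECGFeatures:
    def test_rr_triple_from_known_spacing(self):
        idx = np.array([0, 200, 420, 600])  # intervals 1.0, 1.1, 0.9 s
        peaks = RPeakSet(indices=idx, threshold=0.5, error=0.0, quality="ok")
        mx, mn, mean = rpeak_timing_features(peaks, 200.0)
        assert (mx, mn) == (1.1, 0.9)
        assert mean == pytest.approx(1.0)

    def test_modulation_samples_signal_at_peaks(self, rng):
        x = rng.standard_normal(1000)
        idx = np.array([10, 500, 900])
        peaks = RPeakSet(indices=idx, threshold=0.5, error=0.0, quality="ok")
        mod = respiratory_modulation(peaks, SignalSegment(x, 200.0))
        np.testing.assert_array_equal(mod.amplitudes, x[idx])
        np.testing.assert_allclose(mod.times, idx / 200.0)

    def test_modulation_tracks_breathing_cycle(self):
        """Peak-amplitude series correlates strongly with the true modulator."""
        prof = GroupProfile(noise_sd=0.0, resp_mod_depth=0.3)
        ecg, truth = gen_ecg(prof, 120.0, seed=7)
        rp = iterative_rpeak_detect(ecg)
        mod = respiratory_modulation(rp, ecg)
        # match each detected peak to the nearest annotated beat
        truth_idx = np.asarray(truth["rpeak_indices"])
        truth_amp = np.asarray(truth["rpeak_amplitudes"])
        nearest = np.argmin(np.abs(truth_idx[None, :] - rp.indices[:, None]),
                            axis=1)
        r = np.corrcoef(mod.amplitudes, truth_amp[nearest])[0, 1]
        assert r > 0.99

    def test_breathing_frequency_recovered_within_0p02hz(self):
        prof = GroupProfile(noise_sd=0.0, breath_freq=0.25)
        ecg, _ = gen_ecg(prof, 120.0, seed=9)
        rp = iterative_rpeak_detect(ecg)
        mod = respiratory_modulation(rp, ecg)
        _, _, f_mean, _ = resp_if_features(mod)
        assert abs(f_mean - 0.25) < 0.02

    def test_amplitude_triple(self):
        mod = RespModulation(amplitudes=np.array([0.9, 1.2, 1.05]),
                             times=np.array([0.0, 1.0, 2.0]))
        assert resp_amplitude_features(mod) == (1.2, 0.9, pytest.approx(1.05))

    def test_full_vector_has_ten_values(self):
        ecg, _ = gen_ecg(GroupProfile(), 120.0, seed=4)
        rp = iterative_rpeak_detect(ecg)
        vec = ecg_feature_vector(rp, ecg)
        assert vec.as_array().shape == (10,)
        assert np.all(np.isfinite(vec.as_array()))

    def test_too_short_modulation_rejected(self):
        mod = RespModulation(amplitudes=np.array([1.0, 1.1]),
                             times=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            resp_if_features(mod)
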