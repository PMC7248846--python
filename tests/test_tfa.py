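"""Time-frequency stack: CWT, candidate IF, synchrosqueezing, ridge, inversion."""

import numpy as np
import pytest

from sleepsig.tfa import (MORLET_MU, FrequencyRidge, SignalSegment, TFSpectrum,
                          candidate_if, cwt, enhance_spectrum, extract_ridge,
                          isswt, morlet_fourier, sswt, synchrosqueeze)
from sleepsig.tfa import _scale_increments

BAND = (0.5, 2.0)


def brute_force_synchrosqueeze(W, ifmap, bins):
    """Independent per-(scale, time) reassignment loop (the oracle).

    Bin selection and accumulation are re-derived element by element; the
    scale weights use the same vectorised expression as the implementation so
    that agreement can be asserted bit for bit (scalar and vectorised ``pow``
    may differ in the last ulp).
    """
    bins = np.asarray(bins, float)
    dw = bins[1] - bins[0]
    scales = W.scales
    da = np.empty_like(scales)
    da[1:] = np.diff(scales)
    da[0] = scales[0] * (1.0 - scales[0] / scales[1])
    weights = scales ** -1.5 * da
    T = np.zeros((bins.size, W.n_times), dtype=complex)
    for b in range(W.n_times):
        for k in range(scales.size):
            if not ifmap.valid_mask[k, b]:
                continue
            w = ifmap.omega[k, b]
            # half-open bin [w_l - dw/2, w_l + dw/2)
            l = int(np.floor((w - bins[0] + 0.5 * dw) / dw))
            if 0 <= l < bins.size:
                T[l, b] += W.coeffs[k, b] * weights[k]
    return T / dw


class TestCWT:
    def test_zero_signal_gives_zero_coefficients(self):
        sig = SignalSegment(np.zeros(512), 200.0)
        W = cwt(sig, 16, band=BAND)
        assert np.all(W.coeffs == 0)

    def test_linearity(self, tone):
        s1, s2 = tone(0.8, 10.0), tone(1.6, 10.0, amp=0.5)
        both = SignalSegment(s1.samples + s2.samples, s1.fs)
        W1 = cwt(s1, 16, band=BAND)
        W2 = cwt(s2, 16, band=BAND)
        W12 = cwt(both, 16, band=BAND)
        np.testing.assert_allclose(W12.coeffs, W1.coeffs + W2.coeffs, atol=1e-12)

    def test_harmonic_concentrates_at_matching_scale(self, tone):
        f0 = 1.0
        sig = tone(f0, 20.0)
        W = cwt(sig, 32, band=BAND)
        # modulus maximal at the scale a = mu / (2 pi f0), spread around it
        profile = np.abs(W.coeffs[:, W.n_times // 2])
        a_star = MORLET_MU / (2 * np.pi * f0)
        assert abs(np.log2(W.scales[np.argmax(profile)] / a_star)) < 1.0 / 8
        assert (profile > 0.5 * profile.max()).sum() > 3  # spread over scales

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            cwt(SignalSegment(np.ones(10) + np.arange(10), 200.0), 32)

    def test_non_positive_fs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SignalSegment(np.zeros(100), fs=0.0)


class TestCandidateIF:
    def test_pure_harmonic_if_equals_frequency(self, tone, interior):
        f0 = 1.2
        sig = tone(f0, 20.0)
        W = cwt(sig, 32, band=BAND)
        ifm = candidate_if(W)
        strong = np.abs(W.coeffs) > 0.3 * np.abs(W.coeffs).max()
        strong[:, : len(sig) // 20] = strong[:, -len(sig) // 20:] = False
        assert np.all(ifm.valid_mask[strong])
        np.testing.assert_allclose(ifm.omega[strong], f0, rtol=0.02)

    def test_amplitude_scale_invariance(self, tone):
        sig = tone(1.0, 10.0)
        scaled = SignalSegment(2.0 * sig.samples, sig.fs)
        if1 = candidate_if(cwt(sig, 16, band=BAND))
        if2 = candidate_if(cwt(scaled, 16, band=BAND))
        np.testing.assert_array_equal(if1.valid_mask, if2.valid_mask)
        np.testing.assert_allclose(if1.omega[if1.valid_mask],
                                   if2.omega[if2.valid_mask], rtol=1e-9)

    def test_chirp_if_tracks_analytic_frequency(self, interior):
        fs, dur = 200.0, 40.0
        t = np.arange(int(dur * fs)) / fs
        f0, k = 0.6, 0.02  # f(t) = 0.6 + 0.02 t, stays in band
        sig = SignalSegment(np.cos(2 * np.pi * (f0 * t + 0.5 * k * t ** 2)), fs)
        W = cwt(sig, 32, band=BAND)
        ifm = candidate_if(W)
        f_true = f0 + k * t
        mag = np.abs(W.coeffs)
        ridge_rows = np.argmax(mag, axis=0)
        cols = np.arange(len(sig))[interior(len(sig))]
        est = ifm.omega[ridge_rows[cols], cols]
        rel_err = np.abs(est - f_true[cols]) / f_true[cols]
        assert np.median(rel_err) < 0.02
        assert np.percentile(rel_err, 95) < 0.02

    def test_masked_entries_are_finite_and_zero(self):
        sig = SignalSegment(np.zeros(512), 200.0)
        sig.samples[256] = 1.0  # impulse: lots of near-zero coefficients
        W = cwt(sig, 16, band=BAND)
        ifm = candidate_if(W)
        assert np.isfinite(ifm.omega).all()
        assert np.all(ifm.omega[~ifm.valid_mask] == 0)


class TestSynchrosqueeze:
    def test_matches_brute_force_oracle_exactly(self, rng):
        for trial in range(3):
            n = [256, 400, 512][trial]
            sig = SignalSegment(rng.standard_normal(n), 50.0)
            W = cwt(sig, 8, band=(0.5, 5.0))
            ifm = candidate_if(W)
            bins = np.linspace(0.25, 6.0, 40)
            T = synchrosqueeze(W, ifm, bins)
            T_oracle = brute_force_synchrosqueeze(W, ifm, bins)
            np.testing.assert_array_equal(T.coeffs, T_oracle)

    def test_contribution_conservation_per_column(self, tone):
        sig = tone(1.2, 10.0)
        W = cwt(sig, 16, band=BAND)
        ifm = candidate_if(W)
        # wide grid so every valid IF lands inside
        bins = np.linspace(0.01, 10.0, 400)
        T = synchrosqueeze(W, ifm, bins)
        dw = bins[1] - bins[0]
        weights = W.scales ** -1.5 * _scale_increments(W.scales)
        inside = ifm.valid_mask & (ifm.omega >= bins[0] - dw / 2) \
            & (ifm.omega < bins[-1] + dw / 2)
        expected = (W.coeffs * weights[:, None] * inside).sum(axis=0)
        np.testing.assert_allclose(T.coeffs.sum(axis=0) * dw, expected,
                                   atol=1e-12)

    def test_tone_energy_concentrates_in_true_bin(self, tone, interior):
        f0 = 1.3
        sig = tone(f0, 20.0)
        T = sswt(sig, BAND, n_voices=32, n_bins=64)
        cols = np.arange(T.n_times)[interior(T.n_times)]
        argmax_bins = np.abs(T.coeffs[:, cols]).argmax(axis=0)
        true_bin = np.argmin(np.abs(T.bin_centers - f0))
        assert np.all(np.abs(argmax_bins - true_bin) <= 1)

    def test_zero_spectrum_maps_to_zero(self):
        sig = SignalSegment(np.zeros(512), 200.0)
        W = cwt(sig, 16, band=BAND)
        T = synchrosqueeze(W, candidate_if(W), np.linspace(*BAND, 32))
        assert np.all(T.coeffs == 0)

    def test_empty_bin_grid_rejected(self, tone):
        sig = tone(1.0, 5.0)
        W = cwt(sig, 16, band=BAND)
        with pytest.raises(ValueError, match="empty"):
            synchrosqueeze(W, candidate_if(W), np.array([]))


class TestRidge:
    def test_tone_ridge_within_one_bin(self, tone, interior):
        sig = tone(1.2, 30.0)
        T = sswt(sig, BAND, n_bins=64)
        ridge = extract_ridge(T, BAND)
        assert len(ridge) == len(sig)
        dw = T.bin_width
        idx = interior(len(sig))
        assert np.all(np.abs(ridge.freq[idx] - 1.2) <= 1.5 * dw)

    def test_ridge_confined_to_band(self, rng):
        sig = SignalSegment(rng.standard_normal(2048), 200.0)
        T = sswt(sig, BAND)
        ridge = extract_ridge(T, BAND)
        assert np.all(ridge.freq >= BAND[0]) and np.all(ridge.freq <= BAND[1])

    def test_all_zero_spectrum_flagged_degenerate(self):
        sig = SignalSegment(np.zeros(512), 200.0)
        T = sswt(sig, BAND, n_voices=16)
        ridge = extract_ridge(T, BAND)
        assert ridge.is_degenerate


class TestISSWT:
    def test_tone_round_trip(self, tone, interior):
        f0 = 1.2
        sig = tone(f0, 25.0)
        T = sswt(sig, BAND)
        ridge = extract_ridge(T, BAND)
        rec = isswt(T, ridge, halfwidth_bins=2)
        idx = interior(len(sig))
        rmse = np.sqrt(np.mean((rec.samples[idx] - sig.samples[idx]) ** 2))
        assert rmse / np.sqrt(np.mean(sig.samples[idx] ** 2)) < 0.05

    def test_two_tone_component_separation(self, interior):
        fs, dur = 200.0, 30.0
        t = np.arange(int(dur * fs)) / fs
        comp = 0.7 * np.cos(2 * np.pi * 1.6 * t)
        sig = SignalSegment(np.cos(2 * np.pi * 0.8 * t) + comp, fs)
        T = sswt(sig, BAND)
        ridge = FrequencyRidge(np.full(len(sig), 1.6), BAND)
        rec = isswt(T, ridge, halfwidth_bins=2)
        idx = interior(len(sig))
        r = np.corrcoef(rec.samples[idx], comp[idx])[0, 1]
        assert r > 0.95

    def test_zero_spectrum_reconstructs_zero(self):
        sig = SignalSegment(np.zeros(512), 200.0)
        T = sswt(sig, BAND, n_voices=16)
        ridge = FrequencyRidge(np.full(512, 1.0), BAND)
        assert np.all(isswt(T, ridge).samples == 0)

    def test_length_mismatch_rejected(self, tone):
        T = sswt(tone(1.0, 10.0), BAND)
        ridge = FrequencyRidge(np.full(10, 1.0), BAND)
        with pytest.raises(ValueError, match="length"):
            isswt(T, ridge)


class TestEnhanceSpectrum:
    def test_clean_tone_ridge_preserved(self, tone, interior):
        sig = tone(1.2, 25.0)
        T1 = sswt(sig, BAND)
        T2 = enhance_spectrum(sig, BAND)
        r1 = extract_ridge(T1, BAND)
        r2 = extract_ridge(T2, BAND)
        idx = interior(len(sig))
        assert np.all(np.abs(r1.freq[idx] - r2.freq[idx]) <= T1.bin_width + 1e-12)

    def test_noisy_tone_off_ridge_energy_shrinks(self, rng, interior):
        fs, dur, f0 = 200.0, 25.0, 1.2
        t = np.arange(int(dur * fs)) / fs
        clean = np.cos(2 * np.pi * f0 * t)
        noise = rng.normal(0, np.sqrt(0.5), t.size)  # SNR 0 dB
        sig = SignalSegment(clean + noise, fs)

        def off_ridge_fraction(T):
            idx = interior(T.n_times)
            E = np.abs(T.coeffs[:, idx]) ** 2
            b = np.argmin(np.abs(T.bin_centers - f0))
            mask = np.abs(np.arange(T.bin_centers.size) - b) > 2
            return E[mask].sum() / E.sum()

        frac_orig = off_ridge_fraction(sswt(sig, BAND))
        frac_enh = off_ridge_fraction(enhance_spectrum(sig, BAND))
        assert frac_enh < frac_orig

    def test_degenerate_input_propagates_flag(self):
        sig = SignalSegment(np.zeros(1024), 200.0)
        T = enhance_spectrum(sig, BAND, n_voices=16)
        assert T.degenerate


class TestWavelet:
    def test_one_sided_spectrum(self):
        xi = np.linspace(-10, 20, 301)
        psi = morlet_fourier(xi)
        assert np.all(psi[xi <= 0] == 0)
        assert psi[xi > 0].max() > 0
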