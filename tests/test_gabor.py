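"""Gabor-atom spike detection, localisation, fitting and subtraction."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaborclean.gabor import (DEFAULT_CARRIER_HZ, DetectionConfig,
                              GaborSpike, GaborSpikeRemover,
                              default_corr_thresh, detect_candidates,
                              estimate_sigma, fit_amplitude_and_subtract,
                              gabor_waveform, highpass_detection_filter,
                              locate_center, reconstruct_spike_signal,
                              reduce_emg, refine_center)
from gaborclean.gabor import _sigma_table
from gaborclean.recording import Recording
from gaborclean.simulate import pink_noise

F0 = DEFAULT_CARRIER_HZ


def atom_signal(fs, t0=0.2, sigma=2e-3, phi=0.0, A=20.0, dur=0.4):
    t = np.arange(int(dur * fs)) / fs
    return gabor_waveform(t0, sigma, F0, phi, A, t), t


class TestGaborWaveform:
    def test_phi_zero_is_odd_about_center(self):
        g, t = atom_signal(5000.0, t0=0.2, phi=0.0)
        c = int(0.2 * 5000)
        assert g[c] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(g[c + 1:c + 50], -g[c - 1:c - 50:-1], atol=1e-12)

    def test_phi_half_pi_is_even_with_peak_a(self):
        g, _ = atom_signal(5000.0, t0=0.2, phi=np.pi / 2, A=7.0)
        c = int(0.2 * 5000)
        assert g[c] == pytest.approx(7.0)
        assert np.allclose(g[c + 1:c + 50], g[c - 1:c - 50:-1], atol=1e-12)

    def test_energy_matches_closed_form(self):
        # for phi = pi/2: E = A^2 (sigma sqrt(pi)/2)(1 + exp(-(2 pi f sigma)^2))
        fs, sigma = 50000.0, 2e-3
        g, _ = atom_signal(fs, t0=0.2, sigma=sigma, phi=np.pi / 2, A=1.0)
        discrete = np.sum(g ** 2) / fs
        w = 2 * np.pi * F0
        closed = (sigma * np.sqrt(np.pi) / 2) * (1 + np.exp(-(w * sigma) ** 2))
        assert discrete == pytest.approx(closed, rel=1e-3)

    def test_nonpositive_sigma_is_error(self):
        with pytest.raises(ValueError, match="sigma"):
            gabor_waveform(0.0, 0.0, F0, 0.0, 1.0, np.arange(10) / 100.0)


class TestDetectCandidates:
    FS = 2000.0

    def test_zero_signal_no_candidates(self):
        cfg = DetectionConfig()
        assert detect_candidates(np.zeros(4000), self.FS, cfg).size == 0

    def test_single_atom_detected_within_1ms(self):
        x, _ = atom_signal(self.FS, A=20.0, sigma=1.5e-3, phi=0.0)
        cand = detect_candidates(x, self.FS, DetectionConfig())
        assert cand.size >= 1
        assert np.min(np.abs(cand / self.FS - 0.2)) < 1e-3

    def test_threshold_semantics_brute_force(self):
        # peak-to-peak 3.5 ms change scaled to 6.9 uV stays below the 7 uV gate
        x, _ = atom_signal(self.FS, A=20.0, sigma=1.5e-3, phi=0.0)
        nd = int(round(3.5e-3 * self.FS))
        change = np.max(np.abs(x[nd:] - x[:-nd]))
        x_scaled = x * (6.9 / change)
        cand = detect_candidates(x_scaled, self.FS, DetectionConfig(v_thresh=7.0))
        assert cand.size == 0
        cand = detect_candidates(x * (7.1 / change), self.FS,
                                 DetectionConfig(v_thresh=7.0))
        assert cand.size >= 1

    def test_too_short_signal_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_candidates(np.zeros(8), self.FS, DetectionConfig())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(thresh=st.floats(1.0, 20.0))
    def test_lower_threshold_never_detects_fewer(self, thresh):
        rng = np.random.default_rng(5)
        x = pink_noise(8000, rng, rms=3.0, fs=self.FS, lp_hz=500)
        x += atom_signal(self.FS, t0=2.0, A=25.0, dur=4.0)[0]
        n_hi = detect_candidates(x, self.FS, DetectionConfig(v_thresh=thresh)).size
        n_lo = detect_candidates(x, self.FS,
                                 DetectionConfig(v_thresh=thresh / 2)).size
        assert n_lo >= n_hi


class TestLocateCenter:
    def test_noiseless_atom_gated_in_with_strong_correlation(self):
        fs = 5000.0
        x, _ = atom_signal(fs, sigma=2e-3, phi=0.0)
        out = locate_center(x, fs, int(0.2 * fs), DetectionConfig())
        assert out is not None
        center, corr = out
        assert corr <= -0.98
        assert abs(center / fs - 0.2) < 3e-3   # within the search window

    def test_white_noise_candidates_rejected(self, rng):
        fs = 5000.0
        x = rng.standard_normal(int(fs))
        cfg = DetectionConfig(corr_thresh=-0.84)
        rejected = 0
        idx = rng.integers(100, x.size - 100, 200)
        for i in idx:
            if locate_center(x, fs, int(i), cfg) is None:
                rejected += 1
        assert rejected >= 0.95 * idx.size

    def test_default_gate_depends_on_rate(self):
        assert default_corr_thresh(2000.0) == -0.78
        assert default_corr_thresh(5000.0) == -0.84

    def test_candidate_at_edge_skipped(self):
        x, _ = atom_signal(2000.0)
        assert locate_center(x, 2000.0, 1, DetectionConfig()) is None


class TestEstimateSigma:
    @pytest.mark.parametrize("fs", [2000.0, 5000.0])
    @pytest.mark.parametrize("sigma_ms", [1.0, 2.0, 4.0])
    def test_table_inversion_recovers_sigma(self, fs, sigma_ms):
        x, _ = atom_signal(fs, sigma=sigma_ms * 1e-3, phi=0.0)
        est = estimate_sigma(x, fs, int(round(0.2 * fs)), DetectionConfig())
        assert abs(est - sigma_ms * 1e-3) <= 0.05e-3

    def test_lookup_table_strictly_monotone(self):
        for fs in (2000.0, 5000.0):
            sigmas, q = _sigma_table(fs, F0, (0.5, 6.0, 0.05))
            assert np.all(np.diff(q) > 0)
            assert np.all(np.diff(sigmas) > 0)

    def test_out_of_grid_ratio_clamps_with_warning(self):
        fs = 2000.0
        x, _ = atom_signal(fs, sigma=8e-3, phi=0.0)   # above the 6 ms grid end
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            est = estimate_sigma(x, fs, int(round(0.2 * fs)),
                                 DetectionConfig())
        assert est == pytest.approx(6e-3)
        assert any("clamp" in str(w.message) for w in caught)

    def test_degenerate_center_gradient_falls_back(self):
        # phi = pi/2 puts an extremum (zero gradient) at the center
        fs = 5000.0
        x, _ = atom_signal(fs, sigma=2e-3, phi=np.pi / 2)
        est = estimate_sigma(x, fs, int(round(0.2 * fs)), DetectionConfig())
        assert 0.5e-3 <= est <= 6e-3   # grid-search fallback stays in range


class TestRefineCenter:
    def test_offset_guess_recovered(self):
        fs = 5000.0
        x, _ = atom_signal(fs, t0=0.2, sigma=2e-3, phi=0.7)
        spike = GaborSpike(t0=0.2 + 0.2e-3, sigma=2e-3, f=F0, phi=0.0, A=0.0)
        refined = refine_center(x, fs, spike, DetectionConfig())
        assert abs(refined.t0 - 0.2) <= 0.02e-3

    def test_optimal_guess_is_fixed_point(self):
        fs = 5000.0
        x, _ = atom_signal(fs, t0=0.2, sigma=2e-3, phi=0.0)
        spike = GaborSpike(t0=0.2, sigma=2e-3, f=F0, phi=0.0, A=0.0)
        refined = refine_center(x, fs, spike, DetectionConfig())
        assert refined.t0 == pytest.approx(0.2, abs=1e-9)

    def test_default_step_is_hundredth_of_ms(self):
        assert DetectionConfig().refine_step_s == pytest.approx(1e-5)


class TestFitAmplitudeAndSubtract:
    def test_known_atom_recovered_in_noise(self, rng):
        fs = 5000.0
        x, t = atom_signal(fs, t0=0.2, sigma=2e-3, phi=1.0, A=15.0)
        noise = pink_noise(x.size, rng, rms=1.5, fs=fs, lp_hz=500)
        spike = GaborSpike(t0=0.2, sigma=2e-3, f=F0, phi=0.0, A=0.0)
        out = fit_amplitude_and_subtract(x + noise, fs, spike,
                                         DetectionConfig())
        assert out is not None
        corrected, fitted = out
        assert abs(fitted.A - 15.0) / 15.0 < 0.10
        resid = corrected - noise
        assert np.sum(resid ** 2) <= 0.2 * np.sum(x ** 2)

    def test_locality_outside_support(self, rng):
        fs = 5000.0
        x, _ = atom_signal(fs, t0=0.2, sigma=2e-3, phi=0.5, A=15.0)
        sig = x + pink_noise(x.size, rng, rms=1.0, fs=fs, lp_hz=500)
        spike = GaborSpike(t0=0.2, sigma=2e-3, f=F0, phi=0.0, A=0.0)
        corrected, fitted = fit_amplitude_and_subtract(sig, fs, spike,
                                                       DetectionConfig())
        assert np.array_equal(corrected[:fitted.i0], sig[:fitted.i0])
        assert np.array_equal(corrected[fitted.i1:], sig[fitted.i1:])

    def test_forced_fit_on_pure_noise_is_benign(self, rng):
        fs = 5000.0
        noise = pink_noise(int(0.4 * fs), rng, rms=1.0, fs=fs, lp_hz=500)
        spike = GaborSpike(t0=0.2, sigma=2e-3, f=F0, phi=0.0, A=0.0)
        corrected, fitted = fit_amplitude_and_subtract(noise, fs, spike,
                                                       DetectionConfig())
        assert abs(fitted.A) < 2.0   # ~2x background scale
        p0, p1 = np.sum(noise ** 2), np.sum(corrected ** 2)
        assert abs(p1 - p0) / p0 < 0.01

    def test_support_outside_signal_skipped(self):
        fs = 5000.0
        x, _ = atom_signal(fs)
        spike = GaborSpike(t0=0.001, sigma=3e-3, f=F0, phi=0.0, A=0.0)
        assert fit_amplitude_and_subtract(x, fs, spike,
                                          DetectionConfig()) is None


class TestReduceEmg:
    def test_single_noiseless_atom_removed(self):
        fs = 5000.0
        x, _ = atom_signal(fs, t0=0.2, sigma=2e-3, phi=0.9, A=20.0)
        rec = Recording(x[np.newaxis, :], fs, ["C3"])
        corrected, inventory = reduce_emg(rec)
        assert len(inventory) >= 1
        assert np.sum(corrected.samples[0] ** 2) < 0.02 * np.sum(x ** 2)

    def test_conservation_is_bit_exact(self, small_sim):
        _, rec, _ = small_sim
        remover = GaborSpikeRemover()
        corrected = remover.fit_transform(rec)
        for label in rec.channel_labels:
            ci = rec.channel_index(label)
            recon = reconstruct_spike_signal(remover.inventory_, rec.n_times,
                                             rec.fs, label)
            assert np.array_equal(rec.samples[ci] - recon,
                                  corrected.samples[ci])

    def test_transform_matches_fit_transform(self, small_sim):
        _, rec, _ = small_sim
        remover = GaborSpikeRemover()
        corrected = remover.fit_transform(rec)
        again = remover.transform(rec)
        assert np.array_equal(corrected.samples, again.samples)

    def test_transform_rejects_other_shape(self, small_sim):
        _, rec, _ = small_sim
        remover = GaborSpikeRemover().fit(rec)
        short = Recording(rec.samples[:, :1000], rec.fs, rec.channel_labels)
        with pytest.raises(ValueError, match="differs"):
            remover.transform(short)

    def test_spike_free_signal_untouched_in_gamma(self, rng):
        fs = 2000.0
        noise = pink_noise(int(30 * fs), rng, rms=0.35, fs=fs, lp_hz=500)
        rec = Recording(noise[np.newaxis, :], fs, ["C3"])
        corrected, inventory = reduce_emg(rec)
        spec0 = np.abs(np.fft.rfft(noise))
        spec1 = np.abs(np.fft.rfft(corrected.samples[0]))
        f = np.fft.rfftfreq(noise.size, 1 / fs)
        sel = (f >= 65) & (f <= 85)
        assert abs(1 - spec1[sel].mean() / spec0[sel].mean()) < 0.02
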