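"""Mains cancellation: quadrature extraction, harmonic recursion, regression."""

import numpy as np
import pytest

from gaborclean.powerline import (PowerlineCanceller, build_harmonics,
                                  cancel_powerline, default_n_harmonics,
                                  extract_fundamental)
from gaborclean.recording import Recording
from gaborclean.simulate import pink_noise

FS = 2000.0


def band_power(x, fs, lo, hi):
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[(f >= lo) & (f <= hi)].sum()


class TestExtractFundamental:
    def test_pure_sine_gives_quadrature_pair(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        sine, cosine = extract_fundamental(x, FS, 50.0)
        interior = slice(int(2 * FS), int(18 * FS))
        assert np.max(np.abs(sine[interior] - np.sin(2 * np.pi * 50 * t)[interior])) < 1e-3
        assert np.max(np.abs(cosine[interior] - np.cos(2 * np.pi * 50 * t)[interior])) < 1e-3

    def test_no_mains_component_is_error(self, rng):
        # white noise shaped to exclude the 50 Hz region entirely
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + 0.1 * np.sin(2 * np.pi * 200 * t)
        with pytest.raises(ValueError, match="no mains"):
            extract_fundamental(x, FS, 50.0)

    def test_frequency_wander_is_tracked(self):
        # +-0.05 Hz slow wander: instantaneous phase error < 0.05 rad
        t = np.arange(int(30 * FS)) / FS
        theta = 2 * np.pi * 50 * t + (0.05 / 0.02) * np.sin(2 * np.pi * 0.02 * t)
        x = np.sin(theta)
        sine, cosine = extract_fundamental(x, FS, 50.0)
        interior = slice(int(5 * FS), int(25 * FS))
        phase_err = np.abs(np.angle(
            (sine[interior] + 1j * cosine[interior])
            * np.exp(-1j * (np.pi / 2 - theta[interior]))))
        assert np.percentile(phase_err, 99) < 0.05

    def test_band_outside_nyquist_is_error(self):
        with pytest.raises(ValueError, match="fs/2"):
            extract_fundamental(np.zeros(1000), 80.0, 50.0, bw=2.0)


class TestBuildHarmonics:
    @pytest.fixture()
    def ideal_pair(self):
        t = np.arange(int(10 * FS)) / FS
        return np.sin(2 * np.pi * 50 * t), np.cos(2 * np.pi * 50 * t), t

    def test_k1_returns_inputs(self, ideal_pair):
        s, c, _ = ideal_pair
        pairs = build_harmonics(s, c, 1)
        assert pairs[0][0] is s and pairs[0][1] is c

    def test_second_harmonic_matches_analytic(self, ideal_pair):
        s, c, t = ideal_pair
        pairs = build_harmonics(s, c, 2)
        assert np.max(np.abs(pairs[1][0] - np.sin(2 * np.pi * 100 * t))) < 1e-6
        assert np.max(np.abs(pairs[1][1] - np.cos(2 * np.pi * 100 * t))) < 1e-6

    def test_harmonics_mutually_orthogonal(self, ideal_pair):
        s, c, _ = ideal_pair
        cols = [x for pair in build_harmonics(s, c, 3) for x in pair]
        n = s.size
        for i in range(6):
            for j in range(i + 1, 6):
                r = abs(cols[i] @ cols[j]) / n * 2
                assert r < 1e-3, (i, j, r)

    def test_nyquist_violation_is_error(self, ideal_pair):
        s, c, _ = ideal_pair
        with pytest.raises(ValueError, match="Nyquist"):
            build_harmonics(s, c, 25, fs=FS, f0=50.0)

    def test_default_harmonic_count(self):
        assert default_n_harmonics(2000.0, 50.0) == 8
        assert default_n_harmonics(500.0, 50.0) == 4


class TestCancelPowerline:
    def _recording(self, channels, fs=FS):
        return Recording(np.vstack(channels), fs,
                         [f"ch{i}" for i in range(len(channels))])

    def test_line_power_removed(self, rng):
        t = np.arange(int(20 * FS)) / FS
        line = 3.0 * np.sin(2 * np.pi * 50 * t + 0.7)
        brain = pink_noise(t.size, rng, rms=1.0, fs=FS)
        rec = self._recording([line + brain, line])
        corrected, _ = cancel_powerline(rec, noise_channel="ch1")
        injected = band_power(line, FS, 49, 51)
        residual = band_power(corrected.samples[0] - brain, FS, 49, 51)
        assert residual < 0.01 * injected

    def test_clean_channel_barely_touched(self, rng):
        # "zero mains content" means literally none: notch the mains bands
        # out of the test noise so only spurious removal would register
        t = np.arange(int(20 * FS)) / FS
        line = np.sin(2 * np.pi * 50 * t)
        brain = pink_noise(t.size, rng, rms=1.0, fs=FS, lp_hz=500)
        spec = np.fft.rfft(brain)
        f = np.fft.rfftfreq(brain.size, 1 / FS)
        for k in range(1, 9):
            spec[np.abs(f - 50 * k) < 3.0] = 0.0
        brain = np.fft.irfft(spec, brain.size)
        rec = self._recording([brain, line])
        corrected, weights = cancel_powerline(rec, noise_channel="ch1")
        change = corrected.samples[0] - brain
        assert np.sqrt(np.mean(change ** 2)) < 0.01 * np.sqrt(np.mean(brain ** 2))

    def test_harmonic_also_removed(self, rng):
        t = np.arange(int(20 * FS)) / FS
        sig = (np.sin(2 * np.pi * 50 * t)
               + 0.3 * np.sin(2 * np.pi * 150 * t + 0.4))
        ref = np.sin(2 * np.pi * 50 * t)
        rec = self._recording([sig, ref])
        corrected, _ = cancel_powerline(rec, n_harmonics=3,
                                        noise_channel="ch1")
        for lo, hi in ((49, 51), (149, 151)):
            assert (band_power(corrected.samples[0], FS, lo, hi)
                    < 0.01 * band_power(sig, FS, lo, hi))

    def test_residual_orthogonal_to_basis(self, rng):
        t = np.arange(int(10 * FS)) / FS
        sig = np.sin(2 * np.pi * 50 * t) + pink_noise(t.size, rng, fs=FS)
        rec = self._recording([sig, np.sin(2 * np.pi * 50 * t)])
        model = PowerlineCanceller(noise_channel="ch1").fit(rec)
        out = model.transform(rec)
        resid = out.samples[0]
        for k in range(model.basis_.shape[1]):
            col = model.basis_[:, k]
            assert abs(resid @ col) / np.linalg.norm(col) / np.linalg.norm(resid) < 1e-6

    def test_projection_never_increases_power(self, rng):
        t = np.arange(int(10 * FS)) / FS
        sig = 2 * np.sin(2 * np.pi * 50 * t) + pink_noise(t.size, rng, fs=FS)
        rec = self._recording([sig, np.sin(2 * np.pi * 50 * t)])
        corrected, _ = cancel_powerline(rec, noise_channel="ch1")
        assert np.sum(corrected.samples[0] ** 2) <= np.sum(sig ** 2) * (1 + 1e-12)
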