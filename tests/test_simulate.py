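"""Synthetic-EEG generator: determinism, composition, truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats as spstats

from gaborclean.simulate import (SimulationSpec, cohort_specs, pink_noise,
                                 score_correction, simulate)


class TestPinkNoise:
    def test_seeded_reproducibility(self):
        a = pink_noise(4096, np.random.default_rng(3), fs=2000.0)
        b = pink_noise(4096, np.random.default_rng(3), fs=2000.0)
        assert np.array_equal(a, b)

    def test_spectral_slope_near_one(self, rng):
        x = pink_noise(2 ** 16, rng, alpha=1.0, fs=2000.0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(x.size, 1 / 2000.0)
        sel = (f > 1) & (f < 100)
        slope = np.polyfit(np.log(f[sel]), np.log(spec[sel]), 1)[0]
        assert -1.4 < slope < -0.6

    def test_rms_normalised(self, rng):
        x = pink_noise(2 ** 14, rng, rms=2.5, fs=2000.0)
        assert x.std() == pytest.approx(2.5)


class TestSimulate:
    def test_determinism_bitwise(self):
        spec = SimulationSpec(n_events=5, seed=11)
        rec1, truth1 = simulate(spec)
        rec2, truth2 = simulate(SimulationSpec(n_events=5, seed=11))
        assert np.array_equal(rec1.samples, rec2.samples)
        assert truth1.spikes.equals(truth2.spikes)
        assert np.array_equal(truth1.events.times, truth2.events.times)

    def test_all_amplitudes_zero_gives_silence(self):
        spec = SimulationSpec(n_events=3, seed=1, pink_rms=0.0, mu_amp=0.0,
                              mains_amps=(0.0,), spike_rate=0.0,
                              burst_amp=0.0, smp_amp=0.0)
        rec, truth = simulate(spec)
        assert np.all(rec.samples == 0)
        assert len(truth.spikes) == 0

    def test_spike_count_in_poisson_interval(self):
        spec = SimulationSpec(n_events=39, seed=2, event_interval_mean=1.53,
                              event_interval_jitter=0.0,
                              eeg_channels=("C3",))
        rec, truth = simulate(spec)
        lam = spec.spike_rate * rec.duration
        lo, hi = spstats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(truth.spikes) <= hi

    def test_event_pacing_matches_spec(self):
        spec = SimulationSpec(n_events=70, seed=4)
        _, truth = simulate(spec)
        gaps = np.diff(truth.events.times)
        assert abs(gaps.mean() - 1.53) < 0.15
        assert len(truth.events) == 70

    def test_burst_confined_to_events(self):
        spec = SimulationSpec(n_events=6, seed=5, pink_rms=0.0, mu_amp=0.0,
                              mains_amps=(0.0,), spike_rate=0.0,
                              smp_amp=0.0)
        rec, truth = simulate(spec)
        x = rec.get_channel("C3")
        active = np.abs(x) > 1e-12
        t = rec.times
        in_burst = np.zeros_like(active)
        for row in truth.bursts.itertuples():
            in_burst |= (t >= row.t_on - 1e-9) & (t <= row.t_on + row.duration_s)
        assert not np.any(active & ~in_burst)
        assert np.abs(x).max() == pytest.approx(0.05, rel=0.01)

    def test_oversized_sigma_rejected(self):
        spec = SimulationSpec(spike_sigma_ms=(1.0, 600.0), edge_pad=0.2)
        with pytest.raises(ValueError, match="sigma"):
            simulate(spec)

    def test_truth_component_reconstruction(self):
        spec = SimulationSpec(n_events=4, seed=9, pink_rms=0.0, mu_amp=0.0,
                              mains_amps=(0.0,), burst_amp=0.0, smp_amp=0.0)
        rec, truth = simulate(spec)
        recon = truth.spike_signal("C3", rec.n_times, rec.fs)
        assert np.allclose(recon, rec.get_channel("C3"), atol=1e-12)


class TestEnergyBookkeeping:
    def test_component_powers_add_up(self):
        # cross terms between the spike/burst components and the rest
        # vanish in expectation: var(total) ~ var(rest) + var(spikes+burst)
        spec = SimulationSpec(n_events=30, seed=6)
        rec, truth = simulate(spec)
        x = rec.get_channel("C3")
        comp = (truth.spike_signal("C3", rec.n_times, rec.fs)
                + truth.burst_signal("C3", rec.n_times, rec.fs))
        rest = x - comp
        lhs = np.var(x)
        rhs = np.var(rest) + np.var(comp)
        assert lhs == pytest.approx(rhs, rel=0.05)


class TestCohortSpecs:
    def test_subject_seeds_distinct_and_reproducible(self):
        base = SimulationSpec(n_events=5)
        a = cohort_specs(base, 8, seed=3)
        b = cohort_specs(base, 8, seed=3)
        assert [s.seed for s in a] == [s.seed for s in b]
        assert len({s.seed for s in a}) == 8

    def test_between_subject_interval_spread(self):
        specs = cohort_specs(SimulationSpec(), 50, seed=1)
        means = np.array([s.event_interval_mean for s in specs])
        assert abs(means.mean() - 1.53) < 0.2
        assert 0.2 < means.std() < 0.7


class TestScoreCorrection:
    def test_no_change_no_spikes_scores_zero(self):
        spec = SimulationSpec(n_events=3, seed=1, spike_rate=0.0)
        rec, truth = simulate(spec)
        m = score_correction(truth, rec, rec)
        assert m["residual_spike_energy"] == 0.0
        assert m["false_modification_energy"] == 0.0
        assert m["burst_recovery_ratio"] == pytest.approx(1.0)

    def test_oracle_subtraction_scores_perfect(self):
        from dataclasses import replace as drep
        spec = SimulationSpec(n_events=3, seed=2)
        rec, truth = simulate(spec)
        cleaned = rec.copy()
        for lab in spec.eeg_channels:
            ci = rec.channel_index(lab)
            cleaned.samples[ci] -= truth.spike_signal(lab, rec.n_times, rec.fs)
        m = score_correction(truth, cleaned, rec)
        assert m["residual_spike_energy"] < 1e-20
        assert m["burst_recovery_ratio"] == pytest.approx(1.0)
        assert m["false_modification_energy"] < 1e-20

    def test_length_mismatch_is_error(self):
        spec = SimulationSpec(n_events=3, seed=1)
        rec, truth = simulate(spec)
        from gaborclean.recording import Recording
        short = Recording(rec.samples[:, :-10], rec.fs, rec.channel_labels)
        with pytest.raises(ValueError, match="length"):
            score_correction(truth, short, rec)
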