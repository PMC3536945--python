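"""ERS statistics: baselines, paired tests, topography, unit conversions."""

import numpy as np
import pandas as pd
import pytest

from gaborclean.ers import (amplitude_reduction_from_power, baseline_window,
                            correction_effect_test, ers_test,
                            power_reduction_from_amplitude, topography_z,
                            trial_band_measures)
from gaborclean.rejection import EpochMask


class TestAmplitudePowerConversion:
    def test_known_conversions(self):
        # 33 % power -> 18.15 % amplitude; 93 % power -> 73.54 % amplitude
        assert amplitude_reduction_from_power(0.33) == pytest.approx(
            1 - np.sqrt(0.67))
        assert 100 * amplitude_reduction_from_power(0.33) == pytest.approx(
            18.15, abs=0.01)
        assert 100 * amplitude_reduction_from_power(0.93) == pytest.approx(
            73.54, abs=0.01)

    def test_round_trip(self):
        for p in (0.0, 0.1, 0.33, 0.93, 1.0):
            assert power_reduction_from_amplitude(
                amplitude_reduction_from_power(p)) == pytest.approx(p)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            amplitude_reduction_from_power(1.5)


class TestBaselineWindow:
    def test_long_gap_full_second(self):
        times = np.array([1.0, 2.53])
        lo, hi = baseline_window(times, 1)
        assert lo == pytest.approx(1.53)
        assert hi == pytest.approx(2.53)

    def test_short_gap_starts_after_previous_response(self):
        times = np.array([1.0, 1.8])
        lo, hi = baseline_window(times, 1)
        assert (lo, hi) == (1.25, 1.8)
        assert hi - lo == pytest.approx(0.55)

    def test_quarter_second_gap_excluded(self):
        times = np.array([1.0, 1.25])
        assert baseline_window(times, 1) is None

    def test_first_trial_uses_full_window(self):
        assert baseline_window(np.array([5.0]), 0) == (4.0, 5.0)

    def test_never_overlaps_previous_peak_window(self, rng):
        times = np.cumsum(rng.uniform(0.2, 3.0, 100)) + 2.0
        for i in range(1, 100):
            win = baseline_window(times, i)
            if win is None:
                continue
            assert win[0] >= times[i - 1] + 0.25 - 1e-12


class TestErsTest:
    def test_null_identity(self):
        base = np.full(20, 1.0)
        res = ers_test(base, base)
        assert res.t == 0.0
        assert res.p == pytest.approx(0.5)
        assert res.degenerate

    def test_agrees_with_manual_t_formula(self, rng):
        base = rng.normal(1.0, 0.1, 30)
        peak = base + rng.normal(0.05, 0.1, 30)
        res = ers_test(base, peak)
        d = peak - base
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(t_manual, abs=1e-10)
        from scipy.stats import t as tdist
        assert res.p == pytest.approx(tdist.sf(t_manual, d.size - 1),
                                      abs=1e-12)

    def test_mask_restricts_trials(self, rng):
        base = rng.normal(1.0, 0.1, 40)
        peak = base.copy()
        peak[:20] += 10.0      # effect only in masked-out trials
        mask = EpochMask(keep=np.arange(40) >= 20, threshold_used=0.1,
                         provenance="t")
        res = ers_test(base, peak, mask)
        assert res.t == 0.0

    def test_power_detects_unit_effect_size(self, rng):
        # d ~= 1 with n = 40 trials: p < 0.01 in nearly every repetition
        hits = 0
        for _ in range(40):
            base = rng.normal(1.0, 0.1, 40)
            peak = base + rng.normal(0.1, 0.1, 40)
            if ers_test(base, peak).p < 0.01:
                hits += 1
        assert hits >= 0.9 * 40


class TestCorrectionEffectTest:
    def _measures(self, base, peak):
        return pd.DataFrame({"baseline": base, "peak": peak})

    def test_identical_conditions_t_zero(self, rng):
        base = rng.normal(1.0, 0.1, 30)
        peak = base + 0.05
        m = EpochMask(keep=np.ones(30, bool), threshold_used=0.1,
                      provenance="pre-EMG")
        out = correction_effect_test(self._measures(base, peak),
                                     self._measures(base, peak), m, m)
        assert out["baseline_t"] == 0.0
        assert out["baseline_reduction"] == pytest.approx(0.0)

    def test_mask_mismatch_is_error(self, rng):
        base = rng.normal(1.0, 0.1, 30)
        m1 = EpochMask(keep=np.ones(30, bool), threshold_used=0.1,
                       provenance="pre-EMG")
        m2 = EpochMask(keep=np.ones(30, bool), threshold_used=0.1,
                       provenance="post-EMG")
        with pytest.raises(ValueError, match="masks differ"):
            correction_effect_test(self._measures(base, base),
                                   self._measures(base, base), m1, m2)

    def test_reduction_direction_one_tailed(self, rng):
        base_pre = rng.normal(1.0, 0.05, 40)
        base_post = base_pre - 0.2          # clear reduction
        m = EpochMask(keep=np.ones(40, bool), threshold_used=0.1,
                      provenance="pre-EMG")
        out = correction_effect_test(self._measures(base_pre, base_pre),
                                     self._measures(base_post, base_post),
                                     m, m)
        assert out["baseline_t"] > 0
        assert out["baseline_p"] < 0.01
        assert out["baseline_reduction"] == pytest.approx(0.2, abs=0.02)


class TestTopographyZ:
    def test_zero_mean_derivation_near_zero(self, rng):
        topo = topography_z({"C3-CZ": rng.normal(0.0, 1.0, 500)})
        assert abs(topo.z[0]) < 0.15

    def test_injected_effect_peaks_at_its_derivation(self, rng):
        per = {f"d{i}": rng.normal(0.0, 1.0, 60) for i in range(10)}
        per["C3-CZ"] = rng.normal(1.0, 1.0, 60)
        topo = topography_z(per)
        best = topo.derivations[int(np.nanargmax(np.abs(topo.z)))]
        assert best == "C3-CZ"

    def test_zero_variance_reported_missing(self):
        topo = topography_z({"flat": np.ones(10)})
        assert np.isnan(topo.z[0])


class TestErsUnbiasedness:
    def test_known_burst_amplitude_recovered_without_bias(self, rng):
        # band series with a known additive increase in each peak window:
        # the mean estimated ERS over repeated runs matches the injected
        # value within Monte-Carlo error
        step = np.arange(0, 40, 0.005)
        events = np.arange(3.0, 38.0, 1.6)
        injected = 0.02
        est = []
        for _ in range(50):
            series = 0.1 + 0.01 * rng.standard_normal(step.size)
            for t in events:
                series[(step >= t) & (step <= t + 0.25)] += injected
            df = trial_band_measures(series, step, events)
            ok = df["usable"].to_numpy(bool)
            est.append((df["peak"] - df["baseline"]).to_numpy(float)[ok].mean())
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - injected) < max(3 * se, 1e-4)


class TestTrialBandMeasures:
    def test_usable_flags_and_values(self):
        step = np.arange(0, 30, 0.005)
        series = np.ones_like(step)
        events = np.array([5.0, 5.2, 10.0])   # second press 0.2 s after first
        df = trial_band_measures(series, step, events)
        assert bool(df.loc[1, "usable"]) is False
        assert bool(df.loc[2, "usable"]) is True
        assert df.loc[2, "baseline"] == pytest.approx(1.0)
        assert df.loc[2, "peak"] == pytest.approx(1.0)

    def test_peak_mode_max(self):
        step = np.arange(0, 20, 0.005)
        series = np.ones_like(step)
        series[(step >= 10.0) & (step <= 10.25)] = 3.0
        df = trial_band_measures(series, step, np.array([10.0]),
                                 peak_mode="max")
        assert df.loc[0, "peak"] == pytest.approx(3.0)
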