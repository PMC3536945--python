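"""Event-related gamma synchronisation (ERS) statistics.

Quantifies the 65–85 Hz amplitude increase in the 250 ms after a self-paced
button press against a pre-press baseline, the effect of each artifact
correction stage on the pre-press gamma, and the scalp topography of the
ERS as per-derivation Z scores.

Baseline rule: the default baseline is the 1 s before the press; when the
previous press is closer than 1.25 s, the baseline starts 250 ms after the
previous press (clearing its own gamma response); presses 0.25 s or less
after their predecessor are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .rejection import EpochMask

logger = logging.getLogger(__name__)

__all__ = [
    "ERSResult",
    "TopographyZ",
    "amplitude_reduction_from_power",
    "power_reduction_from_amplitude",
    "baseline_window",
    "trial_band_measures",
    "ers_test",
    "correction_effect_test",
    "topography_z",
]


def amplitude_reduction_from_power(power_reduction: float) -> float:
    """Fractional amplitude reduction equivalent to a power reduction.

    Power is amplitude squared, so a fractional power reduction p maps to an
    amplitude reduction 1 − sqrt(1 − p): e.g. 33 % power → 18 % amplitude
    and 93 % power → 73.5 % amplitude.
    """
    if not 0.0 <= power_reduction <= 1.0:
        raise ValueError("power_reduction must lie in [0, 1]")
    return 1.0 - np.sqrt(1.0 - power_reduction)


def power_reduction_from_amplitude(amp_reduction: float) -> float:
    """Inverse of :func:`amplitude_reduction_from_power`."""
    if not 0.0 <= amp_reduction <= 1.0:
        raise ValueError("amp_reduction must lie in [0, 1]")
    return 1.0 - (1.0 - amp_reduction) ** 2


@dataclass
class ERSResult:
    """Baseline/peak band amplitudes and the paired test on their difference."""

    baseline: np.ndarray      # per trial (or per subject), μV/Hz
    peak: np.ndarray          # per trial (or per subject), μV/Hz
    t: float
    p: float
    tail: str                 # 'one' or 'two'
    degenerate: bool = False

    @property
    def mean_baseline(self) -> float:
        return float(np.mean(self.baseline))

    @property
    def mean_peak(self) -> float:
        return float(np.mean(self.peak))

    @property
    def mean_ers(self) -> float:
        """Mean baseline-corrected peak amplitude."""
        return float(np.mean(self.peak - self.baseline))


@dataclass
class TopographyZ:
    """Per-derivation Z scores (mean baseline-corrected ERS / SD across trials)."""

    z: np.ndarray
    derivations: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"derivation": self.derivations, "z": self.z})


def baseline_window(event_times: np.ndarray, trial_index: int,
                    baseline_s: float = 1.0) -> tuple[float, float] | None:
    """Baseline interval for one trial, or None when the trial is excluded.

    [t − baseline_s, t] by default; when the previous event falls inside
    [t − baseline_s − 0.25, t] the window is [prev + 0.25, t]; a gap of
    0.25 s or less excludes the trial.
    """
    times = np.asarray(event_times, dtype=np.float64)
    t = times[trial_index]
    if trial_index == 0:
        return (t - baseline_s, t)
    gap = t - times[trial_index - 1]
    if gap > baseline_s + 0.25:
        return (t - baseline_s, t)
    if gap > 0.25:
        return (times[trial_index - 1] + 0.25, t)
    logger.info("trial %d excluded: previous press only %.3f s earlier",
                trial_index, gap)
    return None


def trial_band_measures(
    band_series: np.ndarray,
    step_times: np.ndarray,
    event_times: np.ndarray,
    peak_window: tuple[float, float] = (0.0, 0.25),
    baseline_s: float = 1.0,
    peak_mode: str = "mean",
) -> pd.DataFrame:
    """Per-trial baseline and peak band amplitudes from one band time series.

    Parameters
    ----------
    band_series : band amplitude per time step (μV/Hz).
    step_times : window-center times of the series, seconds.
    event_times : button-press times, seconds.
    peak_window : post-press interval defining the "peak", seconds.
    peak_mode : 'mean' (default) averages the band amplitude over the peak
        window; 'max' takes the literal maximum.

    Returns
    -------
    DataFrame with columns trial, baseline, peak, peak_max, usable.
    Trials without a valid baseline (too-close previous press, or windows
    outside the series) are flagged unusable.
    """
    series = np.asarray(band_series, dtype=np.float64)
    st = np.asarray(step_times, dtype=np.float64)
    rows = []
    for i, t in enumerate(np.asarray(event_times, dtype=np.float64)):
        win = baseline_window(event_times, i, baseline_s)
        usable = win is not None
        base = peak = peak_max = np.nan
        if usable:
            bsel = (st >= win[0]) & (st <= win[1])
            psel = (st >= t + peak_window[0]) & (st <= t + peak_window[1])
            if bsel.any() and psel.any():
                base = float(series[bsel].mean())
                peak = float(series[psel].mean() if peak_mode == "mean"
                             else series[psel].max())
                peak_max = float(series[psel].max())
            else:
                usable = False
        rows.append((i, base, peak, peak_max, usable))
    return pd.DataFrame(rows, columns=["trial", "baseline", "peak",
                                       "peak_max", "usable"])


def _paired_t(a: np.ndarray, b: np.ndarray, tail: str,
              alternative: str) -> tuple[float, float, bool]:
    """Paired t test of a vs b; handles the zero-variance degenerate case."""
    d = np.asarray(a, float) - np.asarray(b, float)
    if d.size < 2:
        raise ValueError("need at least two pairs")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 0.5 if tail == "one" else 1.0, True
        sign = np.sign(d.mean())
        if tail == "two":
            return float(sign * np.inf), 0.0, True
        p = 0.0 if (alternative == "greater") == (sign > 0) else 1.0
        return float(sign * np.inf), p, True
    res = spstats.ttest_rel(a, b, alternative=alternative if tail == "one"
                            else "two-sided")
    return float(res.statistic), float(res.pvalue), False


def ers_test(
    baseline: np.ndarray, peak: np.ndarray,
    mask: EpochMask | None = None,
) -> ERSResult:
    """Paired one-tailed t test for peak > baseline.

    Pass per-trial values for a within-subject test or per-subject means
    for an across-subject test.  With a mask, only kept trials enter.
    """
    baseline = np.asarray(baseline, float)
    peak = np.asarray(peak, float)
    if mask is not None:
        baseline, peak = baseline[mask.keep], peak[mask.keep]
    ok = np.isfinite(baseline) & np.isfinite(peak)
    baseline, peak = baseline[ok], peak[ok]
    t, p, degen = _paired_t(peak, baseline, "one", "greater")
    return ERSResult(baseline=baseline, peak=peak, t=t, p=p, tail="one",
                     degenerate=degen)


def correction_effect_test(
    pre: pd.DataFrame, post: pd.DataFrame,
    mask_pre: EpochMask, mask_post: EpochMask,
) -> dict:
    """Effect of a correction stage on pre-press gamma and on the ERS peak.

    *pre*/*post* are per-trial (or per-subject) frames with ``baseline``
    and ``peak`` columns from :func:`trial_band_measures` under the two
    conditions.  The identical-mask contract is enforced.  Returns one-
    tailed t/p for the hypothesised baseline *reduction* (pre > post) and
    two-tailed t/p for the change of the baseline-corrected peak.
    """
    mask_pre.require_same(mask_post)
    keep = mask_pre.keep
    b_pre = pre["baseline"].to_numpy(float)[keep]
    b_post = post["baseline"].to_numpy(float)[keep]
    e_pre = (pre["peak"] - pre["baseline"]).to_numpy(float)[keep]
    e_post = (post["peak"] - post["baseline"]).to_numpy(float)[keep]
    ok = np.isfinite(b_pre) & np.isfinite(b_post)
    t_b, p_b, _ = _paired_t(b_pre[ok], b_post[ok], "one", "greater")
    t_e, p_e, _ = _paired_t(e_post[ok], e_pre[ok], "two", "two-sided")
    return {
        "baseline_t": t_b, "baseline_p": p_b,
        "peak_t": t_e, "peak_p": p_e,
        "baseline_reduction": float(1.0 - np.nanmean(b_post[ok])
                                    / np.nanmean(b_pre[ok])),
    }


def topography_z(per_derivation_ers: dict[str, np.ndarray]) -> TopographyZ:
    """Z score per derivation: mean baseline-corrected ERS / SD across trials.

    Derivations with zero variance or fewer than two trials get NaN.
    """
    labels, zs = [], []
    for name, ers in per_derivation_ers.items():
        ers = np.asarray(ers, float)
        ers = ers[np.isfinite(ers)]
        labels.append(name)
        if ers.size < 2 or np.allclose(ers.std(ddof=1), 0.0):
            zs.append(np.nan)
        else:
            zs.append(float(ers.mean() / ers.std(ddof=1)))
    return TopographyZ(z=np.array(zs), derivations=labels)
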