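"""Adaptive per-subject rejection of EMG-contaminated trials.

The per-subject amplitude threshold is

    threshold = min(a * mean(60–130 Hz amplitude over all trials) + b, cap)

with a = 1.5, b = 0.06 μV/Hz and cap 0.4 μV/Hz, raised only as far as
needed so that no more than 30 of 70 trials are rejected.  The decision is
made once, on the post-SMP / pre-EMG data, and the *same* mask is then
applied to every correction condition — otherwise between-condition
amplitude comparisons would be confounded by different trial sets.  A final
single pass removes any kept trial whose maximum high-gamma amplitude lies
more than six standard deviations above the mean of the kept trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["RejectionConfig", "EpochMask", "compute_threshold", "build_mask",
           "anomaly_reject", "EpochRejector"]


@dataclass(frozen=True)
class RejectionConfig:
    a: float = 1.5                   # threshold multiplier
    b: float = 0.06                  # threshold offset, μV/Hz
    cap: float = 0.4                 # maximum threshold, μV/Hz
    max_reject_frac: float = 30.0 / 70.0
    sd_limit: float = 6.0            # anomaly rule, standard deviations

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0:
            raise ValueError("need a > 0 and b >= 0")
        if not 0.0 < self.max_reject_frac < 1.0:
            raise ValueError("max_reject_frac must be in (0, 1)")


@dataclass
class EpochMask:
    """Frozen per-trial keep/reject decision with provenance.

    The provenance string names the condition the mask was decided on; any
    cross-condition comparison must use one and the same mask.
    """

    keep: np.ndarray
    threshold_used: float
    provenance: str
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if not self.reasons:
            self.reasons = ["" if k else "band_threshold" for k in self.keep]

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def require_same(self, other: "EpochMask") -> None:
        """Raise unless *other* is the identical frozen mask."""
        if (self.provenance != other.provenance
                or self.keep.shape != other.keep.shape
                or not np.array_equal(self.keep, other.keep)):
            raise ValueError(
                "epoch masks differ between conditions; comparisons must "
                "reuse the mask decided on the pre-EMG data"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_index": np.arange(self.keep.size),
            "keep": self.keep,
            "reason": self.reasons,
        })


def compute_threshold(per_trial_band_amp: np.ndarray,
                      cfg: RejectionConfig = RejectionConfig()) -> float:
    """Adaptive rejection threshold in μV/Hz.

    ``min(a * mean + b, cap)``, raised to the smallest value that keeps the
    number of rejections within ``max_reject_frac`` of the trials.
    """
    amps = np.asarray(per_trial_band_amp, dtype=np.float64)
    if amps.size == 0:
        raise ValueError("need at least one trial")
    thr = min(cfg.a * float(amps.mean()) + cfg.b, cfg.cap)
    max_reject = int(np.floor(cfg.max_reject_frac * amps.size))
    if (amps > thr).sum() > max_reject:
        # Smallest threshold rejecting at most max_reject trials: the
        # (max_reject+1)-th largest amplitude (ties kept, as amp <= thr keeps).
        thr_bound = float(np.sort(amps)[::-1][max_reject])
        logger.info("threshold %.3f would reject %d/%d trials; raised to %.3f",
                    thr, int((amps > thr).sum()), amps.size, thr_bound)
        thr = thr_bound
    return float(thr)


def build_mask(per_trial_band_amp: np.ndarray,
               cfg: RejectionConfig = RejectionConfig(),
               provenance: str = "post-SMP/pre-EMG") -> EpochMask:
    """Freeze the keep/reject mask on the post-SMP, pre-EMG band amplitudes."""
    amps = np.asarray(per_trial_band_amp, dtype=np.float64)
    thr = compute_threshold(amps, cfg)
    keep = amps <= thr
    assert keep.any(), "rejection bound guarantees at least one kept trial"
    return EpochMask(keep=keep, threshold_used=thr, provenance=provenance)


def anomaly_reject(per_trial_max_gamma: np.ndarray, mask: EpochMask,
                   cfg: RejectionConfig = RejectionConfig()) -> EpochMask:
    """Single-pass 6-SD anomaly rule on the kept trials' peak gamma."""
    peaks = np.asarray(per_trial_max_gamma, dtype=np.float64)
    if peaks.shape != mask.keep.shape:
        raise ValueError("per-trial maxima do not match the mask length")
    kept = peaks[mask.keep]
    if kept.size < 3:
        logger.warning("fewer than 3 kept trials; anomaly rule skipped")
        return mask
    limit = kept.mean() + cfg.sd_limit * kept.std(ddof=1)
    keep = mask.keep & (peaks <= limit)
    reasons = [
        r if k_old == k_new else "gamma_anomaly"
        for r, k_old, k_new in zip(mask.reasons, mask.keep, keep)
    ]
    return replace(mask, keep=keep, reasons=reasons)


class EpochRejector(BaseEstimator):
    """Sklearn-style wrapper: fit freezes the mask, transform applies it.

    ``fit`` takes the per-trial 60–130 Hz amplitudes of the post-SMP /
    pre-EMG condition (and optionally per-trial peak 65–85 Hz amplitudes
    for the anomaly rule); ``transform`` selects the kept rows of any
    per-trial array, enforcing identical masks across conditions.
    """

    def __init__(self, config: RejectionConfig | None = None,
                 provenance: str = "post-SMP/pre-EMG"):
        self.config = config
        self.provenance = provenance

    def fit(self, per_trial_band_amp, per_trial_max_gamma=None):
        cfg = self.config or RejectionConfig()
        mask = build_mask(per_trial_band_amp, cfg, self.provenance)
        if per_trial_max_gamma is not None:
            mask = anomaly_reject(per_trial_max_gamma, mask, cfg)
        self.mask_ = mask
        self.threshold_ = mask.threshold_used
        return self

    def transform(self, per_trial_values):
        values = np.asarray(per_trial_values)
        if values.shape[0] != self.mask_.keep.size:
            raise ValueError("per-trial array does not match the mask length")
        return values[self.mask_.keep]
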