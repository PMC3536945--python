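"""Saccade-muscle-potential (SMP) correction.

Micro-saccades drive a stereotyped biphasic potential of the extra-ocular
muscles, picked up by electrodes at the outer canthi of the two eyes.  Each
EEG channel is regressed jointly on the left and right eye-corner reference
signals and the weighted references are subtracted.  The references
themselves pass through unchanged for audit.

Fitting two free coefficients generalises subtracting a weighted average of
the two references (the average is the special case of equal weights); a
``constrain_average`` flag provides the single-coefficient reading.
Weights are fitted once over the whole recording: saccade topography is
stationary at this timescale.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator

from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = ["SMPCorrector", "fit_smp", "apply_smp"]


class SMPCorrector(BaseEstimator):
    """Regress the eye-corner references out of every EEG channel.

    Parameters
    ----------
    left_ref, right_ref : labels of the left/right eye-corner channels.
    constrain_average : fit a single coefficient on the mean of the two
        references instead of two free coefficients.

    Attributes
    ----------
    weights_ : ndarray (n_channels, 2) — per-channel (left, right)
        coefficients; reference rows are zero.
    collinear_ : bool — True when the references were near-duplicates
        (|r| > 0.999) and the fit fell back to their mean.
    """

    def __init__(self, left_ref: str = "SMPL", right_ref: str = "SMPR",
                 constrain_average: bool = False):
        self.left_ref = left_ref
        self.right_ref = right_ref
        self.constrain_average = constrain_average

    def fit(self, rec: Recording, y=None) -> "SMPCorrector":
        L = rec.get_channel(self.left_ref)
        R = rec.get_channel(self.right_ref)
        for name, ref in ((self.left_ref, L), (self.right_ref, R)):
            if np.ptp(ref) == 0:
                raise ValueError(f"reference channel {name!r} is constant")
        Lc, Rc = L - L.mean(), R - R.mean()
        r = float(Lc @ Rc / np.sqrt((Lc @ Lc) * (Rc @ Rc)))
        collinear = abs(r) > 0.999
        if collinear:
            logger.warning("SMP references collinear (r=%.4f); regressing on "
                           "their mean", r)
        single = self.constrain_average or collinear
        D = ((Lc + Rc) / 2.0)[:, None] if single else np.column_stack([Lc, Rc])

        ref_rows = {rec.channel_index(self.left_ref),
                    rec.channel_index(self.right_ref)}
        rows = [i for i in range(rec.n_channels) if i not in ref_rows]
        Y = rec.samples[rows] - rec.samples[rows].mean(axis=1, keepdims=True)
        w, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
        weights = np.zeros((rec.n_channels, 2))
        if single:
            weights[rows, 0] = w[0] / 2.0
            weights[rows, 1] = w[0] / 2.0
        else:
            weights[rows] = w.T
        self.weights_ = weights
        self.collinear_ = collinear
        self._ref_means = (float(L.mean()), float(R.mean()))
        self._n_times = rec.n_times
        return self

    def transform(self, rec: Recording) -> Recording:
        """Subtract the weighted references; references pass through."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("SMPCorrector is not fitted")
        if rec.n_times != self._n_times:
            raise ValueError("recording length differs from the fit input")
        Lc = rec.get_channel(self.left_ref) - self._ref_means[0]
        Rc = rec.get_channel(self.right_ref) - self._ref_means[1]
        out = rec.samples.copy()
        out -= np.outer(self.weights_[:, 0], Lc) + np.outer(self.weights_[:, 1], Rc)
        return replace(rec, samples=out)

    def fit_transform(self, rec: Recording, y=None) -> Recording:
        return self.fit(rec).transform(rec)


def fit_smp(rec: Recording, ref_labels: tuple[str, str] = ("SMPL", "SMPR"),
            constrain_average: bool = False) -> SMPCorrector:
    """Fit the SMP regression model (spec-level functional surface)."""
    return SMPCorrector(left_ref=ref_labels[0], right_ref=ref_labels[1],
                        constrain_average=constrain_average).fit(rec)


def apply_smp(rec: Recording, model: SMPCorrector) -> Recording:
    """Apply a fitted SMP model to a recording."""
    return model.transform(rec)
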