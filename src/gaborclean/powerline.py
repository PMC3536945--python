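"""Mains-interference cancellation by harmonic sinusoid regression.

The fundamental is extracted from a recorded noise reference (or, as a
fallback, the channel average) by zero-phase band-pass filtering, and its
quadrature (cosine) partner is obtained from the analytic signal — the
cosine leads the sine by a quarter cycle at the mains frequency.  Harmonic
pairs are then built recursively from the angle-addition identity

    sin((k+1)θ) = sin(kθ) cos(θ) + cos(kθ) sin(θ)
    cos((k+1)θ) = cos(kθ) cos(θ) − sin(kθ) sin(θ)

which tracks slow frequency wander of the mains without ever estimating θ
explicitly.  Ordinary least squares per channel finds the basis weights and
the weighted basis is subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len
from sklearn.base import BaseEstimator

from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "extract_fundamental",
    "build_harmonics",
    "cancel_powerline",
    "default_n_harmonics",
    "PowerlineCanceller",
]


def default_n_harmonics(fs: float, f0: float) -> int:
    """All harmonics below 0.9 * Nyquist, capped at 8."""
    return int(min(8, np.floor(0.9 * (fs / 2.0) / f0)))


def extract_fundamental(
    noise_ref: np.ndarray, fs: float, f0: float = 50.0, bw: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude quadrature pair (sine, cosine) of the mains fundamental.

    The reference is band-passed (zero-phase FIR, f0 ± bw/2), normalised by
    its analytic-signal envelope, and the cosine is the quarter-cycle
    advance of the sine.

    Raises
    ------
    ValueError
        If no mains component is detectable in the band (flat reference).
    """
    x = np.asarray(noise_ref, dtype=np.float64)
    lo, hi = f0 - bw / 2.0, f0 + bw / 2.0
    if lo <= 0 or hi >= fs / 2.0:
        raise ValueError(f"band [{lo}, {hi}] Hz outside (0, fs/2)")
    numtaps = int(round(1.65 * fs)) | 1   # ~2 Hz transition width
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    band = sps.fftconvolve(x, taps, mode="same")

    # In-band line power must stand out against the neighbouring spectrum.
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    in_band = spec[(freqs >= lo) & (freqs <= hi)]
    near = spec[(freqs >= f0 - 10) & (freqs <= f0 + 10) &
                ((freqs < lo) | (freqs > hi))]
    floor = np.median(near) if near.size else 0.0
    if in_band.size == 0 or in_band.max() <= max(3.0 * floor, 1e-12):
        raise ValueError("no mains component detected in the reference")

    z = sps.hilbert(band, N=next_fast_len(band.size))[:band.size]
    env = np.abs(z)
    env = np.maximum(env, 1e-12 * env.max())
    sine = band / env
    cosine = -np.imag(z) / env     # cos leads sin by a quarter cycle
    return sine, cosine


def build_harmonics(
    sine: np.ndarray, cosine: np.ndarray, K: int,
    fs: float | None = None, f0: float | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Quadrature pairs at harmonics 1..K via the angle-addition recursion."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if fs is not None and f0 is not None and K * f0 >= fs / 2.0:
        raise ValueError(f"harmonic {K} * {f0} Hz reaches the Nyquist rate")
    pairs = [(sine, cosine)]
    sk, ck = sine, cosine
    for _ in range(K - 1):
        sk, ck = sk * cosine + ck * sine, ck * cosine - sk * sine
        pairs.append((sk, ck))
    return pairs


def cancel_powerline(
    rec: Recording,
    f0: float = 50.0,
    n_harmonics: int | None = None,
    noise_channel: str | None = None,
    bw: float = 2.0,
    block_seconds: float | None = None,
    exclude: list[str] | None = None,
) -> tuple[Recording, np.ndarray]:
    """Remove mains interference from every channel; returns weights for audit."""
    model = PowerlineCanceller(
        f0=f0, n_harmonics=n_harmonics, noise_channel=noise_channel, bw=bw,
        block_seconds=block_seconds, exclude=exclude,
    )
    corrected = model.fit_transform(rec)
    return corrected, model.weights_


class PowerlineCanceller(BaseEstimator):
    """Sklearn-style transformer regressing out mains harmonics.

    Parameters
    ----------
    f0 : mains frequency, Hz (50 default).
    n_harmonics : number of harmonic pairs; default all below 0.9*Nyquist,
        capped at 8.
    noise_channel : label of a dedicated mains reference channel.  When
        absent the fundamental is extracted from the average of all
        (non-excluded) channels — a documented fallback for recordings made
        without a noise electrode.
    bw : band-pass width around f0, Hz.
    block_seconds : fit weights piecewise over blocks of this length for
        non-stationary mains; default one fit over the whole recording.
    exclude : channels passed through uncorrected (e.g. event channels).

    Attributes
    ----------
    basis_ : ndarray (n_times, 2K) — unit-amplitude regressors.
    weights_ : ndarray (n_channels, 2K) — per-channel OLS coefficients
        (block fits stack along a leading axis).
    """

    def __init__(self, f0: float = 50.0, n_harmonics: int | None = None,
                 noise_channel: str | None = None, bw: float = 2.0,
                 block_seconds: float | None = None,
                 exclude: list[str] | None = None):
        self.f0 = f0
        self.n_harmonics = n_harmonics
        self.noise_channel = noise_channel
        self.bw = bw
        self.block_seconds = block_seconds
        self.exclude = exclude

    def _basis(self, rec: Recording) -> np.ndarray:
        if self.noise_channel is not None:
            ref = rec.get_channel(self.noise_channel)
        else:
            logger.info("no noise channel given; extracting the mains "
                        "fundamental from the channel average")
            keep = [i for i, lab in enumerate(rec.channel_labels)
                    if lab not in (self.exclude or [])]
            ref = rec.samples[keep].mean(axis=0)
        sine, cosine = extract_fundamental(ref, rec.fs, self.f0, self.bw)
        K = (self.n_harmonics if self.n_harmonics is not None
             else default_n_harmonics(rec.fs, self.f0))
        pairs = build_harmonics(sine, cosine, K, fs=rec.fs, f0=self.f0)
        return np.column_stack([c for pair in pairs for c in pair])

    def fit(self, rec: Recording, y=None) -> "PowerlineCanceller":
        basis = self._basis(rec)
        if np.linalg.matrix_rank(basis.T @ basis) < basis.shape[1]:
            raise ValueError("rank-deficient mains basis (degenerate quadrature)")
        skip = set(self.exclude or [])
        if self.noise_channel is not None:
            skip.add(self.noise_channel)
        rows = [i for i, lab in enumerate(rec.channel_labels) if lab not in skip]

        n = rec.n_times
        if self.block_seconds:
            nb = max(1, int(round(n / (self.block_seconds * rec.fs))))
            edges = np.linspace(0, n, nb + 1).astype(int)
        else:
            edges = np.array([0, n])
        weights = np.zeros((len(edges) - 1, rec.n_channels, basis.shape[1]))
        for b, (i0, i1) in enumerate(zip(edges[:-1], edges[1:])):
            B = basis[i0:i1]
            w, *_ = np.linalg.lstsq(B, rec.samples[rows, i0:i1].T, rcond=None)
            weights[b, rows] = w.T
        self.basis_ = basis
        self.block_edges_ = edges
        self.weights_ = weights if self.block_seconds else weights[0]
        self._rows = rows
        return self

    def transform(self, rec: Recording) -> Recording:
        if not hasattr(self, "basis_"):
            raise RuntimeError("PowerlineCanceller is not fitted")
        if rec.n_times != self.basis_.shape[0]:
            raise ValueError("recording length differs from the fit input")
        out = rec.samples.copy()
        W = self.weights_ if self.weights_.ndim == 3 else self.weights_[np.newaxis]
        edges = self.block_edges_
        for b, (i0, i1) in enumerate(zip(edges[:-1], edges[1:])):
            out[self._rows, i0:i1] -= W[b, self._rows] @ self.basis_[i0:i1].T
        return replace(rec, samples=out)

    def fit_transform(self, rec: Recording, y=None) -> Recording:
        return self.fit(rec).transform(rec)
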