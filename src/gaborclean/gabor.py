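"""Detection, fitting and subtraction of scalp/neck EMG muscle spikes.

A muscle spike is modelled as a Gabor atom: a sine wave modulated by a
Gaussian envelope,

    g(t) = A * sin(2*pi*f*(t - t0) + phi) * exp(-(t - t0)**2 / (2*sigma**2)).

The reduction pipeline per channel is

1. **detect** sharp potential changes over 3.5 ms (on a 10 Hz high-passed
   copy of the signal; everything downstream uses the unfiltered data);
2. **locate** the Gaussian center: near the center the atom is locally
   sinusoidal, so its first and third discrete differentials become
   strongly *inversely* correlated — the most negative d1/d3 correlation
   within a few milliseconds of the detection marks the center, and weak
   correlations (less negative than a rate-dependent threshold) reject the
   candidate as non-spike activity;
3. **estimate sigma** from the ratio of the gradient at the center to the
   gradient 1 ms earlier, inverted through a precomputed monotone table;
4. **refine t0** by hill-climbing in 0.01 ms steps on the correlation
   between the regenerated atom and the signal;
5. **fit amplitude and phase** by least squares on a sin/cos quadrature
   pair (plus a second pair at twice the carrier frequency at high
   sampling rates, capturing sharper spike components) over the support
   window t0 ± 4 sigma, and subtract the fitted waveform in place.

Spikes are processed in temporal order and each subtraction is applied
before later candidates are evaluated (sequential greedy, in the spirit of
matching pursuit).  The returned inventory fully explains the correction:
``corrected == input − sum(atom waveforms)`` bit-exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.fft import next_fast_len
from sklearn.base import BaseEstimator

from ._kernels import HAVE_NUMBA, refine_kernel, score_kernel
from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CARRIER_HZ",
    "DetectionConfig",
    "GaborSpike",
    "gabor_waveform",
    "default_corr_thresh",
    "highpass_detection_filter",
    "detect_candidates",
    "locate_center",
    "estimate_sigma",
    "refine_center",
    "fit_amplitude_and_subtract",
    "reduce_emg",
    "spikes_to_frame",
    "reconstruct_spike_signal",
    "GaborSpikeRemover",
]

#: Default carrier frequency: the steepest half-cycle of the sine spans the
#: 3.5 ms spike signature, i.e. f = 1 / (2 * 3.5 ms).
DEFAULT_CARRIER_HZ = 1.0 / (2.0 * 3.5e-3)


def default_corr_thresh(fs: float) -> float:
    """Rate-dependent d1/d3 gate: −0.78 below 3.5 kHz, −0.84 at and above."""
    return -0.78 if fs < 3500.0 else -0.84


@dataclass
class DetectionConfig:
    """Tunable parameters of the spike reduction algorithm.

    Attributes
    ----------
    delta_t : float
        Span of the sharp-change detector, seconds (3.5 ms).
    v_thresh : float
        Minimum potential change over ``delta_t`` in μV.  The standard value
        is 7 μV; per-subject optimised values typically lie in 4–9 μV.
    corr_thresh : float or None
        Most positive d1/d3 correlation still accepted as a spike center
        (−0.78 at 2 kHz, −0.84 at 5 kHz).  ``None`` selects by sampling rate.
    search_ms : float
        Half-window of the center search around a detection, ms.
    hp_cutoff : float
        High-pass cutoff of the detection pre-filter, Hz.
    f : float
        Carrier frequency of the Gabor atoms, Hz.
    sigma_grid_ms : (lo, hi, step)
        Grid for the gradient-ratio lookup table, ms.
    refine_step_s : float
        Center hill-climb step, seconds (0.01 ms).
    max_refine_steps : int
        Bound on accepted hill-climb moves (±2 ms at the default step).
    support_sigmas : float
        Half-width of the fit/subtraction window in units of sigma.
    polish_sigma : bool
        After the t0 refinement, hill-climb sigma on the lookup grid,
        maximising the same atom–signal correlation.
    extra_hf : bool or None
        Add a quadrature pair at 2f to the amplitude fit.  ``None`` enables
        it at sampling rates >= 3.5 kHz, where the faster rate resolves
        higher-frequency spike components.
    envelope_seed : bool
        Also seed the refinement from the analytic-signal envelope of the
        candidate neighbourhood (its argmax and log-parabola width are
        phase-invariant first guesses for t0 and sigma) and keep whichever
        seed refines to the higher atom–signal correlation.
    min_fit_corr : float
        Atoms whose final fit correlation falls below this floor are not
        subtracted: short-support fits on background activity reach
        spuriously inflated correlations, and subtracting them would add,
        not remove, artifact energy.
    n_passes : int
        Number of detect-and-subtract sweeps per channel.  Spikes closer
        than the 3.5 ms detection span merge into one candidate on the
        first sweep; a second sweep over the residual recovers the masked
        partner of such overlapping pairs.
    backfit_overlaps : bool
        Atoms whose support windows overlap are fitted on data still
        containing their neighbours, which couples their estimates.  When
        enabled, each member of an overlapping group is added back to the
        residual and re-estimated in turn (two cycles) — a backfitting
        pass in the matching-pursuit sense.
    """

    delta_t: float = 3.5e-3
    v_thresh: float = 7.0
    corr_thresh: float | None = None
    search_ms: float = 5.0
    hp_cutoff: float = 10.0
    f: float = DEFAULT_CARRIER_HZ
    sigma_grid_ms: tuple[float, float, float] = (0.5, 6.0, 0.05)
    refine_step_s: float = 1e-5
    max_refine_steps: int = 200
    support_sigmas: float = 4.0
    polish_sigma: bool = True
    extra_hf: bool | None = None
    envelope_seed: bool = True
    min_fit_corr: float = 0.5
    n_passes: int = 2
    backfit_overlaps: bool = True

    def __post_init__(self) -> None:
        if self.v_thresh <= 0:
            raise ValueError("v_thresh must be > 0")
        if self.corr_thresh is not None and not -1.0 < self.corr_thresh < 0.0:
            raise ValueError("corr_thresh must lie in (-1, 0)")

    def resolve(self, fs: float) -> "ResolvedConfig":
        n_delta = int(round(self.delta_t * fs))
        if n_delta < 2:
            raise ValueError("delta_t * fs must be at least 2 samples")
        return ResolvedConfig(
            base=self,
            fs=fs,
            n_delta=n_delta,
            w_corr=max(4, int(round(3.5e-3 * fs))),
            n_search=max(1, int(round(self.search_ms * 1e-3 * fs))),
            corr_thresh=(self.corr_thresh if self.corr_thresh is not None
                         else default_corr_thresh(fs)),
            extra_hf=(self.extra_hf if self.extra_hf is not None
                      else fs >= 3500.0),
            f=self.f,
            support_sigmas=self.support_sigmas,
        )


@dataclass
class ResolvedConfig:
    """DetectionConfig with sampling-rate-dependent defaults filled in."""

    base: DetectionConfig
    fs: float
    n_delta: int
    w_corr: int
    n_search: int
    corr_thresh: float
    extra_hf: bool
    f: float = DEFAULT_CARRIER_HZ
    support_sigmas: float = 4.0

    def __getattr__(self, name):
        return getattr(self.base, name)


@dataclass
class GaborSpike:
    """One fitted muscle-spike atom.

    ``coeffs`` holds the least-squares coefficients of the quadrature basis
    ``[sin, cos]`` (and ``[sin_2f, cos_2f]`` when a harmonic pair was
    fitted); ``A`` and ``phi`` are derived from the base pair.  ``i0:i1`` is
    the support window in parent-signal samples.
    """

    t0: float                 # Gaussian center, s
    sigma: float              # Gaussian spread, s
    f: float                  # carrier frequency, Hz
    phi: float                # phase of the sine at the center, rad
    A: float                  # amplitude, μV
    channel: str = ""
    corr: float = np.nan      # atom–signal correlation achieved
    coeffs: tuple = ()
    i0: int = 0
    i1: int = 0

    def waveform(self, fs: float) -> np.ndarray:
        """Regenerate the subtracted waveform on samples ``i0:i1``."""
        basis = _quadrature_basis(
            np.arange(self.i0, self.i1) / fs, self.t0, self.sigma, self.f,
            harmonic=len(self.coeffs) == 4,
        )
        return basis @ np.asarray(self.coeffs)


def gabor_waveform(
    t0: float, sigma: float, f: float, phi: float, A: float,
    time_grid: np.ndarray,
) -> np.ndarray:
    """Evaluate a Gabor atom on a time grid (seconds)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = np.asarray(time_grid, dtype=np.float64) - t0
    return A * np.sin(2.0 * np.pi * f * t + phi) * np.exp(-t * t / (2.0 * sigma * sigma))


def highpass_detection_filter(x: np.ndarray, fs: float, cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase FIR high-pass used only for the detection step.

    A linear-phase odd-length FIR applied with 'same'-mode convolution has
    zero net delay, so detection indices line up with the unfiltered signal.
    """
    numtaps = int(round(0.66 * fs)) | 1
    taps = sps.firwin(numtaps, cutoff, pass_zero=False, fs=fs)
    return sps.fftconvolve(x, taps, mode="same")


def detect_candidates(x: np.ndarray, fs: float, cfg: DetectionConfig | ResolvedConfig) -> np.ndarray:
    """Indices of candidate spikes: sharp potential changes over 3.5 ms.

    *x* must already be high-pass filtered at ``cfg.hp_cutoff``.  Candidates
    are local maxima of ``|x[i + n_delta] − x[i]|`` exceeding ``v_thresh``;
    maxima closer than ``delta_t`` are merged keeping the larger change.
    Each candidate is reported at the sample of steepest gradient inside its
    3.5 ms span.
    """
    rc = cfg if isinstance(cfg, ResolvedConfig) else cfg.resolve(fs)
    nd = rc.n_delta
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2 * nd:
        raise ValueError(f"signal shorter than 2 * {nd} samples")
    d = np.abs(x[nd:] - x[:-nd])
    peaks, _ = sps.find_peaks(d, height=rc.v_thresh, distance=nd)
    grad = np.abs(np.diff(x))
    out = np.empty(peaks.size, dtype=np.intp)
    for k, i in enumerate(peaks):
        out[k] = i + int(np.argmax(grad[i:i + nd]))
    return np.unique(out)


def _windowed_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", a, b) / den
    return np.where(den > 0, r, 0.0)


def locate_center(
    x: np.ndarray, fs: float, candidate_idx: int,
    cfg: DetectionConfig | ResolvedConfig,
) -> tuple[int, float] | None:
    """Find the Gaussian center near a candidate, or reject it.

    Scans ``candidate_idx ± search_ms`` for the most negative correlation
    between the first and third discrete differentials (windows of
    ``w_corr`` samples, both differentials aligned at the same offset).
    Returns ``(center_idx, corr)`` or ``None`` when the best correlation is
    less negative than ``corr_thresh``.
    """
    rc = cfg if isinstance(cfg, ResolvedConfig) else cfg.resolve(fs)
    w, h = rc.w_corr, rc.w_corr // 2
    lo = max(candidate_idx - rc.n_search, h)
    hi = min(candidate_idx + rc.n_search, x.size - 3 + h - w)
    if hi < lo:
        logger.debug("candidate %d: correlation window exceeds bounds", candidate_idx)
        return None
    # differentials only over the local neighbourhood actually needed
    seg0 = lo - h
    seg1 = hi - h + w + 3
    d1 = np.diff(x[seg0:seg1])
    d3 = np.diff(x[seg0:seg1], 3)
    n = hi - lo + 1
    wins1 = sliding_window_view(d1, w)[:n]
    wins3 = sliding_window_view(d3, w)[:n]
    n = min(wins1.shape[0], wins3.shape[0], n)
    r = _windowed_corr(wins1[:n], wins3[:n])
    k = int(np.argmin(r))
    if r[k] > rc.corr_thresh:
        return None
    return lo + k, float(r[k])


# --- sigma estimation -------------------------------------------------------

_SIGMA_TABLE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _sigma_table(fs: float, f: float, grid_ms: tuple[float, float, float]):
    """Tabulate the discrete gradient ratio statistic for phi=0 unit atoms.

    The raw ratio grad(center) / grad(center − 1 ms) has a pole where the
    −1 ms gradient changes sign, so the table stores its reciprocal

        q(sigma) = grad(center − 1 ms) / grad(center),

    which is monotone increasing in sigma (the center gradient of a phi=0
    atom never vanishes).  Gradients are centered differences on the sample
    grid — exactly the statistic :func:`estimate_sigma` measures.  A
    non-injective region at the very small-sigma end (sub-millisecond
    spreads at high sampling rates) is trimmed off; estimates there clamp
    to the first tabulated sigma.
    """
    key = (round(fs, 6), round(f, 6), grid_ms)
    if key in _SIGMA_TABLE_CACHE:
        return _SIGMA_TABLE_CACHE[key]
    lo, hi, step = grid_ms
    sigmas = np.arange(lo, hi + step / 2, step) * 1e-3
    n1 = int(round(1e-3 * fs))
    L = int(np.ceil(8e-3 * fs)) + n1 + 2
    t = (np.arange(2 * L + 1) - L) / fs
    q = np.empty_like(sigmas)
    for i, s in enumerate(sigmas):
        g = gabor_waveform(0.0, s, f, 0.0, 1.0, t)
        grad = np.gradient(g)
        q[i] = grad[L - n1] / grad[L]
    # keep the longest strictly increasing suffix
    dec = np.where(np.diff(q) <= 0)[0]
    start = int(dec[-1]) + 1 if dec.size else 0
    sigmas, q = sigmas[start:], q[start:]
    if sigmas.size < 4 or not np.all(np.diff(q) > 0):
        raise RuntimeError("gradient-ratio table is not strictly monotone")
    _SIGMA_TABLE_CACHE[key] = (sigmas, q)
    return sigmas, q


def estimate_sigma(
    x: np.ndarray, fs: float, center_idx: int,
    cfg: DetectionConfig | ResolvedConfig,
) -> float:
    """Estimate the Gaussian spread from the 0 ms / −1 ms gradient ratio.

    The measured ratio is inverted through the monotone table r(sigma);
    out-of-range ratios are clamped to the grid ends with a warning.  When
    the −1 ms gradient is degenerate (near zero, or the ratio falls outside
    any physical range), a grid search maximising the quadrature-fit
    correlation is used instead.
    """
    sigma, _ = _estimate_sigma_info(x, fs, center_idx, cfg)
    return sigma


def _estimate_sigma_info(x, fs, center_idx, cfg) -> tuple[float, bool]:
    """estimate_sigma plus a flag marking a degenerate/clamped estimate."""
    rc = cfg if isinstance(cfg, ResolvedConfig) else cfg.resolve(fs)
    sigmas, q_table = _sigma_table(fs, rc.f, rc.sigma_grid_ms)
    n1 = int(round(1e-3 * fs))
    if center_idx - n1 - 1 < 0 or center_idx + 2 > x.size:
        return _sigma_grid_search(x, fs, center_idx, rc, sigmas), True
    gc = (x[center_idx + 1] - x[center_idx - 1]) / 2.0
    gp = (x[center_idx - n1 + 1] - x[center_idx - n1 - 1]) / 2.0
    lo_n = max(1, center_idx - 2 * n1)
    hi_n = min(x.size - 1, center_idx + 2 * n1)
    grad_near = (x[lo_n + 1:hi_n + 1] - x[lo_n - 1:hi_n - 1]) / 2.0
    gmax = np.max(np.abs(grad_near)) if grad_near.size else 0.0
    if abs(gc) < 0.6 * gmax or gmax == 0.0:
        # the ratio statistic assumes the carrier zero-crossing sits at
        # the center (phi ~ 0, where the center gradient is the local
        # maximum); a substantially smaller center gradient marks a
        # quadrature-ish phase where the estimate is unreliable
        logger.debug("degenerate center gradient at %d; falling back to grid "
                     "search", center_idx)
        return _sigma_grid_search(x, fs, center_idx, rc, sigmas), True
    q = gp / gc
    if q <= q_table[0] or q >= q_table[-1]:
        warnings.warn("gradient ratio outside the sigma grid; clamping",
                      stacklevel=2)
        return float(sigmas[0] if q <= q_table[0] else sigmas[-1]), True
    return float(np.interp(q, q_table, sigmas)), False


def _sigma_grid_search(x, fs, center_idx, rc, sigmas) -> float:
    t0 = center_idx / fs
    best, best_score = sigmas[len(sigmas) // 2], -np.inf
    for s in sigmas[::4]:
        score = _fit_score(x, fs, t0, s, rc)
        if score > best_score:
            best, best_score = s, score
    return float(best)


# --- quadrature fitting -----------------------------------------------------

def _quadrature_basis(t: np.ndarray, t0: float, sigma: float, f: float,
                      harmonic: bool) -> np.ndarray:
    """Design matrix [sin, cos] (x Gaussian), plus the 2f pair if requested."""
    tau = t - t0
    env = np.exp(-tau * tau / (2.0 * sigma * sigma))
    ang = 2.0 * np.pi * f * tau
    cols = [np.sin(ang) * env, np.cos(ang) * env]
    if harmonic:
        cols += [np.sin(2.0 * ang) * env, np.cos(2.0 * ang) * env]
    return np.column_stack(cols)


def _support(x_size: int, fs: float, t0: float, sigma: float, k: float):
    i0 = int(round((t0 - k * sigma) * fs))
    i1 = int(round((t0 + k * sigma) * fs)) + 1
    if i0 < 0 or i1 > x_size or i1 - i0 < 5:
        return None
    return i0, i1


def _ls_fit(x: np.ndarray, fs: float, t0: float, sigma: float, f: float,
            harmonic: bool, i0: int, i1: int):
    """Least-squares fit of the quadrature atom over x[i0:i1].

    A quadratic baseline is fitted jointly so that slow EEG (mu/alpha
    waves) underneath the spike does not bias the atom coefficients; only
    the atom part of the model is reported for subtraction.  The returned
    correlation is the partial correlation of the atom given the baseline.
    Returns (atom_coeffs, atom_model, corr) or None for a singular design.
    """
    t = np.arange(i0, i1) / fs
    Da = _quadrature_basis(t, t0, sigma, f, harmonic)
    na = Da.shape[1]
    tau = np.linspace(-1.0, 1.0, t.size)
    D = np.column_stack([Da, np.ones_like(tau), tau, tau * tau])
    y = x[i0:i1]
    G = D.T @ D
    b = D.T @ y
    try:
        coef = np.linalg.solve(G, b)
        coef_tr = np.linalg.solve(G[na:, na:], b[na:])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(coef)):
        return None
    model = D @ coef
    sse_full = float(y @ y) - float(b @ coef)
    sse_trend = float(y @ y) - float(b[na:] @ coef_tr)
    if sse_trend > 0:
        corr = float(np.sqrt(max(sse_trend - sse_full, 0.0) / sse_trend))
    else:
        corr = 0.0
    atom_model = Da @ coef[:na]
    return coef[:na], atom_model, corr


def _fit_score(x, fs, t0, sigma, rc) -> float:
    if sigma <= 0:
        return -np.inf
    if HAVE_NUMBA:
        try:
            return float(score_kernel(x, fs, t0, sigma, rc.f,
                                      rc.support_sigmas, rc.extra_hf))
        except np.linalg.LinAlgError:
            return -np.inf
    sup = _support(x.size, fs, t0, sigma, rc.support_sigmas)
    if sup is None:
        return -np.inf
    res = _ls_fit(x, fs, t0, sigma, rc.f, rc.extra_hf, *sup)
    return res[2] if res is not None else -np.inf


def _climb_t0(x, fs, t0, sigma, rc, step, max_steps):
    """Greedy t0 climb at one step size; returns (t0, score)."""
    score = _fit_score(x, fs, t0, sigma, rc)
    direction = None
    for d in (+1.0, -1.0):
        if _fit_score(x, fs, t0 + d * step, sigma, rc) > score:
            direction = d
            break
    if direction is not None:
        for _ in range(max_steps):
            cand = t0 + direction * step
            s = _fit_score(x, fs, cand, sigma, rc)
            if s <= score:
                break
            t0, score = cand, s
    return t0, score


def refine_center(
    x: np.ndarray, fs: float, spike: GaborSpike,
    cfg: DetectionConfig | ResolvedConfig,
) -> GaborSpike:
    """Hill-climb the atom center in 0.01 ms steps.

    The atom is regenerated on the sample grid at each sub-sample shift and
    the move is kept only when the atom–signal correlation increases; the
    climb stops when neither direction improves or after
    ``max_refine_steps`` accepted moves.
    """
    rc = cfg if isinstance(cfg, ResolvedConfig) else cfg.resolve(fs)
    t0, score = _climb_t0(x, fs, spike.t0, spike.sigma, rc,
                          rc.refine_step_s, rc.max_refine_steps)
    return replace(spike, t0=t0, corr=score)


def _envelope_seed(x, fs, center_idx, rc):
    """Phase-invariant (t0, sigma) seed from the analytic-signal envelope.

    The envelope of a Gabor atom is the Gaussian itself, whatever the
    carrier phase: its argmax seeds t0 and the curvature of its logarithm
    around the peak seeds sigma.
    """
    L = int(round(10e-3 * fs))
    i0, i1 = max(0, center_idx - L), min(x.size, center_idx + L + 1)
    seg = x[i0:i1]
    if seg.size < 16:
        return None
    # manual linear detrend + FFT analytic envelope (hot path)
    idx = np.arange(seg.size, dtype=np.float64)
    idx -= idx.mean()
    seg = seg - seg.mean() - (idx @ seg / (idx @ idx)) * idx
    m = next_fast_len(seg.size)
    F = np.fft.fft(seg, m)
    F[1:(m + 1) // 2] *= 2.0
    F[(m + 1) // 2 + (1 - m % 2):] = 0.0
    env = np.abs(np.fft.ifft(F)[:seg.size])
    # light smoothing over ~1/4 carrier cycle suppresses envelope ripple
    k = max(1, int(round(fs / rc.f / 4)))
    if k > 1:
        env = np.convolve(env, np.ones(k) / k, mode="same")
    pk = int(np.argmax(env))
    if pk <= 1 or pk >= env.size - 2:
        return None
    half = env >= 0.5 * env[pk]
    sel = np.arange(max(0, pk - 3 * int(round(1e-3 * fs))),
                    min(env.size, pk + 3 * int(round(1e-3 * fs))))
    sel = sel[half[sel] & (env[sel] > 0)]
    if sel.size < 5:
        return None
    tau = (sel - pk) / fs
    coef = np.polyfit(tau, np.log(env[sel]), 2)
    if coef[0] >= 0:
        return None
    sigma = float(np.sqrt(-1.0 / (2.0 * coef[0])))
    lo, hi, _ = rc.sigma_grid_ms
    sigma = float(np.clip(sigma, lo * 1e-3, hi * 1e-3))
    return (i0 + pk) / fs, sigma


def _climb_sigma(x, fs, t0, sigma, rc, step, max_steps, score=None):
    """Greedy sigma climb within the lookup-grid bounds."""
    lo, hi, _ = rc.sigma_grid_ms
    if score is None:
        score = _fit_score(x, fs, t0, sigma, rc)
    for d in (+1.0, -1.0):
        improved = False
        for _ in range(max_steps):
            cand = sigma + d * step
            if not lo * 1e-3 <= cand <= hi * 1e-3:
                break
            s = _fit_score(x, fs, t0, cand, rc)
            if s <= score:
                break
            sigma, score, improved = cand, s, True
        if improved:
            break
    return sigma, score


def _polish_sigma(x, fs, spike: GaborSpike, rc) -> GaborSpike:
    """Bounded hill-climb of sigma on the lookup grid (design choice)."""
    _, _, step_ms = rc.sigma_grid_ms
    sigma, score = _climb_sigma(x, fs, spike.t0, spike.sigma, rc,
                                step_ms * 1e-3, 40)
    return replace(spike, sigma=sigma, corr=score)


def _parab_step(x, fs, t0, sigma, rc, step, score, vary_t0):
    """Parabolic interpolation of the score around the grid optimum."""
    if vary_t0:
        s_m = _fit_score(x, fs, t0 - step, sigma, rc)
        s_p = _fit_score(x, fs, t0 + step, sigma, rc)
    else:
        s_m = _fit_score(x, fs, t0, sigma - step, rc)
        s_p = _fit_score(x, fs, t0, sigma + step, rc)
    denom = s_m - 2.0 * score + s_p
    if not np.isfinite(denom) or denom >= 0:
        return (t0 if vary_t0 else sigma), score
    delta = float(np.clip(0.5 * step * (s_m - s_p) / denom, -step, step))
    cand = (t0 + delta) if vary_t0 else (sigma + delta)
    if not vary_t0 and cand <= 0:
        return sigma, score
    s_c = (_fit_score(x, fs, cand, sigma, rc) if vary_t0
           else _fit_score(x, fs, t0, cand, rc))
    if s_c > score:
        return cand, s_c
    return (t0 if vary_t0 else sigma), score


def fit_amplitude_and_subtract(
    x: np.ndarray, fs: float, spike: GaborSpike,
    cfg: DetectionConfig | ResolvedConfig,
    inplace: bool = False,
) -> tuple[np.ndarray, GaborSpike] | None:
    """Fit amplitude/phase by regression and subtract the atom in place.

    The design matrix is the sin/cos quadrature pair at the carrier
    frequency (phase enters through the two coefficients), plus a second
    pair at 2f with the same center and spread when ``extra_hf`` is active.
    The fitted waveform is subtracted from the *unfiltered* signal over the
    support window ``t0 ± support_sigmas * sigma`` only; outside it the
    signal is untouched.  Returns ``(corrected, spike)`` or ``None`` when
    the support leaves the signal or the design is singular.
    """
    rc = cfg if isinstance(cfg, ResolvedConfig) else cfg.resolve(fs)
    sup = _support(x.size, fs, spike.t0, spike.sigma, rc.support_sigmas)
    if sup is None:
        logger.debug("support window for t0=%.4f s leaves the signal", spike.t0)
        return None
    i0, i1 = sup
    res = _ls_fit(x, fs, spike.t0, spike.sigma, rc.f, rc.extra_hf, i0, i1)
    if res is None:
        logger.debug("singular design at t0=%.4f s (sigma=%.2g s)", spike.t0,
                     spike.sigma)
        return None
    coef, model, corr = res
    y = x if inplace else x.copy()
    y[i0:i1] -= model
    fitted = replace(
        spike,
        A=float(np.hypot(coef[0], coef[1])),
        phi=float(np.arctan2(coef[1], coef[0])),
        corr=corr,
        coeffs=tuple(float(c) for c in coef),
        i0=i0, i1=i1, f=rc.f,
    )
    return y, fitted


def _explained_union(y, fs, sp: GaborSpike, other: GaborSpike, rc) -> float:
    """Residual energy of *sp*'s fit over the union of both supports.

    Fair basis for choosing between two candidate parameterisations whose
    support windows differ: a tiny-sigma atom can fit its own short window
    almost perfectly while leaving the rest of the spike untouched.
    """
    sup = _support(y.size, fs, sp.t0, sp.sigma, rc.support_sigmas)
    if sup is None:
        return np.inf
    res = _ls_fit(y, fs, sp.t0, sp.sigma, rc.f, rc.extra_hf, *sup)
    if res is None:
        return np.inf
    _, model, _ = res
    sup2 = _support(y.size, fs, other.t0, other.sigma, rc.support_sigmas)
    j0 = min(sup[0], sup2[0]) if sup2 else sup[0]
    j1 = max(sup[1], sup2[1]) if sup2 else sup[1]
    resid = y[j0:j1].copy()
    resid[sup[0] - j0:sup[1] - j0] -= model
    return float(resid @ resid)


def _fit_candidate(y, fs, located, rc, label) -> GaborSpike | None:
    """Parameter estimation for one gated candidate.

    Seeds (t0, sigma) from the gradient-ratio table at the located center
    and, optionally, from the analytic-signal envelope; each seed is
    coarse-climbed, refined at the 0.01 ms step and sigma-polished, and the
    seed reaching the higher atom–signal correlation wins.
    """
    center, gate_corr = located
    lo_ms, hi_ms, step_ms = rc.sigma_grid_ms

    def refine_from(t0_seed, sigma_seed):
        # coarse t0 (0.05 ms), coarse sigma (0.2 ms), then the 0.01 ms
        # climb of the contract, and a fine sigma polish
        if HAVE_NUMBA:
            try:
                t0c, sigma, sc = refine_kernel(
                    y, fs, t0_seed, sigma_seed, rc.f, rc.support_sigmas,
                    rc.extra_hf, rc.refine_step_s, rc.max_refine_steps,
                    step_ms * 1e-3, lo_ms * 1e-3, hi_ms * 1e-3,
                    rc.polish_sigma)
            except np.linalg.LinAlgError:
                return GaborSpike(t0=t0_seed, sigma=sigma_seed, f=rc.f,
                                  phi=0.0, A=0.0, channel=label, corr=-np.inf)
        else:
            t0c, sc = _climb_t0(y, fs, t0_seed, sigma_seed, rc,
                                5.0 * rc.refine_step_s, 25)
            sigma = sigma_seed
            for cand in np.arange(lo_ms, hi_ms + 1e-9, 4 * step_ms) * 1e-3:
                s = _fit_score(y, fs, t0c, cand, rc)
                if s > sc:
                    sigma, sc = float(cand), s
            t0c, sc = _climb_t0(y, fs, t0c, sigma, rc, rc.refine_step_s,
                                rc.max_refine_steps)
            if rc.polish_sigma:
                sigma, sc = _climb_sigma(y, fs, t0c, sigma, rc,
                                         step_ms * 1e-3, 20, score=sc)
                for _ in range(2):
                    sigma, sc = _parab_step(y, fs, t0c, sigma, rc,
                                            step_ms * 1e-3, sc, False)
                    t0c, sc = _parab_step(y, fs, t0c, sigma, rc,
                                          rc.refine_step_s, sc, True)
        return GaborSpike(t0=t0c, sigma=sigma, f=rc.f, phi=0.0, A=0.0,
                          channel=label, corr=sc)

    sigma_seed, seed_degenerate = _estimate_sigma_info(y, fs, center, rc)
    best = refine_from(center / fs, sigma_seed)
    # a sigma at the grid floor with high correlation is suspicious: the
    # correlation is measured over the atom's own (tiny) support and can
    # look excellent while most of the spike is left behind; a degenerate
    # gradient-ratio seed (quadrature-phase spikes) is equally suspect
    at_floor = best.sigma <= lo_ms * 1e-3 * 1.3
    if rc.envelope_seed and (best.corr < 0.95 or at_floor or seed_degenerate):
        es = _envelope_seed(y, fs, center, rc)
        if es is not None:
            alt = refine_from(*es)
            if (_explained_union(y, fs, alt, best, rc)
                    < _explained_union(y, fs, best, alt, rc)):
                best = alt
    return best


def _backfit_overlaps(y, fs, spikes: list[GaborSpike], label: str, rc):
    """Re-estimate atoms whose support windows overlap (two cycles).

    Each member of an overlapping group is added back to the residual and
    refined/refit on data free of its own previous estimate; the list is
    updated in place.  Atoms with disjoint supports are left untouched, so
    the conservation contract (corrected = input − sum of atoms) holds
    throughout.
    """
    idx = [i for i, s in enumerate(spikes) if s.channel == label]
    if len(idx) < 2:
        return y
    idx.sort(key=lambda i: spikes[i].i0)
    groups: list[list[int]] = []
    cur = [idx[0]]
    hi = spikes[idx[0]].i1
    for i in idx[1:]:
        if spikes[i].i0 < hi:
            cur.append(i)
        else:
            groups.append(cur)
            cur = [i]
        hi = max(hi, spikes[i].i1)
    groups.append(cur)
    lo_ms, hi_ms, step_ms = rc.sigma_grid_ms
    for group in groups:
        if len(group) < 2:
            continue
        for _ in range(2):
            for i in group:
                sp = spikes[i]
                y[sp.i0:sp.i1] += sp.waveform(fs)
                if HAVE_NUMBA:
                    try:
                        t0n, sgn, sc = refine_kernel(
                            y, fs, sp.t0, sp.sigma, rc.f, rc.support_sigmas,
                            rc.extra_hf, rc.refine_step_s, 50,
                            step_ms * 1e-3, lo_ms * 1e-3, hi_ms * 1e-3,
                            rc.polish_sigma)
                    except np.linalg.LinAlgError:
                        t0n, sgn, sc = sp.t0, sp.sigma, sp.corr
                else:
                    t0n, sc = _climb_t0(y, fs, sp.t0, sp.sigma, rc,
                                        rc.refine_step_s, 50)
                    sgn, sc = _climb_sigma(y, fs, t0n, sp.sigma, rc,
                                           step_ms * 1e-3, 20, score=sc)
                out = fit_amplitude_and_subtract(
                    y, fs, replace(sp, t0=t0n, sigma=sgn, corr=sc), rc,
                    inplace=True)
                if out is None:
                    # restore the previous estimate
                    y[sp.i0:sp.i1] -= sp.waveform(fs)
                    continue
                y, spikes[i] = out
    return y


def reduce_emg(
    rec: Recording, cfg: DetectionConfig | None = None,
    channels: list[str] | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Run the full spike-reduction pipeline on a recording.

    Per channel: detect → locate center → estimate sigma → refine → fit &
    subtract, in temporal order, each subtraction applied before later
    candidates are evaluated.  Per-candidate failures are logged and
    skipped.  Returns the corrected recording and the spike inventory.
    """
    remover = GaborSpikeRemover(config=cfg or DetectionConfig(), channels=channels)
    corrected = remover.fit_transform(rec)
    return corrected, remover.inventory_


def spikes_to_frame(spikes: list[GaborSpike]) -> pd.DataFrame:
    """Tabulate a spike inventory (one row per fitted atom)."""
    cols = ["channel", "t0_s", "sigma_ms", "f_hz", "phi_rad", "amp_uv",
            "corr", "i0", "i1", "coeffs"]
    rows = [
        (s.channel, s.t0, s.sigma * 1e3, s.f, s.phi, s.A, s.corr, s.i0, s.i1,
         ",".join(repr(c) for c in s.coeffs))
        for s in spikes
    ]
    return pd.DataFrame(rows, columns=cols)


def reconstruct_spike_signal(
    inventory: pd.DataFrame, n_times: int, fs: float, channel: str,
) -> np.ndarray:
    """Sum of the fitted atom waveforms for one channel.

    Regenerates each atom from its inventory row exactly as it was
    subtracted, so ``input − reconstruction == corrected`` bit-exactly.
    """
    out = np.zeros(n_times)
    sub = inventory[inventory["channel"] == channel]
    for row in sub.itertuples(index=False):
        coeffs = tuple(float(v) for v in str(row.coeffs).split(","))
        spike = GaborSpike(
            t0=row.t0_s, sigma=row.sigma_ms * 1e-3, f=row.f_hz,
            phi=row.phi_rad, A=row.amp_uv, coeffs=coeffs,
            i0=int(row.i0), i1=int(row.i1),
        )
        out[spike.i0:spike.i1] += spike.waveform(fs)
    return out


class GaborSpikeRemover(BaseEstimator):
    """Sklearn-style transformer removing EMG spike atoms from a recording.

    Parameters
    ----------
    config : DetectionConfig
        Algorithm parameters (see :class:`DetectionConfig`).
    channels : list of str, optional
        Channels to correct; default all.

    Attributes
    ----------
    spikes_ : list of GaborSpike
        Fitted atoms, in processing order.
    inventory_ : DataFrame
        Tabular audit of ``spikes_``.
    n_candidates_ : int
        Detections prior to the d1/d3 gate.
    """

    def __init__(self, config: DetectionConfig | None = None,
                 channels: list[str] | None = None):
        self.config = config
        self.channels = channels

    def fit(self, rec: Recording, y=None) -> "GaborSpikeRemover":
        cfg = self.config or DetectionConfig()
        rc = cfg.resolve(rec.fs)
        channels = self.channels if self.channels is not None else rec.channel_labels
        spikes: list[GaborSpike] = []
        corrected = rec.samples.copy()
        n_cand = 0
        for label in channels:
            ci = rec.channel_index(label)
            y_ch = corrected[ci]
            for sweep in range(max(1, cfg.n_passes)):
                xf = highpass_detection_filter(y_ch, rec.fs, cfg.hp_cutoff)
                candidates = detect_candidates(xf, rec.fs, rc)
                n_cand += candidates.size
                n_new = 0
                for idx in candidates:
                    try:
                        located = locate_center(y_ch, rec.fs, int(idx), rc)
                        if located is None:
                            continue
                        spike = _fit_candidate(y_ch, rec.fs, located, rc, label)
                        if spike is None or spike.corr < rc.min_fit_corr:
                            continue
                        out = fit_amplitude_and_subtract(
                            y_ch, rec.fs, spike, rc, inplace=True)
                        if out is None:
                            continue
                        y_ch, fitted = out
                        spikes.append(fitted)
                        n_new += 1
                    except Exception:  # pragma: no cover - defensive
                        logger.exception("candidate at index %d skipped", idx)
                if n_new == 0:
                    break
            if cfg.backfit_overlaps:
                y_ch = _backfit_overlaps(y_ch, rec.fs, spikes, label, rc)
            corrected[ci] = y_ch
        self.spikes_ = spikes
        self.inventory_ = spikes_to_frame(spikes)
        self.n_candidates_ = n_cand
        self._fitted_on = (rec.n_times, rec.fs)
        # the published corrected signal is rebuilt through the same
        # reconstruction path as transform(), so that
        # corrected == input − sum(inventory atoms) holds bit-exactly
        # (backfitting would otherwise perturb the float summation order)
        self._corrected = self.transform(rec).samples
        return self

    def transform(self, rec: Recording) -> Recording:
        """Return ``rec`` minus the fitted atoms (conservation contract)."""
        if not hasattr(self, "spikes_"):
            raise RuntimeError("GaborSpikeRemover is not fitted")
        if (rec.n_times, rec.fs) != self._fitted_on:
            raise ValueError("recording shape/rate differs from the fit input")
        out = rec.samples.copy()
        for label in set(s.channel for s in self.spikes_):
            ci = rec.channel_index(label)
            out[ci] -= reconstruct_spike_signal(
                self.inventory_, rec.n_times, rec.fs, label)
        return replace(rec, samples=out)

    def fit_transform(self, rec: Recording, y=None) -> Recording:
        self.fit(rec)
        return replace(rec, samples=self._corrected)
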