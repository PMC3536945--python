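"""Sliding Hanning-windowed FFT amplitude analysis.

Windows are cut every 5 ms (default), tapered with a Hann window, and the
single-sided amplitude spectrum is coherent-gain normalised so that a
unit-amplitude on-bin sinusoid reads 1 μV, then divided by the bin width to
report amplitude densities in μV/Hz.  Window *centers* define the time
stamps, so a post-event interval selects windows whose centers fall inside
it.  Default window lengths are 512 samples at 2 kHz (256 ms) and 2,048
samples at 5 kHz (409.6 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .recording import BipolarDerivation

__all__ = [
    "TimeFrequencyMap",
    "default_window_samples",
    "sliding_fft_amplitude",
    "band_amplitude",
    "save_map",
    "load_map",
]


def default_window_samples(fs: float) -> int:
    """Analysis window length (samples) for a sampling rate.

    512 points at 2,000 Hz and 2,048 points at 5,000 Hz; other rates get the
    power of two whose duration is closest to 0.3 s.
    """
    if int(round(fs)) == 2000:
        return 512
    if int(round(fs)) == 5000:
        return 2048
    return int(2 ** np.round(np.log2(0.3 * fs)))


@dataclass
class TimeFrequencyMap:
    """Band-amplitude densities on a (time-step × frequency-bin) grid."""

    amplitudes: np.ndarray          # (n_times, n_freqs), μV/Hz
    times: np.ndarray               # window-center seconds
    freqs: np.ndarray               # Hz
    window_samples: int
    derivation: BipolarDerivation | None = None

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def sliding_fft_amplitude(
    signal: np.ndarray,
    fs: float,
    window_samples: int | None = None,
    step_s: float = 0.005,
    start_time: float = 0.0,
    derivation: BipolarDerivation | None = None,
) -> TimeFrequencyMap:
    """Compute a sliding-window amplitude-density map of a single signal.

    Parameters
    ----------
    signal : 1-D ndarray, μV
    fs : sampling rate, Hz
    window_samples : FFT window length; default per :func:`default_window_samples`
    step_s : window step in seconds (default 5 ms)
    start_time : time of ``signal[0]`` in seconds

    Returns
    -------
    TimeFrequencyMap
        ``amplitudes[i, j]`` is the amplitude density (μV/Hz) of window *i*
        at frequency ``freqs[j]``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if window_samples is None:
        window_samples = default_window_samples(fs)
    if window_samples > x.size:
        raise ValueError(
            f"window of {window_samples} samples longer than signal ({x.size})"
        )
    step = max(1, int(round(step_s * fs)))
    win = np.hanning(window_samples)
    segs = sliding_window_view(x, window_samples)[::step]
    spec = np.fft.rfft(segs * win, axis=1)
    # Coherent gain: a unit on-bin sinusoid reads 1 μV in its bin.
    amp = 2.0 * np.abs(spec) / win.sum()
    amp[:, 0] /= 2.0
    if window_samples % 2 == 0:
        amp[:, -1] /= 2.0
    bin_width = fs / window_samples
    freqs = np.fft.rfftfreq(window_samples, d=1.0 / fs)
    centers = start_time + (np.arange(segs.shape[0]) * step
                            + (window_samples - 1) / 2.0) / fs
    return TimeFrequencyMap(
        amplitudes=amp / bin_width,
        times=centers,
        freqs=freqs,
        window_samples=window_samples,
        derivation=derivation,
    )


def save_map(tfmap: TimeFrequencyMap, path: str) -> None:
    """Write a map as a plain-text matrix with a JSON sidecar.

    ``<path>`` holds the (time x frequency) amplitude matrix; ``<path>.json``
    holds times, freqs, window length and the derivation label.
    """
    import json

    np.savetxt(path, tfmap.amplitudes, fmt="%.8g", delimiter="\t")
    sidecar = {
        "times": tfmap.times.tolist(),
        "freqs": tfmap.freqs.tolist(),
        "window_samples": int(tfmap.window_samples),
        "derivation": str(tfmap.derivation) if tfmap.derivation else None,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_map(path: str) -> TimeFrequencyMap:
    """Read a map written by :func:`save_map`."""
    import json

    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    deriv = None
    if sidecar.get("derivation"):
        anode, cathode = sidecar["derivation"].split("-", 1)
        deriv = BipolarDerivation(anode, cathode)
    return TimeFrequencyMap(
        amplitudes=np.loadtxt(path, delimiter="\t", ndmin=2),
        times=np.asarray(sidecar["times"], dtype=float),
        freqs=np.asarray(sidecar["freqs"], dtype=float),
        window_samples=int(sidecar["window_samples"]),
        derivation=deriv,
    )


def band_amplitude(tfmap: TimeFrequencyMap, f_lo: float, f_hi: float) -> np.ndarray:
    """Mean amplitude density over ``f_lo <= f <= f_hi`` (inclusive), per step."""
    if f_lo > f_hi:
        raise ValueError("f_lo must not exceed f_hi")
    sel = (tfmap.freqs >= f_lo) & (tfmap.freqs <= f_hi)
    if not sel.any():
        raise ValueError(
            f"no frequency bins inside [{f_lo}, {f_hi}] Hz "
            f"(bin width {tfmap.bin_width:.3f} Hz)"
        )
    return tfmap.amplitudes[:, sel].mean(axis=1)
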