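"""Core data model: multichannel recordings, event series and bipolar derivations.

Conventions (enforced at construction):

* voltages are stored in microvolts (μV) throughout;
* ``samples`` is 2-D with channels as rows and time as columns;
* sample indexing is 0-based; event times are seconds and are converted to
  sample indices with banker's rounding (``round(t * fs)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EventSeries",
    "BipolarDerivation",
    "Epoch",
    "derive_bipolar",
    "segment_epochs",
]


@dataclass
class Recording:
    """A uniformly sampled multichannel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Voltages in μV.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        Unique 10–20-system channel names, one per row.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[np.newaxis, :]
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains NaN or Inf samples")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_times) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel label {label!r}; available: "
                f"{', '.join(self.channel_labels)}"
            ) from None

    def get_channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view (do not mutate)."""
        return self.samples[self.channel_index(label)]

    def copy(self) -> "Recording":
        return replace(self, samples=self.samples.copy())

    def sample_index(self, t: float) -> int:
        """Convert a time in seconds to a 0-based sample index (round-half-even)."""
        return int(round((t - self.start_time) * self.fs))


@dataclass
class EventSeries:
    """Strictly increasing event times (seconds) with a shared label."""

    times: np.ndarray
    label: str = "button_press"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValueError("event times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def validate_against(self, rec: Recording) -> None:
        lo, hi = rec.start_time, rec.start_time + rec.duration
        if self.times.size and (self.times[0] < lo or self.times[-1] > hi):
            raise ValueError(
                f"event times outside recording span [{lo:.3f}, {hi:.3f}] s"
            )


@dataclass(frozen=True)
class BipolarDerivation:
    """An anode-minus-cathode channel pair, e.g. C3–CZ."""

    anode: str
    cathode: str

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")

    def __str__(self) -> str:
        return f"{self.anode}-{self.cathode}"


@dataclass
class Epoch:
    """One event-locked segment with its sample-index provenance."""

    samples: np.ndarray      # (n_channels, n_epoch_times)
    event_time: float        # seconds
    start_index: int         # index of first sample in the parent recording
    stop_index: int          # exclusive


def derive_bipolar(rec: Recording, d: BipolarDerivation) -> np.ndarray:
    """Return the bipolar signal ``anode − cathode`` in μV, sample-aligned."""
    return rec.get_channel(d.anode) - rec.get_channel(d.cathode)


def segment_epochs(
    rec: Recording,
    events: EventSeries,
    pre_s: float,
    post_s: float,
) -> list[Epoch]:
    """Cut event-locked epochs of identical length from a recording.

    Each epoch spans ``[t − pre_s, t + post_s)`` around its event and has
    exactly ``round((pre_s + post_s) * fs)`` samples.  Events whose window
    would leave the recording are dropped with a logged warning.

    Raises
    ------
    ValueError
        If ``pre_s + post_s`` is not positive or no event yields a usable
        epoch.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    n_len = int(round((pre_s + post_s) * rec.fs))
    if n_len <= 0:
        raise ValueError("epoch length is zero: pre_s + post_s must be > 0")

    epochs: list[Epoch] = []
    n_dropped = 0
    for t in events.times:
        i0 = rec.sample_index(t - pre_s)
        i1 = i0 + n_len
        if i0 < 0 or i1 > rec.n_times:
            n_dropped += 1
            continue
        epochs.append(
            Epoch(
                samples=rec.samples[:, i0:i1],
                event_time=float(t),
                start_index=i0,
                stop_index=i1,
            )
        )
    if n_dropped:
        logger.warning(
            "dropped %d of %d events too close to the recording edges",
            n_dropped, len(events),
        )
    if not epochs:
        raise ValueError("no usable events: all epochs fall outside the recording")
    return epochs
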