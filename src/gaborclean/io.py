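"""Reading and writing recordings and event markers.

Two recording formats are supported:

* EDF/EDF+ (``.edf``), read through :mod:`mne`; physical dimensions are
  honoured and converted to μV.  Writing EDF is not supported.
* A delimited-text format (``.txt``/``.tsv``): one header line
  ``# gaborclean fs=<Hz> start=<s> channels=<a,b,...>`` followed by one row
  per sample, tab-separated, μV.

Event markers are EDF+ annotations or a two-column CSV ``time_s,label``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .recording import EventSeries, Recording

__all__ = ["read_recording", "write_recording", "read_events", "write_events"]

_HEADER_PREFIX = "# gaborclean"


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording in the delimited-text format."""
    header = "{} fs={!r} start={!r} channels={}".format(
        _HEADER_PREFIX.lstrip("# "), rec.fs, rec.start_time,
        ",".join(rec.channel_labels),
    )
    np.savetxt(path, rec.samples.T, fmt="%.8g", delimiter="\t",
               header=header, comments="# ")


def _read_text_recording(path: str | os.PathLike) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith(_HEADER_PREFIX):
        raise ValueError(
            f"{path}: missing '{_HEADER_PREFIX} ...' header line"
        )
    fields = dict(
        item.split("=", 1)
        for item in header[len(_HEADER_PREFIX):].split()
        if "=" in item
    )
    try:
        fs = float(fields["fs"])
        labels = fields["channels"].split(",")
    except KeyError as exc:
        raise ValueError(f"{path}: header lacks required field {exc}") from None
    start = float(fields.get("start", 0.0))
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return Recording(samples=data.T, fs=fs, channel_labels=labels,
                     start_time=start)


def _read_edf_recording(path: str | os.PathLike) -> Recording:
    try:
        import mne
    except ImportError:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the 'mne' package") from None
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=0.0,
    )


def read_recording(path: str | os.PathLike) -> Recording:
    """Read a recording from EDF/EDF+ or the delimited-text format."""
    if str(path).lower().endswith(".edf"):
        return _read_edf_recording(path)
    return _read_text_recording(path)


def read_events(path: str | os.PathLike, label: str | None = None) -> EventSeries:
    """Read event markers from a two-column CSV (``time_s,label``) or from
    EDF+ annotations (``.edf`` input).

    If *label* is given, only rows with that label are kept.
    """
    if str(path).lower().endswith(".edf"):
        return _read_edf_events(path, label)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    if "label" not in df.columns:
        df["label"] = "event"
    if label is not None:
        df = df[df["label"] == label]
        if df.empty:
            raise ValueError(f"{path}: no events labelled {label!r}")
    name = label if label is not None else str(df["label"].iloc[0])
    return EventSeries(times=np.sort(df["time_s"].to_numpy(float)), label=name)


def _read_edf_events(path: str | os.PathLike, label: str | None) -> EventSeries:
    try:
        import mne
    except ImportError:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF+ annotations requires 'mne'") from None
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    ann = raw.annotations
    times = np.asarray(ann.onset, dtype=float)
    descs = np.asarray(ann.description)
    if label is not None:
        times = times[descs == label]
        if times.size == 0:
            raise ValueError(f"{path}: no annotations labelled {label!r}")
    name = label if label is not None else (str(descs[0]) if descs.size
                                            else "event")
    return EventSeries(times=np.sort(times), label=name)


def write_events(events: EventSeries, path: str | os.PathLike) -> None:
    pd.DataFrame({"time_s": events.times, "label": events.label}).to_csv(
        path, index=False
    )
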