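"""File-based pipeline orchestration.

Runs the correction/analysis stages in the canonical order

    powerline -> smp -> emg -> tfr -> reject -> ers

over a recording on disk, writing each stage's artifacts as new files
(no stage mutates its input):

* ``<stem>.powerline.txt`` / ``.smp.txt`` / ``.emg.txt`` — corrected
  recordings in the delimited-text format;
* ``<stem>.spikes.csv`` — the Gabor-atom inventory;
* ``<stem>.mask.csv`` — the frozen epoch keep/reject mask;
* ``<stem>.ers.csv`` — per-trial baseline/peak band amplitudes and the
  within-subject test;
* ``<stem>.runlog.json`` — parameters, versions, seed and per-stage
  summary statistics.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ers import ers_test, trial_band_measures
from .gabor import DetectionConfig, GaborSpikeRemover
from .io import read_events, read_recording, write_recording
from .powerline import PowerlineCanceller
from .recording import BipolarDerivation, derive_bipolar
from .rejection import RejectionConfig, anomaly_reject, build_mask
from .smp import SMPCorrector
from .timefreq import band_amplitude, sliding_fft_amplitude

ALL_STAGES = ("powerline", "smp", "emg", "tfr", "reject", "ers")

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    """Flat, human-editable pipeline configuration.

    Defaults equal the standard analysis parameters: 7 μV detection
    threshold, rate-dependent d1/d3 gate, a=1.5 / b=0.06 / cap=0.4 μV/Hz
    rejection, 65–85 Hz gamma and 60–130 Hz rejection bands.
    """

    input: str = ""
    events: str = ""
    out_dir: str = "."
    stages: tuple[str, ...] = ALL_STAGES
    # powerline
    f0: float = 50.0
    n_harmonics: int | None = None
    noise_channel: str | None = None
    # smp
    left_ref: str = "SMPL"
    right_ref: str = "SMPR"
    # emg
    v_thresh: float = 7.0
    corr_thresh: float | None = None
    hp_cutoff: float = 10.0
    search_ms: float = 5.0
    extra_hf: bool | None = None
    # analysis
    anode: str = "C3"
    cathode: str = "CZ"
    gamma_band: tuple[float, float] = (65.0, 85.0)
    mask_band: tuple[float, float] = (60.0, 130.0)
    reject_a: float = 1.5
    reject_b: float = 0.06
    reject_cap: float = 0.4
    peak_window: tuple[float, float] = (0.0, 0.25)
    baseline_s: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "gamma_band", "mask_band", "peak_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run log (also on disk)."""
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    rec = read_recording(config.input)
    events = read_events(config.events) if config.events else None
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = out_dir / Path(config.input).stem
    log: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "artifacts": [],
    }

    def record(name: str, path: Path, **stats) -> None:
        log["stages"][name] = {k: v for k, v in stats.items()}
        if path is not None:
            log["artifacts"].append(str(path))

    current = rec
    stage = "setup"
    try:
        stage = "powerline"
        if "powerline" in config.stages:
            model = PowerlineCanceller(
                f0=config.f0, n_harmonics=config.n_harmonics,
                noise_channel=config.noise_channel)
            current = model.fit_transform(current)
            path = stem.with_suffix(".powerline.txt")
            write_recording(current, path)
            record("powerline", path,
                   n_harmonics=int(model.weights_.shape[-1] // 2),
                   max_weight=float(np.abs(model.weights_).max()))
        stage = "smp"
        if "smp" in config.stages:
            model = SMPCorrector(left_ref=config.left_ref,
                                 right_ref=config.right_ref)
            current = model.fit_transform(current)
            path = stem.with_suffix(".smp.txt")
            write_recording(current, path)
            record("smp", path,
                   max_weight=float(np.abs(model.weights_).max()))
        pre_emg = current
        stage = "emg"
        if "emg" in config.stages:
            eeg_channels = [c for c in current.channel_labels
                            if c not in (config.left_ref, config.right_ref)]
            remover = GaborSpikeRemover(config=DetectionConfig(
                v_thresh=config.v_thresh, corr_thresh=config.corr_thresh,
                hp_cutoff=config.hp_cutoff, search_ms=config.search_ms,
                extra_hf=config.extra_hf), channels=eeg_channels)
            current = remover.fit_transform(current)
            path = stem.with_suffix(".emg.txt")
            write_recording(current, path)
            inv_path = stem.with_suffix(".spikes.csv")
            _write_csv(remover.inventory_, inv_path)
            log["artifacts"].append(str(inv_path))
            record("emg", path, n_atoms=len(remover.spikes_),
                   n_candidates=int(remover.n_candidates_))

        stage = "tfr"
        needs_tfr = {"tfr", "reject", "ers"} & set(config.stages)
        if needs_tfr:
            deriv = BipolarDerivation(config.anode, config.cathode)
            tf_pre = sliding_fft_amplitude(
                derive_bipolar(pre_emg, deriv), rec.fs, derivation=deriv)
            tf_post = sliding_fft_amplitude(
                derive_bipolar(current, deriv), rec.fs, derivation=deriv)
            record("tfr", None, n_windows=int(tf_post.times.size),
                   window_samples=int(tf_post.window_samples))

        mask = None
        stage = "reject"
        if "reject" in config.stages:
            if events is None:
                raise ValueError("the reject stage requires an events file")
            wide = band_amplitude(tf_pre, *config.mask_band)
            meas = trial_band_measures(wide, tf_pre.times, events.times,
                                       config.peak_window, config.baseline_s)
            stat = np.nan_to_num(
                (meas["baseline"].fillna(0.0) + meas["peak"].fillna(0.0))
                .to_numpy(float) / 2.0)
            cfg_rej = RejectionConfig(a=config.reject_a, b=config.reject_b,
                                      cap=config.reject_cap)
            mask = build_mask(stat, cfg_rej)
            gam_post = band_amplitude(tf_post, *config.gamma_band)
            meas_post = trial_band_measures(gam_post, tf_post.times,
                                            events.times, config.peak_window,
                                            config.baseline_s)
            mask = anomaly_reject(
                np.nan_to_num(meas_post["peak_max"].to_numpy(float)),
                mask, cfg_rej)
            path = stem.with_suffix(".mask.csv")
            _write_csv(mask.to_frame(), path)
            record("reject", path, n_kept=mask.n_kept,
                   threshold=mask.threshold_used)

        stage = "ers"
        if "ers" in config.stages:
            if events is None:
                raise ValueError("the ers stage requires an events file")
            gam = band_amplitude(tf_post, *config.gamma_band)
            meas = trial_band_measures(gam, tf_post.times, events.times,
                                       config.peak_window, config.baseline_s)
            keep = meas["usable"].to_numpy(bool)
            if mask is not None:
                keep &= mask.keep
            res = ers_test(meas["baseline"].to_numpy(float)[keep],
                           meas["peak"].to_numpy(float)[keep])
            out = meas.copy()
            out["kept"] = keep
            path = stem.with_suffix(".ers.csv")
            _write_csv(out, path)
            record("ers", path, t=res.t, p=res.p,
                   mean_baseline=res.mean_baseline, mean_peak=res.mean_peak)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_path = stem.with_suffix(".runlog.json")
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=1)
    log["artifacts"].append(str(log_path))
    return log
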