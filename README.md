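# gaborclean

Tonic scalp and neck muscle activity contaminates the gamma band
(> 30 Hz) of the scalp EEG so severely that most apparent "EEG gamma" can
be myogenic.  Spatial source separation (ICA/CCA) fails for this artifact:
each tonically active muscle fibre group is a separate, spatially local
source with the same spatial frequency content as EEG.  In the *time*
domain, however, individual muscle spikes have a stereotyped waveform that
is well modelled by a **Gabor atom** — a sine wave modulated by a Gaussian:

```
g(t) = A · sin(2πf (t − t0) + φ) · exp(−(t − t0)² / (2σ²))
```

`gaborclean` detects individual muscle spikes, fits Gabor atoms to them
and subtracts the fitted waveforms, leaving neural oscillations intact.
It implements the surrounding analysis chain for self-paced-movement
gamma studies, for EEG researchers who need high-gamma (65–85 Hz) band
measures from scalp recordings sampled at 2–5 kHz:

* **Power-line cancellation** — the mains fundamental is band-passed from
  a noise reference, its quadrature partner taken from the analytic
  signal, harmonics built by the angle-addition recursion
  `sin((k+1)θ) = sin(kθ)cos(θ) + cos(kθ)sin(θ)`, and the basis regressed
  out of every channel.
* **Saccade-muscle-potential (SMP) correction** — regression of each EEG
  channel on left/right eye-corner reference electrodes.
* **EMG Gabor-spike reduction** (the core) — detection of sharp potential
  changes over 3.5 ms, localisation of the Gaussian center by the
  inverse correlation of the first and third discrete differentials,
  spread estimation from a gradient-ratio lookup table, 0.01 ms center
  refinement, quadrature least-squares amplitude/phase fitting, and
  in-place subtraction.  The inventory of fitted atoms fully explains the
  correction: `corrected == input − Σ atoms`, bit-exactly.
* **Time–frequency analysis** — sliding Hanning-windowed FFT amplitudes
  every 5 ms (512-point windows at 2 kHz, 2,048-point at 5 kHz).
* **Adaptive epoch rejection** — per-subject threshold
  `min(1.5 · mean(60–130 Hz amplitude) + 0.06, 0.4) μV/Hz`, at most 30 of
  70 trials rejected, plus a 6 SD anomaly rule; the mask is frozen once
  and shared by all correction conditions.
* **Event-related synchronisation (ERS) statistics** — baseline vs
  post-press 65–85 Hz amplitudes, paired one-tailed tests within and
  across subjects, and Z-score topographies over bipolar derivations.
* **Synthetic EEG generator** — seeded, ground-truth-labelled recordings
  (1/f background, sawtooth-like mu rhythm, wandering mains, Poisson
  Gabor spikes, event-locked 75 Hz / 0.05 μV gamma bursts, biphasic SMP
  waveforms) so every stage is testable without human data.

## Worked example

```python
import numpy as np
from gaborclean import (SimulationSpec, simulate, PowerlineCanceller,
                        SMPCorrector, GaborSpikeRemover, score_correction)

spec = SimulationSpec(n_events=20, seed=3)        # ~34 s of 4-channel EEG
rec, truth = simulate(spec)

rec_pl = PowerlineCanceller().fit_transform(rec)
rec_smp = SMPCorrector().fit_transform(rec_pl)

remover = GaborSpikeRemover(channels=["C3", "CZ"])
clean = remover.fit_transform(rec_smp)
print(f"{len(remover.spikes_)} atoms fitted "
      f"({len(truth.spikes)} spikes injected)")

metrics = score_correction(truth, clean, rec_smp)
print(f"residual spike energy: {metrics['residual_spike_energy']:.1%}")
print(f"65-85 Hz amplitude reduction at C3: "
      f"{metrics['per_channel']['C3']['band_reduction'][(65.0, 85.0)]:.1%}")
print(f"gamma-burst recovery: {metrics['burst_recovery_median']:.3f}")
```

prints (seed 3):

```
375 atoms fitted (338 spikes injected)
residual spike energy: 0.7%
65-85 Hz amplitude reduction at C3: 78.7%
gamma-burst recovery: 0.998
```

The 338 injected spikes carried most of the 65–85 Hz band amplitude above
the 0.35 μV neural floor; after subtraction only 0.7% of their energy
remains, while the event-locked 0.05 μV gamma burst — four hundred times
weaker than a typical spike — is recovered to 0.2%.

A command-line interface wraps the same stages:

```bash
gaborclean simulate --seed 5 --out rec.txt
gaborclean run --input rec.txt --events rec.txt.events.csv --out-dir out
gaborclean clean-emg rec.txt --v-thresh 7 --out clean.txt --inventory atoms.csv
```

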