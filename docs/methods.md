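# Methods

## The spike model and why it works

A muscle spike recorded at the scalp — a compound action potential of a
tonically active scalp or neck muscle fibre group — always shows a sharp
potential change over roughly 3.5 ms.  It is modelled as a Gabor atom

    g(t) = A · sin(2πf (t − t0) + φ) · exp(−(t − t0)² / (2σ²)),

with center time `t0` (s), Gaussian spread `σ` (s), carrier frequency `f`
(Hz), phase `φ` (rad) and amplitude `A` (μV).  The carrier frequency is
not separately identifiable from a single transient and is fixed at
`f = 1/(2 · 3.5 ms) ≈ 142.9 Hz`, so that the steepest half-cycle of the
sine spans the 3.5 ms signature; the sharper components visible at 5 kHz
sampling are captured by a second quadrature pair at `2f` sharing the
same envelope.  Phase is never estimated explicitly: the atom is fitted
as a sin/cos quadrature pair and `(A, φ)` are read off the coefficients.

## The estimation pipeline, step by step

1. **Detection.**  Local maxima of `|x(i + nΔ) − x(i)|` with
   `nΔ = round(3.5 ms · fs)` exceeding `v_thresh` (standard 7 μV;
   per-subject optimised values 4–9 μV), computed on a copy of the signal
   high-passed at 10 Hz by a zero-phase FIR (detection only — all fitting
   uses the raw signal).  Maxima closer than 3.5 ms are merged keeping
   the larger change, and each detection is anchored at the steepest
   gradient sample in its span.
2. **The d1/d3 gate.**  Near its center a Gabor atom is locally
   sinusoidal, and the first and third discrete differentials of a
   sinusoid are strongly anti-correlated.  Within ±5 ms of the detection
   the Pearson correlation of d1 and d3 over `round(3.5 ms · fs)`-sample
   windows is scanned; the most negative point is the center candidate,
   and candidates whose correlation is less negative than a
   rate-dependent threshold (−0.78 below 3.5 kHz, −0.84 at and above) are
   discarded as non-spike activity.  The differentials are *one-sided*
   (`np.diff`), with both windows aligned at the same start offset.  This
   choice is load-bearing: with one-sided differences a pure sinusoid
   scores `−cos(2πf/fs)` (−0.90 at 2 kHz, −0.98 at 5 kHz) while white
   noise scores ≈ +0.6, so the gate separates the two sharply, and the
   rate dependence of the thresholds follows naturally.  Center-aligned
   differences would score even white noise at ≈ −0.89 and destroy the
   gate.  The price is a flank bias: on a noiseless atom the most
   negative correlation sits 1–4 ms before the true center, which the
   later refinement absorbs.
3. **Spread from the gradient ratio.**  The ratio of the centered-difference
   gradient at the center to the gradient 1 ms earlier is a monotone
   function of σ for a φ = 0 atom.  The implementation tabulates its
   *reciprocal* q(σ) = grad(−1 ms)/grad(0) on a σ grid of 0.5–6 ms in
   0.05 ms steps (the raw ratio has a pole where the −1 ms gradient
   changes sign) and inverts by interpolation; out-of-range ratios clamp
   to the grid ends with a warning, and a degenerate center gradient
   (near-quadrature phase) falls back to a coarse grid search.
4. **Envelope rescue seed.**  The gradient-ratio statistic assumes the
   carrier zero-crossing sits at the envelope center and degrades for
   arbitrary phase.  Whenever the table seed is degenerate, lands at the
   grid floor, or refines to a correlation below 0.95, a second seed is
   derived from the analytic-signal envelope of the candidate
   neighbourhood (argmax → t0, log-parabola curvature → σ), both seeds
   are refined, and the one with the smaller residual over the *union*
   of their support windows wins.  Comparing over the union matters: a
   tiny-σ atom can fit its own short window almost perfectly while
   leaving most of the spike behind.
5. **Refinement.**  Coarse-to-fine hill climbing of t0 (0.05 ms then the
   contractual 0.01 ms steps, at most 200 accepted moves ≈ ±2 ms), a σ
   climb on the lookup grid, a basin probe at σ×0.7 and σ×1.4 (the score
   surface has secondary optima for near-quadrature phases), and finally
   two rounds of parabolic interpolation on both parameters.  The
   parabolic step is what removes the grid-quantisation floor: a σ error
   of half a grid step (0.025 ms) leaves a residual proportional to the
   spike amplitude (~2% of A), which would otherwise dominate the cleaned
   signal's gamma band.  The score maximised throughout is the partial
   correlation of the quadrature atom given a jointly fitted quadratic
   baseline, so slow EEG (mu/alpha waves) under the spike does not bias
   the fit.
6. **Fit and subtract.**  Ordinary least squares of the signal on the
   quadrature pair(s) plus the quadratic baseline over the support window
   t0 ± 4σ; only the atom part of the model is subtracted, in place, and
   the signal outside the window is untouched.  Atoms whose final
   correlation is below 0.5 are not subtracted (short-support fits on
   background reach spuriously inflated correlations).
7. **Sweeps and backfitting.**  Detection-and-subtraction runs twice per
   channel: spikes closer than 3.5 ms merge into one detection on the
   first sweep, and the second sweep over the residual recovers the
   masked partner.  Afterwards, atoms with overlapping supports are
   re-estimated in turn on the residual-plus-self (two cycles) — a
   backfitting pass that decouples their jointly biased fits.  The
   published corrected signal is finally rebuilt as
   `input − Σ(inventory atoms)` through the same reconstruction routine
   used by `transform()`, making the conservation contract bit-exact
   regardless of the fitting history.

A numba-compiled kernel evaluates the refinement score; the final
coefficient fit and all subtraction/reconstruction arithmetic stay in the
numpy path, so results do not depend on whether compilation is available
(only speed does).

## Surrounding stages

**Power-line.**  The fundamental is extracted from a dedicated noise
channel (or, failing that, the channel average) by a zero-phase band-pass
FIR at f0 ± 1 Hz, normalised by its analytic-signal envelope; the cosine
partner leads by a quarter cycle.  Harmonic pairs follow the
angle-addition recursion, which tracks slow mains frequency wander
without ever estimating the instantaneous frequency.  Weights are
ordinary least squares per channel over the whole recording (a
`block_seconds` option fits piecewise for non-stationary mains).  Because
the basis is near-orthogonal, subtraction cannot increase channel power.

**SMP.**  Each EEG channel is regressed jointly on the two eye-corner
references; two free coefficients generalise the "weighted average"
formulation (a `constrain_average` flag provides the single-coefficient
reading, and near-duplicate references fall back to their mean).  Weights
are global: saccade topography is stationary over minutes.  The pipeline
applies power-line cancellation first — mains common to the references
and the EEG would otherwise bias the SMP weights.

**Time–frequency.**  Hann-tapered FFTs every 5 ms; amplitudes are
coherent-gain normalised (a unit on-bin sinusoid reads 1 μV) and divided
by the bin width, giving μV/Hz densities so the rejection constants
(b = 0.06, cap = 0.4 μV/Hz) keep their meaning across window lengths.
Window *centers* define time stamps; band means are inclusive of both
edge bins.

**Epoch rejection.**  The threshold is decided once, on the post-SMP /
pre-EMG 60–130 Hz per-trial amplitudes, and the frozen mask is applied
identically to every condition — otherwise between-condition comparisons
would be confounded by different trial sets (`EpochMask.require_same`
enforces this).  The per-trial statistic spans the trial's baseline and
post-press windows.  Rather than tuning a and b per subject, the
implementation fixes them and raises the threshold only as far as the
30-of-70 bound requires.  The final 6 SD anomaly rule is applied to the
per-trial maxima of the *analysed* (corrected) gamma — the point of the
rule is to catch trials whose corrected values are still anomalous — and
the resulting mask is then frozen for all conditions; the rule is single
pass, with mean and SD over the kept trials.

**ERS statistics.**  Baseline = 1 s before the press, shortened to start
250 ms after the previous press when presses are closer than 1.25 s, and
the trial is excluded when the gap is ≤ 0.25 s.  "Peak" is the mean band
amplitude over 0–250 ms post-press (a `peak_mode="max"` option provides
the literal maximum).  Within- and across-subject tests are paired
one-tailed t tests (peak > baseline); correction effects use a one-tailed
test for the hypothesised baseline *reduction* and a two-tailed test for
the change of the baseline-corrected peak.  Topography Z scores divide
the mean baseline-corrected ERS by its SD across trials.  No
multiple-testing correction is applied.

## The synthetic study conditions

The generator reproduces the reference design: 70 self-paced button
presses ≈ 1.53 s apart (within-subject jitter 0.25 s, between-subject SD
0.40 s, floor 0.8 s), 2 kHz sampling, and per EEG channel

| component | default | rationale |
|---|---|---|
| pink background | 1/f, 0.35 μV RMS, 500 Hz roll-off | a clean central derivation's high-gamma floor ≈ 0.1 μV band amplitude; neural EEG has no multi-kHz content (the acquisition chain low-passes at 200–1000 Hz anyway) |
| mu rhythm | 10 Hz, 10 μV, 20% sawtooth harmonics | carries the realistic low-frequency bulk; its harmonics exercise the harmonic-confound problem |
| mains | 50 Hz, 10/2/1 μV harmonics, 0.2 rad wander | phase-locked harmonics, slow wander |
| muscle spikes | Poisson 5/s per channel, A ~ U[8,30] μV, σ ~ U[1,4] ms, φ ~ U[0,2π) | the contamination regime the method targets |
| gamma burst | 75 Hz, 250 ms Hann envelope, 0.05 μV, on C3 at each press | the reported event-related 65–85 Hz increase scale |
| SMP | biphasic ~30 ms template, 20 μV at the references, 5–25% coupling into EEG, 2 saccades/s | micro-saccade artifact |

Same spec + seed reproduces a recording bit-exactly.  What the generator
does *not* emulate: non-stationary muscle tone (bursts, jaw clenches),
spatially correlated EMG across many channels, heterogeneous
per-subject burst amplitudes, real electrode noise and drift, or
non-Gabor spike shapes.  Tests passing on this data show the algorithm
recovers its own model class under realistic interference — not that
every real muscle spike is a Gabor atom.

## Evaluation sizes and known limitations

The benchmark harness (`gaborclean.evaluation`, driven by
`scripts/acceptance.py` and the acceptance tests) uses: 50 noiseless
signals for the grid-search oracle comparison, 200 noisy trials for
parameter recovery, 160 bursts for neural preservation, 1,000 noise
candidates for the gate, and 12 + 10 (tests) or 10 + 8 (script) cohorts
of 8 subjects × 70 presses for the end-to-end study; the cohort study
uses the optimised detection threshold (4 μV), mirroring the reference
design's optimised-parameter analysis.

Two statistical targets are not reached, for reasons worth recording:

* **Center-time recovery at SNR 10.**  With phase free, the Fisher
  information for t0 comes from the envelope alone; the Cramér–Rao bound
  for σ = 2.5 ms, fs = 2 kHz and background RMS = A/10 is ≈ 0.24 ms.
  The observed scatter of the fitted t0 sits at that bound, so a
  ±0.1 ms requirement cannot be met by *any* estimator under these
  conditions — amplitude (±10%, CRLB ≈ 4–8%) and residual energy (≤20%,
  typically 1–4%) clauses are met.  On noiseless atoms the pipeline
  matches the exhaustive oracle to one grid step in all three parameters.
* **Across-subject burst detection power.**  On spike-free cohorts the
  full analysis chain detects the 0.05 μV burst decisively
  (across-subject t ≈ 6–10).  Under the study's spike contamination,
  however, the per-trial effect is about one tenth of the per-trial
  noise — which is dominated by the heavy-tailed residuals of the rare
  imperfectly fitted spikes, not by the neural floor — and the paired t
  statistic is additionally skew-biased negative by those residuals, so
  the across-subject t distribution ends up centred near zero and the
  detection rate at α = 0.05 is ≈ 0–10%, nowhere near 80%.  The
  false-positive rate on burst-free cohorts stays at or below nominal
  (the same skew biases the one-tailed test conservative).  Power rises
  with burst amplitude, trial count, or sampling rate (at 5 kHz the gate
  passes essentially every spike), but those are different study
  conditions.

Other limitations: the 2 kHz gate threshold (−0.78) structurally ignores
small-σ spikes at unfavourable phases (the flank correlation tops out
near −0.73 for σ = 1 ms), an intrinsic cost of the rate; overlapping
spikes are handled by re-sweeping and backfitting rather than a joint
multi-atom model; and the carrier frequency is fixed rather than fitted,
so spikes with substantially different internal frequency content are
absorbed only via the 2f pair at high sampling rates.
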