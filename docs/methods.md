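# Methods

## Scope and model

`phasepower` implements a single-channel, single-trial analysis of
stimulus-locked EEG: how the phase and power of ongoing band-limited
oscillations immediately before a stimulus relate to the rectified area
under the curve (AUC) of the post-stimulus waveform, and how to isolate
the stimulus-specific part of any power dependence from the continuation
of ongoing dynamics. The pipeline is deterministic given a seed, the
unit of statistical analysis is the dataset, and all group tests are
classical paired / one-sample t-tests with Bonferroni adjustment (no
hierarchical modeling; datasets are treated as independent).

The corrected effect assumes **additivity**: the recorded trial is
ongoing activity plus an evoked waveform, and the power dependence of
the control-window AUC estimates the continuation component that also
contaminates the post-stimulus window. Rectification makes the AUC a
nonlinear functional, so additivity holds only to first order — see
*Known limitations*.

## Synthetic generator

Each trial is

```
x(t) = Σ_b A_b · Re z_b(t)  +  n(t)  +  g · k(t)·1[t ≥ 0],
```

* `z_b` — unit-RMS complex **analytic** narrowband Gaussian noise,
  synthesized in the frequency domain with support exactly on the band
  `[lo, hi]`. Because the trace is its own analytic signal, the exact
  instantaneous phase and envelope are available as ground truth.
* `A_b = rms_b · exp(σ·z)` — per-epoch amplitude: drawn once per trial
  (log-normal across trials, constant within the epoch), which realizes
  the premise that oscillatory power at time 0 predicts amplitude at
  time +t. The standardized draw `z` is truncated at ±1.5 SD so the
  linear evoked-gain model below is well-posed for gains up to the
  values used in the recovery study.
* `n(t)` — 1/f^1 Gaussian background (flat below 1 Hz), RMS 4 µV.
* `k(t)` — evoked kernel: two onset-delayed damped sinusoids (periods
  40 and 15 ms, onsets 18 ms, decay constants 35 and 25 ms), rescaled to
  a 5 µV absolute peak that falls inside 25–80 ms and decays to a few
  percent by 150 ms.
* `g = 1 + γ·z_int + κ·cos φ_int` — evoked gain, modulated by the
  interaction band's standardized amplitude draw and/or its oscillator
  phase at t = 0 (defaults γ = κ = 0, interaction band alpha). Configs
  whose worst case over |z| ≤ 1.5 makes `g` negative are rejected.
* A 500 µV decaying-exponential artifact overwrites samples strictly
  inside (−2, 20) ms, so the excision stage has something real to
  remove; the boundary samples stay clean because they serve as the
  excision's interpolation anchors.

Defaults: band RMS 4/6/3 µV (theta/alpha/beta, alpha-dominant as in
eyes-open frontal EEG; total ongoing RMS ≈ 11 µV), σ = 0.85 (roughly a
ten-fold across-trial range of band power, enough for the per-epoch
amplitude to dominate short-window power estimates), 100 trials per
dataset, epochs at 1 kHz.

**Epoch span.** Epochs default to −2200..+1000 ms rather than ±1 s: the
control condition reads phase at −1000 ms and needs up to 1000 ms of
power window plus an estimator window *before* that time, which only
continuous or longer-epoch data can supply. The stimulus-locked
analysis itself uses only −1000..+1000 ms.

**Evoked-kernel scale.** The 5 µV single-trial peak (≈ 0.5× ongoing
RMS) is realistic for single-trial stimulation responses, which are not
visible above ongoing EEG without averaging. It is also the regime in
which the corrected effect's additivity premise holds: when the kernel
dominates the window, `|x + k| ≈ |k|` and the AUC loses its sensitivity
to ongoing power, biasing the corrected effect negative under the null.
At the default scale this rectification bias is a few µV·ms — small
against the per-dataset sampling SD (~60 µV·ms) — and the null
rejection rate of the one-sample test is nominal.

**What the generator does not emulate:** volume conduction and
multi-channel structure, non-stationary drift across the session,
muscle/ocular artifacts, line noise, auditory/somatosensory
co-activation, and any cross-frequency coupling. Passing tests
therefore validate the *statistical machinery* under the stated
generative assumptions, not robustness to real-world recording
pathology.

## Preprocessing

Fixed order excise → baseline → downsample. Excision replaces samples
strictly inside the artifact span with the line joining the nearest
retained samples (idempotent; samples exactly at −2 and 20 ms are
anchors). Baseline subtracts each trial's mean over −500..−200 ms.
Downsampling requires an integer rate ratio and uses a zero-phase FIR
anti-alias decimator, keeping every q-th sample from the first (so the
t = 0 grid point is preserved).

## Phase estimation

The forward-prediction estimator uses only causal data (window ending
at −4 ms for the stimulus condition; the control readout at −1000 ms
mirrors the same 4 ms margin): demean; zero-phase forward–backward FIR
band-pass (Hamming-windowed, `filter_order + 1` taps); trim `edge_ms`
from both ends; fit Yule–Walker AR coefficients (biased/MLE
autocovariance, as in standard AR toolboxes); iterate the recursion
forward so the target sits half a Hilbert window before the end of the
extrapolated segment; read the analytic-signal angle at the target
sample. Convention: degrees in [0, 360), 0° at the positive peak,
increasing in time. Diverging predictions yield NaN in the batched API
(trial flagged for exclusion) and an exception in the scalar API.

Per-band defaults (filter order / window / edge / AR order / Hilbert
window): theta 320/1000 ms/140 ms/30/256; alpha 192/718 ms/65 ms/25/128;
beta 100/500 ms/30 ms/15/64. `optimize_params` grid-searches these
against the non-causal Hilbert oracle at a training time of −1000 ms,
breaking ties toward smaller AR order, then smaller filter order.

Error metric: circular SD `sqrt(−2 ln R̄)` of wrapped pairwise
differences; `R̄ = 0` returns infinity. On noiseless in-band sinusoids
the forecast agrees with the oracle within ~8° circular SD; on
broadband stochastic rhythms the intrinsic predictability limit
dominates (tens of degrees), shrinking with oscillation SNR.

## Spectral features

Welch power uses segments of half the band's window with 50% overlap
and a Hann taper, constant-detrended, integrated over the band on the
DFT grid (rectangle rule); a unit in-band sinusoid yields ≈ 0.5 µV².
Median split: below-median → low, above → high; trials exactly at the
median alternate into whichever group is smaller (low first), keeping
the halves within one trial of each other. The mean-power threshold
retains trials *strictly* above the dataset-band mean; with
right-skewed power distributions this keeps fewer than half the trials.

## Trial metrics and group statistics

AUC is the trapezoidal integral of |x| over the inclusive window
(µV·ms). Phase bins are inclusive 60° intervals centered at
0/90/180/270°; phases between bins carry no label, and "random" is the
full trial set, so labeled-bin counts sum to less than the total.
Normalized AUC = bin mean − all-trials mean, per dataset; empty bins
propagate NaN and drop that dataset from the affected contrast only.
Zero-variance test inputs are flagged degenerate (t = 0, p = 1 when the
mean matches the null; infinite t, p = 0 otherwise) rather than raising.

## Problem sizes

The replication studies use cohorts of 16 datasets × 100 trials:
100 trials matches the per-dataset design the pipeline targets, and 16
datasets give the one-sample corrected-effect test enough precision for
its calibration to be measured over 200 replicate cohorts, which is the
scale the validation suite runs at. The recovery study sweeps
γ ∈ {0, 0.3, 0.6} under common random numbers, so the monotone trend in
the group-mean corrected effect is read pathwise rather than against
independent sampling noise.

## Known limitations

* **Rectification bias.** The corrected effect is exactly unbiased only
  for a linear response functional; with rectified AUC the bias grows
  with the kernel-to-background ratio (negative under the null). At the
  default scale it is negligible, but configurations with a dominant
  evoked response should interpret small corrected effects cautiously.
* **Second-order sensitivity to γ.** When the kernel is below the
  ongoing RMS, a multiplicative gain enters the AUC only quadratically,
  so moderate γ produces corrected-effect means of a few µV·ms —
  detectable as a monotone trend under common random numbers, but not
  individually significant in small cohorts.
* Phase-bin occupancies are not uniform: the estimator's errors are
  phase-dependent on stochastic rhythms, enriching some bins. The
  analysis treats bins per dataset, so this affects power, not
  validity.
* The median split uses measured (noisy) power, so the low/high labels
  misclassify trials near the median; all power effects are therefore
  attenuated relative to a split on true amplitude.
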