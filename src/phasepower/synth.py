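"""Synthetic epoched EEG with known oscillatory ground truth.

The generator emulates a single-channel stimulation experiment: ongoing
activity is a sum of band-limited stochastic oscillators (theta, alpha,
beta) over a 1/f background; a stimulus artifact overwrites a short
peri-stimulus segment; and an evoked response with compact support in the
25-80 ms window is added at t >= 0.  Two properties of real EEG that drive
the downstream analysis are built in deliberately:

* **Power continuation** - each band oscillator's amplitude is drawn once
  per epoch (log-normal across trials, constant within the epoch), so
  pre-stimulus band power predicts post-stimulus signal amplitude even in
  the absence of any stimulus interaction.  This is the confound the
  corrected-effect statistic is designed to remove.
* **State-dependent evoked gain** - the evoked kernel's amplitude may be
  modulated linearly by the standardized pre-stimulus power (``gamma``)
  and/or by the cosine of the pre-stimulus oscillator phase (``kappa``) of
  a chosen interaction band, providing known effect sizes for recovery
  tests.

Oscillators are synthesized directly in the frequency domain as one-sided
(analytic) Gaussian processes, so the exact instantaneous phase and
envelope of every clean oscillator trace are available as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BandSpec, get_band
from .epochs import EpochSet, TrialTruth

__all__ = ["EvokedKernel", "GenConfig", "generate_dataset", "generate_cohort", "truth_phase"]


@dataclass(frozen=True)
class EvokedKernel:
    """Evoked-response waveform: a sum of onset-delayed damped sinusoids.

    Each component is ``weight * sin(2*pi*(t-onset)/period) *
    exp(-(t-onset)/tau)`` for ``t >= onset``; the sum is rescaled so its
    absolute peak equals ``peak_uv``.  The defaults place the main
    deflection near 27 ms, keep most of the energy inside 25-80 ms, and
    decay to a few percent by 150 ms.
    """

    peak_uv: float = 5.0
    components: tuple[tuple[float, float, float, float], ...] = (
        # (period_ms, tau_ms, onset_ms, weight)
        (40.0, 35.0, 18.0, 1.0),
        (15.0, 25.0, 18.0, -0.5),
    )

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        """Evaluate the kernel (zero before every onset) on ``times_ms``."""
        t = np.asarray(times_ms, dtype=float)
        k = np.zeros_like(t)
        for period, tau, onset, weight in self.components:
            tt = t - onset
            active = tt >= 0
            k[active] += weight * np.sin(2 * np.pi * tt[active] / period) * np.exp(-tt[active] / tau)
        peak = np.max(np.abs(k)) if np.any(k) else 0.0
        if peak > 0 and self.peak_uv > 0:
            k *= self.peak_uv / peak
        elif self.peak_uv == 0:
            k[:] = 0.0
        return k


def _default_band_amplitudes() -> dict[str, float]:
    # RMS in microvolts of each band oscillator at unit amplitude draw;
    # alpha dominant, as in eyes-open resting frontal EEG.
    return {"theta": 4.0, "alpha": 6.0, "beta": 3.0}


@dataclass
class GenConfig:
    """Configuration of the synthetic-EEG generator.

    Parameters
    ----------
    n_datasets, n_trials : int
        Cohort geometry; defaults mirror a 64-dataset, 100-pulse design.
    fs : float
        Sampling rate in Hz.
    epoch_span : (float, float)
        Epoch limits in ms around the stimulus.  The default extends to
        -2200 ms so that the control-condition analysis (phase at
        -1000 ms, power over up to 1000 ms before it) has data to work
        with; the stimulus-locked analysis uses only -1000..+1000 ms.
    band_amplitudes : dict
        Per-band oscillator RMS amplitude (microvolts) at unit draw.
    sigma_log_amp : float
        Log-SD of the per-epoch amplitude multiplier ``exp(sigma * z)``.
        The default gives roughly a 10-fold across-trial range of band
        power, the regime in which pre-stimulus power is a strong
        predictor of post-window amplitude.
    z_truncation : float
        The standardized amplitude draw ``z`` is truncated at this many
        SDs so the linear evoked-gain model stays well-posed.
    noise_exponent, noise_scale : float
        1/f^exponent background slope and its RMS in microvolts.
    evoked_kernel : EvokedKernel
        Stimulus-evoked waveform added at t >= 0.
    artifact_span : (float, float)
        Interval (ms) overwritten by a large stimulus-artifact transient.
    gain_power_interaction : float
        ``gamma``: evoked amplitude is scaled by ``1 + gamma * z_power``
        with ``z_power`` the interaction band's standardized (truncated)
        log-amplitude.
    gain_phase_interaction : float
        ``kappa``: additional modulation by ``cos(phase)`` of the
        interaction band's oscillator at t = 0.
    interaction_band : str
        Band whose state drives the gain modulation.
    seed : int
        Base seed; dataset ``i`` uses an independent child stream.
    """

    n_datasets: int = 64
    n_trials: int = 100
    fs: float = 1000.0
    epoch_span: tuple[float, float] = (-2200.0, 1000.0)
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    sigma_log_amp: float = 0.85
    z_truncation: float = 1.5
    noise_exponent: float = 1.0
    noise_scale: float = 4.0
    evoked_kernel: EvokedKernel = field(default_factory=EvokedKernel)
    artifact_span: tuple[float, float] = (-2.0, 20.0)
    artifact_amplitude: float = 500.0
    gain_power_interaction: float = 0.0
    gain_phase_interaction: float = 0.0
    interaction_band: str = "alpha"
    seed: int = 0
    #: optional per-band edge overrides (name -> BandSpec); defaults to the
    #: canonical theta/alpha/beta definitions
    band_specs: dict[str, BandSpec] | None = None

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_span
        a0, a1 = self.artifact_span
        if not (t0 < a0 < a1 < t1):
            raise ValueError("epoch_span must strictly contain artifact_span")
        if not (t0 < 25.0 and t1 > 80.0):
            raise ValueError("epoch_span must contain the 25-80 ms response window")
        if self.n_trials < 1 or self.n_datasets < 1:
            raise ValueError("n_trials and n_datasets must be >= 1")
        if min(self.band_amplitudes.values(), default=0.0) < 0 or self.noise_scale < 0:
            raise ValueError("amplitude/scale fields must be >= 0")
        if self.evoked_kernel.peak_uv < 0:
            raise ValueError("evoked kernel peak must be >= 0")
        if self.interaction_band not in self.band_amplitudes:
            raise ValueError(f"interaction_band {self.interaction_band!r} has no amplitude entry")
        gamma, kappa = self.gain_power_interaction, self.gain_phase_interaction
        # Worst case of 1 + gamma*z + kappa*cos(phi) over |z| <= z_truncation.
        if abs(gamma) * self.z_truncation + abs(kappa) > 1.0 + 1e-12:
            raise ValueError(
                "gain_power_interaction/gain_phase_interaction would make the evoked "
                f"amplitude negative for some trials (|gamma|*{self.z_truncation} + |kappa| > 1)"
            )

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_span
        n = int(round((t1 - t0) * self.fs / 1000.0)) + 1
        return t0 + np.arange(n) * 1000.0 / self.fs

    def band_for(self, name: str) -> BandSpec:
        if self.band_specs and name in self.band_specs:
            return self.band_specs[name]
        return get_band(name)


def _truncated_normal(rng: np.random.Generator, size: int, bound: float) -> np.ndarray:
    """Standard normal draws rejected outside [-bound, bound]."""
    out = rng.standard_normal(size)
    bad = np.abs(out) > bound
    while np.any(bad):
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def _analytic_band_noise(rng: np.random.Generator, n: int, fs: float,
                         lo: float, hi: float, n_trials: int) -> np.ndarray:
    """One-sided spectral synthesis of unit-RMS band-limited Gaussian noise.

    Returns a complex (n, n_trials) array whose real part is the signal and
    whose angle is its instantaneous phase (the trace is its own analytic
    signal by construction).  The real part has expected variance 1.
    """
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    band = (freqs >= lo) & (freqs <= hi)  # positive frequencies only
    m = int(band.sum())
    if m == 0:
        raise ValueError(f"band [{lo}, {hi}] Hz contains no DFT bin at this epoch length")
    coef = np.zeros((n, n_trials), dtype=complex)
    coef[band, :] = (rng.standard_normal((m, n_trials))
                     + 1j * rng.standard_normal((m, n_trials))) / np.sqrt(2.0)
    # Scale so that Var[Re z(t)] = 1:  E|z|^2 = m * s^2 / n^2, Re-part half.
    coef *= n * np.sqrt(2.0 / m)
    return np.fft.ifft(coef, axis=0)


def _background_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, rms: float, n_trials: int) -> np.ndarray:
    """Real 1/f^exponent Gaussian background with expected RMS ``rms``."""
    if rms == 0:
        return np.zeros((n, n_trials))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs >= 1.0  # flat cutoff below 1 Hz avoids the DC divergence
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    coef = (rng.standard_normal((len(freqs), n_trials))
            + 1j * rng.standard_normal((len(freqs), n_trials))) * amp[:, None]
    x = np.fft.irfft(coef, n=n, axis=0)
    # Var[x(t)] = (1/n^2) * sum over all n Hermitian bins of E|c|^2
    #           = (1/n^2) * 2 * sum_rfft (2 * amp^2)   (Re+Im draws, +/- freqs)
    expected_var = 4.0 * np.sum(amp**2) / n**2
    x *= rms / np.sqrt(expected_var)
    return x


def generate_dataset(cfg: GenConfig, dataset_index: int = 0) -> EpochSet:
    """Generate one dataset's epoched trials with full ground truth.

    Identical ``(cfg.seed, dataset_index)`` pairs give bit-identical
    output; different ``dataset_index`` values use independent streams.
    """
    if not 0 <= dataset_index:
        raise ValueError("dataset_index must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(dataset_index,)))
    times = cfg.times
    n = len(times)
    nt = cfg.n_trials
    data = _background_noise(rng, n, cfg.fs, cfg.noise_exponent, cfg.noise_scale, nt)

    clean: dict[str, np.ndarray] = {}
    truth_cols: dict[str, np.ndarray] = {"trial": np.arange(nt)}
    i0 = int(np.argmin(np.abs(times)))  # sample at t = 0
    for name, rms in cfg.band_amplitudes.items():
        band = cfg.band_for(name)
        z = _truncated_normal(rng, nt, cfg.z_truncation)
        amp_mult = np.exp(cfg.sigma_log_amp * z)
        trace = _analytic_band_noise(rng, n, cfg.fs, band.lo, band.hi, nt)
        trace *= rms * amp_mult[None, :]
        clean[name] = trace
        data += trace.real
        truth_cols[f"z_power_{name}"] = z
        truth_cols[f"amp_mult_{name}"] = amp_mult
        truth_cols[f"phase0_deg_{name}"] = np.degrees(np.angle(trace[i0, :])) % 360.0

    gamma, kappa = cfg.gain_power_interaction, cfg.gain_phase_interaction
    z_int = truth_cols[f"z_power_{cfg.interaction_band}"]
    phi_int = np.radians(truth_cols[f"phase0_deg_{cfg.interaction_band}"])
    gain = 1.0 + gamma * z_int + kappa * np.cos(phi_int)
    if np.any(gain < 0):
        raise ValueError("realized evoked gain negative for some trial; ill-posed config")
    kernel = cfg.evoked_kernel.waveform(np.where(times >= 0, times, -1.0))
    kernel[times < 0] = 0.0
    data += kernel[:, None] * gain[None, :]
    truth_cols["evoked_gain"] = gain

    # Overwrite strictly inside the artifact span; the boundary samples stay
    # clean, matching the excision stage's open-interval convention (its
    # interpolation anchors are the samples at exactly the span edges).
    a0, a1 = cfg.artifact_span
    am = (times > a0) & (times < a1)
    if cfg.artifact_amplitude > 0:
        transient = cfg.artifact_amplitude * np.exp(-(times[am] - a0) / 5.0)
        data[am, :] = transient[:, None]

    truth = TrialTruth(pd.DataFrame(truth_cols), clean)
    meta = {"dataset_index": dataset_index, "seed": cfg.seed}
    return EpochSet(data, times, cfg.fs, truth, meta)


def generate_cohort(cfg: GenConfig) -> list[EpochSet]:
    """Generate all ``cfg.n_datasets`` datasets."""
    return [generate_dataset(cfg, i) for i in range(cfg.n_datasets)]


def truth_phase(es: EpochSet, band: BandSpec | str, t_ms: float) -> np.ndarray:
    """Ground-truth oscillator phase (degrees in [0, 360)) at ``t_ms``.

    Reads the stored clean analytic oscillator trace; 0 degrees is the
    positive peak of the band-limited oscillation and phase increases in
    time.  Requires an in-memory synthetic :class:`EpochSet` (clean traces
    are not persisted to disk).
    """
    name = band.name if isinstance(band, BandSpec) else str(band)
    if es.truth is None or es.truth.clean is None or name not in es.truth.clean:
        raise ValueError(f"no ground-truth oscillator trace for band {name!r}")
    i = es.time_index(t_ms)
    return np.degrees(np.angle(es.truth.clean[name][i, :])) % 360.0


def with_gamma(cfg: GenConfig, gamma: float) -> GenConfig:
    """Copy of ``cfg`` with a different power-interaction gain."""
    return replace(cfg, gain_power_interaction=gamma)
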