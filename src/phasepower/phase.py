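"""Pre-stimulus instantaneous phase estimation.

The forward-prediction estimator (the PHASTIMATE procedure) uses only data
up to a causal cutoff: the analysis window is demeaned, band-pass filtered
with a zero-phase (forward-backward) linear-phase FIR, trimmed of its
filter-transient edges, extended forward in time with a Yule-Walker
autoregressive prediction through the target time, and read out as the
angle of the analytic signal over the final samples.  A non-causal Hilbert
oracle (band-pass + analytic signal on the full, uncut trace) provides the
reference phase for validation and for parameter optimization.

Phase convention everywhere: degrees in [0, 360), 0 at the positive peak
of the band-limited oscillation, increasing in time (90 degrees is a
quarter period after a positive peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import signal
from statsmodels.regression.linear_model import yule_walker

from .bands import DEFAULT_PHASTIMATE, BandSpec, PhastimateParams, get_band

__all__ = ["PhaseEstimate", "UnstablePredictionError", "estimate_phase_phastimate",
           "estimate_phases_phastimate", "hilbert_oracle_phase", "circular_error_sd",
           "optimize_params", "param_grid"]


class UnstablePredictionError(RuntimeError):
    """Raised when the AR forward prediction diverges (trial should be excluded)."""


@dataclass(frozen=True)
class PhaseEstimate:
    phase_deg: float
    target_time_ms: float
    method: str  # {"phastimate", "hilbert_oracle"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_deg < 360.0:
            raise ValueError("phase_deg must lie in [0, 360)")


def design_bandpass(band: BandSpec | str, fs: float, filter_order: int) -> np.ndarray:
    """Linear-phase FIR band-pass (Hamming-windowed, ``filter_order + 1`` taps)."""
    band = get_band(band)
    band.validate_fs(fs)
    return signal.firwin(filter_order + 1, [band.lo, band.hi], pass_zero=False,
                         window="hamming", fs=fs)


def _zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return signal.filtfilt(taps, [1.0], x, axis=0)


def _ar_forward_predict(x: np.ndarray, ar_order: int, n_pred: int) -> np.ndarray:
    """Append ``n_pred`` Yule-Walker AR predictions to a 1-D series."""
    rho, _ = yule_walker(x, order=ar_order, method="mle")
    out = np.concatenate([x, np.empty(n_pred)])
    n = len(x)
    for i in range(n_pred):
        out[n + i] = rho @ out[n + i - 1:n + i - 1 - ar_order:-1]
    if not np.all(np.isfinite(out)):
        raise UnstablePredictionError("autoregressive forward prediction diverged")
    return out


def estimate_phase_phastimate(trial_window: np.ndarray, params: PhastimateParams,
                              band: BandSpec | str, fs: float,
                              t_end_ms: float = -4.0,
                              target_time_ms: float = 0.0) -> PhaseEstimate:
    """Estimate phase at ``target_time_ms`` from data ending at ``t_end_ms``.

    ``trial_window`` must contain at least ``params.window_size_ms`` of
    data; its last sample is taken to lie at ``t_end_ms``.  The prediction
    is extended so that the target sits half a Hilbert window from the end
    of the analytic-transform segment, which keeps the analytic-signal
    edge distortion away from the readout sample.
    """
    band = get_band(band)
    x = np.asarray(trial_window, dtype=float)
    if x.ndim != 1:
        raise ValueError("trial_window must be 1-D; see estimate_phases_phastimate for batches")
    n_win = params.n_window(fs)
    if len(x) < n_win:
        raise ValueError(f"need at least {n_win} samples ({params.window_size_ms} ms), got {len(x)}")
    if target_time_ms < t_end_ms:
        raise ValueError("target_time_ms must not precede the end of the data window")
    x = x[-n_win:]
    x = x - x.mean()
    filtered = _zero_phase_filter(x, design_bandpass(band, fs, params.filter_order))
    n_edge = params.n_edge(fs)
    trimmed = filtered[n_edge:len(filtered) - n_edge]
    if params.ar_order >= len(trimmed):
        raise ValueError("ar_order must be smaller than the retained window length")
    delta = int(round((target_time_ms - t_end_ms) * fs / 1000.0))
    half_hw = math.ceil(params.hilbert_window / 2)
    n_pred = n_edge + delta + half_hw
    series = _ar_forward_predict(trimmed, params.ar_order, n_pred)
    segment = series[-params.hilbert_window:]
    analytic = signal.hilbert(segment)
    phase = math.degrees(np.angle(analytic[len(segment) - 1 - half_hw])) % 360.0
    return PhaseEstimate(phase, target_time_ms, "phastimate")


def estimate_phases_phastimate(windows: np.ndarray, params: PhastimateParams,
                               band: BandSpec | str, fs: float,
                               t_end_ms: float = -4.0,
                               target_time_ms: float = 0.0) -> np.ndarray:
    """Batched estimator over a (time x trial) matrix of pre-stimulus windows.

    Filtering is vectorized across trials; the AR fit and prediction run
    per trial.  Trials whose prediction diverges yield NaN (flagged for
    exclusion) instead of raising.
    """
    band = get_band(band)
    x = np.asarray(windows, dtype=float)
    if x.ndim != 2:
        raise ValueError("windows must be 2-D (time x trial)")
    n_win = params.n_window(fs)
    if x.shape[0] < n_win:
        raise ValueError(f"need at least {n_win} samples, got {x.shape[0]}")
    x = x[-n_win:, :]
    x = x - x.mean(axis=0, keepdims=True)
    filtered = _zero_phase_filter(x, design_bandpass(band, fs, params.filter_order))
    n_edge = params.n_edge(fs)
    trimmed = filtered[n_edge:filtered.shape[0] - n_edge, :]
    delta = int(round((target_time_ms - t_end_ms) * fs / 1000.0))
    half_hw = math.ceil(params.hilbert_window / 2)
    n_pred = n_edge + delta + half_hw
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        try:
            series = _ar_forward_predict(trimmed[:, j], params.ar_order, n_pred)
        except UnstablePredictionError:
            out[j] = np.nan
            continue
        segment = series[-params.hilbert_window:]
        analytic = signal.hilbert(segment)
        out[j] = math.degrees(np.angle(analytic[len(segment) - 1 - half_hw])) % 360.0
    return out


def hilbert_oracle_phase(full_signal: np.ndarray, times: np.ndarray,
                         band: BandSpec | str, fs: float, t_ms: float,
                         filter_order: int | None = None) -> np.ndarray | float:
    """Non-causal reference phase at ``t_ms`` from the full, uncut signal.

    Band-passes the whole trace (zero-phase FIR), applies the analytic-
    signal transform, and reads the angle at the sample nearest ``t_ms``.
    ``t_ms`` must be at least one filter length away from both edges.
    ``full_signal`` may be 1-D or 2-D (time x trial).
    """
    band = get_band(band)
    if filter_order is None:
        filter_order = DEFAULT_PHASTIMATE[band.name].filter_order if band.name in DEFAULT_PHASTIMATE else 128
    x = np.asarray(full_signal, dtype=float)
    t = np.asarray(times, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    if x.shape[0] != len(t):
        raise ValueError("times must match the signal's time axis")
    i = int(np.argmin(np.abs(t - t_ms)))
    margin = filter_order + 1
    if i < margin or i > len(t) - 1 - margin:
        raise ValueError(f"t_ms={t_ms} is within one filter transient ({margin} samples) of the signal edge")
    x = x - x.mean(axis=0, keepdims=True)
    filtered = _zero_phase_filter(x, design_bandpass(band, fs, filter_order))
    analytic = signal.hilbert(filtered, axis=0)
    phases = np.degrees(np.angle(analytic[i, :])) % 360.0
    return float(phases[0]) if one_d else phases


def circular_error_sd(estimates_deg: np.ndarray, references_deg: np.ndarray) -> float:
    """Circular standard deviation of paired angular errors, in radians.

    Pairwise differences are wrapped to (-180, 180] degrees; with mean
    resultant length ``R`` of the wrapped errors the circular SD is
    ``sqrt(-2 ln R)``.  Returns ``inf`` when ``R`` vanishes (dispersion
    undefined, e.g. errors spread uniformly around the circle).
    """
    a = np.asarray(estimates_deg, dtype=float)
    b = np.asarray(references_deg, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("estimates and references must be equal-length and non-empty")
    diff = np.radians(a - b)
    r = np.abs(np.mean(np.exp(1j * diff)))
    if r < 1e-12:
        return math.inf
    return math.sqrt(-2.0 * math.log(min(r, 1.0)))


def param_grid(filter_orders, window_sizes_ms, edges_ms, ar_orders, hilbert_windows) -> list[PhastimateParams]:
    """Cartesian product of parameter values, skipping invalid combinations."""
    grid = []
    for fo, ws, e, ar, hw in product(filter_orders, window_sizes_ms, edges_ms, ar_orders, hilbert_windows):
        try:
            grid.append(PhastimateParams(fo, ws, e, ar, hw))
        except ValueError:
            continue
    return grid


def optimize_params(training_signals: np.ndarray, times: np.ndarray,
                    band: BandSpec | str, fs: float,
                    grid: list[PhastimateParams],
                    t_train_ms: float = -1000.0,
                    margin_ms: float = 4.0) -> PhastimateParams:
    """Exhaustive grid search for the lowest-error parameter set.

    For each candidate, phases are forecast at ``t_train_ms`` from data
    ending ``margin_ms`` earlier and scored by :func:`circular_error_sd`
    against the Hilbert oracle on the full traces.  Ties break toward the
    smaller AR order, then the smaller filter order.  Deterministic.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    band = get_band(band)
    x = np.asarray(training_signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("training_signals must be 2-D (time x trial)")
    t = np.asarray(times, dtype=float)
    reference = hilbert_oracle_phase(x, t, band, fs, t_train_ms)
    t_end = t_train_ms - margin_ms
    i_end = int(np.argmin(np.abs(t - t_end)))
    best: tuple | None = None
    for params in grid:
        n_win = params.n_window(fs)
        if i_end + 1 < n_win:
            raise ValueError(f"training windows too short for window_size_ms={params.window_size_ms}")
        est = estimate_phases_phastimate(x[:i_end + 1, :], params, band, fs,
                                         t_end_ms=t_end, target_time_ms=t_train_ms)
        ok = np.isfinite(est)
        err = circular_error_sd(est[ok], reference[ok]) if np.any(ok) else math.inf
        key = (err, params.ar_order, params.filter_order, params.window_size_ms,
               params.edge_ms, params.hilbert_window)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1]
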