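"""Pre-stimulus band power (Welch) and power-based trial stratification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import BandSpec, get_band

__all__ = ["WelchConfig", "welch_band_power", "median_split", "mean_power_threshold"]


@dataclass(frozen=True)
class WelchConfig:
    """Welch segmentation scheme.

    Segments are half the analysis window with 50% overlap and a Hann
    (cosine) taper; the signal is demeaned per segment so that a constant
    offset contributes nothing.
    """

    segment_fraction: float = 0.5
    overlap_fraction: float = 0.5
    window: str = "hann"
    detrend: str = "constant"


def welch_band_power(trial_window: np.ndarray, band: BandSpec | str, fs: float,
                     welch_cfg: WelchConfig | None = None) -> np.ndarray | float:
    """Band-integrated Welch power of a pre-stimulus window, in uV^2.

    ``trial_window`` is 1-D (time) or 2-D (time x trial).  The spectral
    density is integrated over ``[band.lo, band.hi]`` with the rectangle
    rule on the DFT grid; a unit-amplitude in-band sinusoid yields about
    ``amplitude**2 / 2`` (0.5), up to spectral leakage.
    """
    band = get_band(band)
    cfg = welch_cfg or WelchConfig()
    x = np.asarray(trial_window, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    nperseg = max(int(round(n * cfg.segment_fraction)), 2)
    if n < nperseg:
        raise ValueError(f"window of {n} samples shorter than one Welch segment ({nperseg})")
    noverlap = int(nperseg * cfg.overlap_fraction)
    freqs, psd = signal.welch(x, fs=fs, window=cfg.window, nperseg=nperseg,
                              noverlap=noverlap, detrend=cfg.detrend, axis=0,
                              scaling="density")
    band.validate_fs(fs)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    df = freqs[1] - freqs[0]
    power = psd[mask, :].sum(axis=0) * df
    return float(power[0]) if one_d else power


def median_split(powers: np.ndarray) -> np.ndarray:
    """Label each trial ``low`` (below the median) or ``high`` (above).

    Trials exactly at the median are assigned alternately (in trial
    order) to whichever group is currently smaller, starting with ``low``
    on a balanced count, so the two group sizes differ by at most one.
    """
    p = np.asarray(powers, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("median_split needs a 1-D array of at least two powers")
    med = np.median(p)
    labels = np.where(p < med, "low", "high").astype(object)
    labels[p == med] = ""
    n_low = int(np.sum(labels == "low"))
    n_high = int(np.sum(labels == "high"))
    for idx in np.where(labels == "")[0]:
        if n_low <= n_high:
            labels[idx] = "low"
            n_low += 1
        else:
            labels[idx] = "high"
            n_high += 1
    return labels.astype(str)


def mean_power_threshold(powers: np.ndarray) -> np.ndarray:
    """Boolean mask of trials whose power strictly exceeds the mean power.

    The threshold is the arithmetic mean of the power values for this
    dataset and band; because trial power is right-skewed, typically fewer
    than half of the trials are retained.
    """
    p = np.asarray(powers, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("mean_power_threshold needs a non-empty 1-D array")
    return p > p.mean()
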