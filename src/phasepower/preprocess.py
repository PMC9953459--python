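"""Deterministic single-channel epoch conditioning.

Three operations, applied in the fixed order excise -> baseline ->
downsample: the stimulus-artifact segment is cut out and bridged by a
straight line, each trial is baseline-corrected against a pre-stimulus
window, and the data may be decimated to a lower rate after anti-alias
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = ["PreprocConfig", "excise_and_interpolate", "baseline_correct", "downsample", "preprocess"]


@dataclass(frozen=True)
class PreprocConfig:
    artifact_span: tuple[float, float] = (-2.0, 20.0)
    baseline_span: tuple[float, float] = (-500.0, -200.0)
    target_fs: float = 1000.0

    def __post_init__(self) -> None:
        a0, a1 = self.artifact_span
        b0, b1 = self.baseline_span
        if a0 >= a1 or b0 >= b1:
            raise ValueError("spans must be increasing (start < end)")
        if max(a0, b0) <= min(a1, b1):
            raise ValueError("artifact_span and baseline_span must be disjoint")
        if self.target_fs <= 0:
            raise ValueError("target_fs must be positive")


def excise_and_interpolate(es: EpochSet, span: tuple[float, float]) -> EpochSet:
    """Replace samples strictly inside ``span`` by linear interpolation.

    The interpolation anchors are the last retained sample at/before the
    span start and the first at/after its end; samples exactly on the span
    edges are kept (the span is open).  Idempotent.
    """
    t0, t1 = span
    if t0 >= t1:
        raise ValueError("span must be increasing")
    times = es.times
    inside = (times > t0 + 1e-9) & (times < t1 - 1e-9)
    if not np.any(inside):
        return es.copy()
    left = np.where(times <= t0 + 1e-9)[0]
    right = np.where(times >= t1 - 1e-9)[0]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("span touches the epoch edge; no anchor sample to interpolate from")
    i_left, i_right = left[-1], right[0]
    out = es.copy()
    frac = (times[inside] - times[i_left]) / (times[i_right] - times[i_left])
    out.data[inside, :] = (es.data[i_left, :][None, :] * (1 - frac[:, None])
                           + es.data[i_right, :][None, :] * frac[:, None])
    return out


def baseline_correct(es: EpochSet, span: tuple[float, float]) -> EpochSet:
    """Subtract each trial's mean over ``span`` (inclusive) from the whole trial."""
    t0, t1 = span
    mask = es.window_mask(t0, t1)
    if not np.any(mask):
        raise ValueError(f"baseline span [{t0}, {t1}] ms contains no samples")
    out = es.copy()
    out.data -= es.data[mask, :].mean(axis=0, keepdims=True)
    return out


def downsample(es: EpochSet, target_fs: float) -> EpochSet:
    """Anti-alias filter and decimate to ``target_fs`` (integer ratio only)."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    ratio = es.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"fs {es.fs} Hz is not an integer multiple of target {target_fs} Hz")
    if q == 1:
        return es.copy()
    out = es.copy()
    out.data = signal.decimate(es.data, q, ftype="fir", zero_phase=True, axis=0)
    out.times = es.times[::q]
    out.fs = target_fs
    return out


def preprocess(es: EpochSet, cfg: PreprocConfig | None = None) -> EpochSet:
    """Full conditioning chain: excise -> baseline -> downsample."""
    cfg = cfg or PreprocConfig()
    es = excise_and_interpolate(es, cfg.artifact_span)
    es = baseline_correct(es, cfg.baseline_span)
    return downsample(es, cfg.target_fs)
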