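"""Single-trial response quantification and phase-bin assignment.

The single-trial response measure is the rectified area under the curve
(AUC): the trapezoidal integral of the absolute signal over a 55 ms
window, in uV*ms.  For the stimulation condition the window is 25-80 ms
after the pulse; the no-stimulus control uses a matched 55 ms window
placed 29 ms after the control phase-readout time (for the default
-1000 ms readout: -971..-916 ms).  Trials are categorized by pre-stimulus
phase into four 60-degree-wide bins centered on the positive peak (0),
90, the negative peak (180) and 270 degrees; trials between bins belong
to no labeled bin, and the "random" category is simply the full trial
set.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TMS_WINDOW_MS", "PHASE_BINS", "compute_auc", "assign_phase_bin",
           "assign_phase_bins", "control_window_for"]

#: Post-stimulus response window (ms), free of early sensory artifacts.
TMS_WINDOW_MS: tuple[float, float] = (25.0, 80.0)

#: Labeled phase bins: label -> (center, half-width), degrees.
PHASE_BINS: dict[str, tuple[float, float]] = {
    "positive_peak": (0.0, 30.0),
    "deg90": (90.0, 30.0),
    "negative_peak": (180.0, 30.0),
    "deg270": (270.0, 30.0),
}


def compute_auc(trial: np.ndarray, times: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray | float:
    """Rectified trapezoidal AUC over an inclusive time window, in uV*ms.

    ``trial`` is 1-D (time) or 2-D (time x trial); ``times`` is the ms
    axis.  Scaling a trial by ``c`` scales the AUC by ``|c|``.
    """
    x = np.asarray(trial, dtype=float)
    t = np.asarray(times, dtype=float)
    t0, t1 = window_ms
    if t0 >= t1:
        raise ValueError("window must be increasing")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"AUC window [{t0}, {t1}] ms outside epoch [{t[0]}, {t[-1]}] ms")
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    auc = np.trapezoid(np.abs(x[mask]), t[mask], axis=0)
    return auc


def assign_phase_bin(phase_deg: float) -> str:
    """Label a phase with its 60-degree bin, or ``none`` between bins.

    The phase is wrapped modulo 360, so adding full turns never changes
    the label; bin boundaries are inclusive.
    """
    if not np.isfinite(phase_deg):
        raise ValueError(f"phase must be finite, got {phase_deg}")
    p = float(phase_deg) % 360.0
    for label, (center, half) in PHASE_BINS.items():
        d = (p - center + 180.0) % 360.0 - 180.0
        if abs(d) <= half + 1e-9:
            return label
    return "none"


def assign_phase_bins(phases_deg: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_phase_bin`."""
    return np.array([assign_phase_bin(p) for p in np.asarray(phases_deg, dtype=float)])


def control_window_for(phase_target_ms: float = -1000.0) -> tuple[float, float]:
    """Control AUC window: 29 ms after the phase-readout time, 55 ms long.

    For the default readout at -1000 ms this is (-971, -916) ms, the same
    length as the 25-80 ms post-stimulus window.
    """
    length = TMS_WINDOW_MS[1] - TMS_WINDOW_MS[0]
    return (phase_target_ms + 29.0, phase_target_ms + 29.0 + length)
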