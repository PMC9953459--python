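"""Frequency-band definitions and per-band analysis parameters.

The three canonical bands used throughout the package are theta (4-7 Hz),
alpha (8-13 Hz) and beta (14-30 Hz).  Each band carries the length of the
pre-stimulus window over which its power is measured (longer windows for
slower rhythms, so that every window spans at least a few cycles), and has
an associated default parameter set for the forward-prediction phase
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its power-analysis window length.

    Parameters
    ----------
    name : str
        Band label (``theta``, ``alpha`` or ``beta`` for the defaults).
    lo, hi : float
        Band edges in Hz, ``0 < lo < hi``.
    power_window_ms : float
        Length of the pre-stimulus window (ms) used when measuring this
        band's power with Welch's method.
    """

    name: str
    lo: float
    hi: float
    power_window_ms: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lo < self.hi:
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got {self.lo}, {self.hi}")
        if self.power_window_ms <= 0:
            raise ValueError("power_window_ms must be positive")

    def validate_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(f"band {self.name} upper edge {self.hi} Hz >= Nyquist ({fs / 2} Hz)")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class PhastimateParams:
    """Tunable parameters of the forward-prediction phase estimator.

    Attributes
    ----------
    filter_order : int
        Order of the linear-phase FIR band-pass applied forward and
        backward (zero phase); ``filter_order + 1`` taps.
    window_size_ms : float
        Length of the pre-stimulus analysis window.
    edge_ms : float
        Length trimmed from each end of the filtered window to discard
        filter transients.
    ar_order : int
        Order of the Yule-Walker autoregressive model used for forward
        prediction.
    hilbert_window : int
        Number of samples entering the analytic-signal transform.
    """

    filter_order: int
    window_size_ms: float
    edge_ms: float
    ar_order: int
    hilbert_window: int

    def __post_init__(self) -> None:
        if min(self.filter_order, self.window_size_ms, self.edge_ms,
               self.ar_order, self.hilbert_window) <= 0:
            raise ValueError("all phase-estimator parameters must be positive")
        if self.window_size_ms <= 2 * self.edge_ms:
            raise ValueError("window_size_ms must exceed twice edge_ms")

    def n_window(self, fs: float) -> int:
        return int(round(self.window_size_ms * fs / 1000.0))

    def n_edge(self, fs: float) -> int:
        return int(round(self.edge_ms * fs / 1000.0))


THETA = BandSpec("theta", 4.0, 7.0, 1000.0)
ALPHA = BandSpec("alpha", 8.0, 13.0, 500.0)
BETA = BandSpec("beta", 14.0, 30.0, 250.0)

DEFAULT_BANDS: dict[str, BandSpec] = {b.name: b for b in (THETA, ALPHA, BETA)}

#: Default estimator parameters per band (filter order, window, trimmed
#: edge, AR order, Hilbert window), tuned for 1 kHz data.
DEFAULT_PHASTIMATE: dict[str, PhastimateParams] = {
    "theta": PhastimateParams(320, 1000.0, 140.0, 30, 256),
    "alpha": PhastimateParams(192, 718.0, 65.0, 25, 128),
    "beta": PhastimateParams(100, 500.0, 30.0, 15, 64),
}


def get_band(band: "BandSpec | str") -> BandSpec:
    """Resolve a band given by name or already as a :class:`BandSpec`."""
    if isinstance(band, BandSpec):
        return band
    try:
        return DEFAULT_BANDS[band]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(DEFAULT_BANDS)}") from None
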