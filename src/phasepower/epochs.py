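"""Epoched single-channel EEG container and plain-text I/O.

An :class:`EpochSet` holds one dataset's trials as a time x trial matrix in
microvolts together with a millisecond time axis.  When the data come from
the synthetic generator, a :class:`TrialTruth` record carries the
ground-truth oscillator state (phase at stimulus time, per-epoch amplitude
draw, injected evoked gain) used to validate the estimators downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "TrialTruth"]


@dataclass
class TrialTruth:
    """Ground truth for synthetic trials.

    ``table`` has one row per trial with, per band ``b``, columns
    ``phase0_deg_{b}`` (oscillator phase at t=0), ``z_power_{b}``
    (standardized log-amplitude draw) and ``amp_mult_{b}`` (per-epoch
    amplitude multiplier), plus ``evoked_gain`` (the realized multiplicative
    gain of the injected evoked kernel).  ``clean`` optionally maps band
    name -> complex analytic trace (time x trial) of the noiseless
    oscillator; it is kept in memory only and is not round-tripped to disk.
    """

    table: pd.DataFrame
    clean: dict[str, np.ndarray] | None = None


@dataclass
class EpochSet:
    """Single-channel epoched EEG: ``data`` is time x trial, in microvolts."""

    data: np.ndarray
    times: np.ndarray
    fs: float
    truth: TrialTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x trial)")
        if self.times.ndim != 1 or len(self.times) != self.data.shape[0]:
            raise ValueError("times must be 1-D and match data's first axis")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.fs, atol=1e-6)):
            raise ValueError("times must increase uniformly with spacing 1000/fs ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    # -- geometry helpers -------------------------------------------------

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest ``t_ms``."""
        i = int(np.argmin(np.abs(self.times - t_ms)))
        return i

    def window_mask(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        """Boolean mask of samples with ``t0_ms <= t <= t1_ms`` (inclusive)."""
        if t0_ms > t1_ms:
            raise ValueError("window start must not exceed end")
        return (self.times >= t0_ms - 1e-9) & (self.times <= t1_ms + 1e-9)

    def window(self, t0_ms: float, t1_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, data)`` restricted to the inclusive window."""
        if t0_ms < self.times[0] - 1e-9 or t1_ms > self.times[-1] + 1e-9:
            raise ValueError(
                f"window [{t0_ms}, {t1_ms}] ms extends outside epoch "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        m = self.window_mask(t0_ms, t1_ms)
        return self.times[m], self.data[m, :]

    def copy(self) -> "EpochSet":
        truth = None
        if self.truth is not None:
            truth = TrialTruth(
                self.truth.table.copy(),
                None if self.truth.clean is None
                else {k: v.copy() for k, v in self.truth.clean.items()},
            )
        return EpochSet(self.data.copy(), self.times.copy(), self.fs, truth, dict(self.meta))

    # -- plain-text I/O ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the epoch set as delimited text plus a JSON sidecar.

        Layout: ``data.tsv`` (time x trial matrix), ``meta.json`` (fs, time
        span, extra metadata) and, for synthetic data, ``truth.tsv`` (the
        per-trial truth table; clean oscillator traces are not persisted).
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "data.tsv", self.data, delimiter="\t", fmt="%.6f")
        meta = {
            "fs": self.fs,
            "t_start_ms": float(self.times[0]),
            "n_times": int(self.n_times),
            "n_trials": int(self.n_trials),
            **self.meta,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        if self.truth is not None:
            self.truth.table.to_csv(directory / "truth.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        data = np.loadtxt(directory / "data.tsv", delimiter="\t", ndmin=2)
        fs = float(meta.pop("fs"))
        t0 = float(meta.pop("t_start_ms"))
        n = int(meta.pop("n_times"))
        meta.pop("n_trials", None)
        times = t0 + np.arange(n) * 1000.0 / fs
        truth = None
        truth_path = directory / "truth.tsv"
        if truth_path.exists():
            truth = TrialTruth(pd.read_csv(truth_path, sep="\t"))
        return cls(data, times, fs, truth, meta)
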