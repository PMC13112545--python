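"""Core domain containers: single-lead ECG records and their ground truth.

All signals are one-dimensional float arrays in millivolts at a fixed
sampling rate (300 Hz by default, the rate of handheld single-lead
recorders).  Sample indices are 0-based throughout the package; times are
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["Rhythm", "EcgRecord", "GroundTruth"]


class Rhythm(str, Enum):
    """Two-class rhythm label: sinus rhythm vs. atrial fibrillation."""

    NORMAL = "normal"
    AFIB = "afib"

    @classmethod
    def parse(cls, token: str) -> "Rhythm":
        token = token.strip().lower()
        aliases = {
            "normal": cls.NORMAL,
            "n": cls.NORMAL,
            "sinus": cls.NORMAL,
            "afib": cls.AFIB,
            "af": cls.AFIB,
            "a": cls.AFIB,
            "atrial fibrillation": cls.AFIB,
        }
        if token not in aliases:
            raise ValueError(f"unknown rhythm label {token!r}")
        return aliases[token]


@dataclass(frozen=True)
class GroundTruth:
    """Synthetic-generator fiducials used as test oracles.

    Attributes
    ----------
    r_times:
        R-peak centers in seconds, strictly increasing.
    p_windows:
        ``(start, end)`` second pairs bracketing each P-wave; empty for
        AFib (the P-wave is absent by construction).
    rhythm:
        The generating rhythm class.
    """

    r_times: Tuple[float, ...]
    p_windows: Tuple[Tuple[float, float], ...]
    rhythm: Rhythm

    def __post_init__(self) -> None:
        rt = np.asarray(self.r_times, dtype=float)
        if rt.size and np.any(np.diff(rt) <= 0):
            raise ValueError("r_times must be strictly increasing")
        for s, e in self.p_windows:
            if e <= s:
                raise ValueError("p_window end must exceed start")
        if self.rhythm is Rhythm.AFIB and self.p_windows:
            raise ValueError("afib ground truth has no P-wave windows")


@dataclass(frozen=True)
class EcgRecord:
    """One single-lead ECG strip.

    Attributes
    ----------
    record_id:
        Identifier used in file names and output tables.
    samples:
        Signal in millivolts, finite everywhere.
    fs:
        Sampling rate in Hz.
    label:
        Optional rhythm class.
    annotations:
        Optional synthetic ground truth.
    """

    record_id: str
    samples: np.ndarray
    fs: float = 300.0
    label: Optional[Rhythm] = None
    annotations: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2 * self.fs:
            raise ValueError(
                f"record {self.record_id!r} shorter than 2 s "
                f"({samples.size} samples at {self.fs} Hz)"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"record {self.record_id!r} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def with_samples(self, samples: Sequence[float]) -> "EcgRecord":
        """Copy of this record with replaced signal (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))
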