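"""The in-memory container for a single-channel EGG voltage series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "downsampled", "detrended", "filtered")


@dataclass
class EggRecording:
    """A single-channel cutaneous EGG time series.

    Parameters
    ----------
    samples
        Voltage samples in microvolts (µV).
    fs
        Sampling rate in Hz.
    subject_id
        Opaque subject identifier.
    t0
        Recording start time in seconds (offset of samples[0]).
    stage_tag
        Processing stage; advances only forward through
        raw → downsampled → detrended → filtered.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    t0: float = 0.0
    stage_tag: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("EGG recording must be a 1-D voltage series")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EGG samples must be finite")
        if self.stage_tag not in STAGES:
            raise ValueError(f"unknown stage {self.stage_tag!r}; expected one of {STAGES}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at t0."""
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def advance(self, samples: np.ndarray, fs: float | None = None,
                stage_tag: str | None = None) -> "EggRecording":
        """Return a copy with new samples, optionally advancing the stage tag."""
        new_stage = stage_tag if stage_tag is not None else self.stage_tag
        if STAGES.index(new_stage) < STAGES.index(self.stage_tag):
            raise ValueError(
                f"stage may only advance forward: {self.stage_tag!r} -> {new_stage!r}")
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs, stage_tag=new_stage)
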