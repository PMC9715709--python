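"""Readers, writers and the session configuration.

CSV is the canonical interchange format: recordings as two columns
(time_s, voltage_uV), feed schedules and tidy result tables as plain
CSV, configuration as YAML.  All writers are deterministic (fixed column
order, UTF-8, NaN as empty cell) so a fixed configuration and seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import EggRecording
from .segmentation import FeedEvent

__all__ = ["SessionConfig", "read_recording", "write_recording",
           "read_feeds", "write_tidy", "load_config", "save_config"]


@dataclass
class SessionConfig:
    """Every tunable of the analysis chain, with the standard defaults:
    2000 Hz acquisition decimated ×4 to 500 Hz, order-3 detrend, 1-Hz
    zero-phase low-pass, 4-min/2-min Hamming Welch, 0.5–15 cpm band-pass
    and 4-Hz analysis rate for the wavelet stage."""

    fs_raw: float = 2000.0
    downsample_factor: int = 4
    detrend_order: int = 3
    lowpass_hz: float = 1.0
    welch_window_s: float = 240.0
    welch_overlap_s: float = 120.0
    welch_taper: str = "hamming"
    welch_detrend_blocks: bool = False
    wavelet: str = "morlet"
    voices: int = 12
    analysis_fs: float = 4.0
    bandpass_lo_cpm: float = 0.5
    bandpass_hi_cpm: float = 15.0
    denominator_mode: str = "total"
    halves_mode: str = "capped"
    allow_single_window: bool = False
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> SessionConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return SessionConfig.from_dict(data)


def save_config(cfg: SessionConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def read_recording(path: str | Path, fs: float | None = None,
                   subject_id: str = "") -> EggRecording:
    """Read a two-column (time_s, voltage_uV) CSV recording.

    The sampling rate is inferred from the time column (and checked
    against ``fs`` when given).  Non-monotone time or malformed rows are
    rejected with descriptive errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    required = {"time_s", "voltage_uV"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path} must have columns {sorted(required)}, got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["voltage_uV"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: a recording needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError(f"{path}: sampling interval is not uniform")
    inferred = 1.0 / dt.mean()
    if fs is not None and abs(inferred - fs) > 1e-3 * fs:
        raise ValueError(
            f"{path}: stated rate {fs} Hz does not match the time column "
            f"({inferred:.6g} Hz)")
    return EggRecording(v, fs if fs is not None else float(inferred),
                        subject_id=subject_id, t0=float(t[0]))


def write_recording(rec: EggRecording, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rec.times_s(), "voltage_uV": rec.samples})
    df.to_csv(path, index=False)


def read_feeds(path: str | Path) -> list[FeedEvent]:
    """Read a feed schedule from YAML (`feeds: [{start_min, end_min}, ...]`)
    or from a CSV with start_min/end_min columns."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        entries = data["feeds"] if isinstance(data, dict) else data
        return [FeedEvent(float(e["start_min"]), float(e["end_min"]))
                for e in entries]
    df = pd.read_csv(path)
    return [FeedEvent(float(r.start_min), float(r.end_min))
            for r in df.itertuples()]


def write_tidy(df: pd.DataFrame, path: str | Path,
               columns: list[str] | None = None) -> None:
    """Deterministic tidy CSV: fixed column order, UTF-8, NaN as empty."""
    if columns is not None:
        df = df.loc[:, columns]
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")
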