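"""Welch power spectral density and band spectral means (mPSD).

The PSD of each sub-feeding window is estimated by Welch's method with a
4-min Hamming-tapered window and 2-min overlap, giving a frequency
resolution of 1/240 s ≈ 0.004 Hz — fine enough to resolve the gastric
bands, while the averaging of overlapped periodograms suppresses the
broadband noise and motion-artifact power that single-periodogram
estimates inherit.  The band feature mPSD_GR is the arithmetic mean of
the density over the grid bins falling in a gastric rhythm band (bins
assigned by bin centre, half-open [lo, hi)); averaging density rather
than integrating keeps the unit µV²/Hz.

Windows shorter than the nominal Welch window are estimated with a single
segment equal to the window length (degraded resolution); a floor of
125 s guarantees at least one bin inside the bradygastria band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import BANDS, RhythmBand
from .recording import EggRecording

__all__ = ["PsdSpectrum", "BandMeanPsd", "welch_psd", "band_mean",
           "band_means", "phase_average", "MIN_SEGMENT_S"]

#: Minimum analysable segment length: 1/125 s = 0.008 Hz resolution puts
#: one bin at the bradygastria lower edge.
MIN_SEGMENT_S = 125.0


@dataclass
class PsdSpectrum:
    """One-sided Welch power spectral density estimate."""

    freqs_hz: np.ndarray
    density: np.ndarray        # µV²/Hz
    resolution_hz: float
    window_label: str = ""

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("PSD density must be non-negative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class BandMeanPsd:
    """Band spectral means mPSD_brady/normo/tachy for one window or phase."""

    subject_id: str
    phase: str                 # pre | during | post, or a window label
    mPSD_brady: float
    mPSD_normo: float
    mPSD_tachy: float
    n_windows: int = 1

    def value(self, band_name: str) -> float:
        return getattr(self, f"mPSD_{band_name}")


def welch_psd(segment: EggRecording, window_s: float = 240.0,
              overlap_s: float = 120.0, taper: str = "hamming",
              detrend_blocks: bool = False,
              window_label: str = "") -> PsdSpectrum:
    """Welch PSD of one sub-feeding window.

    Uses Hamming-tapered segments of ``window_s`` seconds with
    ``overlap_s`` seconds overlap, one-sided density scaling.  If the
    segment is shorter than one Welch window, a single full-length window
    is used instead (with a warning), subject to the 125-s floor.
    Per-block detrending is off by default because the global cubic
    detrend runs before any segmentation.
    """
    n = len(segment.samples)
    if n == 0:
        raise ValueError("cannot estimate the PSD of an empty segment")
    if segment.duration_s < MIN_SEGMENT_S:
        raise ValueError(
            f"segment of {segment.duration_s:.0f} s is too short; at least "
            f"{MIN_SEGMENT_S:.0f} s is required for one bradygastria bin")
    nperseg = int(round(window_s * segment.fs))
    noverlap = int(round(overlap_s * segment.fs))
    if nperseg > n:
        warnings.warn(
            f"segment ({segment.duration_s:.0f} s) shorter than the "
            f"{window_s:.0f}-s Welch window; using a single full-length "
            "window with degraded resolution", stacklevel=2)
        nperseg, noverlap = n, 0
    freqs, density = signal.welch(
        segment.samples, fs=segment.fs, window=taper, nperseg=nperseg,
        noverlap=noverlap, detrend=("constant" if detrend_blocks else False),
        scaling="density")
    return PsdSpectrum(freqs, density, resolution_hz=segment.fs / nperseg,
                       window_label=window_label)


def band_mean(spec: PsdSpectrum, band: RhythmBand) -> float:
    """Arithmetic mean of the density over bins with lo_hz <= f < hi_hz."""
    mask = (spec.freqs_hz >= band.lo_hz) & (spec.freqs_hz < band.hi_hz)
    if not np.any(mask):
        min_window = 1.0 / (band.hi_hz - band.lo_hz)
        raise ValueError(
            f"no PSD bins fall in the {band.name} band "
            f"[{band.lo_hz:.4f}, {band.hi_hz:.4f}) Hz at resolution "
            f"{spec.resolution_hz:.4f} Hz; a window of at least "
            f"{min_window:.0f} s is required")
    return float(spec.density[mask].mean())


def band_means(spec: PsdSpectrum, subject_id: str = "",
               phase: str = "") -> BandMeanPsd:
    """mPSD over all three gastric rhythm bands."""
    vals = {b.name: band_mean(spec, b) for b in BANDS}
    return BandMeanPsd(subject_id, phase or spec.window_label,
                       vals["brady"], vals["normo"], vals["tachy"])


def phase_average(per_window: dict[str, BandMeanPsd],
                  allow_single: bool = False) -> dict[str, BandMeanPsd]:
    """Average window-level mPSD into per-phase values.

    Pre-feed 1 with pre-feed 2, during 1 with during 2, post 1 with
    post 2 — unweighted.  With ``allow_single`` a phase whose second
    window is missing passes the available window through (flagged by
    ``n_windows=1``); otherwise both windows are required.
    """
    out: dict[str, BandMeanPsd] = {}
    for phase in ("pre", "during", "post"):
        pair = [per_window[k] for k in (f"{phase}1", f"{phase}2") if k in per_window]
        if not pair:
            raise ValueError(f"no windows available for phase {phase!r}")
        if len(pair) == 1 and not allow_single:
            raise ValueError(
                f"phase {phase!r} has only one window; pass allow_single=True "
                "to accept it")
        subject = pair[0].subject_id
        out[phase] = BandMeanPsd(
            subject, phase,
            float(np.mean([w.mPSD_brady for w in pair])),
            float(np.mean([w.mPSD_normo for w in pair])),
            float(np.mean([w.mPSD_tachy for w in pair])),
            n_windows=len(pair))
    return out
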