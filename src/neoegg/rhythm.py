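"""Per-minute dominant-rhythm partition and percent time in band.

The EGG signal is non-stationary: the dominant rhythm wanders between
bands on the scale of minutes.  The partition procedure is:

1. zero-phase Butterworth band-pass to 0.5–15 cpm;
2. continuous wavelet transform spectrogram (the signal is decimated to
   a low analysis rate first — content is below 0.25 Hz, so a few Hz is
   ample and keeps the transform cheap);
3. for each whole minute and each gastric band, average the non-COI CWT
   power over the band's frequencies and the minute's time span, and
   form its ratio against the average over the entire 0.5–9 cpm range;
4. the minute's dominant band is the one with the largest ratio (ties
   broken toward the lower-frequency band; a minute with no valid cells
   is unclassified);
5. percent time in a band over a window is 100 · (dominant-minute count)
   / denominator, where the denominator is all whole minutes in the
   window (default) or only the classified ones.

Minutes whose cells are all inside the cone of influence cannot be
classified; partial trailing minutes (< 60 s) are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .bands import BANDS, GASTRIC_HI_CPM, GASTRIC_LO_CPM
from .cwt import CwtSpectrogram, analytic_cwt
from .recording import EggRecording
from .segmentation import SubFeedWindow

__all__ = ["MinutePartition", "PercentTime", "bandpass_gastric", "cwt_power",
           "minute_band_ratios", "percent_time", "phase_average_pct"]


@dataclass
class MinutePartition:
    """Band power ratios and the dominant label for one whole minute."""

    minute_index: int
    ratio_brady: float
    ratio_normo: float
    ratio_tachy: float
    dominant: str              # band name or 'unclassified'
    coi_fraction: float        # fraction of the minute's cells masked

    def ratios(self) -> dict[str, float]:
        return {"brady": self.ratio_brady, "normo": self.ratio_normo,
                "tachy": self.ratio_tachy}


@dataclass
class PercentTime:
    """Percent of minutes each band was dominant in one window or phase."""

    subject_id: str
    phase: str
    pct_brady: float
    pct_normo: float
    pct_tachy: float
    T_brady: int
    T_normo: int
    T_tachy: int
    total_minutes: int
    n_windows: int = 1

    def pct(self, band_name: str) -> float:
        return getattr(self, f"pct_{band_name}")


def bandpass_gastric(rec: EggRecording, lo_cpm: float = 0.5,
                     hi_cpm: float = 15.0, order: int = 3) -> EggRecording:
    """Zero-phase Butterworth band-pass to the gastric range (cpm units)."""
    lo_hz, hi_hz = lo_cpm / 60.0, hi_cpm / 60.0
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"invalid band [{lo_cpm}, {hi_cpm}] cpm")
    if hi_hz >= rec.fs / 2:
        raise ValueError(
            f"band edge {hi_cpm} cpm = {hi_hz:.3f} Hz reaches the Nyquist "
            f"frequency {rec.fs / 2} Hz")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="band", fs=rec.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.samples)
    return EggRecording(out, rec.fs, subject_id=rec.subject_id, t0=rec.t0,
                        stage_tag=rec.stage_tag)


def _decimate_to(rec: EggRecording, target_fs: float) -> EggRecording:
    """Polyphase resample to the analysis rate (content is far below the
    target Nyquist, so this is essentially lossless)."""
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return EggRecording(out, target_fs, subject_id=rec.subject_id, t0=rec.t0,
                        stage_tag=rec.stage_tag)


def cwt_power(rec: EggRecording, wavelet: str = "morlet",
              analysis_fs: float = 4.0, lo_cpm: float = 0.5,
              hi_cpm: float = 15.0, voices: int = 12,
              prefiltered: bool = False) -> CwtSpectrogram:
    """CWT spectrogram of one sub-feeding window.

    Band-passes to [lo_cpm, hi_cpm] (skipped when ``prefiltered``),
    decimates to ``analysis_fs``, and transforms onto a log frequency
    grid with ``voices`` voices per octave.
    """
    if rec.duration_s < 120:
        raise ValueError(
            f"recording of {rec.duration_s:.0f} s is too short for a "
            "minute-resolved spectrogram (need at least 2 min)")
    work = rec if prefiltered else bandpass_gastric(rec, lo_cpm, hi_cpm)
    work = _decimate_to(work, analysis_fs)
    return analytic_cwt(work.samples, work.fs, wavelet=wavelet,
                        lo_cpm=lo_cpm, hi_cpm=hi_cpm, voices=voices)


def minute_band_ratios(spec: CwtSpectrogram) -> list[MinutePartition]:
    """Partition a spectrogram into whole minutes and label each one.

    For each minute and band the mean non-COI power over (band
    frequencies × minute times) is divided by the mean over the full
    0.5–9 cpm range for the same minute.  COI-masked cells are excluded
    from numerator and denominator alike.
    """
    dt = spec.times_s[1] - spec.times_s[0]
    per_min = int(round(60.0 / dt))
    n_minutes = spec.power.shape[1] // per_min
    if n_minutes < 1:
        raise ValueError("spectrogram covers less than one whole minute")

    gastric_rows = ((spec.freqs_cpm >= GASTRIC_LO_CPM)
                    & (spec.freqs_cpm < GASTRIC_HI_CPM))
    band_rows = {b.name: (spec.freqs_cpm >= b.lo_cpm) & (spec.freqs_cpm < b.hi_cpm)
                 for b in BANDS}
    valid = ~spec.coi_mask

    out: list[MinutePartition] = []
    for m in range(n_minutes):
        cols = slice(m * per_min, (m + 1) * per_min)
        p = spec.power[:, cols]
        v = valid[:, cols]

        tot_v = v[gastric_rows]
        denom = p[gastric_rows][tot_v].mean() if tot_v.any() else np.nan

        ratios: dict[str, float] = {}
        for b in BANDS:
            bv = v[band_rows[b.name]]
            if bv.any() and np.isfinite(denom) and denom > 0:
                ratios[b.name] = float(p[band_rows[b.name]][bv].mean() / denom)
            else:
                ratios[b.name] = math.nan

        coi_frac = float(spec.coi_mask[:, cols].mean())
        if all(math.isnan(r) for r in ratios.values()):
            dominant = "unclassified"
        else:
            # ties broken toward the lower-frequency band (iteration order)
            dominant = max(BANDS, key=lambda b: (
                -math.inf if math.isnan(ratios[b.name]) else ratios[b.name],
                -b.lo_cpm)).name
        out.append(MinutePartition(
            m, ratios["brady"], ratios["normo"], ratios["tachy"],
            dominant, coi_frac))
    return out


def percent_time(partitions: list[MinutePartition],
                 window: SubFeedWindow | None = None,
                 denominator_mode: str = "total",
                 subject_id: str = "") -> PercentTime:
    """Percent of minutes spent in each band over one window.

    ``denominator_mode='total'`` divides the dominant-minute counts by
    all whole minutes in the window; ``'classified'`` divides by the
    classified minutes only, so the three percentages always sum to 100.
    """
    if denominator_mode not in ("total", "classified"):
        raise ValueError(
            f"denominator_mode must be 'total' or 'classified', got "
            f"{denominator_mode!r}")
    if not partitions:
        raise ValueError("cannot compute percent time over zero minutes")
    counts = {b.name: sum(1 for p in partitions if p.dominant == b.name)
              for b in BANDS}
    n_classified = sum(counts.values())
    denom = len(partitions) if denominator_mode == "total" else n_classified
    if denom == 0:
        raise ValueError("no classified minutes in window")
    pct = {k: 100.0 * v / denom for k, v in counts.items()}
    return PercentTime(
        subject_id, window.label if window is not None else "",
        pct["brady"], pct["normo"], pct["tachy"],
        counts["brady"], counts["normo"], counts["tachy"],
        total_minutes=denom)


def phase_average_pct(per_window: dict[str, PercentTime],
                      allow_single: bool = False) -> dict[str, PercentTime]:
    """Average window-level percent-time into per-phase values (unweighted
    mean of the two windows of each phase, per band)."""
    out: dict[str, PercentTime] = {}
    for phase in ("pre", "during", "post"):
        pair = [per_window[k] for k in (f"{phase}1", f"{phase}2") if k in per_window]
        if not pair:
            raise ValueError(f"no windows available for phase {phase!r}")
        if len(pair) == 1 and not allow_single:
            raise ValueError(
                f"phase {phase!r} has only one window; pass allow_single=True "
                "to accept it")
        out[phase] = PercentTime(
            pair[0].subject_id, phase,
            float(np.mean([w.pct_brady for w in pair])),
            float(np.mean([w.pct_normo for w in pair])),
            float(np.mean([w.pct_tachy for w in pair])),
            sum(w.T_brady for w in pair), sum(w.T_normo for w in pair),
            sum(w.T_tachy for w in pair),
            total_minutes=sum(w.total_minutes for w in pair),
            n_windows=len(pair))
    return out
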