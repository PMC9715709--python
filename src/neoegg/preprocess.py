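"""Raw-data conditioning chain for cutaneous EGG.

Four steps, applied in order to the raw 2000-Hz voltage series:

1. decimation to 500 Hz by keeping every k-th sample,
2. 3rd-order polynomial detrend fitted over the whole recording,
3. subtraction of the fitted trend,
4. zero-phase 1-Hz low-pass (Butterworth order 3, forward-backward).

The keep-every-kth decimation deliberately applies no anti-alias filter:
the analysis band ends at 0.15 Hz and the subsequent 1-Hz low-pass makes
aliased slow-wave content negligible, so we favour fidelity to the
conventional decimation step over filter hygiene.  The polynomial is fit
against time rescaled to [-1, 1] to keep the normal equations
well-conditioned on multi-hour series.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal

from .recording import EggRecording

__all__ = ["downsample", "detrend_poly", "lowpass", "preprocess_chain"]


def downsample(rec: EggRecording, factor: int) -> EggRecording:
    """Keep every ``factor``-th sample starting at index 0.

    The sampling rate is divided by ``factor`` (2000 Hz with factor 4
    gives the conventional 500 Hz working rate).  ``factor`` must be a
    positive integer and must divide ``rec.fs`` exactly.
    """
    if not isinstance(factor, (int, np.integer)) or isinstance(factor, bool):
        raise TypeError(f"downsampling factor must be an integer, got {factor!r}")
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    new_fs = rec.fs / factor
    if abs(rec.fs / factor - round(rec.fs / factor)) > 1e-9 * rec.fs:
        raise ValueError(
            f"sampling rate {rec.fs} Hz is not divisible by factor {factor}")
    return rec.advance(rec.samples[::factor], fs=new_fs, stage_tag="downsampled")


def detrend_poly(rec: EggRecording, order: int = 3) -> EggRecording:
    """Subtract a least-squares polynomial trend fit over the entire recording.

    ``order=3`` reproduces the standard cubic detrend; ``order=0`` is mean
    removal.  The fit abscissa is time rescaled to [-1, 1].
    """
    n = len(rec.samples)
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if n <= order + 1:
        raise ValueError(
            f"recording of {n} samples too short for order-{order} detrend")
    t = np.linspace(-1.0, 1.0, n)
    coefs = npoly.polyfit(t, rec.samples, order)
    trend = npoly.polyval(t, coefs)
    return rec.advance(rec.samples - trend, stage_tag="detrended")


def lowpass(rec: EggRecording, cutoff_hz: float = 1.0, order: int = 3) -> EggRecording:
    """Zero-phase Butterworth low-pass (applied forward-backward).

    The forward-backward pass doubles the effective order and cancels the
    phase response, so slow-wave content below the cutoff passes without
    time shift.
    """
    nyq = rec.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return rec.advance(filtered, stage_tag="filtered")


def preprocess_chain(raw: EggRecording, downsample_factor: int = 4,
                     detrend_order: int = 3, cutoff_hz: float = 1.0) -> EggRecording:
    """Run the full conditioning chain: decimate, detrend, low-pass."""
    rec = downsample(raw, downsample_factor)
    rec = detrend_poly(rec, order=detrend_order)
    return lowpass(rec, cutoff_hz=cutoff_hz)
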