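"""Analytic continuous wavelet transform with cone-of-influence masking.

The transform is computed in the frequency domain: the signal's FFT is
multiplied by the wavelet's frequency response at each scale and inverse
transformed, which for analytic wavelets (support on positive
frequencies only) yields the complex coefficients directly.  Two wavelet
families are provided:

* ``morlet`` — analytic Morlet with centre frequency ω₀ = 6,
  ψ̂(ω) ∝ exp(−(ω − ω₀)²/2) for ω > 0;
* ``morse`` — generalized Morse wavelet with γ = 3, β = 20
  (time-bandwidth product P² = βγ = 60), ψ̂(ω) ∝ ω^β exp(−ω^γ).

Responses are L1-normalised (peak amplitude 2), so a unit-amplitude tone
produces coefficients of magnitude ≈ 1 at every frequency — power ratios
between bands are then directly comparable across the log-spaced grid.

The cone of influence (COI) marks coefficients within one e-folding time
of the wavelet's temporal envelope from either edge of the segment;
those cells are boundary-contaminated and are excluded from all
downstream averages.  The e-folding time is measured numerically from
the envelope of each family's time-domain wavelet, so the same rule
applies to both families.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as sfft

__all__ = ["CwtSpectrogram", "analytic_cwt", "WAVELET_FAMILIES"]

WAVELET_FAMILIES = ("morlet", "morse")

_MORLET_W0 = 6.0
_MORSE_GAMMA = 3.0
_MORSE_BETA = 20.0


def _freq_response(family: str, omega: np.ndarray) -> np.ndarray:
    """Wavelet frequency response at angular frequencies ``omega`` (>=0),
    for a wavelet whose envelope peaks at omega = 1 (unit peak frequency),
    L1-normalised to peak amplitude 2."""
    h = np.zeros_like(omega)
    pos = omega > 0
    if family == "morlet":
        # shift so the Gaussian peak sits at omega = 1
        h[pos] = 2.0 * np.exp(-0.5 * (_MORLET_W0 * (omega[pos] - 1.0)) ** 2)
    elif family == "morse":
        wp = (_MORSE_BETA / _MORSE_GAMMA) ** (1.0 / _MORSE_GAMMA)
        w = omega[pos] * wp
        log_h = (_MORSE_BETA * np.log(w) - w ** _MORSE_GAMMA
                 - (_MORSE_BETA / _MORSE_GAMMA) * (np.log(_MORSE_BETA / _MORSE_GAMMA) - 1.0))
        h[pos] = 2.0 * np.exp(log_h)
    else:
        raise ValueError(
            f"unknown wavelet family {family!r}; expected one of {WAVELET_FAMILIES}")
    return h


@lru_cache(maxsize=None)
def _efolding_cycles(family: str) -> float:
    """e-folding time of the wavelet's temporal envelope, in periods of its
    peak frequency.  Measured numerically from the inverse FFT of the
    frequency response at unit peak frequency."""
    fs, n = 64.0, 1 << 15
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    psi = np.fft.ifft(_freq_response(family, omega))
    env = np.abs(psi[: n // 2])          # t >= 0 half; envelope peaks at t = 0
    target = env[0] / np.e
    idx = int(np.argmax(env < target))
    # linear interpolation between the straddling samples
    t_hi, t_lo = idx / fs, (idx - 1) / fs
    e_hi, e_lo = env[idx], env[idx - 1]
    t_e = t_lo + (e_lo - target) / (e_lo - e_hi) * (t_hi - t_lo)
    # the response peaks at omega = 1 rad/s, i.e. peak frequency 1/(2*pi) Hz:
    # convert the e-folding time to periods of the peak frequency
    return float(t_e / (2 * np.pi))


@dataclass
class CwtSpectrogram:
    """CWT power on a log frequency grid, with the COI mask.

    ``power[i, j]`` is |coefficient|² at ``freqs_cpm[i]``, ``times_s[j]``;
    ``coi_mask[i, j]`` is True where the cell lies inside the cone of
    influence (boundary-contaminated, to be excluded).
    """

    times_s: np.ndarray
    freqs_cpm: np.ndarray
    power: np.ndarray
    coi_mask: np.ndarray
    wavelet: str = "morlet"

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs_cpm), len(self.times_s)):
            raise ValueError("power grid shape mismatch")
        if np.any(self.power < 0):
            raise ValueError("CWT power must be non-negative")


@lru_cache(maxsize=8)
def _response_matrix(wavelet: str, npad: int, fs: float, lo_cpm: float,
                     hi_cpm: float, voices: int) -> np.ndarray:
    """Stack of wavelet frequency responses, one row per grid frequency.
    Windows of equal length share this matrix, so it is cached."""
    freqs_hz = _log_freq_grid(lo_cpm, hi_cpm, voices) / 60.0
    omega = 2 * np.pi * sfft.fftfreq(npad, d=1.0 / fs)
    return _freq_response(wavelet, omega[None, :] / (2 * np.pi * freqs_hz[:, None]))


def _log_freq_grid(lo_cpm: float, hi_cpm: float, voices: int) -> np.ndarray:
    n_octaves = np.log2(hi_cpm / lo_cpm)
    k = np.arange(int(np.ceil(n_octaves * voices)) + 1)
    freqs = lo_cpm * 2.0 ** (k / voices)
    if freqs[-1] < hi_cpm:
        freqs = np.append(freqs, hi_cpm)
    return freqs


def analytic_cwt(x: np.ndarray, fs: float, wavelet: str = "morlet",
                 lo_cpm: float = 0.5, hi_cpm: float = 15.0,
                 voices: int = 12) -> CwtSpectrogram:
    """Continuous wavelet transform power of ``x`` on a log frequency grid.

    Parameters
    ----------
    x
        Real signal, already band-limited to the gastric range.
    fs
        Sampling rate in Hz (a few Hz suffices for sub-0.25-Hz content).
    wavelet
        ``'morlet'`` or ``'morse'``.
    lo_cpm, hi_cpm
        Frequency grid span in cycles per minute.
    voices
        Voices per octave (grid density).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("signal too short for a wavelet transform")
    freqs_cpm = _log_freq_grid(lo_cpm, hi_cpm, voices)
    freqs_hz = freqs_cpm / 60.0

    t_total = n / fs
    cycles = _efolding_cycles(wavelet)
    coi_time_s = cycles / freqs_hz       # e-folding time per row
    if np.all(2 * coi_time_s.min() >= t_total):
        raise ValueError(
            f"segment of {t_total:.0f} s lies entirely inside the cone of "
            "influence at every analysed frequency")

    npad = sfft.next_fast_len(int(n * 1.5))
    xf = sfft.fft(x, npad)
    h = _response_matrix(wavelet, npad, fs, lo_cpm, hi_cpm, voices)
    w = sfft.ifft(xf[None, :] * h, axis=1, workers=1)[:, :n]
    power = np.abs(w) ** 2

    times = np.arange(n) / fs
    dist_edge = np.minimum(times, (n - 1) / fs - times)
    coi_mask = dist_edge[None, :] < coi_time_s[:, None]

    return CwtSpectrogram(times_s=times, freqs_cpm=freqs_cpm, power=power,
                          coi_mask=coi_mask, wavelet=wavelet)
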