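"""Gastric rhythm frequency bands.

Gastric myoelectrical activity is conventionally partitioned into three
rhythm bands on the cycles-per-minute (cpm) axis: bradygastria
[0.5, 2) cpm, normogastria [2, 4) cpm (the healthy ~3 cpm rhythm), and
tachygastria [4, 9) cpm.  All intervals are half-open so the three bands
tile [0.5, 9) cpm without gap or overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

CPM_PER_HZ = 60.0


@dataclass(frozen=True)
class RhythmBand:
    """One gastric rhythm band, half-open in frequency: lo <= f < hi."""

    name: str
    lo_cpm: float
    hi_cpm: float

    @property
    def lo_hz(self) -> float:
        return self.lo_cpm / CPM_PER_HZ

    @property
    def hi_hz(self) -> float:
        return self.hi_cpm / CPM_PER_HZ

    def contains_cpm(self, f_cpm: float) -> bool:
        return self.lo_cpm <= f_cpm < self.hi_cpm

    def contains_hz(self, f_hz: float) -> bool:
        return self.lo_hz <= f_hz < self.hi_hz


BRADY = RhythmBand("brady", 0.5, 2.0)
NORMO = RhythmBand("normo", 2.0, 4.0)
TACHY = RhythmBand("tachy", 4.0, 9.0)

#: The three gastric rhythm bands in ascending frequency order.
BANDS: tuple[RhythmBand, ...] = (BRADY, NORMO, TACHY)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: Full gastric range spanned by the three bands, in cpm.
GASTRIC_LO_CPM = BRADY.lo_cpm
GASTRIC_HI_CPM = TACHY.hi_cpm


def band_by_name(name: str) -> RhythmBand:
    for b in BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown rhythm band {name!r}; expected one of {BAND_NAMES}")


def band_of_frequency(f_cpm: float) -> str | None:
    """Name of the band containing ``f_cpm``, or None outside [0.5, 9)."""
    for b in BANDS:
        if b.contains_cpm(f_cpm):
            return b.name
    return None
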