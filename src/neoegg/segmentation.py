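"""Sub-feeding window derivation.

A 6-h neonatal EGG session brackets two consecutive enteral feeds.  Each
feed defines a During window equal to the actual administration interval,
and the surrounding time yields Pre and Post windows of nominally 30 min:

* pre1 — the 30 min immediately before feed 1 (truncated at recording start);
* during1 / during2 — the feed events themselves;
* the gap between the feeds is split at its midpoint: post1 occupies the
  first half adjacent to the end of feed 1, pre2 the second half adjacent
  to the start of feed 2, each capped at 30 min in the default
  ``halves_mode='capped'`` (``'full'`` keeps whole halves);
* post2 — the 30 min after feed 2 (truncated at recording end).

Windows shorter than the nominal 30 min are kept and flagged
``truncated``.  All intervals are half-open minutes from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass

from .recording import EggRecording

NOMINAL_MIN = 30.0

WINDOW_LABELS = ("pre1", "during1", "post1", "pre2", "during2", "post2")

#: Window label -> feeding phase.
PHASE_OF = {"pre1": "pre", "pre2": "pre", "during1": "during",
            "during2": "during", "post1": "post", "post2": "post"}


@dataclass(frozen=True)
class FeedEvent:
    """One enteral feed administration interval, minutes from recording start."""

    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not self.end_min > self.start_min:
            raise ValueError(
                f"feed must have positive duration, got [{self.start_min}, {self.end_min})")

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class SubFeedWindow:
    """One analysis window, half-open [start_min, end_min)."""

    label: str
    start_min: float
    end_min: float
    truncated: bool = False

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min

    @property
    def phase(self) -> str:
        return PHASE_OF[self.label]


def _flank(anchor: float, limit: float, side: str, label: str) -> SubFeedWindow:
    """A <=30-min window hugging ``anchor`` on the given side, bounded by limit."""
    if side == "before":
        start = max(limit, anchor - NOMINAL_MIN)
        win = SubFeedWindow(label, start, anchor, truncated=(anchor - start) < NOMINAL_MIN)
    else:
        end = min(limit, anchor + NOMINAL_MIN)
        win = SubFeedWindow(label, anchor, end, truncated=(end - anchor) < NOMINAL_MIN)
    if win.duration_min <= 0:
        raise ValueError(f"window {label} has non-positive duration")
    return win


def segment(feeds: list[FeedEvent], recording_duration_min: float,
            halves_mode: str = "capped") -> list[SubFeedWindow]:
    """Derive the six sub-feeding windows from two feed events.

    Parameters
    ----------
    feeds
        Exactly two non-overlapping, time-ordered feed events, both inside
        the recording.
    recording_duration_min
        Total recording length in minutes.
    halves_mode
        How to place post1/pre2 inside the inter-feed gap. ``'capped'``
        (default) caps each at 30 min adjacent to its feed boundary;
        ``'full'`` uses the complete halves of the gap.

    Returns
    -------
    list of six SubFeedWindow, in chronological order.
    """
    if len(feeds) != 2:
        raise ValueError(
            f"exactly two feeds are required per session, got {len(feeds)}")
    f1, f2 = feeds
    if not f1.end_min <= f2.start_min:
        raise ValueError("feed events must be time-ordered and non-overlapping")
    if f1.start_min < 0 or f2.end_min > recording_duration_min:
        raise ValueError("feed events must lie inside the recording")
    gap = f2.start_min - f1.end_min
    if gap <= 0:
        raise ValueError(f"inter-feed gap must be positive, got {gap} min")
    if halves_mode not in ("capped", "full"):
        raise ValueError(f"halves_mode must be 'capped' or 'full', got {halves_mode!r}")

    mid = f1.end_min + gap / 2.0

    pre1 = _flank(f1.start_min, 0.0, "before", "pre1")
    during1 = SubFeedWindow("during1", f1.start_min, f1.end_min)
    during2 = SubFeedWindow("during2", f2.start_min, f2.end_min)
    post2 = _flank(f2.end_min, recording_duration_min, "after", "post2")

    if halves_mode == "capped":
        post1 = _flank(f1.end_min, mid, "after", "post1")
        pre2 = _flank(f2.start_min, mid, "before", "pre2")
    else:
        half = gap / 2.0
        post1 = SubFeedWindow("post1", f1.end_min, mid, truncated=half < NOMINAL_MIN)
        pre2 = SubFeedWindow("pre2", mid, f2.start_min, truncated=half < NOMINAL_MIN)

    return [pre1, during1, post1, pre2, during2, post2]


def extract(rec: EggRecording, window: SubFeedWindow) -> EggRecording:
    """Slice the samples of a sub-feeding window out of a recording.

    Minute boundaries are converted to sample indices by flooring; the
    slice is half-open, so a 30-min window at 500 Hz yields exactly
    900,000 samples.
    """
    i0 = int(window.start_min * 60 * rec.fs)
    i1 = int(window.end_min * 60 * rec.fs)
    if i0 < 0 or i1 > len(rec.samples):
        raise ValueError(
            f"window {window.label} [{window.start_min}, {window.end_min}) min "
            f"lies outside the {rec.duration_min:.1f}-min recording")
    if i1 <= i0:
        raise ValueError(f"window {window.label} is empty")
    out = EggRecording(rec.samples[i0:i1], rec.fs, subject_id=rec.subject_id,
                       t0=rec.t0 + i0 / rec.fs, stage_tag=rec.stage_tag)
    return out
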