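"""Synthetic neonatal EGG cohort with known ground truth.

No public neonatal EGG dataset exists, so every analysis stage is
exercised on simulated recordings whose rhythm content is known exactly.
The signal model is deliberately simple — one active gastric rhythm at a
time, not a mechanistic stomach model:

* a three-state Markov chain over {brady, normo, tachy} switches on
  whole-minute boundaries (so the true per-minute label is unambiguous);
  its stationary distribution is the configured band occupancy and the
  nominal mean dwell time sets the switching rate;
* the active band contributes a single sinusoid whose frequency is drawn
  uniformly inside the band and held for the dwell; phase is continuous
  across switches;
* amplitude depends on band and on feeding phase: a during-feed gain
  that increases with gestational age injects the maturational trend the
  analysis must recover;
* broadband Gaussian noise plus sparse 2–5-s high-amplitude
  low-frequency motion-artifact bursts (artifacts are never removed
  downstream, mirroring bedside practice, so the spectral estimators
  must tolerate them).

Cohort generation stratifies gestational age (GA) into early (< 29 wk),
mid (29–33 wk) and term (>= 37 wk) groups — the 34–36-week range is
never generated — and interpolates occupancy and feed gain continuously
in GA between the group anchors, so the injected trends are smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BANDS, band_by_name
from .recording import EggRecording
from .segmentation import FeedEvent, SubFeedWindow, segment

__all__ = ["SubjectSpec", "SimulationParams", "GroundTruth", "ga_group_of",
           "GA_RANGES", "simulate_recording", "simulate_cohort",
           "DEFAULT_N_PER_GROUP"]

#: GA sampling range per group, weeks (term capped at 41 for simulation).
GA_RANGES = {"early": (24.0, 29.0), "mid": (29.0, 34.0), "term": (37.0, 41.0)}

#: Study-design group sizes: early / mid / term.
DEFAULT_N_PER_GROUP = (25, 22, 4)

GROUPS = ("early", "mid", "term")


def ga_group_of(ga_weeks: float) -> str:
    """Deterministic GA stratification; 34–36.9 weeks is excluded by design."""
    if ga_weeks < 29:
        return "early"
    if ga_weeks < 34:
        return "mid"
    if ga_weeks >= 37:
        return "term"
    raise ValueError(
        f"gestational age {ga_weeks} weeks falls in the excluded 34–36.9 range")


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated neonate."""

    subject_id: str
    ga_weeks: float
    seed: int

    @property
    def ga_group(self) -> str:
        return ga_group_of(self.ga_weeks)


@dataclass
class SimulationParams:
    """Generator configuration.

    Occupancies are the stationary probabilities of the minute-quantised
    rhythm chain per GA group, ordered (brady, normo, tachy); the normo
    occupancy rises with GA — that rise is the ground-truth maturational
    trend.  Amplitudes are in µV; neonatal EGG amplitude is not well
    standardised, so the defaults (tens of µV slow wave over ~20 µV
    noise) are plausible placeholders and fully configurable.
    """

    fs_raw: float = 2000.0
    duration_min: float = 360.0
    feed_times: list[tuple[float, float]] = field(
        default_factory=lambda: [(90.0, 120.0), (270.0, 300.0)])
    occupancy_by_band: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "early": (0.45, 0.25, 0.30),
            "mid": (0.33, 0.45, 0.22),
            "term": (0.16, 0.70, 0.14),
        })
    mean_dwell_min: float = 4.0
    amp_by_band: dict[str, float] = field(
        default_factory=lambda: {"brady": 60.0, "normo": 80.0, "tachy": 40.0})
    #: during-feed amplitude gain: 1 + slope * (ga_weeks - 24)
    feed_gain_slope: float = 0.05
    noise_sd: float = 20.0
    artifact_rate_per_h: float = 4.0
    artifact_amp: float = 300.0
    artifact_duration_s: tuple[float, float] = (2.0, 5.0)

    def validate(self) -> None:
        if self.fs_raw < 4:
            raise ValueError("fs_raw must be at least 4 Hz")
        if self.duration_min < 10:
            raise ValueError("recording must be at least 10 min long")
        prev_end = -1.0
        for start, end in self.feed_times:
            if not 0 <= start < end <= self.duration_min:
                raise ValueError(
                    f"feed ({start}, {end}) min lies outside the "
                    f"{self.duration_min}-min recording")
            if start < prev_end:
                raise ValueError("feed windows overlap")
            prev_end = end
        for g, occ in self.occupancy_by_band.items():
            if abs(sum(occ) - 1.0) > 1e-9 or any(p < 0 for p in occ):
                raise ValueError(f"occupancy for {g!r} is not a distribution")
        normos = [self.occupancy_by_band[g][1] for g in GROUPS
                  if g in self.occupancy_by_band]
        if len(normos) == 3 and not (normos[0] <= normos[1] <= normos[2]):
            raise ValueError(
                "normogastria occupancy must not decrease from early to "
                "mid to term")
        if any(a < 0 for a in self.amp_by_band.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0 or self.artifact_rate_per_h < 0 or self.artifact_amp < 0:
            raise ValueError("noise and artifact parameters must be non-negative")
        if self.mean_dwell_min < 1:
            raise ValueError("mean dwell must be at least 1 min")


@dataclass
class GroundTruth:
    """Realised simulation state: the oracle for downstream stages."""

    minute_band_labels: list[str]
    minute_freq_cpm: np.ndarray
    true_amp_profile: np.ndarray          # µV per minute
    #: window label -> {band name -> true % of the window's minutes}
    true_percent_time: dict[str, dict[str, float]]

    def percent_over(self, minutes: range) -> dict[str, float]:
        labels = [self.minute_band_labels[m] for m in minutes]
        return {b.name: 100.0 * labels.count(b.name) / len(labels)
                for b in BANDS}


def _occupancy_for(params: SimulationParams, group: str) -> np.ndarray:
    occ = np.asarray(params.occupancy_by_band[group], dtype=float)
    return occ / occ.sum()


def _markov_minutes(rng: np.random.Generator, n_minutes: int,
                    occupancy: np.ndarray, mean_dwell_min: float) -> np.ndarray:
    """Minute-quantised chain: stay with prob 1 - 1/dwell, else redraw the
    state from the stationary distribution (so the stationary law is the
    occupancy exactly; the realised dwell is slightly above nominal because
    a redraw may return the same state)."""
    a = 1.0 / mean_dwell_min
    states = np.empty(n_minutes, dtype=int)
    states[0] = rng.choice(3, p=occupancy)
    jumps = rng.random(n_minutes - 1) < a
    redraws = rng.choice(3, p=occupancy, size=n_minutes - 1)
    for m in range(1, n_minutes):
        states[m] = redraws[m - 1] if jumps[m - 1] else states[m - 1]
    return states


def simulate_recording(spec: SubjectSpec, params: SimulationParams
                       ) -> tuple[EggRecording, GroundTruth]:
    """Generate one recording and its ground truth.

    Bit-identical output for identical (spec, params).
    """
    params.validate()
    rng = np.random.default_rng(spec.seed)
    fs = params.fs_raw
    n_minutes = int(np.floor(params.duration_min))
    spm = int(round(60 * fs))             # samples per minute

    occupancy = _occupancy_for(params, spec.ga_group)
    states = _markov_minutes(rng, n_minutes, occupancy, params.mean_dwell_min)

    # per-dwell frequency, drawn uniformly inside the active band
    freqs_cpm = np.empty(n_minutes)
    for m in range(n_minutes):
        if m == 0 or states[m] != states[m - 1]:
            band = BANDS[states[m]]
            f = rng.uniform(band.lo_cpm, band.hi_cpm)
        freqs_cpm[m] = f

    feed_gain = 1.0 + params.feed_gain_slope * (spec.ga_weeks - 24.0)
    minute_in_feed = np.zeros(n_minutes, dtype=bool)
    for start, end in params.feed_times:
        minute_in_feed[int(np.floor(start)):int(np.ceil(end))] = True

    amps = np.array([params.amp_by_band[BANDS[s].name] for s in states])
    amps[minute_in_feed] *= feed_gain

    # slow wave with phase continuity across minute boundaries
    n = n_minutes * spm
    t_local = np.arange(spm) / fs
    x = np.empty(n)
    phase = 0.0
    for m in range(n_minutes):
        w = 2 * np.pi * freqs_cpm[m] / 60.0
        x[m * spm:(m + 1) * spm] = amps[m] * np.sin(phase + w * t_local)
        phase += w * 60.0

    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, n)

    n_bursts = rng.poisson(params.artifact_rate_per_h * n_minutes / 60.0)
    for _ in range(n_bursts):
        dur = rng.uniform(*params.artifact_duration_s)
        start_s = rng.uniform(0.0, n_minutes * 60.0 - dur)
        i0 = int(start_s * fs)
        k = int(dur * fs)
        burst_t = np.arange(k) / fs
        # Hann-windowed low-frequency lobe, random polarity
        lobe = np.sin(np.pi * burst_t / dur) ** 2
        sign = rng.choice([-1.0, 1.0])
        x[i0:i0 + k] += sign * params.artifact_amp * lobe

    rec = EggRecording(x, fs, subject_id=spec.subject_id, stage_tag="raw")

    labels = [BANDS[s].name for s in states]
    true_pct: dict[str, dict[str, float]] = {}
    if len(params.feed_times) == 2:
        windows = segment([FeedEvent(s, e) for s, e in params.feed_times],
                          params.duration_min)
        for w in windows:
            m0, m1 = int(np.floor(w.start_min)), int(np.floor(w.end_min))
            m1 = min(m1, n_minutes)
            if m1 > m0:
                truth_w = GroundTruth(labels, freqs_cpm, amps, {})
                true_pct[w.label] = truth_w.percent_over(range(m0, m1))

    truth = GroundTruth(labels, freqs_cpm, amps, true_pct)
    return rec, truth


def _interp_occupancy(params: SimulationParams, ga_weeks: float
                      ) -> tuple[float, float, float]:
    """Occupancy at a given GA, interpolated linearly between the group
    anchor points (group mid-range GA) and renormalised."""
    anchors_ga = [np.mean(GA_RANGES[g]) for g in GROUPS]
    occ = np.array([
        np.interp(ga_weeks, anchors_ga,
                  [params.occupancy_by_band[g][i] for g in GROUPS])
        for i in range(3)])
    occ /= occ.sum()
    return tuple(occ)


def simulate_cohort(n_per_group: tuple[int, int, int] = DEFAULT_N_PER_GROUP,
                    params: SimulationParams | None = None,
                    master_seed: int = 0
                    ) -> tuple[list[tuple[SubjectSpec, EggRecording, GroundTruth]],
                               pd.DataFrame]:
    """Generate a stratified cohort of recordings plus a metadata table.

    GA is drawn uniformly within each group's range; each subject's
    occupancy (and thus the normogastria trend) is interpolated
    continuously in GA so the injected slopes are smooth rather than
    stepped.  Fully reproducible from ``master_seed``.
    """
    if params is None:
        params = SimulationParams()
    if any(c < 0 for c in n_per_group):
        raise ValueError("group counts must be non-negative")
    params.validate()

    master = np.random.default_rng(master_seed)
    subjects: list[tuple[SubjectSpec, EggRecording, GroundTruth]] = []
    rows = []
    idx = 0
    for group, count in zip(GROUPS, n_per_group):
        lo, hi = GA_RANGES[group]
        for _ in range(count):
            ga = float(master.uniform(lo, hi))
            seed = int(master.integers(0, 2 ** 31 - 1))
            spec = SubjectSpec(f"S{idx:03d}", ga, seed)
            occ = _interp_occupancy(params, ga)
            subj_params = replace(
                params, occupancy_by_band={**params.occupancy_by_band,
                                           group: occ})
            rec, truth = simulate_recording(spec, subj_params)
            subjects.append((spec, rec, truth))
            rows.append({"subject_id": spec.subject_id, "ga_weeks": ga,
                         "ga_group": group, "seed": seed})
            idx += 1
    table = pd.DataFrame(rows, columns=["subject_id", "ga_weeks",
                                        "ga_group", "seed"])
    return subjects, table
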