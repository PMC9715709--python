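"""Gastric band-pass, minute partition, and percent time in band."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoegg.bands import BANDS
from neoegg.cwt import CwtSpectrogram
from neoegg.recording import EggRecording
from neoegg.rhythm import (MinutePartition, bandpass_gastric, cwt_power,
                           minute_band_ratios, percent_time,
                           phase_average_pct)
from neoegg.segmentation import SubFeedWindow
from tests.conftest import make_tone


class TestBandpass:
    def test_3cpm_tone_passes(self):
        rec = make_tone(3.0, fs=8.0)
        out = bandpass_gastric(rec)
        core = slice(len(rec) // 6, -len(rec) // 6)
        gain = np.sqrt((out.samples[core] ** 2).mean()
                       / (rec.samples[core] ** 2).mean())
        assert 0.95 <= gain <= 1.05

    def test_dc_removed(self):
        rec = EggRecording(np.full(8 * 1800, 5.0), 8.0, stage_tag="filtered")
        out = bandpass_gastric(rec)
        assert np.abs(out.samples).max() < 0.05

    def test_very_slow_drift_attenuated(self):
        rec = make_tone(0.2, duration_min=60.0, fs=8.0)
        out = bandpass_gastric(rec)
        core = slice(len(rec) // 6, -len(rec) // 6)
        gain = np.sqrt((out.samples[core] ** 2).mean()
                       / (rec.samples[core] ** 2).mean())
        assert gain < 0.2

    def test_fast_oscillation_attenuated(self):
        rec = make_tone(30.0, fs=8.0)
        out = bandpass_gastric(rec)
        gain = np.sqrt((out.samples ** 2).mean() / (rec.samples ** 2).mean())
        assert gain < 0.1

    def test_band_beyond_nyquist_rejected(self):
        rec = make_tone(3.0, fs=0.4)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_gastric(rec, hi_cpm=15.0)


class TestMinutePartition:
    def test_interior_minutes_of_tone_are_normo(self, tone_3cpm):
        sg = cwt_power(tone_3cpm)
        parts = minute_band_ratios(sg)
        interior = [p for p in parts if p.coi_fraction == 0]
        assert interior and all(p.dominant == "normo" for p in interior)

    def test_fully_masked_minute_unclassified(self, tone_3cpm):
        sg = cwt_power(tone_3cpm)
        sg.coi_mask[:, :] = True
        parts = minute_band_ratios(sg)
        assert all(p.dominant == "unclassified" for p in parts)

    def test_one_dominant_label_per_classified_minute(self, tone_3cpm):
        parts = minute_band_ratios(cwt_power(tone_3cpm))
        for p in parts:
            if p.dominant != "unclassified":
                ratios = p.ratios()
                finite = {k: v for k, v in ratios.items() if np.isfinite(v)}
                assert p.dominant in finite
                assert finite[p.dominant] == max(finite.values())

    def test_tie_breaks_toward_lower_band(self):
        # two equal-ratio bands constructed by hand
        times = np.arange(0, 120, 0.25)
        freqs = np.array([1.0, 3.0, 6.0])
        power = np.ones((3, len(times)))
        power[2] *= 0.5
        sg = CwtSpectrogram(times, freqs, power,
                            np.zeros_like(power, dtype=bool))
        parts = minute_band_ratios(sg)
        assert all(p.dominant == "brady" for p in parts)

    def test_partial_trailing_minute_dropped(self, tone_3cpm):
        sg = cwt_power(tone_3cpm)
        n_full = int(tone_3cpm.duration_min)
        assert len(minute_band_ratios(sg)) == n_full
        # 30.5-min recording still yields 30 whole minutes
        rec = make_tone(3.0, duration_min=30.5)
        assert len(minute_band_ratios(cwt_power(rec))) == 30

    @pytest.mark.parametrize("wavelet", ["morlet", "morse"])
    @pytest.mark.parametrize("freq_cpm,band", [(1.0, "brady"), (3.0, "normo"),
                                               (6.0, "tachy")])
    def test_tone_classified_to_containing_band(self, wavelet, freq_cpm, band):
        rec = make_tone(freq_cpm, duration_min=40.0)
        parts = minute_band_ratios(cwt_power(rec, wavelet=wavelet))
        valid = [p for p in parts if p.coi_fraction == 0]
        hits = sum(p.dominant == band for p in valid)
        assert hits / len(valid) >= 0.95


class TestPercentTime:
    def _parts(self, labels):
        return [MinutePartition(i, 1.0, 1.0, 1.0, lab, 0.0)
                for i, lab in enumerate(labels)]

    def test_simple_arithmetic(self):
        parts = self._parts(["normo"] * 18 + ["brady"] * 12)
        pt = percent_time(parts, SubFeedWindow("pre1", 0, 30))
        assert (pt.pct_normo, pt.pct_brady, pt.pct_tachy) == (60.0, 40.0, 0.0)
        assert pt.total_minutes == 30

    def test_all_one_band(self):
        pt = percent_time(self._parts(["tachy"] * 10))
        assert (pt.pct_brady, pt.pct_normo, pt.pct_tachy) == (0.0, 0.0, 100.0)

    def test_unclassified_minute_total_vs_classified_mode(self):
        parts = self._parts(["normo"] * 9 + ["unclassified"])
        total = percent_time(parts, denominator_mode="total")
        assert total.pct_normo == pytest.approx(90.0)
        classified = percent_time(parts, denominator_mode="classified")
        assert classified.pct_normo == pytest.approx(100.0)

    def test_zero_minutes_rejected(self):
        with pytest.raises(ValueError, match="zero minutes"):
            percent_time([])

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="denominator_mode"):
            percent_time(self._parts(["normo"]), denominator_mode="both")

    @given(st.lists(st.sampled_from(["brady", "normo", "tachy",
                                     "unclassified"]),
                    min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_classified_mode_conserves_100(self, labels):
        parts = self._parts(labels)
        if all(lab == "unclassified" for lab in labels):
            with pytest.raises(ValueError):
                percent_time(parts, denominator_mode="classified")
        else:
            pt = percent_time(parts, denominator_mode="classified")
            assert pt.pct_brady + pt.pct_normo + pt.pct_tachy == \
                pytest.approx(100.0, abs=1e-9)
            total = percent_time(parts, denominator_mode="total")
            assert (total.pct_brady + total.pct_normo + total.pct_tachy
                    <= 100.0 + 1e-9)


class TestPhaseAveragePct:
    def _pt(self, phase, b, n, t):
        from neoegg.rhythm import PercentTime
        return PercentTime("s", phase, b, n, t, 0, 0, 0, 30)

    def test_unweighted_mean(self):
        wins = {"pre1": self._pt("pre1", 60, 40, 0),
                "pre2": self._pt("pre2", 40, 40, 20),
                "during1": self._pt("during1", 0, 100, 0),
                "during2": self._pt("during2", 0, 100, 0),
                "post1": self._pt("post1", 10, 80, 10),
                "post2": self._pt("post2", 30, 60, 10)}
        out = phase_average_pct(wins)
        assert (out["pre"].pct_brady, out["pre"].pct_normo,
                out["pre"].pct_tachy) == (50.0, 40.0, 10.0)
        assert out["during"].pct_normo == 100.0

    def test_missing_window_needs_flag(self):
        wins = {"pre1": self._pt("pre1", 60, 40, 0),
                "during1": self._pt("during1", 0, 100, 0),
                "during2": self._pt("during2", 0, 100, 0),
                "post1": self._pt("post1", 10, 80, 10),
                "post2": self._pt("post2", 30, 60, 10)}
        with pytest.raises(ValueError, match="allow_single"):
            phase_average_pct(wins)
        out = phase_average_pct(wins, allow_single=True)
        assert out["pre"].pct_brady == 60.0
        assert out["pre"].n_windows == 1
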