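"""Cohort simulator: determinism, ground truth, and injected trends."""

import numpy as np
import pytest

from neoegg.bands import BANDS, NORMO, band_of_frequency
from neoegg.synthetic import (GA_RANGES, SimulationParams, SubjectSpec,
                              ga_group_of, simulate_cohort, simulate_recording)


def quiet_params(**kw):
    base = dict(fs_raw=8.0, duration_min=30.0, feed_times=[(10.0, 15.0)],
                noise_sd=0.0, artifact_rate_per_h=0.0)
    base.update(kw)
    return SimulationParams(**base)


class TestGaStratification:
    @pytest.mark.parametrize("ga,group", [(24.0, "early"), (28.9, "early"),
                                          (29.0, "mid"), (33.5, "mid"),
                                          (37.0, "term"), (41.0, "term")])
    def test_groups(self, ga, group):
        assert ga_group_of(ga) == group

    @pytest.mark.parametrize("ga", [34.0, 35.5, 36.9])
    def test_excluded_range_rejected(self, ga):
        with pytest.raises(ValueError, match="excluded"):
            ga_group_of(ga)


class TestSimulateRecording:
    def test_determinism_bit_identical(self):
        spec = SubjectSpec("A", 30.0, 99)
        params = SimulationParams(fs_raw=8.0, duration_min=30.0,
                                  feed_times=[(10.0, 15.0)])
        r1, t1 = simulate_recording(spec, params)
        r2, t2 = simulate_recording(spec, params)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert t1.minute_band_labels == t2.minute_band_labels

    def test_degenerate_chain_pure_normo_tone(self):
        params = quiet_params(occupancy_by_band={
            g: (0.0, 1.0, 0.0) for g in ("early", "mid", "term")})
        rec, truth = simulate_recording(SubjectSpec("A", 30.0, 1), params)
        assert all(lab == "normo" for lab in truth.minute_band_labels)
        assert all(NORMO.contains_cpm(f) for f in truth.minute_freq_cpm)

    def test_signal_length(self):
        params = quiet_params()
        rec, _ = simulate_recording(SubjectSpec("A", 30.0, 1), params)
        assert len(rec) == 30 * 60 * 8
        assert rec.fs == 8.0

    def test_minute_labels_match_bandlimited_rms_argmax(self):
        # occupancy consistency: with zero noise the per-minute argmax of
        # band-limited RMS power recovers the true label
        from scipy import signal as sg
        params = quiet_params(duration_min=120.0, feed_times=[(30.0, 60.0)])
        hits = total = 0
        for seed in range(5):
            rec, truth = simulate_recording(SubjectSpec("A", 27.0, seed),
                                            params)
            spm = int(60 * rec.fs)
            band_sig = {}
            for b in BANDS:
                sos = sg.butter(4, [b.lo_hz, b.hi_hz], btype="band",
                                fs=rec.fs, output="sos")
                band_sig[b.name] = sg.sosfiltfilt(sos, rec.samples)
            for m, lab in enumerate(truth.minute_band_labels):
                sl = slice(m * spm, (m + 1) * spm)
                rms = {name: float((x[sl] ** 2).mean())
                       for name, x in band_sig.items()}
                hits += max(rms, key=rms.get) == lab
                total += 1
        assert hits / total >= 0.99

    def test_ground_truth_percent_time_sums_to_100(self):
        params = SimulationParams(fs_raw=8.0, duration_min=216.0,
                                  feed_times=[(30.0, 60.0), (156.0, 186.0)])
        _, truth = simulate_recording(SubjectSpec("A", 30.0, 3), params)
        assert len(truth.true_percent_time) == 6
        for window, pct in truth.true_percent_time.items():
            assert sum(pct.values()) == pytest.approx(100.0)

    def test_frequency_always_inside_labelled_band(self):
        params = quiet_params(duration_min=120.0, feed_times=[(30.0, 60.0)])
        _, truth = simulate_recording(SubjectSpec("A", 40.0, 11), params)
        for lab, f in zip(truth.minute_band_labels, truth.minute_freq_cpm):
            assert band_of_frequency(f) == lab

    def test_stationary_occupancy_recovered(self):
        # long-run minute fractions converge to the configured occupancy
        occ = {g: (1 / 3, 1 / 3, 1 / 3) for g in ("early", "mid", "term")}
        params = quiet_params(duration_min=360.0, feed_times=[(90.0, 120.0)],
                              occupancy_by_band=occ, mean_dwell_min=5.0)
        fractions = []
        for seed in range(50):
            _, truth = simulate_recording(SubjectSpec("A", 30.0, seed), params)
            labs = truth.minute_band_labels
            fractions.append([labs.count(b.name) / len(labs) for b in BANDS])
        mean_frac = np.mean(fractions, axis=0)
        # SE of the mean over 50 six-hour chains; dwell correlation inflates
        # the naive binomial SE by roughly sqrt(2 * dwell)
        se = np.sqrt((1 / 3) * (2 / 3) / (50 * 360)) * np.sqrt(2 * 5.0)
        np.testing.assert_allclose(mean_frac, 1 / 3, atol=3 * se)

    @pytest.mark.parametrize("bad_kw,msg", [
        (dict(duration_min=5.0), "10 min"),
        (dict(feed_times=[(10.0, 40.0)], duration_min=30.0), "outside"),
        (dict(feed_times=[(5.0, 15.0), (10.0, 20.0)]), "overlap"),
        (dict(fs_raw=2.0), "4 Hz"),
    ])
    def test_invalid_configuration_rejected(self, bad_kw, msg):
        params = quiet_params(**bad_kw)
        with pytest.raises(ValueError, match=msg):
            simulate_recording(SubjectSpec("A", 30.0, 1), params)

    def test_non_monotone_normo_occupancy_rejected(self):
        params = quiet_params(occupancy_by_band={
            "early": (0.2, 0.6, 0.2), "mid": (0.4, 0.3, 0.3),
            "term": (0.2, 0.7, 0.1)})
        with pytest.raises(ValueError, match="not decrease"):
            simulate_recording(SubjectSpec("A", 30.0, 1), params)


class TestSimulateCohort:
    def test_default_design_has_51_subjects(self):
        params = quiet_params()
        subjects, table = simulate_cohort((25, 22, 4), params, master_seed=7)
        assert len(subjects) == 51
        counts = table["ga_group"].value_counts()
        assert counts["early"] == 25 and counts["mid"] == 22 \
            and counts["term"] == 4

    def test_single_term_subject(self):
        subjects, table = simulate_cohort((0, 0, 1), quiet_params(),
                                          master_seed=1)
        assert len(subjects) == 1
        assert table.iloc[0]["ga_group"] == "term"
        assert table.iloc[0]["ga_weeks"] >= 37

    def test_ga_within_group_ranges(self):
        _, table = simulate_cohort((5, 5, 2), quiet_params(), master_seed=3)
        for _, row in table.iterrows():
            lo, hi = GA_RANGES[row["ga_group"]]
            assert lo <= row["ga_weeks"] < hi

    def test_reproducible_from_master_seed(self):
        s1, t1 = simulate_cohort((2, 2, 1), quiet_params(), master_seed=5)
        s2, t2 = simulate_cohort((2, 2, 1), quiet_params(), master_seed=5)
        assert t1.equals(t2)
        for (a, ra, _), (b, rb, _) in zip(s1, s2):
            assert a == b
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_normo_occupancy_trend_in_truth(self):
        # the injected trend: term truths spend more minutes in normo
        params = quiet_params(duration_min=120.0, feed_times=[(30.0, 60.0)])
        subjects, table = simulate_cohort((8, 8, 4), params, master_seed=11)
        frac = {}
        for (spec, _, truth), (_, row) in zip(subjects, table.iterrows()):
            labs = truth.minute_band_labels
            frac.setdefault(row["ga_group"], []).append(
                labs.count("normo") / len(labs))
        assert np.mean(frac["early"]) < np.mean(frac["mid"]) \
            < np.mean(frac["term"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_cohort((-1, 2, 2), quiet_params())
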