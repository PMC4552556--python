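"""Generator contracts: determinism, clipping, signature recovery, dives, sleep."""

import numpy as np
import pytest
from scipy.signal import periodogram

from castoract.profiles import BehaviourProfile, default_behaviour_profiles
from castoract.signal import decompose
from castoract.simulate import (
    concatenate_segments,
    simulate_dataset,
    simulate_dive,
    simulate_segment,
    simulate_sleep_session,
)


def test_identical_seeds_give_bit_identical_traces(profiles):
    a = simulate_segment(profiles["walking"], 10.0, seed=77)
    b = simulate_segment(profiles["walking"], 10.0, seed=77)
    for ch in ("surge", "sway", "heave", "pressure"):
        assert np.array_equal(getattr(a.trace, ch), getattr(b.trace, ch))
    c = simulate_segment(profiles["walking"], 10.0, seed=78)
    assert not np.array_equal(a.trace.sway, c.trace.sway)


def test_samples_clipped_to_sensor_range(profiles):
    for label, prof in profiles.items():
        if label == "sleeping":
            seg = simulate_sleep_session(600.0, seed=5)
        else:
            seg = simulate_segment(prof, 30.0, seed=5)
        for ch in (seg.trace.surge, seg.trace.sway, seg.trace.heave):
            assert ch.min() >= -4.0 and ch.max() <= 4.0


def test_standing_segment_recovers_table_row(profiles):
    """10-s standing segments: mean vector within 3 SE of the published
    posture and within-segment SDs below the published total SDs."""
    prof = profiles["standing"]
    segs = [simulate_segment(prof, 10.0, seed=s) for s in range(60)]
    means = np.array([s.trace.axes().mean(axis=1) for s in segs])
    grand = means.mean(axis=0)
    se = means.std(axis=0, ddof=1) / np.sqrt(len(segs))
    assert np.all(np.abs(grand - np.array(prof.posture_mean)) <= 3 * se)
    sds = np.array([s.trace.axes().std(axis=1, ddof=1) for s in segs])
    assert np.all(sds.mean(axis=0) <= np.array(prof.raw_sd) + 3 * se)


def test_zero_noise_zero_jitter_profile_is_constant():
    prof = BehaviourProfile(
        label="standing", posture_mean=(0.853, -0.004, 0.360),
        raw_sd=(0.0, 0.0, 0.0), odba_target=1e-4, odba_sd=0.0,
    )
    seg = simulate_segment(prof, 10.0, seed=1)
    assert np.allclose(seg.trace.axes(), np.array(prof.posture_mean)[:, None], atol=2e-3)


def test_walking_sway_spectrum_peaks_at_gait_frequency(profiles):
    hits = 0
    for s in range(20):
        seg = simulate_segment(profiles["walking"], 10.0, seed=1000 + s)
        f, p = periodogram(seg.trace.sway - seg.trace.sway.mean(), fs=8.0)
        peak = f[np.argmax(p)]
        hits += 0.82 - 3 * 0.14 <= peak <= 0.82 + 3 * 0.14
    assert hits >= 18  # the drawn frequency itself is ~N(0.82, 0.14)


def test_pooled_raw_sd_matches_table_decomposition(profiles):
    """Across many segments the pooled per-axis SD reproduces the published
    total SDs (jitter + oscillation + noise), except where the ODBA-implied
    noise already exceeds the published SD (diving heave/sway: the SD is
    then read as posture variability and noise adds on top)."""
    for label in ("standing", "walking", "swimming", "grooming", "feeding"):
        prof = profiles[label]
        segs = [simulate_segment(prof, 20.0, seed=3000 + i) for i in range(100)]
        pooled = np.hstack([s.trace.axes() for s in segs])
        sd = pooled.std(axis=1, ddof=1)
        assert np.all(np.abs(sd - prof.raw_sd) <= 0.2 * np.array(prof.raw_sd)), label
    # diving: heave/sway carry the documented noise-on-top-of-posture excess
    prof = profiles["diving"]
    segs = [simulate_dive(2.0, seed=3100 + i, profile=prof) for i in range(40)]
    pooled = np.hstack([s.trace.axes() for s in segs])
    sd = pooled.std(axis=1, ddof=1)
    assert abs(sd[0] - prof.raw_sd[0]) <= 0.2 * prof.raw_sd[0]  # surge still closes
    expected_heave = np.hypot(prof.raw_sd[2], 0.1003)  # posture SD + noise SD
    assert sd[2] == pytest.approx(expected_heave, rel=0.2)


def test_calibration_closure_through_the_pipeline(profiles):
    """Long simulated segments reproduce their ODBA targets through the
    actual decomposition pipeline (within 0.005 g).

    Tested with the per-segment ODBA jitter zeroed, since the jitter is an
    intentional between-segment effect. Swimming's printed target sits below
    its oscillation floor, so its closure is against the analytic expectation
    E[max(target, floor(A, f))] over the amplitude/frequency law.
    """
    from dataclasses import replace

    from castoract.calibrate import oscillation_odba_floor

    for label in ("standing", "walking", "grooming", "feeding", "diving"):
        prof = replace(profiles[label], odba_sd=0.0)
        seg = simulate_segment(prof, 600.0, seed=71)
        odba = decompose(seg).odba.mean()
        assert odba == pytest.approx(prof.odba_target, abs=0.005), label

    swim = replace(profiles["swimming"], odba_sd=0.0)
    measured = np.mean(
        [decompose(simulate_segment(swim, 60.0, seed=72 + i)).odba.mean()
         for i in range(20)]
    )
    rng = np.random.default_rng(73)  # oracle: expectation over the osc law
    osc = swim.oscillation
    floors = [
        oscillation_odba_floor(
            osc,
            amp=abs(rng.normal(osc.amp_mean, osc.amp_sd)),
            freq=float(np.clip(rng.normal(osc.freq_mean, osc.freq_sd), 0.02, 3.9)),
            n_samples=480,
        )
        for _ in range(400)
    ]
    expected = np.mean(np.maximum(swim.odba_target, floors))
    assert measured == pytest.approx(expected, abs=0.008)


class TestDive:
    def test_peak_pressure_from_depth_conversion(self):
        seg = simulate_dive(2.0, 10.0, 2.0, 10.0, seed=4)
        assert seg.trace.pressure.max() == pytest.approx(1013.0 + 196.2, abs=0.5)

    def test_zero_bottom_time_is_strictly_v_shaped(self):
        seg = simulate_dive(2.0, 10.0, 0.0, 10.0, seed=4)
        depth = (seg.trace.pressure - 1013.0) / 98.1
        assert (depth == depth.max()).sum() == 1

    def test_long_dive_static_heave_near_published_value(self, profiles):
        """Grand mean over dives (single dives carry the ±0.08 g posture
        jitter of the published diving heave SD)."""
        vals = []
        for s in range(20):
            dec = decompose(simulate_dive(3.0, 60.0, 10.0, 60.0, seed=40 + s))
            vals.append(dec.static[2][80:].mean())  # skip the transient
        assert np.mean(vals) == pytest.approx(0.91, abs=0.05)

    def test_initiation_transient_dips_heave_and_surge(self, profiles):
        quiet = default_behaviour_profiles()["diving"]
        seg = simulate_dive(2.0, 13.0, 4.0, 13.0, seed=11, profile=quiet)
        ref = simulate_dive(2.0, 13.0, 4.0, 13.0, seed=11, profile=quiet,
                            transient_amp_g=0.0)
        dip = seg.trace.heave[:8] - ref.trace.heave[:8]
        assert dip.min() == pytest.approx(-0.4, abs=0.02)

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError, match="sensor range"):
            simulate_dive(100.0, 30.0, 5.0, 30.0, seed=1)


class TestSleep:
    def test_session_visits_multiple_postures(self):
        seg = simulate_sleep_session(1800.0, seed=0)  # 3 x mean dwell
        names = {p[2] for p in seg.meta["postures"]}
        assert len(names) >= 2

    def test_right_side_bout_has_positive_sway(self):
        seg = simulate_sleep_session(3600.0, seed=0)
        fs = seg.trace.sample_rate_accel
        dec = decompose(seg)
        for (t0, t1, name) in seg.meta["postures"]:
            if name == "right_side" and t1 - t0 >= 60:
                i0, i1 = int(t0 * fs) + 40, int(t1 * fs) - 40
                assert dec.static[1][i0:i1].mean() >= 0.5
                break
        else:
            pytest.skip("no long right-side bout at this seed")

    def test_within_posture_odba_near_sleeping_target(self):
        seg = simulate_sleep_session(3600.0, seed=0)
        fs = seg.trace.sample_rate_accel
        dec = decompose(seg)
        vals = []
        for (t0, t1, _name) in seg.meta["postures"]:
            i0, i1 = int(t0 * fs) + 40, int(t1 * fs) - 40
            if i1 > i0:
                vals.append(dec.odba[i0:i1].mean())
        assert np.mean(vals) == pytest.approx(0.057, abs=0.008)

    def test_short_sessions_rejected(self):
        with pytest.raises(ValueError, match="600"):
            simulate_sleep_session(120.0, seed=1)


class TestDataset:
    def test_counts_and_labels(self):
        segs = simulate_dataset(10, seed=5)
        assert len(segs) == 60
        labels = [s.label for s in segs]
        for lab in ("standing", "walking", "swimming", "grooming", "feeding", "diving"):
            assert labels.count(lab) == 10

    def test_durations_follow_observation_protocol(self):
        segs = simulate_dataset(2, seed=5)
        by_label = {}
        for s in segs:
            by_label.setdefault(s.label, []).append(s.duration_s)
        assert set(by_label["standing"]) == {10.0}
        assert set(by_label["walking"]) == {10.0}
        for lab in ("swimming", "grooming", "feeding"):
            assert set(by_label[lab]) == {60.0}
        assert set(by_label["diving"]) == {30.0}

    def test_same_seed_reproduces_dataset_exactly(self):
        a = simulate_dataset(3, seed=8)
        b = simulate_dataset(3, seed=8)
        for sa, sb in zip(a, b):
            assert sa.segment_id == sb.segment_id
            assert np.array_equal(sa.trace.sway, sb.trace.sway)
            assert np.array_equal(sa.trace.pressure, sb.trace.pressure)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            simulate_dataset(0, seed=1)


def test_concatenate_segments_preserves_samples():
    segs = simulate_dataset(2, seed=12)
    trace, rebased = concatenate_segments(segs)
    assert trace.n_samples == sum(s.trace.n_samples for s in segs)
    assert rebased[0].start_s == 0.0
    assert rebased[-1].end_s == pytest.approx(trace.duration_s)
    # slicing the combined trace reproduces each segment's samples
    mid = rebased[3]
    np.testing.assert_allclose(
        trace.slice(mid.start_s, mid.end_s).sway, mid.trace.sway
    )
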