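"""Generator: phase registry, event trains, rendering, tail tracks, cohorts."""

import numpy as np
import pytest

from cionacpg.synthetic_data import (
    LONG_BURST_THRESHOLD, PHASE_LABELS, EventTrain, KernelParams, PhaseParams,
    burst_kernel, phase_defaults, render_trace, sample_event_trains,
    simulate_cohort, simulate_tail,
)


class TestPhaseDefaults:
    def test_printed_interval_regimes(self):
        # the regular regimes: ~40 s (II-IV), 55 s (V), 85 s (VI)
        assert phase_defaults("III").mean_interval == 40.0
        assert phase_defaults("V").mean_interval == 55.0
        assert phase_defaults("VI").mean_interval == 85.0

    def test_coupling_progression(self):
        # phase III precedes any synchronization; V is fully coupled
        assert phase_defaults("III").coupling_prob == 0.0
        assert phase_defaults("V").coupling_prob == 1.0
        assert phase_defaults("V").sync_jitter_sd == 0.5

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown phase label"):
            phase_defaults("VIII")

    def test_long_burst_range_exceeds_threshold(self):
        for lab in PHASE_LABELS:
            lo, hi = phase_defaults(lab).long_burst_duration_range
            assert lo > LONG_BURST_THRESHOLD and hi >= lo

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PhaseParams("X", mean_interval=-1, interval_cv=0.1, coupling_prob=0)
        with pytest.raises(ValueError):
            PhaseParams("X", mean_interval=40, interval_cv=0.1, coupling_prob=1.5)
        with pytest.raises(ValueError):
            PhaseParams("X", mean_interval=40, interval_cv=0.1, coupling_prob=0,
                        long_burst_duration_range=(10.0, 20.0))


class TestSampleEventTrains:
    def test_full_coupling_zero_jitter_gives_identical_times(self):
        p = PhaseParams("V", mean_interval=55, interval_cv=0.1,
                        coupling_prob=1.0, sync_jitter_sd=0.0)
        left, right = sample_event_trains(p, 2000.0, 7)
        np.testing.assert_allclose(left.event_times, right.event_times)
        np.testing.assert_allclose(left.event_durations, right.event_durations)

    def test_independent_interval_mean_within_3_se(self):
        # gamma renewal oracle: mean 40 s, cv 0.35 over a 4000 s span,
        # aggregated across seeds to reach n ~ 1000 intervals
        p = PhaseParams("III", mean_interval=40, interval_cv=0.35,
                        coupling_prob=0.0)
        intervals = []
        for seed in range(10):
            _, right = sample_event_trains(p, 4000.0, seed)
            intervals.append(np.diff(right.event_times))
        iv = np.concatenate(intervals)
        assert iv.size > 900
        se = iv.std(ddof=1) / np.sqrt(iv.size)
        assert abs(iv.mean() - 40.0) < 3 * se + 0.2  # +0.2: refractory-floor bias

    def test_marginal_cv_recovered(self):
        p = PhaseParams("III", mean_interval=40, interval_cv=0.35,
                        coupling_prob=0.0)
        iv = np.concatenate([np.diff(sample_event_trains(p, 4000.0, s)[1].event_times)
                             for s in range(10)])
        cv = iv.std(ddof=1) / iv.mean()
        assert abs(cv - 0.35) < 0.05

    def test_no_long_bursts_when_prob_zero(self):
        p = phase_defaults("V")
        left, right = sample_event_trains(p, 4000.0, 3)
        assert not np.any(left.event_durations > LONG_BURST_THRESHOLD)
        assert not np.any(right.event_durations > LONG_BURST_THRESHOLD)

    def test_long_bursts_appear_when_requested(self):
        left, right = sample_event_trains(phase_defaults("VI"), 8000.0, 3)
        assert np.any(right.event_durations > LONG_BURST_THRESHOLD)

    def test_times_sorted_unique_durations_positive(self):
        for lab in PHASE_LABELS:
            left, right = sample_event_trains(phase_defaults(lab), 1500.0, 11)
            for tr in (left, right):
                assert np.all(np.diff(tr.event_times) > 0)
                assert np.all(tr.event_durations > 0)

    def test_seed_determinism(self):
        a = sample_event_trains(phase_defaults("IV"), 1000.0, 5)
        b = sample_event_trains(phase_defaults("IV"), 1000.0, 5)
        np.testing.assert_array_equal(a[0].event_times, b[0].event_times)
        np.testing.assert_array_equal(a[1].event_durations, b[1].event_durations)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_event_trains(phase_defaults("I"), -5.0, 0)
        with pytest.raises(ValueError):
            sample_event_trains(phase_defaults("I"), 100.0, -1)


class TestRenderTrace:
    def test_no_events_no_noise_is_flat_baseline(self, noiseless_kernel):
        tr = render_trace([EventTrain("L", [], []), EventTrain("R", [], [])],
                          noiseless_kernel, 100.0, 0)
        for x in tr.channels.values():
            np.testing.assert_allclose(x, noiseless_kernel.baseline)

    def test_single_event_decay_matches_k_off(self, noiseless_kernel):
        # log-linear regression on the post-plateau tail recovers k_off
        k = KernelParams(noise_sd=0.0, amplitude_cv=0.0, frame_interval=0.05)
        tr = render_trace([EventTrain("R", [10.0], [5.0])], k, 40.0, 0, ["mn2r"])
        x = (tr.channels["mn2r"] - k.baseline) / k.baseline
        t = tr.times
        sel = (t > 15.5) & (t < 19.0) & (x > 1e-8)
        slope = np.polyfit(t[sel], np.log(x[sel]), 1)[0]
        assert abs(-slope - k.k_off) / k.k_off < 0.01

    def test_two_events_two_maxima_40s_apart(self, noiseless_kernel):
        tr = render_trace([EventTrain("R", [10.0, 50.0], [4.0, 4.0])],
                          noiseless_kernel, 100.0, 0, ["mn2r"])
        x = tr.channels["mn2r"]
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(x, height=noiseless_kernel.baseline * 1.5)
        assert peaks.size == 2
        gap = tr.times[peaks[1]] - tr.times[peaks[0]]
        assert abs(gap - 40.0) <= noiseless_kernel.frame_interval + 1e-9

    def test_rendering_is_additive(self, noiseless_kernel):
        a = EventTrain("R", [20.0], [5.0])
        b = EventTrain("R", [60.0], [8.0])
        ab = EventTrain("R", [20.0, 60.0], [5.0, 8.0])
        base = noiseless_kernel.baseline
        xa = render_trace([a], noiseless_kernel, 120.0, 0, ["c"]).channels["c"]
        xb = render_trace([b], noiseless_kernel, 120.0, 0, ["c"]).channels["c"]
        xab = render_trace([ab], noiseless_kernel, 120.0, 0, ["c"]).channels["c"]
        np.testing.assert_allclose(xab - base, (xa - base) + (xb - base),
                                   atol=1e-9 * base)

    def test_kernel_zero_outside_support(self, kernel):
        t = np.array([-1.0, 0.0, 2.0, 5.0, 20.0])
        k = burst_kernel(t, 3.0, kernel)
        assert k[0] == 0.0
        assert np.all(k[1:] >= 0.0)

    def test_frame_interval_longer_than_span_rejected(self, kernel):
        with pytest.raises(ValueError):
            render_trace([EventTrain("R", [], [])], kernel, 0.1, 0, ["c"])


class TestSimulateTail:
    def test_single_retf_is_single_signed(self):
        from cionacpg.kinematics import bending_angle
        track = simulate_tail([("rETF", 1.0, 0.5, 0.0)], fps=200, rng_seed=0,
                              span=3.0)
        theta = bending_angle(track)
        moving = theta[np.abs(theta) > 3.0]
        assert moving.size > 0
        assert np.all(moving < 0)  # right flick = negative (leftward positive)

    def test_empty_plan_is_flat(self):
        from cionacpg.kinematics import curvature_series
        track = simulate_tail([], fps=200, rng_seed=0, span=2.0)
        kappa = curvature_series(track)
        assert np.nanmax(np.abs(kappa)) < 1e-3  # coordinate noise only

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            simulate_tail([("rETF", 1.0, 1.0, 0.0), ("swim", 1.5, 2.0, 5.0)],
                          fps=200, rng_seed=0)

    def test_coordinates_consistent_with_bending_series(self):
        # recomputing the angle from rendered coordinates returns the
        # generating waveform (up to coordinate noise)
        from cionacpg.kinematics import bending_angle
        track = simulate_tail([("lETF", 0.5, 0.5, 0.0)], fps=200, rng_seed=1,
                              span=2.0)
        theta = bending_angle(track)
        i_peak = int(np.nanargmax(np.abs(theta)))
        assert theta[i_peak] == pytest.approx(40.0, abs=2.0)


class TestSimulateCohort:
    @pytest.mark.parametrize("p,expected", [(1.0, "R"), (0.0, "L")])
    def test_degenerate_probabilities(self, p, expected):
        table = simulate_cohort(10, p, rng_seed=0)
        assert set(table["first_onset"]) == {expected}

    def test_binomial_oracle_at_large_n(self):
        table = simulate_cohort(17000, 13 / 17, rng_seed=2)
        frac = (table["first_onset"] == "R").mean()
        se = np.sqrt((13 / 17) * (4 / 17) / 17000)
        assert abs(frac - 13 / 17) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, 0.5, rng_seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(5, 1.5, rng_seed=0)


class TestGroundTruthRecoveryLoop:
    def test_noiseless_recovery_all_phases(self, noiseless_kernel):
        """Count and peak-time recovery on noiseless renders, per phase.

        Every in-bounds truth burst must be covered by a detection, with
        no spurious detections; isolated bursts (no kernel overlap with a
        neighbour) must have their peak recovered to within one frame.
        """
        from cionacpg import trace_processing as tp
        span, margin, tail = 1500.0, 15.0, 10.0 / noiseless_kernel.k_off
        for lab in PHASE_LABELS:
            from cionacpg.synthetic_data import sample_event_trains
            left, right = sample_event_trains(phase_defaults(lab), span, 3)
            tr = render_trace([left, right], noiseless_kernel, span, 4)
            dff = tp.compute_dff(tr)
            trains = tp.detect_all_channels(dff)
            for truth, chan in ((left, "L"), (right, "R")):
                on, dur = truth.event_times, truth.event_durations
                pk = truth.peak_times
                det = trains[chan]
                inb = (pk > margin) & (pk < span - margin)
                # coverage: each truth burst inside the span is detected
                for t in pk[inb]:
                    assert any(e.onset_time - 1.0 <= t <= e.offset_time + 1.0
                               for e in det.events), (lab, chan, t)
                # no spurious detections
                for e in det.events:
                    if not (margin < e.peak_time < span - margin):
                        continue
                    assert any(o - 1.0 <= e.peak_time <= p + tail + 1.0
                               for o, p in zip(on, pk)), (lab, chan, e)
                # isolated bursts: peak within one frame
                prev_end = np.r_[-np.inf, pk[:-1] + tail]
                next_on = np.r_[on[1:], np.inf]
                isolated = inb & (on > prev_end + 1.0) & (pk + tail < next_on)
                det_pk = det.peak_times
                for t in pk[isolated]:
                    err = np.min(np.abs(det_pk - t))
                    assert err <= noiseless_kernel.frame_interval + 1e-9, \
                        (lab, chan, t, err)
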