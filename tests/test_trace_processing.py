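"""Normalization, derivative filtering and burst detection."""

import numpy as np
import pytest

from cionacpg.io_formats import FluorescenceTrace
from cionacpg.synthetic_data import (EventTrain, KernelParams, phase_defaults,
                                     render_trace, sample_event_trains)
from cionacpg import trace_processing as tp


def make_trace(values, dt=0.2, normalized=False, name="mn2r"):
    values = np.asarray(values, dtype=float)
    return FluorescenceTrace(times=np.arange(values.size) * dt,
                             channels={name: values}, frame_interval=dt,
                             normalized=normalized)


class TestComputeDff:
    def test_constant_trace_normalizes_to_zero(self):
        dff = tp.compute_dff(make_trace(np.full(600, 123.0)))
        np.testing.assert_allclose(dff.channels["mn2r"], 0.0, atol=1e-12)
        assert dff.normalized

    def test_doubling_frame_gives_dff_of_one(self):
        f = np.full(600, 100.0)
        f[300] = 200.0
        dff = tp.compute_dff(make_trace(f))
        assert dff.channels["mn2r"][300] == pytest.approx(1.0)

    def test_rolling_percentile_absorbs_slow_drift(self):
        # drift-only trace: +10% linear drift over 600 s; residual dF/F
        # after baseline subtraction stays below 0.05
        t = np.arange(3000) * 0.2
        f = 100.0 * (1.0 + 0.1 * t / 600.0)
        dff = tp.compute_dff(make_trace(f), window=60.0)
        assert np.max(np.abs(dff.channels["mn2r"])) < 0.05

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            tp.compute_dff(make_trace(np.linspace(-1.0, 1.0, 600)))

    def test_double_normalization_rejected(self):
        dff = tp.compute_dff(make_trace(np.full(600, 10.0)))
        with pytest.raises(ValueError):
            tp.compute_dff(dff)


class TestDenoisedDerivative:
    def test_linear_ramp_slope_recovered(self):
        m = 0.37
        t = np.arange(200) * 0.2
        d = tp.denoised_derivative(make_trace(m * t, normalized=True))["mn2r"]
        np.testing.assert_allclose(d[10:-10], m, atol=1e-9)

    def test_constant_gives_zero(self):
        d = tp.denoised_derivative(make_trace(np.full(100, 0.5),
                                              normalized=True))["mn2r"]
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_fused_and_two_step_paths_agree_on_polynomials(self):
        t = np.arange(300) * 0.2
        quad = 0.3 * t**2 - 0.5 * t + 1.0
        trace = make_trace(quad, normalized=True)
        fused = tp.denoised_derivative(trace)["mn2r"]
        two = tp.difference_then_smooth(trace)["mn2r"]
        np.testing.assert_allclose(fused[8:-8], two[8:-8], atol=1e-9)

    def test_rendered_burst_has_one_positive_then_one_negative_lobe(self):
        kern = KernelParams(noise_sd=0.0, amplitude_cv=0.0)
        tr = render_trace([EventTrain("R", [20.0], [5.0])], kern, 60.0, 0,
                          ["mn2r"])
        dff = tp.compute_dff(tr)
        d = tp.denoised_derivative(dff)["mn2r"]
        # 25% significance cut: the smoothing filter leaves a small
        # overshoot ripple at the sharp plateau-to-decay corner
        sig = d[np.abs(d) > 0.25 * np.max(np.abs(d))]
        flips = np.count_nonzero(np.diff(np.sign(sig)))
        assert flips == 1 and sig[0] > 0 and sig[-1] < 0

    def test_window_validation(self):
        trace = make_trace(np.zeros(50), normalized=True)
        with pytest.raises(ValueError):
            tp.denoised_derivative(trace, sg_window=6)
        with pytest.raises(ValueError):
            tp.denoised_derivative(trace, sg_window=3, sg_order=3)
        with pytest.raises(ValueError):
            tp.denoised_derivative(trace, sg_window=51)

    def test_raw_trace_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            tp.denoised_derivative(make_trace(np.zeros(50)))


class TestDetectBursts:
    def test_noiseless_five_bursts_exact(self):
        kern = KernelParams(noise_sd=0.0, amplitude_cv=0.0)
        onsets = np.array([50.0, 100.0, 150.0, 200.0, 250.0])
        durs = np.full(5, 5.0)
        tr = render_trace([EventTrain("R", onsets, durs)], kern, 320.0, 0,
                          ["mn2r"])
        dff = tp.compute_dff(tr)
        d = tp.denoised_derivative(dff)["mn2r"]
        train = tp.detect_bursts(d, dff, "mn2r")
        assert train.n_events == 5
        np.testing.assert_allclose(train.peak_times, onsets + 5.0,
                                   atol=kern.frame_interval + 1e-9)

    def test_pure_noise_rarely_yields_events(self):
        # Monte-Carlo false-positive check at the default thresholds:
        # noise-only traces produce zero events in >= 95% of seeds
        kern = KernelParams()
        clean = 0
        n_seeds = 200
        for seed in range(n_seeds):
            tr = render_trace([EventTrain("R", [], [])], kern, 600.0, seed,
                              ["mn2r"])
            dff = tp.compute_dff(tr)
            d = tp.denoised_derivative(dff)["mn2r"]
            if tp.detect_bursts(d, dff, "mn2r").n_events == 0:
                clean += 1
        assert clean / n_seeds >= 0.95

    def test_35s_plateau_flagged_long(self):
        kern = KernelParams(noise_sd=0.0, amplitude_cv=0.0)
        tr = render_trace([EventTrain("R", [30.0], [35.0])], kern, 120.0, 0,
                          ["mn2r"])
        dff = tp.compute_dff(tr, window=240.0)
        d = tp.denoised_derivative(dff)["mn2r"]
        train = tp.detect_bursts(d, dff, "mn2r")
        assert train.n_events == 1
        assert train.events[0].is_long
        assert train.events[0].duration > 35.0

    def test_translation_equivariance(self):
        # shifting all events by k frames shifts all peaks by k*dt
        kern = KernelParams(noise_sd=0.0, amplitude_cv=0.0)
        onsets = np.array([40.0, 90.0, 140.0])
        shift = 10 * kern.frame_interval
        t1 = render_trace([EventTrain("R", onsets, np.full(3, 4.0))], kern,
                          200.0, 0, ["mn2r"])
        t2 = render_trace([EventTrain("R", onsets + shift, np.full(3, 4.0))],
                          kern, 200.0, 0, ["mn2r"])
        det = []
        for tr in (t1, t2):
            dff = tp.compute_dff(tr)
            d = tp.denoised_derivative(dff)["mn2r"]
            det.append(tp.detect_bursts(d, dff, "mn2r").peak_times)
        np.testing.assert_allclose(det[1] - det[0], shift, atol=1e-9)

    def test_mismatched_lengths_rejected(self):
        dff = tp.compute_dff(make_trace(np.full(100, 10.0)))
        with pytest.raises(ValueError):
            tp.detect_bursts(np.zeros(50), dff, "mn2r")


class TestIntervals:
    def _train_at(self, peaks):
        from cionacpg.trace_processing import BurstEvent, BurstTrain
        return BurstTrain("R", [BurstEvent("R", p, p - 1.0, p + 1.0, 1.0)
                                for p in peaks])

    def test_regular_peaks(self):
        iv, s = tp.compute_intervals(self._train_at([0.0, 40.0, 80.0]))
        np.testing.assert_allclose(iv, [40.0, 40.0])
        assert s.defined and s.mean == pytest.approx(40.0) and s.cv == 0.0

    def test_single_event_undefined_summary(self):
        iv, s = tp.compute_intervals(self._train_at([10.0]))
        assert iv.size == 0 and not s.defined

    def test_intervals_telescope(self):
        peaks = np.sort(np.random.default_rng(0).uniform(0, 500, 20))
        iv, _ = tp.compute_intervals(self._train_at(peaks))
        assert iv.sum() == pytest.approx(peaks[-1] - peaks[0])

    def test_phase_iii_interval_recovery_within_10pct(self):
        # the ~40 s constant regime is recovered from the full pipeline
        means = []
        for seed in (0, 1, 2):
            left, right = sample_event_trains(phase_defaults("III"), 2400.0,
                                              seed)
            tr = render_trace([left, right], KernelParams(), 2400.0, seed + 50)
            dff = tp.compute_dff(tr)
            trains = tp.detect_all_channels(dff)
            _, s = tp.compute_intervals(trains["R"])
            assert s.n_intervals >= 50
            means.append(s.mean)
        assert abs(np.mean(means) - 40.0) / 40.0 < 0.10


def test_detection_recall_precision_on_default_noise():
    """Recall and precision >= 0.95 against ground truth for every phase."""
    from cionacpg.synthetic_data import PHASE_LABELS
    span, margin = 2000.0, 15.0
    for lab in PHASE_LABELS:
        matched = n_truth = n_det = 0
        for seed in (0, 1, 2):
            left, right = sample_event_trains(phase_defaults(lab), span, seed)
            tr = render_trace([left, right], KernelParams(), span, seed + 100)
            dff = tp.compute_dff(tr)
            trains = tp.detect_all_channels(dff)
            for truth, chan in ((left, "L"), (right, "R")):
                pk = truth.peak_times
                pk = pk[(pk > margin) & (pk < span - margin)]
                dets = [e for e in trains[chan].events
                        if margin < e.peak_time < span - margin]
                used = set()
                for t in pk:
                    for j, e in enumerate(dets):
                        if j not in used and \
                                e.onset_time - 1.0 <= t <= e.offset_time + 1.0:
                            used.add(j)
                            matched += 1
                            break
                n_truth += pk.size
                n_det += len(dets)
        assert matched / n_truth >= 0.95, lab
        assert matched / n_det >= 0.95, lab
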