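"""Event detection: smoothing, decimation, thresholds, QC and rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miniens import (
    CalciumEventDetector,
    DetectionParams,
    InvalidInputError,
    QCParams,
    SimConfig,
    TraceQC,
    activity_ratio,
    decimate,
    detect_events,
    event_rate,
    gaussian_smooth,
    generate_spike_trains,
    normalize_to_first,
    qc_neuron,
    render_traces,
    steepness_threshold,
)
from miniens.events import EventRaster

from conftest import score_detection


class TestGaussianSmooth:
    def test_constant_preserved(self):
        out = gaussian_smooth(np.full(500, 3.7), sd_ms=100, fps=30)
        assert np.allclose(out, 3.7)

    def test_impulse_response_has_kernel_sd(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        sd_frames = 100 / 1000 * 30  # 3 frames
        out = gaussian_smooth(x, sd_ms=100, fps=30)
        t = np.arange(2001)
        mu = (t * out).sum() / out.sum()
        sd = np.sqrt(((t - mu) ** 2 * out).sum() / out.sum())
        assert mu == pytest.approx(1000, abs=0.01)
        assert sd == pytest.approx(sd_frames, rel=0.02)

    def test_white_noise_variance_closed_form(self, rng):
        # var_out = sigma^2 / (2 k sqrt(pi)) for kernel SD k frames
        sigma, k = 2.0, 3.0
        x = rng.normal(0, sigma, 200_000)
        out = gaussian_smooth(x, sd_ms=k / 30 * 1000, fps=30)
        expected = sigma / np.sqrt(2 * k * np.sqrt(np.pi))
        assert out.std() == pytest.approx(expected, rel=0.05)

    def test_empty_trace_rejected(self):
        with pytest.raises(InvalidInputError):
            gaussian_smooth(np.array([]), 50, 30)


class TestDecimate:
    @pytest.mark.parametrize(
        "series,factor,expected",
        [
            ([1, 2, 3, 4], 1, [1, 2, 3, 4]),
            ([1, 2, 3, 4, 5, 6], 3, [2, 5]),
            ([1, 2, 3, 4, 5, 6, 7], 3, [2, 5]),  # trailing partial block dropped
        ],
    )
    def test_block_mean(self, series, factor, expected):
        np.testing.assert_allclose(decimate(np.array(series, float), factor), expected)

    def test_paper_grid_30fps(self):
        # 18,000 frames at 30 fps, 3x decimation -> 6,000 points of 100 ms
        out = decimate(np.zeros(18_000), 3)
        assert out.shape[-1] == 6_000

    def test_subsample_mode(self):
        np.testing.assert_allclose(
            decimate(np.arange(6.0), 3, mode="subsample"), [0.0, 3.0]
        )

    def test_factor_longer_than_series_rejected(self):
        with pytest.raises(InvalidInputError):
            decimate(np.arange(4.0), 5)


class TestSteepnessThreshold:
    def test_standard_normal_approaches_2p698_sd(self, rng):
        thr = steepness_threshold(rng.standard_normal(10**6))
        assert thr == pytest.approx(2.698, rel=0.01)

    def test_uniform_sample(self, rng):
        thr = steepness_threshold(rng.uniform(0, 1, 10**6))
        assert thr == pytest.approx(1.5, rel=0.01)

    def test_constant_series_degenerate_zero(self):
        assert steepness_threshold(np.full(100, 2.0)) == 0.0

    def test_scales_linearly(self, rng):
        x = rng.standard_normal(10_000)
        assert steepness_threshold(3 * x) == pytest.approx(3 * steepness_threshold(x))


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        x = np.zeros((1, 300))
        raster = detect_events(x, DetectionParams())
        assert raster.events.sum() == 0

    def test_single_transient_one_onset_cluster_no_decay_events(self):
        cfg = SimConfig(n_neurons=1, duration_s=60, noise_sd=0.05, amplitude=10, seed=4)
        tm = render_traces([np.array([20.0])], cfg)
        raster = detect_events(tm)
        ev = np.flatnonzero(raster.events[0])
        onset_bin = int(20.0 * 30 / 3)
        assert ev.size >= 1
        # zero-phase smoothing may pull the onset one decimated point early;
        # no events may appear on the slow decay
        assert np.all((ev >= onset_bin - 1) & (ev <= onset_bin + 3))

    def test_raster_shape_and_binarity(self):
        cfg = SimConfig(n_neurons=3, duration_s=20, seed=5)
        trains = generate_spike_trains(cfg)
        tm = render_traces(trains, cfg)
        raster = detect_events(tm)
        assert raster.events.shape == (3, tm.n_frames // 3)
        assert set(np.unique(raster.events)) <= {0, 1}
        assert raster.dt_s == pytest.approx(0.1)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0),
        offset=st.floats(-100.0, 100.0),
    )
    def test_invariant_under_positive_affine_transform(self, scale, offset):
        cfg = SimConfig(n_neurons=2, duration_s=20, seed=6)
        tm = render_traces(generate_spike_trains(cfg), cfg)
        base = detect_events(tm.values)
        trans = detect_events(scale * tm.values + offset)
        np.testing.assert_array_equal(base.events, trans.events)

    def test_count_recovery_within_20_percent(self):
        cfg = SimConfig(
            n_neurons=40, duration_s=600, firing_rate_hz=0.1, amplitude=10, noise_sd=1.0, seed=7
        )
        trains = generate_spike_trains(cfg)
        tm = render_traces(trains, cfg)
        raster = detect_events(tm, DetectionParams(merge_consecutive=True))
        true = np.array([t.size for t in trains])
        got = raster.events.sum(axis=1)
        ok = true > 0
        ratio = got[ok] / true[ok]
        assert np.mean(np.abs(ratio - 1) <= 0.2) >= 0.9

    def test_recall_precision_monotone_in_snr(self):
        scores = []
        for snr in (5, 10, 20):
            cfg = SimConfig(
                n_neurons=30,
                duration_s=300,
                firing_rate_hz=0.1,
                amplitude=float(snr),
                noise_sd=1.0,
                seed=8,
            )
            trains = generate_spike_trains(cfg)
            tm = render_traces(trains, cfg)
            raster = detect_events(tm)
            scores.append(score_detection(raster.events, trains, cfg.fps, 3))
        recalls = [s[0] for s in scores]
        precisions = [s[1] for s in scores]
        # non-decreasing up to finite-sample jitter of one point in ~100
        assert all(recalls[i + 1] >= recalls[i] - 0.01 for i in range(len(recalls) - 1))
        assert all(
            precisions[i + 1] >= precisions[i] - 0.01 for i in range(len(precisions) - 1)
        )

    def test_deterministic_across_runs(self):
        cfg = SimConfig(n_neurons=5, duration_s=30, seed=9)
        tm = render_traces(generate_spike_trains(cfg), cfg)
        a = detect_events(tm).events
        b = detect_events(tm).events
        np.testing.assert_array_equal(a, b)

    def test_estimator_api(self):
        det = CalciumEventDetector(decim_factor=3)
        assert det.get_params()["decim_factor"] == 3
        cfg = SimConfig(n_neurons=4, duration_s=20, seed=10)
        tm = render_traces(generate_spike_trains(cfg), cfg)
        det.fit(tm)
        assert det.thresholds_.shape == (4, 2)
        raster = det.transform(tm)
        assert isinstance(raster, EventRaster)
        det.set_params(merge_consecutive=True)
        assert det.get_params()["merge_consecutive"] is True


class TestRatesAndRatios:
    def test_event_rate_arithmetic(self):
        ev = np.zeros((1, 6000), dtype=np.uint8)
        ev[0, :60] = 1
        r = event_rate(EventRaster(ev, dt_s=0.1))
        assert r.loc[0, "rate_per_point"] == pytest.approx(0.01)
        assert r.loc[0, "rate_events_per_s"] == pytest.approx(0.1)

    @pytest.mark.parametrize("fill,expected", [(0, 0.0), (1, 1.0)])
    def test_event_rate_boundaries(self, fill, expected):
        ev = np.full((2, 100), fill, dtype=np.uint8)
        r = event_rate(EventRaster(ev, dt_s=0.1))
        assert (r["rate_per_point"] == expected).all()

    def test_normalize_to_first(self):
        rates = np.array([[0.2, 0.4, 0.0], [0.1, 0.4, 0.3]])
        out, excluded = normalize_to_first(rates)
        np.testing.assert_allclose(out[:, 0], [1.0, 0.5])
        np.testing.assert_allclose(out[:, 1], [1.0, 1.0])
        assert excluded.tolist() == [False, False, True]
        assert np.isnan(out[:, 2]).all()

    def test_normalize_identity_sessions(self):
        rates = np.tile([[0.3, 0.6]], (3, 1))
        out, _ = normalize_to_first(rates)
        np.testing.assert_allclose(out, 1.0)

    @pytest.mark.parametrize(
        "r1,r2,expected", [(2, 0, 1.0), (5, 5, 0.0), (1, 3, -0.5)]
    )
    def test_activity_ratio(self, r1, r2, expected):
        assert activity_ratio(r1, r2) == pytest.approx(expected)

    def test_activity_ratio_undefined_for_double_zero(self):
        assert np.isnan(activity_ratio(0.0, 0.0))


class TestQC:
    def test_pure_noise_flagged_low_pnr(self, rng):
        res = qc_neuron(rng.normal(0, 1, 18_000))
        assert not res["keep"]
        assert "low_pnr" in res["reasons"]
        assert res["pnr"] < 20

    def test_clean_high_amplitude_trace_kept(self):
        cfg = SimConfig(
            n_neurons=1, duration_s=300, firing_rate_hz=0.1, amplitude=50, noise_sd=1.0, seed=12
        )
        tm = render_traces(generate_spike_trains(cfg), cfg)
        res = qc_neuron(tm.values[0])
        assert res["keep"], res

    def test_symmetric_noise_not_flagged_for_asymmetry(self, rng):
        res = qc_neuron(rng.normal(0, 1, 18_000), QCParams(pnr_min=0.1))
        assert abs(res["asymmetry"]) < 0.5
        assert "noise_asymmetry" not in res["reasons"]

    def test_flagged_set_deterministic(self):
        cfg = SimConfig(n_neurons=10, duration_s=60, amplitude=10, seed=13)
        tm = render_traces(generate_spike_trains(cfg), cfg)
        a = TraceQC().fit(tm.values).flags_
        b = TraceQC().fit(tm.values).flags_
        np.testing.assert_array_equal(a, b)
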