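"""Tests for ATP-sensor event extraction and flash/surge classification."""

import math

import numpy as np
import pandas as pd
import pytest

from sliceglia.atp_events import (
    CalibrationCurve,
    DEFAULT_CALIBRATION_LEVELS_M,
    EventDetection,
    TimelapseStack,
    background_decay,
    calibrate_concentration,
    cluster_flash_surge,
    compute_dff,
    detect_atp_events,
    event_features,
    fit_background_tau,
    incidence_and_prevalence,
)
from sliceglia.simulate import (
    ATPSimSpec,
    FLASH_PARAMS,
    SURGE_PARAMS,
    sample_event_features,
    simulate_atp_movie,
)


def _detection(trace, footprint=None):
    if footprint is None:
        footprint = np.ones((2, 2), dtype=bool)
    trace = np.asarray(trace, float)
    return EventDetection(
        id=0, footprint=footprint, trace=trace,
        centroid=(0.0, 0.0), t_start=0, t_stop=trace.size - 1,
    )


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        dff = compute_dff(np.full(50, 80.0))
        np.testing.assert_allclose(dff, 0.0)

    def test_peak_over_baseline_arithmetic(self):
        trace = np.full(100, 100.0)
        trace[50] = 150.0
        dff = compute_dff(trace)
        assert dff[50] == pytest.approx(0.5)

    def test_nonpositive_baseline_identifies_location(self):
        movie = np.ones((10, 4, 4))
        movie[:, 2, 3] = 0.0
        with pytest.raises(ValueError, match=r"\(2, 3\)"):
            compute_dff(movie)

    def test_pre_window_rule(self):
        trace = np.concatenate([np.full(20, 100.0), np.full(20, 130.0)])
        dff = compute_dff(trace, baseline_rule="pre_window", pre_window=(0, 20))
        assert dff[-1] == pytest.approx(0.3)

    def test_peak_dff_recovered_from_movie(self):
        # stationary background so the percentile baseline matches F0
        spec = ATPSimSpec(
            seed=3, background_decay_tau=1e9, height=96, width=96,
            flash_rate=4, surge_rate=3,
        )
        stack, truth = simulate_atp_movie(spec)
        detections = detect_atp_events(stack, dff_threshold=0.15)
        assert len(detections) == truth.n
        for det in detections:
            ev = event_features(det, stack.dt, stack.pixel_size)
            d2 = (truth.events.row - ev.centroid[0]) ** 2 + (
                truth.events.col - ev.centroid[1]
            ) ** 2
            match = truth.events.loc[d2.idxmin()]
            assert ev.peak_dff == pytest.approx(match.peak_dff, rel=0.10)


class TestDetectEvents:
    def test_uniform_movie_yields_no_events(self):
        stack = TimelapseStack(np.full((20, 16, 16), 50.0), dt=2.0, pixel_size=1.0)
        assert detect_atp_events(stack) == []

    def test_disjoint_events_detected_with_accurate_centroids(self):
        # five hand-placed Gaussian transients on a flat background
        T, H, W = 60, 80, 80
        frames = np.full((T, H, W), 100.0)
        rr, cc = np.mgrid[0:H, 0:W]
        centers = [(15, 15), (15, 60), (40, 40), (65, 15), (65, 60)]
        for k, (r0, c0) in enumerate(centers):
            foot = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 3.0**2))
            tprof = np.exp(-((np.arange(T) - (10 + 8 * k)) ** 2) / (2 * 2.0**2))
            frames += 60.0 * tprof[:, None, None] * foot[None]
        stack = TimelapseStack(frames, dt=2.0, pixel_size=1.0)
        detections = detect_atp_events(stack, dff_threshold=0.2)
        assert len(detections) == 5
        got = sorted(tuple(np.round(d.centroid)) for d in detections)
        for (gr, gc), (tr, tc) in zip(got, sorted(centers)):
            assert abs(gr - tr) <= 2 and abs(gc - tc) <= 2

    def test_spatially_disjoint_but_simultaneous_events_stay_separate(self):
        T, H, W = 30, 40, 40
        frames = np.full((T, H, W), 100.0)
        rr, cc = np.mgrid[0:H, 0:W]
        tprof = np.exp(-((np.arange(T) - 15) ** 2) / (2 * 2.0**2))
        for r0, c0 in [(10, 10), (30, 30)]:
            foot = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 2.5**2))
            frames += 50.0 * tprof[:, None, None] * foot[None]
        stack = TimelapseStack(frames, dt=2.0, pixel_size=1.0)
        assert len(detect_atp_events(stack, dff_threshold=0.2)) == 2


class TestEventFeatures:
    def test_square_pulse_fwhm_equals_width(self):
        dt, width_frames = 2.0, 7
        trace = np.zeros(40)
        trace[10 : 10 + width_frames] = 1.0
        trace[13] = 1.2  # strict interior maximum
        ev = event_features(_detection(trace), dt, 1.0)
        assert ev.duration == pytest.approx(width_frames * dt, abs=dt)

    def test_exponential_rise_time_is_tau_ln9(self):
        dt, tau = 0.5, 6.0
        t = np.arange(0, 60, dt)
        rise = 1.0 - np.exp(-t / tau)
        trace = np.concatenate([rise, rise[-1] * np.exp(-np.arange(0, 30, dt) / 4.0)])
        ev = event_features(_detection(trace), dt, 1.0)
        assert ev.rise == pytest.approx(tau * math.log(9.0), abs=dt)

    def test_disk_footprint_area_matches_pi_r_squared(self):
        rr, cc = np.mgrid[0:40, 0:40]
        footprint = (rr - 20) ** 2 + (cc - 20) ** 2 <= 10**2
        trace = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        ev = event_features(_detection(trace, footprint), 1.0, 1.0)
        assert ev.area == pytest.approx(math.pi * 100.0, rel=0.05)

    def test_peak_at_edge_flags_event(self):
        trace = np.linspace(0, 1, 20)  # maximum at the last sample
        ev = event_features(_detection(trace), 1.0, 1.0)
        assert not ev.valid
        assert math.isnan(ev.duration)

    @pytest.mark.parametrize("gain,offset", [(3.0, 0.0), (0.5, 0.0), (7.0, 0.0)])
    def test_kinetics_invariant_under_intensity_rescaling(self, gain, offset):
        rng = np.random.default_rng(0)
        t = np.arange(0, 80, 2.0)
        trace = np.exp(-((t - 40) ** 2) / (2 * 8.0**2)) + 0.01 * rng.standard_normal(t.size)
        base = event_features(_detection(trace), 2.0, 1.0)
        scaled = event_features(_detection(gain * trace + offset), 2.0, 1.0)
        assert scaled.duration == pytest.approx(base.duration, rel=1e-9)
        assert scaled.rise == pytest.approx(base.rise, rel=1e-9)
        assert scaled.decay == pytest.approx(base.decay, rel=1e-9)


class TestClusterFlashSurge:
    def _features(self, seed, n=60):
        rng = np.random.default_rng(seed)
        flash = sample_event_features(FLASH_PARAMS, n, rng)
        surge = sample_event_features(SURGE_PARAMS, n // 2, rng)
        table = pd.concat([flash, surge], ignore_index=True)
        labels_true = np.array(["flash"] * n + ["surge"] * (n // 2))
        return table, labels_true

    def test_separated_clusters_agree_with_truth_across_seeds(self):
        agreements = []
        for seed in range(20):
            table, truth = self._features(seed)
            labels, _ = cluster_flash_surge(table, seed=seed)
            agreements.append(np.mean(labels == truth))
        assert np.mean(agreements) >= 0.95

    def test_identical_features_yield_unassigned_with_warning(self):
        table = pd.DataFrame(
            {"peak_dff": [1.0] * 6, "duration_s": [2.0] * 6, "area_um2": [3.0] * 6}
        )
        with pytest.warns(UserWarning, match="identical"):
            labels, centroids = cluster_flash_surge(table)
        assert list(labels) == ["unassigned"] * 6
        assert centroids.size == 0

    def test_flash_label_always_has_lower_mean_intensity(self):
        for seed in (0, 1, 2):
            table, _ = self._features(seed, n=40)
            labels, _ = cluster_flash_surge(table, seed=seed)
            flash_mean = table.loc[labels == "flash", "peak_dff"].mean()
            surge_mean = table.loc[labels == "surge", "peak_dff"].mean()
            assert flash_mean < surge_mean

    def test_too_few_events_rejected(self):
        table = pd.DataFrame(
            {"peak_dff": [1.0, 2.0], "duration_s": [1.0, 2.0], "area_um2": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            cluster_flash_surge(table)


class TestIncidencePrevalence:
    def test_counts_and_fractions(self):
        events = pd.DataFrame(
            {
                "window": ["m1"] * 12,
                "timepoint": ["1h"] * 12,
                "label": ["flash"] * 9 + ["surge"] * 3,
            }
        )
        counts, frac = incidence_and_prevalence(events)
        assert counts["m1"] == 12
        assert frac.loc["1h", "flash"] == pytest.approx(0.75)
        assert frac.loc["1h", "surge"] == pytest.approx(0.25)
        assert frac.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_class_fractions_match_generative_rates(self):
        # flash:surge = 10:5 per movie -> expected fractions 2/3 and 1/3
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(50):
            n_flash = rng.poisson(10)
            n_surge = rng.poisson(5)
            if n_flash + n_surge == 0:
                continue
            events = pd.DataFrame(
                {
                    "window": "w",
                    "timepoint": "t",
                    "label": ["flash"] * n_flash + ["surge"] * n_surge,
                }
            )
            _, frac = incidence_and_prevalence(events)
            fracs.append(frac.loc["t"].get("flash", 0.0))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 2.0 / 3.0) <= 3 * se


class TestBackgroundDecay:
    def test_default_roi_geometry(self):
        import inspect

        sig = inspect.signature(background_decay)
        assert sig.parameters["roi_size_um"].default == 12.5
        assert sig.parameters["n_rois"].default == 4

    def test_constant_background_gives_flat_trace(self):
        stack = TimelapseStack(np.full((30, 64, 64), 200.0), dt=2.0, pixel_size=1.0)
        table = background_decay(stack, rois=[(0, 0), (20, 20)])
        mean_trace = table[table.roi == "mean"].mfi.to_numpy()
        np.testing.assert_allclose(mean_trace, 200.0)

    def test_decay_tau_recovered_within_10_percent(self):
        spec = ATPSimSpec(
            seed=1, flash_rate=0, surge_rate=0, height=64, width=64,
            background_decay_tau=1200.0,
        )
        stack, _ = simulate_atp_movie(spec)
        table = background_decay(stack, seed=0)
        mean = table[table.roi == "mean"]
        _, tau = fit_background_tau(mean.time_s.to_numpy(), mean.mfi.to_numpy())
        assert tau == pytest.approx(1200.0, rel=0.10)

    def test_event_overlapping_roi_rejected_with_warning(self):
        stack = TimelapseStack(np.full((10, 32, 32), 100.0), dt=2.0, pixel_size=1.0)
        footprint = np.zeros((32, 32), dtype=bool)
        footprint[0:16, 0:16] = True
        with pytest.warns(UserWarning, match="rejected"):
            table = background_decay(
                stack, rois=[(0, 0), (18, 18)], event_footprints=[footprint]
            )
        assert set(table.roi.unique()) == {0, "mean"}


class TestCalibration:
    def test_default_levels_span_10nM_to_5uM(self):
        assert DEFAULT_CALIBRATION_LEVELS_M == (10e-9, 50e-9, 100e-9, 0.5e-6, 1e-6, 5e-6)

    def test_linear_curve_slope_recovered_within_1_percent(self):
        slope_true, intercept_true = 3.2e9, 14.0
        points = tuple(
            (c, slope_true * c + intercept_true) for c in DEFAULT_CALIBRATION_LEVELS_M
        )
        curve = CalibrationCurve(points=points)
        _, _, (slope, intercept) = calibrate_concentration(curve, 100.0)
        assert slope == pytest.approx(slope_true, rel=0.01)

    def test_intensity_at_a_calibration_point_maps_back(self):
        points = tuple((c, 2e9 * c + 5.0) for c in DEFAULT_CALIBRATION_LEVELS_M)
        curve = CalibrationCurve(points=points)
        conc, extrapolated, _ = calibrate_concentration(curve, points[2][1])
        assert conc == pytest.approx(points[2][0], rel=1e-6)
        assert not extrapolated

    def test_out_of_range_estimate_flagged_extrapolated(self):
        points = tuple((c, 2e9 * c) for c in DEFAULT_CALIBRATION_LEVELS_M)
        curve = CalibrationCurve(points=points)
        _, extrapolated, _ = calibrate_concentration(curve, 2e9 * 50e-6)
        assert extrapolated

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(points=((1e-8, 5.0),))
        with pytest.raises(ValueError):
            CalibrationCurve(points=((1e-8, 5.0), (1e-8, 6.0)))
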