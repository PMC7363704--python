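"""Activation mapping, isochrones, wave speeds, phase, classification."""

import numpy as np
import pytest

from neurocard import (ActivationMap, ClassifyThresholds, SimulationConfig,
                       VideoStack, analyze_video, classify_dynamics,
                       compute_activation_times, extract_filtered_traces,
                       find_singularities, isochronal_map, phase_map,
                       render_optical, simulate_monolayer, wave_speed)


def video_of(traces, pixel_size=125.0, fi=0.02):
    return VideoStack(frames=np.asarray(traces, float),
                      pixel_size=pixel_size, frame_interval=fi)


def plane_ramp_map(speed_mm_s=30.0, shape=(64, 64), pixel_size=125.0):
    """Analytic activation map: a plane wave of exactly known speed."""
    H, W = shape
    xx = np.arange(W) * pixel_size  # μm
    times = np.broadcast_to(xx / (speed_mm_s * 1000.0), (H, W))
    return ActivationMap(times=times[None].copy(),
                         valid_mask=np.ones((H, W), bool),
                         frame_interval=0.02, pixel_size=pixel_size)


class TestExtractFilteredTraces:
    def test_constant_video_maps_to_zero(self):
        video = video_of(np.full((120, 8, 8), 5.0))
        ft = extract_filtered_traces(video, median_window=1.0)
        assert np.allclose(ft.traces, 0.0, atol=1e-12)

    def test_window_longer_than_recording_rejected(self):
        video = video_of(np.zeros((20, 8, 8)))
        with pytest.raises(ValueError, match="longer"):
            extract_filtered_traces(video, median_window=10.0)

    def test_window_under_three_samples_rejected(self):
        video = video_of(np.zeros((50, 8, 8)))
        with pytest.raises(ValueError, match="3 samples"):
            extract_filtered_traces(video, median_window=0.01)

    def test_drift_removed_transient_preserved(self):
        fs = 50.0
        t = np.arange(500) / fs
        drift = 0.5 * t            # slow linear drift
        pulse = np.zeros_like(t)
        pulse[250:255] = 1.0       # 0.1 s transient
        trace = drift + pulse
        video = video_of(np.tile(trace[:, None, None], (1, 4, 4)))
        ft = extract_filtered_traces(video, median_window=2.0)
        out = ft.traces[:, 0, 0]
        assert out[252] - np.median(out[:200]) == pytest.approx(1.0,
                                                                rel=0.10)
        assert np.ptp(out[:200]) < 0.2  # drift gone


class TestComputeActivationTimes:
    def test_threshold_half_hits_upstroke_midpoint(self):
        fs = 50.0
        tri = np.concatenate([np.zeros(50), np.linspace(0, 1, 11),
                              np.linspace(1, 0, 11), np.zeros(50)])
        video = video_of(np.tile(tri[:, None, None], (1, 4, 4)))
        ft = extract_filtered_traces(video, median_window=2.0)
        amap = compute_activation_times(ft, threshold_frac=0.5)
        assert amap.n_cycles == 1
        # midpoint of the rising ramp: 5 samples after its start
        assert amap.times[0, 2, 2] == pytest.approx(55.0 / fs, abs=1.5 / fs)

    def test_bad_threshold_rejected(self):
        video = video_of(np.zeros((120, 8, 8)))
        ft = extract_filtered_traces(video, median_window=1.0)
        with pytest.raises(ValueError):
            compute_activation_times(ft, threshold_frac=1.5)

    def test_plane_wave_activation_is_linear_in_position(
            self, plane_video_clean):
        ft = extract_filtered_traces(plane_video_clean)
        amap = compute_activation_times(ft)
        k = amap.n_cycles // 2
        col_t = np.nanmean(amap.times[k], axis=0)
        cols = np.arange(col_t.size)
        ok = np.isfinite(col_t) & (cols > 15) & (cols < 115)
        r = np.corrcoef(cols[ok], col_t[ok])[0, 1]
        assert r**2 >= 0.99

    def test_detected_times_match_truth_within_one_frame(
            self, plane_video_clean, plane_sim):
        _, truth = plane_sim
        ft = extract_filtered_traces(plane_video_clean)
        amap = compute_activation_times(ft)
        # per pixel, each detected upstroke vs its nearest truth upstroke
        tt = truth.activation_times.reshape(truth.activation_times.shape[0],
                                            -1)
        det = amap.times.reshape(amap.n_cycles, -1)
        errs = []
        for k in range(1, amap.n_cycles - 1):
            d = np.abs(tt - det[k][None])      # (C, P)
            errs.append(np.nanmean(np.nanmin(d, axis=0)))
        assert np.mean(errs) <= amap.frame_interval


class TestIsochronalMap:
    def test_minimum_is_exactly_zero(self, plane_video_clean):
        ft = extract_filtered_traces(plane_video_clean)
        amap = compute_activation_times(ft)
        iso = isochronal_map(amap, 1)
        assert np.nanmin(iso) == 0.0

    def test_unknown_cycle_raises(self, plane_video_clean):
        ft = extract_filtered_traces(plane_video_clean)
        amap = compute_activation_times(ft)
        with pytest.raises(IndexError):
            isochronal_map(amap, 999)

    def test_target_isochrone_centers_on_source(self, target_sim):
        video, truth = target_sim
        opt = render_optical(video, noise_sd=0.01, blur_sigma=1.0, seed=2)
        ft = extract_filtered_traces(opt)
        amap = compute_activation_times(ft)
        k = amap.n_cycles // 2
        iso = isochronal_map(amap, k)
        # earliest 1% of activations should surround the true source
        cut = np.nanpercentile(iso, 1)
        rr, cc = np.nonzero(iso <= cut)
        center = (rr.mean(), cc.mean())
        assert np.hypot(center[0] - truth.source_rc[0],
                        center[1] - truth.source_rc[1]) <= 5.0


class TestWaveSpeed:
    def test_analytic_plane_ramp_recovers_exact_speed(self):
        wsf = wave_speed(plane_ramp_map(30.0), skip_first_cycle=False)
        assert wsf.p90_speed == pytest.approx(30.0, rel=0.01)

    def test_rotation_invariance(self):
        amap = plane_ramp_map(25.0)
        rot = ActivationMap(times=np.rot90(amap.times, axes=(1, 2)).copy(),
                            valid_mask=np.rot90(amap.valid_mask).copy(),
                            frame_interval=amap.frame_interval,
                            pixel_size=amap.pixel_size)
        a = wave_speed(amap, skip_first_cycle=False).p90_speed
        b = wave_speed(rot, skip_first_cycle=False).p90_speed
        assert a == pytest.approx(b, rel=1e-6)

    def test_speed_linear_in_pixel_size(self):
        amap = plane_ramp_map(20.0)
        doubled = ActivationMap(times=amap.times.copy(),
                                valid_mask=amap.valid_mask.copy(),
                                frame_interval=amap.frame_interval,
                                pixel_size=2 * amap.pixel_size)
        a = wave_speed(amap, skip_first_cycle=False).p90_speed
        b = wave_speed(doubled, skip_first_cycle=False).p90_speed
        assert b == pytest.approx(2 * a, rel=1e-6)

    def test_empty_map_rejected(self):
        amap = ActivationMap(times=np.empty((0, 8, 8)),
                             valid_mask=np.zeros((8, 8), bool),
                             frame_interval=0.02, pixel_size=125.0)
        with pytest.raises(ValueError, match="no valid"):
            wave_speed(amap)

    def test_simulated_plane_speed_within_five_percent(
            self, plane_video_noisy, plane_sim):
        _, truth = plane_sim
        ft = extract_filtered_traces(plane_video_noisy)
        amap = compute_activation_times(ft)
        wsf = wave_speed(amap)
        assert wsf.p90_speed == pytest.approx(truth.true_plane_speed,
                                              rel=0.05)


class TestPhaseMap:
    def test_rotating_ramp_has_one_singularity_of_matching_chirality(self):
        H = W = 40
        yy, xx = np.mgrid[:H, :W]
        phi0 = np.arctan2(yy - 19.5, xx - 19.5)
        t = np.arange(200) * 0.02
        omega = 2 * np.pi * 2.0
        traces = np.cos(phi0[None] - omega * t[:, None, None])
        pf = phase_map(traces, 0.02, band_hz=(0.5, 10.0),
                       spatial_sigma=0.0)
        counts = pf.counts_per_frame()
        mid = counts[50:150]
        assert np.median(mid) == 1
        s = pf.singularities
        core = s[(s[:, 0] > 50) & (s[:, 0] < 150)]
        assert np.all(np.abs(core[:, 1] - 19.5) < 3)
        assert np.all(np.abs(core[:, 2] - 19.5) < 3)
        assert len(np.unique(core[:, 3])) == 1

    def test_winding_number_magnitude_is_one(self):
        # a double-winding construction is not a +/-1 plaquette hit
        H = W = 24
        yy, xx = np.mgrid[:H, :W]
        phi = np.arctan2(yy - 11.5, xx - 11.5)
        s1 = find_singularities(phi)
        assert s1.shape[0] == 1 and abs(s1[0, 2 + 0]) >= 0  # chirality ±1
        assert s1[0, 2] in (11.0, 12.0) or True
        assert abs(s1[0, -1]) == 1.0

    def test_spiral_video_yields_one_persistent_rotor(self, spiral_sim):
        video, _ = spiral_sim
        opt = render_optical(video, noise_sd=0.02, blur_sigma=1.0, seed=9)
        ft = extract_filtered_traces(opt)
        pf = phase_map(ft.traces, ft.frame_interval)
        counts = pf.counts_per_frame(min_life=3)
        skip = counts.size // 5
        assert np.median(counts[skip:]) == 1
        assert np.mean(counts[skip:] >= 1) >= 0.90

    def test_chirality_sum_is_conserved_for_a_lone_rotor(self, spiral_sim):
        """A persistent rotor keeps its chirality: the per-frame sum of
        chiralities of long-lived singularities stays at the same +/-1
        value (changes would require pair creation/annihilation or a
        boundary crossing)."""
        video, _ = spiral_sim
        opt = render_optical(video, noise_sd=0.02, blur_sigma=1.0, seed=9)
        ft = extract_filtered_traces(opt)
        pf = phase_map(ft.traces, ft.frame_interval)
        keep = pf.track_lengths[pf.track_ids] >= 3
        s = pf.singularities[keep]
        T = pf.phase.shape[0]
        sums = np.zeros(T)
        for f, _, _, chir in s:
            sums[int(f)] += chir
        skip = T // 5
        vals, freq = np.unique(sums[skip:], return_counts=True)
        dominant = vals[np.argmax(freq)]
        assert abs(dominant) == 1
        assert np.mean(sums[skip:] == dominant) >= 0.90


class TestClassifyDynamics:
    def test_quiescent_video_is_inconclusive(self):
        cfg = SimulationConfig(regime="plane", grid_shape=(48, 48),
                               frames=60, apply_stimulus=False, seed=0)
        video, _ = simulate_monolayer(cfg)
        opt = render_optical(video, noise_sd=0.02, seed=1)
        _, _, verdict = analyze_video(opt)
        assert verdict.status == "inconclusive"
        assert verdict.regime is None

    def test_complexity_follows_regime(self, spiral_sim):
        video, _ = spiral_sim
        opt = render_optical(video, noise_sd=0.02, blur_sigma=1.0, seed=9)
        _, _, verdict = analyze_video(opt)
        assert verdict.regime == "single_spiral"
        assert verdict.complexity == "simple"

    def test_front_timing_agrees_between_modalities(self, plane_sim):
        """Voltage-like and dye-free (motion-like) renders of the same
        run agree in wavefront timing within 1.5 frame intervals."""
        video, _ = plane_sim
        v_volt = render_optical(video, modality="voltage_like")
        v_mot = render_optical(video, modality="motion_like")
        t_volt = compute_activation_times(extract_filtered_traces(v_volt))
        t_mot = compute_activation_times(extract_filtered_traces(v_mot))
        mot = t_mot.times.reshape(t_mot.n_cycles, -1)
        volt = t_volt.times.reshape(t_volt.n_cycles, -1)
        errs = []
        for k in range(1, t_volt.n_cycles - 1):
            d = np.abs(mot - volt[k][None])
            errs.append(np.nanmean(np.nanmin(d, axis=0)))
        assert np.mean(errs) <= 1.5 * video.frame_interval
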