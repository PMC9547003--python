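"""Kymograph tracking: bead finding, genomic mapping, sub-pixel
localization, linking, state segmentation, bleach-step counting and
downsampling."""
import numpy as np
import pytest

from kymotrap.simulate import (
    SyntheticSceneConfig,
    make_diffusion_track,
    render_kymograph,
)
from kymotrap.structures import STATIC, DIFFUSIVE, BeadGeometry, ForceTrace, Trajectory
from kymotrap.tracking import (
    count_bleach_steps,
    downsample_force,
    downsample_kymograph,
    find_beads,
    intensity_profile,
    localize_spot,
    segment_states,
    to_genomic,
    track,
)


@pytest.fixture
def small_bead_scene():
    """1 µm beads at px 5 and 95 (radius 5 px, tether spanning 10–90)."""
    return SyntheticSceneConfig(
        seed=0, duration=20.0, bead_diameter_um=1.0, pixel_size=100.0,
        n_pixels=100, tether_extension_nm=8000.0,
    )


def _gauss_profile(n_px, center, sigma, amp, offset=0.0):
    px = np.arange(n_px, dtype=float)
    return offset + amp * np.exp(-0.5 * ((px - center) / sigma) ** 2)


class TestFindBeads:
    def test_centers_recovered_within_half_pixel(self, small_bead_scene):
        assert small_bead_scene.left_bead_center_px == pytest.approx(5.0)
        assert small_bead_scene.right_bead_center_px == pytest.approx(95.0)
        kymo = render_kymograph([], small_bead_scene)
        beads = find_beads(kymo)
        assert beads.left_center_px == pytest.approx(5.0, abs=0.5)
        assert beads.right_center_px == pytest.approx(95.0, abs=0.5)

    def test_symmetric_scene_midpoint(self, scene):
        kymo = render_kymograph([], scene)
        beads = find_beads(kymo)
        midpoint = (beads.left_center_px + beads.right_center_px) / 2
        truth = (scene.left_bead_center_px + scene.right_bead_center_px) / 2
        assert midpoint == pytest.approx(truth, abs=0.5)

    def test_bead_free_image_errors(self, scene):
        kymo = render_kymograph([], scene, render_beads=False)
        with pytest.raises(ValueError):
            find_beads(kymo)


class TestToGenomic:
    @pytest.fixture
    def beads(self):
        # surfaces at px 10 and 90, 15 kbp tether
        return BeadGeometry(
            left_center_px=5.0, right_center_px=95.0, bead_diameter_um=1.0,
            tether_length_kbp=15.0, pixel_size_nm=100.0,
        )

    def test_midpoint_maps_to_half_tether(self, beads):
        assert to_genomic(50.0, beads) == pytest.approx(7.5)

    def test_left_surface_is_origin(self, beads):
        assert to_genomic(10.0, beads) == pytest.approx(0.0)

    def test_quarter_span_interpolation(self, beads):
        assert to_genomic(10.0 + 0.25 * 80.0, beads) == pytest.approx(3.75)

    def test_outside_tether_errors(self, beads):
        with pytest.raises(ValueError):
            to_genomic(5.0, beads)

    def test_centers_mode(self, beads):
        assert to_genomic(50.0, beads, mode="centers") == pytest.approx(7.5)
        assert to_genomic(5.0, beads, mode="centers") == pytest.approx(0.0)


class TestLocalizeSpot:
    def test_noiseless_integer_center_is_exact(self):
        counts = np.tile(_gauss_profile(40, 10.0, 1.5, 100.0, 2.0), (5, 1))
        fit = localize_spot(counts, 2, 10.0)
        assert fit.center_px == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("truth", [10.1, 10.4, 10.77])
    def test_noiseless_subpixel_unbiased(self, truth):
        counts = np.tile(_gauss_profile(40, truth, 1.5, 100.0, 2.0), (5, 1))
        fit = localize_spot(counts, 2, round(truth))
        assert abs(fit.center_px - truth) < 1e-3

    def test_poisson_precision_below_a_third_pixel(self, rng):
        errors = []
        clean = _gauss_profile(40, 10.3, 1.5, 100.0, 2.0)
        for _ in range(1000):
            counts = rng.poisson(np.tile(clean, (3, 1))).astype(float)
            fit = localize_spot(counts, 1, 10.0)
            if fit is not None:
                errors.append(fit.center_px - 10.3)
        assert len(errors) > 950
        assert np.std(errors) < 0.3

    def test_edge_window_errors(self):
        counts = np.tile(_gauss_profile(40, 10.0, 1.5, 100.0), (5, 1))
        with pytest.raises(ValueError):
            localize_spot(counts, 0, 10.0)
        with pytest.raises(ValueError):
            localize_spot(counts, 4, 10.0)

    def test_dim_or_deformed_spots_rejected(self, rng):
        noise = rng.normal(50.0, 5.0, (3, 40)).clip(min=0)
        assert localize_spot(noise, 1, 20.0, background_sd=15.0) is None


class TestTrack:
    def test_single_static_emitter_single_full_trajectory(self, scene):
        pos = np.full(scene.n_lines, scene.tether_span_nm / 2)
        kymo = render_kymograph([pos], scene, rng=np.random.default_rng(0),
                                bleach=False)
        trajs = track(kymo)
        assert len(trajs) == 1
        # spans the movie up to the 3-line window edges
        assert len(trajs[0]) >= scene.n_lines - 2

    def test_two_separated_emitters_no_identity_swaps(self, scene):
        x1 = np.full(scene.n_lines, scene.tether_span_nm * 0.3)
        x2 = np.full(scene.n_lines, scene.tether_span_nm * 0.7)
        kymo = render_kymograph([x1, x2], scene, rng=np.random.default_rng(1),
                                bleach=False)
        trajs = track(kymo)
        assert len(trajs) == 2
        for traj, truth in zip(sorted(trajs, key=lambda t: t.position_nm[0]),
                               (x1[0], x2[0])):
            assert np.all(np.abs(traj.position_nm - truth) < 200.0)

    def test_brownian_round_trip_rms(self, scene):
        # RMS error bound: localization noise plus the motion blur of the
        # 3-line moving window, var = (2/9)·2·D·dt for a random walk
        D = 0.02
        truth = make_diffusion_track(
            D, scene.line_time, scene.duration, x0=scene.tether_span_nm / 2,
            bounds=(600.0, scene.tether_span_nm - 600.0), seed=11,
        )[: scene.n_lines]
        kymo = render_kymograph([truth], scene, rng=np.random.default_rng(11),
                                bleach=False)
        trajs = track(kymo)
        assert len(trajs) == 1
        traj = trajs[0]
        start = int(round(traj.time[0] / scene.line_time))
        matched = truth[start : start + len(traj)]
        rms = np.sqrt(np.mean((traj.position_nm[: len(matched)] - matched) ** 2))
        sigma_loc = 10.0  # generous bound at this photon budget, nm
        sigma_blur = np.sqrt(2.0 / 9.0 * 2.0 * D * 1e6 * scene.line_time)
        assert rms < 2.0 * np.hypot(sigma_loc, sigma_blur)
        # ground-truth frames matched within the gate
        assert len(traj) >= 0.99 * (scene.n_lines - 2)


class TestSegmentStates:
    def test_pure_static_track_is_one_static_segment(self, rng):
        traj = Trajectory(time=np.arange(300) * 0.1,
                          position_nm=rng.normal(0, 30, 300))
        segment_states(traj)
        assert np.all(traj.states == STATIC)

    def test_pure_brownian_track_is_diffusive(self):
        x = make_diffusion_track(0.02, 0.1, 60.0, seed=2)
        traj = Trajectory(time=np.arange(len(x)) * 0.1, position_nm=x)
        segment_states(traj)
        assert np.mean(traj.states == STATIC) < 0.05

    def test_switch_boundary_recovered_within_two_windows(self, rng):
        window = 51
        diff = make_diffusion_track(0.02, 0.1, 30.0, seed=3)
        static = np.full(300, diff[-1]) + rng.normal(0, 30, 300)
        x = np.concatenate([diff[:-1] + rng.normal(0, 30, 300), static])
        traj = Trajectory(time=np.arange(len(x)) * 0.1, position_nm=x)
        segment_states(traj, window=window)
        boundary = np.flatnonzero(traj.states[:-1] != traj.states[1:])
        assert len(boundary) >= 1
        assert abs(boundary[0] - 300) <= 2 * window
        assert traj.states[0] == DIFFUSIVE and traj.states[-1] == STATIC

    def test_short_trajectory_gets_single_global_label(self):
        x = make_diffusion_track(0.02, 0.1, 2.0, seed=4)
        traj = Trajectory(time=np.arange(len(x)) * 0.1, position_nm=x)
        segment_states(traj, window=51)
        assert len(set(traj.states)) == 1


class TestCountBleachSteps:
    def test_noiseless_two_step_staircase(self):
        y = np.concatenate([np.full(60, 200.0), np.full(50, 100.0),
                            np.full(50, 0.0)])
        assert count_bleach_steps(y) == 2

    def test_constant_trace_has_no_steps(self):
        assert count_bleach_steps(np.full(100, 150.0)) == 0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            count_bleach_steps(np.full(10, 1.0))

    def test_poisson_dimer_traces_scored_two_steps(self):
        rng = np.random.default_rng(0)
        hits = 0
        clean = np.concatenate([np.full(70, 200.0), np.full(60, 100.0),
                                np.full(60, 0.0)])
        for _ in range(100):
            hits += count_bleach_steps(rng.poisson(clean + 5.0).astype(float)) == 2
        assert hits >= 90


class TestIntensityProfile:
    def test_docked_emitter_peak_at_junction(self, scene):
        pos = np.full(scene.n_lines, scene.kbp_to_nm(7.5))
        kymo = render_kymograph([pos], scene, rng=np.random.default_rng(5),
                                bleach=False)
        _, peaks_px, peaks_kbp = intensity_profile(kymo, (0.0, 60.0))
        assert len(peaks_kbp) == 1
        assert peaks_kbp[0] == pytest.approx(7.5, abs=0.3)

    def test_no_emitter_no_interior_peaks(self, scene):
        kymo = render_kymograph([], scene, rng=np.random.default_rng(6))
        _, peaks_px, _ = intensity_profile(kymo, (0.0, 60.0))
        assert len(peaks_px) == 0

    def test_empty_window_errors(self, scene):
        kymo = render_kymograph([], scene, rng=np.random.default_rng(7))
        with pytest.raises(ValueError):
            intensity_profile(kymo, (10.0, 10.0))


class TestDownsample:
    def test_factor_one_is_identity(self, scene):
        kymo = render_kymograph([], scene, rng=np.random.default_rng(8))
        down = downsample_kymograph(kymo, 1)
        np.testing.assert_array_equal(down.counts["green"], kymo.counts["green"])
        assert down.line_time == kymo.line_time

    def test_counts_conserved_under_downsampling(self, scene):
        kymo = render_kymograph([], scene, rng=np.random.default_rng(9))
        down = downsample_kymograph(kymo, 3)
        kept = (kymo.n_lines // 3) * 3
        assert down.counts["green"].sum() == kymo.counts["green"][:kept].sum()
        assert down.line_time == pytest.approx(3 * kymo.line_time)

    def test_force_60hz_to_3hz_block_means(self):
        t = np.arange(120) / 60.0
        f = np.arange(120, dtype=float)
        down = downsample_force(ForceTrace(time=t, force=f), target_rate=3.0)
        # 20-sample blocks: means 9.5, 29.5, ...
        np.testing.assert_allclose(down.force,
                                   [9.5, 29.5, 49.5, 69.5, 89.5, 109.5])

    def test_oversized_factor_errors(self, scene):
        kymo = render_kymograph([], scene, rng=np.random.default_rng(10))
        with pytest.raises(ValueError):
            downsample_kymograph(kymo, kymo.n_lines + 1)
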