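import numpy as np
import pytest

from pelvitherm import (
    PRFSConstants,
    PhaseScan,
    ScanGeometry,
    apply_exclusion,
    build_series,
    compute_delta_t,
    correct_drift,
    mask_low_snr,
    optimize_exclusion_threshold,
    roi_mean_series,
    simulate_session,
)
from pelvitherm.core import ProbeTrace, wrap_phase
from pelvitherm.thermometry import (
    RoiSet,
    Stage,
    TemperatureMapSeries,
)

CONST = PRFSConstants()


def _scan(phase, t=0.0):
    phase = np.asarray(phase, dtype=float)
    return PhaseScan(phase=wrap_phase(phase), magnitude=np.ones_like(phase), time_s=t)


def _series(maps, times=None, stage=Stage.UNCORRECTED, valid=None):
    maps = np.asarray(maps, dtype=float)
    if times is None:
        times = np.arange(maps.shape[0], dtype=float)
    if valid is None:
        valid = np.ones_like(maps, dtype=bool)
    return TemperatureMapSeries(maps=maps, valid=valid,
                                scan_times_s=np.asarray(times, float), stage=stage)


class TestComputeDeltaT:
    def test_identical_phases_give_zero(self):
        shape = (8, 8, 2)
        s = _scan(np.random.default_rng(0).uniform(-3, 3, shape))
        assert (compute_delta_t(s, s, CONST) == 0).all()

    def test_known_phase_difference_decodes_to_one_degree(self):
        shape = (4, 4, 1)
        ref = _scan(np.zeros(shape))
        scan = _scan(np.full(shape, CONST.phase_rad_per_c * 1.0))
        np.testing.assert_allclose(compute_delta_t(scan, ref, CONST), 1.0, rtol=1e-12)

    def test_alpha_scaling_inverse_linearity(self):
        """Scaling alpha by k scales the decoded temperature by 1/k."""
        shape = (4, 4, 1)
        ref = _scan(np.zeros(shape))
        scan = _scan(np.full(shape, -0.002))
        base = compute_delta_t(scan, ref, CONST)
        scaled = compute_delta_t(
            scan, ref, PRFSConstants(alpha_ppm_per_c=CONST.alpha_ppm_per_c * 4)
        )
        np.testing.assert_allclose(scaled, base / 4, rtol=1e-12)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            compute_delta_t(_scan(np.zeros((4, 4, 1))), _scan(np.zeros((5, 5, 1))), CONST)


class TestMaskLowSnr:
    def test_uniform_map_masks_nothing(self):
        s = mask_low_snr(_series(np.full((2, 6, 6, 2), 1.5)))
        assert s.valid.all()
        assert s.stage is Stage.SNR_MASKED

    @pytest.mark.parametrize("spike,masked", [(5.0, True), (2.9, False)])
    def test_single_spike_against_flat_background(self, spike, masked):
        m = np.zeros((1, 7, 7, 1))
        m[0, 3, 3, 0] = spike
        s = mask_low_snr(_series(m))
        assert bool(~s.valid[0, 3, 3, 0]) is masked

    def test_neighbors_of_spike_survive(self):
        # |0 - 5/8| < 3 for the 8 neighbors of a lone 5-degree spike
        m = np.zeros((1, 7, 7, 1))
        m[0, 3, 3, 0] = 5.0
        s = mask_low_snr(_series(m))
        assert s.valid.sum() == 7 * 7 - 1

    def test_border_voxels_use_available_neighbors(self):
        m = np.zeros((1, 5, 5, 1))
        m[0, 0, 0, 0] = 5.0  # corner spike, 3 neighbors
        s = mask_low_snr(_series(m))
        assert not s.valid[0, 0, 0, 0]

    def test_stage_enforced(self):
        s = _series(np.zeros((1, 4, 4, 1)), stage=Stage.DRIFT_CORRECTED)
        with pytest.raises(ValueError, match="stage"):
            mask_low_snr(s)


class TestCorrectDrift:
    def test_planar_ramp_with_fat_everywhere_is_removed(self):
        nx = ny = 12
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        ramp = 0.5 + 0.1 * x - 0.05 * y
        s = _series(ramp[None, :, :, None], stage=Stage.SNR_MASKED)
        fat = np.ones((nx, ny, 1), dtype=bool)
        out = correct_drift(s, fat)
        np.testing.assert_allclose(out.maps, 0.0, atol=1e-9)
        assert out.stage is Stage.DRIFT_CORRECTED

    def test_fat_mean_residual_is_zero_per_slice(self, test_geometry):
        session = simulate_session(
            geometry=test_geometry, drift_rad=0.08, noise_sd_rad=1e-3,
            air_artifact_rad=0.0, seed=4,
        )
        series = correct_drift(
            mask_low_snr(build_series(session.scans, session.constants)),
            session.anatomy.fat_mask,
        )
        fat = session.anatomy.fat_mask
        for n in range(series.maps.shape[0]):
            for z in range(test_geometry.n_slices):
                sel = fat[:, :, z] & series.valid[n, :, :, z]
                assert abs(series.maps[n, :, :, z][sel].mean()) <= 0.05

    def test_idempotence(self, test_geometry):
        """A second drift fit sees ~zero fat residual and changes nothing."""
        session = simulate_session(
            geometry=test_geometry, drift_rad=0.08, noise_sd_rad=1e-3,
            air_artifact_rad=0.0, seed=4,
        )
        once = correct_drift(
            mask_low_snr(build_series(session.scans, session.constants)),
            session.anatomy.fat_mask,
        )
        again = correct_drift(
            once.__class__(maps=once.maps, valid=once.valid,
                           scan_times_s=once.scan_times_s, stage=Stage.SNR_MASKED),
            session.anatomy.fat_mask,
        )
        assert np.abs(again.maps - once.maps).max() <= 1e-9

    def test_no_drift_session_changes_little(self, test_geometry):
        noise = 1e-3
        session = simulate_session(
            geometry=test_geometry, drift_rad=0.0, noise_sd_rad=noise,
            air_artifact_rad=0.0, seed=5,
        )
        before = mask_low_snr(build_series(session.scans, session.constants))
        after = correct_drift(before, session.anatomy.fat_mask)
        noise_equiv_c = np.sqrt(2) * noise / abs(session.constants.phase_rad_per_c)
        body = session.anatomy.body_mask
        delta = np.abs(after.maps - before.maps)[:, body]
        assert delta.max() <= 3 * noise_equiv_c

    def test_sparse_fat_falls_back_with_warning(self):
        m = np.zeros((1, 10, 10, 1))
        fat = np.zeros((10, 10, 1), dtype=bool)
        fat[4, 4:8, 0] = True  # 4 voxels < 6 coefficients
        s = _series(m, stage=Stage.SNR_MASKED)
        with pytest.warns(UserWarning, match="order reduced"):
            correct_drift(s, fat)

    def test_zero_fat_slice_flagged(self):
        s = _series(np.zeros((1, 8, 8, 2)), stage=Stage.SNR_MASKED)
        fat = np.zeros((8, 8, 2), dtype=bool)
        fat[2:6, 2:6, 0] = True  # slice 1 has no fat
        out = correct_drift(s, fat)
        assert (0, 1) in out.uncorrected_slices


class TestRoiSet:
    @pytest.mark.parametrize("matrix", [128, 256])
    def test_rasterized_area_close_to_nominal(self, matrix):
        g = ScanGeometry(matrix=matrix, n_slices=3)
        rois = RoiSet(geometry=g, centers={"bladder": {1: (matrix / 2, matrix / 2)}})
        area = len(rois.voxels["bladder"][1]) * g.voxel_inplane_cm**2
        # center-in-circle rasterization biases slightly low; tolerance is one
        # voxel area or 0.06 cm^2 (~4%), whichever the grid makes larger
        assert abs(area - 1.47) <= max(g.voxel_inplane_cm**2, 0.06)


def _toy_threshold_setup(roi_values, probe_value, n_scans=1):
    """One-slice, one-location series with given ROI voxel temperatures."""
    nx = ny = 16
    maps = np.zeros((n_scans, nx, ny, 1))
    g = ScanGeometry(matrix=nx, n_slices=1, fov_cm=16.0)  # 1 cm voxels
    cx = cy = 8.0
    rois = RoiSet(geometry=g, centers={"bladder": {0: (cx, cy)}}, diameter_cm=3.0)
    assert len(rois.voxels["bladder"][0]) >= len(roi_values)
    rois.voxels["bladder"][0] = rois.voxels["bladder"][0][: len(roi_values)]
    coords = rois.voxels["bladder"][0]
    for n in range(n_scans):
        for v, (i, j) in zip(roi_values, coords):
            maps[n, i, j, 0] = v
    series = _series(maps, times=np.zeros(n_scans), stage=Stage.DRIFT_CORRECTED)
    trace = ProbeTrace(
        location="bladder",
        cycle_times_s=np.array([0.0]),
        positions=np.array([[8, 8, 0]]),
        slice_offsets_cm=np.array([-2.0]),
        readings=np.array([[probe_value]]),
    )
    return series, rois, {"bladder": trace}


class TestExclusionThreshold:
    def test_outliers_push_optimum_between_truth_and_spike(self):
        """ROI at 4 C with 12 C outliers, probe 4 C: optimum strictly
        separates signal from outliers and beats the open threshold."""
        vals = [3.6, 3.8, 4.0, 4.2, 4.4, 4.0] + [12.0] * 2
        series, rois, probes = _toy_threshold_setup(vals, probe_value=4.0)
        res = optimize_exclusion_threshold(series, rois, probes,
                                           scan_duration_s=0.0, max_offset_s=1.0)
        assert 4.05 <= res.threshold_c <= 11.95
        g20 = res.objective[np.argmin(np.abs(res.grid_c - 20.0))]
        assert res.objective.min() < g20

    def test_perfect_agreement_gives_zero_objective(self):
        vals = [2.0] * 5
        series, rois, probes = _toy_threshold_setup(vals, probe_value=2.0)
        res = optimize_exclusion_threshold(series, rois, probes,
                                           scan_duration_s=0.0, max_offset_s=1.0)
        assert res.threshold_c == pytest.approx(2.0, abs=0.051)
        assert res.objective[res.grid_c >= 2.0].max() <= 1e-9

    def test_matches_exhaustive_oracle(self):
        """Argmin of G(p) agrees with a naive loop over the same grid."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            vals = rng.uniform(0, 15, size=8)
            probe = float(rng.uniform(0, 6))
            series, rois, probes = _toy_threshold_setup(list(vals), probe)
            res = optimize_exclusion_threshold(series, rois, probes,
                                               scan_duration_s=0.0, max_offset_s=1.0)
            grid = res.grid_c
            g_ref = []
            for p in grid:
                surv = vals[np.abs(vals) <= p]
                g_ref.append(abs(surv.mean() - probe) if len(surv) else np.inf)
            g_ref = np.asarray(g_ref)
            assert res.threshold_c == pytest.approx(grid[int(np.argmin(g_ref))])
            np.testing.assert_allclose(res.objective, g_ref, atol=1e-12)

    def test_requires_drift_corrected_stage(self):
        series, rois, probes = _toy_threshold_setup([1.0], 1.0)
        series = _series(series.maps, times=series.scan_times_s)
        with pytest.raises(ValueError, match="stage"):
            optimize_exclusion_threshold(series, rois, probes)


class TestApplyExclusion:
    def test_open_threshold_changes_nothing(self):
        m = np.random.default_rng(0).uniform(-10, 10, (2, 6, 6, 2))
        s = apply_exclusion(_series(m, stage=Stage.DRIFT_CORRECTED), 20.0)
        assert s.valid.all()
        assert s.stage is Stage.FILTERED

    def test_zero_threshold_kills_all_nonzero_voxels(self):
        m = np.array([[[[0.0], [1.0]], [[-0.5], [0.0]]]])
        s = apply_exclusion(_series(m, stage=Stage.DRIFT_CORRECTED), 0.0)
        assert (s.valid == (m == 0)).all()

    def test_survivor_count_monotone_in_threshold(self):
        m = np.random.default_rng(1).uniform(-15, 15, (3, 8, 8, 2))
        counts = [
            apply_exclusion(_series(m, stage=Stage.DRIFT_CORRECTED), p).valid.sum()
            for p in [12.0, 9.0, 6.0, 3.0, 0.0]
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRoiMeanSeries:
    def test_uniform_roi_mean(self):
        series, rois, _ = _toy_threshold_setup([2.0] * 5, 2.0)
        out = roi_mean_series(apply_exclusion(series, 20.0), rois)
        assert out.mean_c["bladder"][0] == pytest.approx(2.0)

    def test_mean_arithmetic_with_and_without_exclusion(self):
        vals = [1.0, 2.0, 3.0, 6.0]
        nx = 8
        g = ScanGeometry(matrix=nx, n_slices=1, fov_cm=8.0)
        rois = RoiSet(geometry=g, centers={"rectum": {0: (4.0, 4.0)}}, diameter_cm=2.5)
        coords = rois.voxels["rectum"][0][: len(vals)]
        rois.voxels["rectum"][0] = coords  # exactly these four voxels
        maps = np.zeros((1, nx, nx, 1))
        for v, (i, j) in zip(vals, coords):
            maps[0, i, j, 0] = v
        s = _series(maps, stage=Stage.DRIFT_CORRECTED)
        out = roi_mean_series(apply_exclusion(s, 7.0), rois)
        assert out.mean_c["rectum"][0] == pytest.approx(3.0)
        # 6 -> 8: now excluded by the 7-degree threshold, mean of survivors
        maps2 = maps.copy()
        i, j = coords[3]
        maps2[0, i, j, 0] = 8.0
        s2 = _series(maps2, stage=Stage.DRIFT_CORRECTED)
        out2 = roi_mean_series(apply_exclusion(s2, 7.0), rois)
        assert out2.mean_c["rectum"][0] == pytest.approx(2.0)
        assert out2.n_valid["rectum"][0] == 3

    def test_zero_survivors_flagged_as_nan(self):
        maps = np.full((1, 8, 8, 1), 10.0)
        g = ScanGeometry(matrix=8, n_slices=1, fov_cm=8.0)
        rois = RoiSet(geometry=g, centers={"vagina": {0: (4.0, 4.0)}}, diameter_cm=2.5)
        out = roi_mean_series(
            apply_exclusion(_series(maps, stage=Stage.DRIFT_CORRECTED), 7.0), rois
        )
        assert np.isnan(out.mean_c["vagina"][0])
        assert out.surviving_fraction("vagina")[0] == 0.0
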