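"""3D detection, segmentation, signed distances, classification, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotchip import (
    CalibratedStack3D,
    DepthWindow,
    DetectionParams3D,
    SyntheticSceneSpec3D,
    classify_infiltration,
    detect_tcells_3d,
    generate_scene,
    pool_chips,
    quantify_chamber,
    segment_organoid,
    signed_distance,
)
from spotchip.infiltrate import CellDetection3D, InfiltrationResult

from oracles import match_detections

VOXEL_DIAG_211 = np.sqrt(2.0**2 + 1.0 + 1.0)


def _empty_stack(noise_sd=0.0, seed=0, shape=(40, 80, 80), voxel=(4.0, 2.0, 2.0)):
    rng = np.random.default_rng(seed)
    base = np.full(shape, 10.0)
    if noise_sd:
        base = base + rng.normal(0, noise_sd, shape)
    return CalibratedStack3D(
        {"tcell": base, "organoid": np.full(shape, 10.0)}, voxel
    )


class TestDetectTcells3D:
    def test_constant_background_yields_no_detections(self):
        assert detect_tcells_3d(_empty_stack()) == []

    def test_noisy_background_yields_no_detections(self):
        assert detect_tcells_3d(_empty_stack(noise_sd=8.0, seed=1)) == []

    def test_single_blob_found_within_one_voxel(self):
        spec = SyntheticSceneSpec3D(
            stack_size_vox=(40, 80, 80),
            organoid_semi_axes_um=(20.0, 20.0, 20.0),
            organoid_intensity=0.0,
            cells_outside=[30.0],
            noise_sd_tcell=0.0,
            noise_sd_organoid=0.0,
            seed=3,
        )
        stack, truth = generate_scene(spec)
        dets = detect_tcells_3d(stack)
        assert len(dets) == 1
        err = np.abs(np.array(dets[0].centroid_um) - np.array(truth.cells[0].position_um))
        assert np.all(err <= np.array(spec.voxel_size_um))

    def test_fifty_cells_high_recall_and_precision(self):
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            spec = SyntheticSceneSpec3D(
                cells_inside=list(rng.uniform(-90, -10, 20)),
                cells_outside=list(rng.uniform(10, 60, 30)),
                seed=seed,
            )
            stack, truth = generate_scene(spec)
            dets = detect_tcells_3d(stack)
            tp, fp, fn = match_detections(
                np.array([c.position_um for c in truth.cells]),
                np.array([d.centroid_um for d in dets]),
                tol_um=6.0,
            )
            assert tp / (tp + fn) >= 0.98
            assert tp / (tp + fp) >= 0.98

    def test_missing_channel_raises(self):
        stack = CalibratedStack3D({"organoid": np.zeros((4, 4, 4))}, (1.0, 1.0, 1.0))
        with pytest.raises(Exception, match="tcell"):
            detect_tcells_3d(stack)

    def test_thin_stack_warns_but_runs(self):
        stack = CalibratedStack3D(
            {"tcell": np.zeros((2, 16, 16)), "organoid": np.zeros((2, 16, 16))},
            (2.0, 2.0, 2.0),
        )
        with pytest.warns(UserWarning, match="thinner"):
            assert detect_tcells_3d(stack) == []


class TestSegmentOrganoid:
    def test_sphere_volume_within_5pct(self, sphere_scene):
        spec, stack, truth = sphere_scene
        seg = segment_organoid(stack)
        analytic = 4.0 / 3.0 * np.pi * 60.0**3
        assert seg.volume_um3 == pytest.approx(analytic, rel=0.05)
        assert seg.mesh_volume_um3 == pytest.approx(seg.volume_um3, rel=0.05)

    def test_ellipsoid_volume_within_5pct(self):
        spec = SyntheticSceneSpec3D(
            stack_size_vox=(60, 120, 120),
            organoid_shape="ellipsoid",
            organoid_semi_axes_um=(80.0, 60.0, 50.0),
            seed=5,
        )
        stack, truth = generate_scene(spec)
        seg = segment_organoid(stack)
        assert seg.volume_um3 == pytest.approx(truth.analytic_volume_um3, rel=0.05)
        assert seg.mesh_volume_um3 == pytest.approx(seg.volume_um3, rel=0.05)

    def test_largest_of_two_bodies_kept(self):
        shape = (40, 100, 100)
        voxel = (2.0, 2.0, 2.0)
        zc = np.arange(shape[0])[:, None, None] * voxel[0]
        yc = np.arange(shape[1])[None, :, None] * voxel[1]
        xc = np.arange(shape[2])[None, None, :] * voxel[2]
        big = ((zc - 40) ** 2 + (yc - 60) ** 2 + (xc - 60) ** 2) <= 30**2
        small = ((zc - 40) ** 2 + (yc - 160) ** 2 + (xc - 160) ** 2) <= 10**2
        arr = np.where(big | small, 100.0, 0.0)
        stack = CalibratedStack3D({"organoid": arr, "tcell": np.zeros(shape)}, voxel)
        seg = segment_organoid(stack)
        assert seg.mask[20, 30, 30] and not seg.mask[20, 80, 80]
        assert seg.volume_um3 == pytest.approx(4 / 3 * np.pi * 30**3, rel=0.05)

    def test_empty_channel_raises_no_organoid(self):
        stack = CalibratedStack3D(
            {"organoid": np.zeros((8, 8, 8)), "tcell": np.zeros((8, 8, 8))},
            (1.0, 1.0, 1.0),
        )
        with pytest.raises(ValueError, match="no organoid"):
            segment_organoid(stack, threshold_method="fixed", fixed_value=10.0)

    def test_internal_holes_filled(self):
        arr = np.zeros((20, 20, 20))
        arr[4:16, 4:16, 4:16] = 100.0
        arr[9:11, 9:11, 9:11] = 0.0  # internal cavity
        stack = CalibratedStack3D({"organoid": arr, "tcell": np.zeros((20, 20, 20))}, (1.0, 1.0, 1.0))
        seg = segment_organoid(stack, threshold_method="fixed", fixed_value=50.0)
        assert seg.mask[10, 10, 10]
        assert seg.volume_um3 == pytest.approx(12.0**3)


class TestSignedDistance:
    def _sphere_seg(self, sphere_scene):
        _, stack, truth = sphere_scene
        return truth, segment_organoid(stack)

    def test_sphere_closed_forms(self, sphere_scene):
        """Cells at radii {30, 60, 75} from a R=60 sphere center give signed
        distances {-30, 0, +15} within one voxel diagonal."""
        truth, seg = self._sphere_seg(sphere_scene)
        center = np.array(truth.organoid_center_um)
        cells = []
        for i, radius in enumerate((30.0, 60.0, 75.0), start=1):
            pos = center + np.array([0.0, radius, 0.0])
            cells.append(CellDetection3D(i, tuple(pos), 0.0, (1, 1, 1)))
        dists = dict(signed_distance(cells, seg))
        assert dists[1] == pytest.approx(-30.0, abs=VOXEL_DIAG_211)
        assert dists[2] == pytest.approx(0.0, abs=VOXEL_DIAG_211)
        assert dists[3] == pytest.approx(15.0, abs=VOXEL_DIAG_211)

    def test_sign_matches_mask_membership(self, sphere_scene):
        """signed_distance < 0 exactly when the centroid voxel is inside."""
        truth, seg = self._sphere_seg(sphere_scene)
        rng = np.random.default_rng(17)
        voxel = np.array(seg.voxel_size_um)
        extent = (np.array(seg.mask.shape) - 1) * voxel
        points = rng.uniform(0, 1, (1000, 3)) * extent
        cells = [CellDetection3D(i, tuple(p), 0.0, (1, 1, 1)) for i, p in enumerate(points)]
        for (cid, d), p in zip(signed_distance(cells, seg), points):
            idx = tuple(np.rint(p / voxel).astype(int))
            inside = bool(seg.mask[idx])
            assert (d < 0) == inside or d == 0.0

    def test_planted_cells_match_analytic_distance(self, sphere_scene):
        spec, stack, truth = sphere_scene
        seg = segment_organoid(stack)
        cells = [
            CellDetection3D(i, c.position_um, 0.0, (1, 1, 1))
            for i, c in enumerate(truth.cells, start=1)
        ]
        for (cid, d), c in zip(signed_distance(cells, seg), truth.cells):
            assert d == pytest.approx(c.signed_distance_um, abs=VOXEL_DIAG_211)


class TestClassifyInfiltration:
    def test_window_membership_forced_cases(self):
        """Distances {-250, -100, -10, 0, +15} µm under the default
        [-200, 0] window classify as deep/in/in/in/outside."""
        dists = [(1, -250.0), (2, -100.0), (3, -10.0), (4, 0.0), (5, 15.0)]
        res = classify_infiltration(dists)
        classes = [r.classification for r in res.records]
        assert classes == ["excluded_deep", "infiltrated", "infiltrated", "infiltrated", "outside"]
        assert res.n_infiltrated == 3
        assert res.infiltrated_fraction == pytest.approx(3 / 5)

    def test_empty_cell_list(self):
        res = classify_infiltration([])
        assert res.n_cells_total == 0
        assert res.infiltrated_fraction == 0.0

    def test_all_far_outside(self):
        res = classify_infiltration([(i, 500.0) for i in range(5)])
        assert res.n_infiltrated == 0

    def test_include_deep_merges_deep_cells(self):
        res = classify_infiltration([(1, -250.0)], include_deep=True)
        assert res.n_infiltrated == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 9999),
        grow=st.floats(0.0, 300.0),
    )
    def test_enlarging_window_is_monotone(self, seed, grow):
        rng = np.random.default_rng(seed)
        dists = [(i, float(d)) for i, d in enumerate(rng.uniform(-400, 200, 50))]
        base = DepthWindow()
        wider = DepthWindow(d_min_um=base.d_min_um - grow, d_max_um=base.d_max_um + grow)
        assert (
            classify_infiltration(dists, wider).n_infiltrated
            >= classify_infiltration(dists, base).n_infiltrated
        )


class TestPoolChips:
    def _result(self, n_inf, n_total=20):
        recs = [
            type("R", (), {})  # placeholder, replaced below
            for _ in range(0)
        ]
        from spotchip.infiltrate import CellDistanceRecord

        records = [CellDistanceRecord(i, -10.0, "infiltrated") for i in range(n_inf)]
        records += [CellDistanceRecord(n_inf + i, 50.0, "outside") for i in range(n_total - n_inf)]
        return InfiltrationResult(
            chamber_id="c",
            n_cells_total=n_total,
            n_infiltrated=n_inf,
            infiltrated_fraction=n_inf / n_total,
            organoid_volume_um3=1e6,
            records=records,
        ).validate()

    def test_two_chips_mean_and_sem(self):
        pooled = pool_chips([self._result(10), self._result(14)])
        assert pooled.mean_n_infiltrated == pytest.approx(12.0)
        assert pooled.sem_n_infiltrated == pytest.approx(2.0)

    def test_single_chip_refused(self):
        with pytest.raises(ValueError, match="at least 2 chips"):
            pool_chips([self._result(10)])

    def test_identical_chips_sem_zero(self):
        pooled = pool_chips([self._result(8)] * 4)
        assert pooled.sem_n_infiltrated == 0.0
        assert pooled.mean_n_infiltrated == 8.0


class TestQuantifyChamber:
    def test_planted_depths_recovered(self):
        """20 cells at depths -150..-5 µm inside a R=170 µm organoid plus 30
        outside cells: exactly the 20 are classified infiltrated."""
        rng = np.random.default_rng(77)
        spec = SyntheticSceneSpec3D(
            stack_size_vox=(110, 230, 230),
            organoid_semi_axes_um=(170.0, 170.0, 170.0),
            cells_inside=list(rng.uniform(-150, -8, 20)),
            cells_outside=list(rng.uniform(8, 60, 30)),
            seed=8,
        )
        stack, truth = generate_scene(spec)
        res = quantify_chamber(stack)
        assert res.n_cells_total == 50
        assert res.n_infiltrated == 20

    def test_organoid_only_chamber(self):
        spec = SyntheticSceneSpec3D(seed=12)
        stack, _ = generate_scene(spec)
        res = quantify_chamber(stack)
        assert res.n_cells_total == 0
        assert res.infiltrated_fraction == 0.0

    def test_same_seed_identical_results(self):
        spec = SyntheticSceneSpec3D(cells_inside=[-50.0, -20.0], cells_outside=[30.0], seed=21)
        outs = []
        for _ in range(2):
            stack, _ = generate_scene(spec)
            outs.append(quantify_chamber(stack).to_dict())
        assert outs[0] == outs[1]

    def test_stage_error_names_stage(self):
        stack = CalibratedStack3D(
            {"tcell": np.zeros((8, 8, 8)), "organoid": np.zeros((8, 8, 8))},
            (1.0, 1.0, 1.0),
        )
        with pytest.raises(ValueError, match="segment_organoid failed"):
            quantify_chamber(stack, threshold_method="fixed", fixed_value=5.0)

    def test_result_echoes_parameters(self):
        spec = SyntheticSceneSpec3D(cells_outside=[40.0], seed=30)
        stack, _ = generate_scene(spec)
        res = quantify_chamber(stack, DetectionParams3D(xy_diameter_um=5, z_height_um=10))
        assert res.params["detection"]["xy_diameter_um"] == 5
        assert res.params["depth_window_um"] == [-200.0, 0.0]
        assert res.params["voxel_size_um"] == [4.0, 2.0, 2.0]
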