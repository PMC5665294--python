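import numpy as np
import pandas as pd
import pytest

import sfxgeom.fingerprint as fp
from sfxgeom.fingerprint import (
    MAX_VECTOR_LEN,
    SpotTriad,
    _SpotTable,
    angle_tolerance_deg,
    build_ideal_lookup,
    collect_vectors,
    refine_pair_noneuclidean,
    refine_panel_euclidean_pre,
    refine_preindex_full,
    triad_score,
)
from sfxgeom.geometry import rms_corner_displacement
from sfxgeom.indexed import RefineConfig
from sfxgeom.synthetic import PerturbBounds, SceneSpec, make_scene, perturb

LAMBDA = 1.46
CELL = (105.5, 105.5, 105.5, 90.0, 90.0, 90.0)


def _spots_df(rows):
    return pd.DataFrame(rows, columns=["image_id", "panel_id", "fast", "slow",
                                       "value"])


class TestCollectVectors:
    def test_two_spots_same_panel_one_intra_vector(self, grid_detector):
        spots = _spots_df([(0, "p00", 40.0, 40.0, 9.0), (0, "p00", 43.0, 45.0, 8.0)])
        vecs = collect_vectors(spots, grid_detector, LAMBDA)
        assert len(vecs) == 1
        assert vecs[0].kind == "intra"
        assert vecs[0].panels == ("p00",)

    def test_long_vectors_excluded(self, grid_detector):
        # spots on opposite detector corners give |v| > 0.15 A^-1
        spots = _spots_df([(0, "p00", 95.0, 95.0, 9.0), (0, "p11", 5.0, 5.0, 8.0)])
        vecs = collect_vectors(spots, grid_detector, LAMBDA)
        assert vecs == []

    def test_counts_match_hand_enumeration(self, grid_detector):
        # 3 panels x 3 nearby spots; every in-cutoff pair must appear once
        rows = []
        for pid in ("p00", "p01", "p10"):
            for k in range(3):
                rows.append((0, pid, 48.0 + 2 * k, 50.0, 5.0))
        spots = _spots_df(rows)
        vecs = collect_vectors(spots, grid_detector, LAMBDA)
        from sfxgeom.fingerprint import _spot_qs

        q = _spot_qs(grid_detector, spots["panel_id"].to_numpy(object),
                     spots["fast"].to_numpy(), spots["slow"].to_numpy(), LAMBDA)
        expected = sum(
            1
            for i in range(9)
            for j in range(i + 1, 9)
            if np.linalg.norm(q[j] - q[i]) <= MAX_VECTOR_LEN
        )
        assert len(vecs) == expected > 0
        n_intra = sum(1 for v in vecs if v.kind == "intra")
        assert n_intra == 9  # 3 pairs within each of the 3 panels

    def test_filter_invariant_never_violated(self, small_scene):
        sub = small_scene.spots[small_scene.spots.image_id < 3]
        vecs = collect_vectors(sub, small_scene.detector, LAMBDA)
        assert len(vecs) > 0
        assert all(np.linalg.norm(v.v) <= MAX_VECTOR_LEN for v in vecs)


@pytest.fixture(scope="module")
def lookup40():
    return build_ideal_lookup(CELL, "I", rlp_radius=0.002, voxels=40)


class TestLookup:
    def test_default_grid_shape_and_dtype(self, default_lookup):
        assert default_lookup.grid.shape == (240, 240, 240)
        assert default_lookup.grid.dtype == np.float32

    def test_scores_bounded(self, lookup40):
        assert lookup40.grid.min() >= 0.0
        assert lookup40.grid.max() <= 1.0

    def test_swap_symmetry(self, lookup40):
        np.testing.assert_allclose(lookup40.grid,
                                   np.swapaxes(lookup40.grid, 0, 1), atol=1e-7)

    def test_ideal_orthogonal_shortest_pair_scores_high(self, default_lookup):
        # two orthogonal (1,1,0)-type vectors of the I-centred cubic cell
        l = np.sqrt(2.0) / 105.5
        s_ideal = float(default_lookup.score(l, l, 90.0))
        assert s_ideal > 0.9
        # strictly above surrounding off-ideal queries
        assert s_ideal > float(default_lookup.score(l + 0.0015, l, 90.0))
        assert s_ideal > float(default_lookup.score(l, l, 90.0 - 2.5 *
                                                    angle_tolerance_deg(l, l, 0.002)))

    def test_monotone_decay_toward_tolerance_edge(self, default_lookup):
        l = np.sqrt(2.0) / 105.5
        deltas = np.array([0.0, 0.0005, 0.001, 0.0015, 0.0025])
        scores = default_lookup.score(l + deltas, np.full_like(deltas, l),
                                      np.full_like(deltas, 90.0))
        assert all(scores[i] >= scores[i + 1] - 1e-6 for i in range(len(deltas) - 1))

    def test_out_of_range_scores_zero(self, lookup40):
        assert lookup40.score(0.2, 0.01, 45.0) == 0.0

    def test_angle_folding_equivalence(self, lookup40):
        # vector pairs at 100 and 80 degrees land in the same voxel slice:
        # only the (v1, v2) angle differs here, the other two pair angles
        # are 90 degrees in both configurations
        v1 = np.array([0.01, 0.0, 0.0])
        v3 = np.array([0.0, 0.0, 0.011])
        scores = {}
        for ang in (80.0, 100.0):
            rot = np.deg2rad(ang)
            v2 = 0.012 * np.array([np.cos(rot), np.sin(rot), 0.0])
            scores[ang] = fp._score_triad_vectors(v1[None], v2[None], v3[None],
                                                  lookup40)
        np.testing.assert_allclose(scores[100.0], scores[80.0], atol=1e-12)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_lookup(CELL, "I", 0.002, voxels=8)

    def test_huge_cell_without_vectors_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_lookup((2.0, 2.0, 2.0, 90, 90, 90), "P", 0.002,
                               voxels=40, max_len=0.15)


class TestTriadScore:
    def test_empty_triads_score_zero(self, default_lookup):
        assert triad_score([], default_lookup) == 0.0

    def test_ideal_triad_contributes_near_one(self, default_lookup):
        # three lattice vectors pairwise at ideal (length, length, angle)
        b = 1.0 / 105.5
        v1 = np.array([2 * b, 0.0, 0.0])  # (2,0,0)
        v2 = np.array([0.0, 2 * b, 0.0])  # (0,2,0)
        v3 = -(v1 + v2)
        triad = SpotTriad(0, (0, 1, 2), (v1, v2, v3))
        score = triad_score([triad], default_lookup)
        # trilinear sampling of off-voxel-centre peaks attenuates the ideal
        # product below 1, but it stays well above any perturbed triad
        assert 0.3 < score <= 1.0
        bad = SpotTriad(0, (0, 1, 2), (v1 * 1.07, v2, -(v1 * 1.07 + v2)))
        assert triad_score([bad], default_lookup) < score

    def test_panel_shift_lowers_score(self, small_scene, default_lookup):
        det = small_scene.detector
        table = _SpotTable(small_scene.spots, det, LAMBDA, MAX_VECTOR_LEN, 40)
        assert len(table.triads) > 50
        qs = table.qs(det, np.arange(len(table.fast)))
        base = fp._score_triad_vectors(*fp._triad_vectors(qs, table.triads),
                                       default_lookup).sum()
        shifted = det.copy()
        for panel in shifted.panels():
            panel.midpoint = panel.midpoint + np.array([3 * panel.pixel_size, 0, 0])
        # whole-detector shift distorts the fingerprint (it is not a sphere move)
        qs2 = table.qs(shifted, np.arange(len(table.fast)))
        moved = fp._score_triad_vectors(*fp._triad_vectors(qs2, table.triads),
                                        default_lookup).sum()
        assert base > moved


class TestTriadClosure:
    def test_triad_vectors_close(self, small_scene):
        table = _SpotTable(small_scene.spots, small_scene.detector, LAMBDA,
                           MAX_VECTOR_LEN, 40)
        qs = table.qs(small_scene.detector, np.arange(len(table.fast)))
        v1, v2, v3 = fp._triad_vectors(qs, table.triads)
        np.testing.assert_allclose(v1 + v2 + v3, 0.0, atol=1e-12)


class TestPanelStagePre:
    def test_unperturbed_panel_stays(self, preindex_scene, default_lookup):
        # drift on truth input is bounded by the voxel-quantization floor of
        # the lookup grid (about half a pixel equivalent)
        det = preindex_scene.detector.copy()
        table = _SpotTable(preindex_scene.spots, det, LAMBDA, MAX_VECTOR_LEN, 40)
        panel = det.panels()[5]
        ok = refine_panel_euclidean_pre(panel, table, default_lookup,
                                        RefineConfig())
        assert ok
        assert abs(panel.pending.d) < 0.08
        assert abs(panel.pending.alpha) < np.deg2rad(0.2)
        assert abs(panel.pending.beta) < np.deg2rad(0.2)

    def test_inplane_shift_recovered(self, default_lookup):
        scene = make_scene(SceneSpec(n_images=120, seed=17))
        det = scene.detector.copy()
        panel = det.panels()[5]
        shift = 1.5 * panel.pixel_size
        panel.midpoint = panel.midpoint + np.array([shift, 0.0, 0.0])
        before = rms_corner_displacement(det, scene.detector)
        table = _SpotTable(scene.spots, det, LAMBDA, MAX_VECTOR_LEN, 40)
        cfg = RefineConfig()
        ok = refine_panel_euclidean_pre(panel, table, default_lookup, cfg)
        assert ok
        # the Euclidean component of a lateral shift is small; after this
        # stage the residual must not exceed the injected 1.5 px by more
        # than 0.5 px equivalent
        from sfxgeom.geometry import absorb_offsets

        absorb_offsets(det)
        after = rms_corner_displacement(det, scene.detector)
        assert after <= before + 0.5 * panel.pixel_size

    def test_sparse_panel_skipped(self, grid_detector, default_lookup):
        spots = _spots_df([(0, "p00", 50.0, 50.0, 5.0), (0, "p00", 52.0, 50.0, 4.0),
                           (0, "p00", 50.0, 52.0, 3.0)])
        table = _SpotTable(spots, grid_detector, LAMBDA, MAX_VECTOR_LEN, 40)
        panel = grid_detector.copy().panels()[3]
        assert refine_panel_euclidean_pre(panel, table, default_lookup,
                                          RefineConfig()) is False


class TestPairStage:
    def test_groups_at_truth_keep_small_angles(self, small_scene, default_lookup):
        det = small_scene.detector.copy()
        table = _SpotTable(small_scene.spots, det, LAMBDA, MAX_VECTOR_LEN, 40)
        grp = [g for g in det.groups() if len(g.children) == 2][-1]
        a, b = grp.children
        ca0 = fp._node_centre(a, det)
        cb0 = fp._node_centre(b, det)
        refine_pair_noneuclidean(a, b, table, default_lookup, RefineConfig(), det)
        # pendings absorbed; displacement of each group centre stays tiny
        assert np.linalg.norm(fp._node_centre(a, det) - ca0) < 5e-3
        assert np.linalg.norm(fp._node_centre(b, det) - cb0) < 5e-3

    def test_equal_and_opposite_conserves_sample_distances(self, small_scene,
                                                           default_lookup):
        det = small_scene.detector.copy()
        r_before = {p.id: np.linalg.norm(det.panel_geometry(p.id)[0])
                    for p in det.panels()}
        table = _SpotTable(small_scene.spots, det, LAMBDA, MAX_VECTOR_LEN, 40)
        grp = [g for g in det.groups() if len(g.children) == 2][0]
        refine_pair_noneuclidean(grp.children[0], grp.children[1], table,
                                 default_lookup, RefineConfig(), det)
        for p in det.panels():
            assert abs(np.linalg.norm(det.panel_geometry(p.id)[0]) -
                       r_before[p.id]) < 1e-9

    def test_opposite_lateral_shifts_realigned(self, default_lookup):
        scene = make_scene(SceneSpec(n_images=150, seed=23))
        det = scene.detector.copy()
        grp = [g for g in det.groups() if len(g.children) == 2
               and all(not hasattr(c, "children") for c in g.children)][0]
        pa, pb = grp.children
        pa.midpoint = pa.midpoint + np.array([pa.pixel_size, 0.0, 0.0])
        pb.midpoint = pb.midpoint - np.array([pb.pixel_size, 0.0, 0.0])
        rel0 = np.linalg.norm(
            (pa.midpoint - scene.detector.find(pa.id).midpoint)
            - (pb.midpoint - scene.detector.find(pb.id).midpoint)
        )
        table = _SpotTable(scene.spots, det, LAMBDA, MAX_VECTOR_LEN, 40)
        ok = refine_pair_noneuclidean(pa, pb, table, default_lookup,
                                      RefineConfig(), det)
        assert ok
        rel1 = np.linalg.norm(
            (det.find(pa.id).midpoint - scene.detector.find(pa.id).midpoint)
            - (det.find(pb.id).midpoint - scene.detector.find(pb.id).midpoint)
        )
        assert rel1 < 0.3 * rel0


class TestFullPreIndex:
    def test_zero_perturbation_is_stable(self, preindex_scene, default_lookup):
        det = refine_preindex_full(preindex_scene.detector, preindex_scene.spots,
                                   CELL, "I", LAMBDA, RefineConfig(),
                                   lookup=default_lookup)
        rms = rms_corner_displacement(det, preindex_scene.detector)
        # within the lookup's voxel-quantization noise floor
        assert rms < 0.75 * 0.11

    def test_invariant_to_image_label_shuffling(self, default_lookup):
        # no orientation information is used: relabelling images changes nothing
        scene = make_scene(SceneSpec(n_images=30, seed=31))
        pert, _ = perturb(scene.detector, PerturbBounds(slide_px=1.0), 5)
        shuffled = scene.spots.copy()
        mapping = {i: (i * 7 + 3) % 30 for i in range(30)}
        shuffled["image_id"] = shuffled["image_id"].map(mapping)
        shuffled = shuffled.sort_values(["image_id", "panel_id", "fast"],
                                        ignore_index=True)
        cfg = RefineConfig()
        det_a = refine_preindex_full(pert, scene.spots, CELL, "I", LAMBDA, cfg,
                                     lookup=default_lookup)
        det_b = refine_preindex_full(pert, shuffled, CELL, "I", LAMBDA, cfg,
                                     lookup=default_lookup)
        assert rms_corner_displacement(det_a, det_b) < 1e-6

    def test_cost_scales_linearly_with_images(self, default_lookup):
        counts = {}
        for n in (10, 20):
            scene = make_scene(SceneSpec(n_images=n, seed=37))
            fp.TRIAD_OPS["scored"] = 0
            refine_preindex_full(scene.detector, scene.spots, CELL, "I", LAMBDA,
                                 RefineConfig(param_passes=1),
                                 lookup=default_lookup)
            counts[n] = fp.TRIAD_OPS["scored"]
        # doubling the images at most ~doubles the triad evaluations
        # (quadratic growth would quadruple them)
        assert counts[20] <= 3.0 * counts[10]
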