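import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sfxgeom.geometry import pixel_to_lab
from sfxgeom.projection import (
    EvidenceGrid,
    Lattice,
    back_project,
    centring_mask,
    compute_offsets,
    local_max_search,
    predict_stills,
    reciprocal_basis,
)

CELL = (105.5, 105.5, 105.5, 90.0, 90.0, 90.0)
LAMBDA = 1.46


class TestBackProject:
    def test_forward_beam_maps_to_origin(self):
        np.testing.assert_allclose(back_project([0.0, 0.0, 123.0], LAMBDA),
                                   np.zeros(3), atol=1e-15)

    def test_90_degree_scattering(self):
        # closed form |q| = 2 sin(theta)/lambda at 2theta = 90 deg
        q = back_project([100.0, 0.0, 0.0], LAMBDA)
        assert np.linalg.norm(q) == pytest.approx(np.sqrt(2.0) / LAMBDA, rel=1e-12)

    def test_everything_lands_on_the_ewald_sphere(self, rng):
        pos = rng.normal(size=(50, 3)) * 40 + [0, 0, 90]
        q = back_project(pos, LAMBDA)
        centre = q + [0, 0, 1.0 / LAMBDA]
        np.testing.assert_allclose(np.linalg.norm(centre, axis=1), 1.0 / LAMBDA,
                                   atol=1e-12)

    def test_lowest_resolution_reflection_angle(self):
        # body-centred cubic a = 105.5 A: lowest allowed reflection is (1,1,0);
        # its scattering angle at 1.46 A is 1.1 degrees
        d110 = 105.5 / np.sqrt(2.0)
        two_theta = 2.0 * np.degrees(np.arcsin(LAMBDA / (2.0 * d110)))
        assert round(two_theta, 1) == 1.1
        # and back_project of a ray at that angle gives |q| = 1/d(110)
        z = 90.0
        r = z * np.tan(np.radians(two_theta))
        q = back_project([r, 0.0, z], LAMBDA)
        assert np.linalg.norm(q) == pytest.approx(1.0 / d110, rel=1e-6)

    def test_zero_position_rejected(self):
        with pytest.raises(ValueError):
            back_project([0.0, 0.0, 0.0], LAMBDA)


class TestCentring:
    @pytest.mark.parametrize("centring,allowed,forbidden", [
        ("P", (1, 0, 0), None),
        ("I", (1, 1, 0), (1, 0, 0)),
        ("C", (1, 1, 1), (1, 0, 0)),
        ("F", (1, 1, 1), (1, 1, 0)),
    ])
    def test_rules(self, centring, allowed, forbidden):
        assert centring_mask(np.array([allowed]), centring)[0]
        if forbidden is not None:
            assert not centring_mask(np.array([forbidden]), centring)[0]


def _lattice(seed=0, cell=CELL, centring="I"):
    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat))
    return Lattice(image_id=0, ub=rot.as_matrix() @ reciprocal_basis(cell),
                   cell=cell, centring=centring)


class TestPredictStills:
    def test_zero_radius_random_orientation_empty(self, grid_detector):
        preds = predict_stills(_lattice(3), grid_detector, LAMBDA, 0.0, 3.5)
        assert len(preds) == 0

    def test_constructed_on_sphere_reflection_hits_oracle_pixel(self, grid_detector):
        # orientation built so (6,6,8) sits exactly on the sphere and its ray
        # lands on a panel; the predicted pixel must match a hand-computed
        # ray-plane intersection
        miller = np.array([6.0, 6.0, 8.0])
        bmat = reciprocal_basis(CELL)
        q0 = bmat @ miller
        qlen = np.linalg.norm(q0)
        # on-sphere target with the same length, aimed into the x,y > 0 panel
        qz = -(qlen**2) * LAMBDA / 2.0
        qxy = np.sqrt(qlen**2 - qz**2)
        target = np.array([qxy / np.sqrt(2), qxy / np.sqrt(2), qz])
        rot, _ = Rotation.align_vectors(target[None, :], q0[None, :])
        lat = Lattice(0, rot.as_matrix() @ bmat, CELL, "I")
        preds = predict_stills(lat, grid_detector, LAMBDA, 1e-9, 3.5)
        rows = np.flatnonzero(np.all(preds.miller == miller, axis=1))
        assert len(rows) == 1
        n = rows[0]
        ray = target + [0, 0, 1.0 / LAMBDA]
        panel = grid_detector.find(preds.panel_ids[n])
        mid, f_ax, s_ax = panel.effective()
        normal = np.cross(f_ax, s_ax)
        hit = ray * (mid @ normal) / (ray @ normal)
        fast = (hit - mid) @ f_ax / panel.pixel_size + panel.n_fast / 2
        slow = (hit - mid) @ s_ax / panel.pixel_size + panel.n_slow / 2
        np.testing.assert_allclose(preds.pixel[n], [fast, slow], atol=1e-8)

    def test_matches_brute_force_enumeration(self, grid_detector):
        # independent oracle: explicit Python loop over all |h|,|k|,|l| <= H
        lat = _lattice(7)
        max_res = 8.0
        rlp = 5e-4
        preds = predict_stills(lat, grid_detector, LAMBDA, rlp, max_res)
        got = {tuple(m) for m in preds.miller}

        expected = set()
        hmax = int(np.ceil(105.5 / max_res)) + 1
        for h in range(-hmax, hmax + 1):
            for k in range(-hmax, hmax + 1):
                for l in range(-hmax, hmax + 1):
                    if (h + k + l) % 2:
                        continue
                    q = lat.ub @ [h, k, l]
                    if q @ q == 0 or q @ q > (1 / max_res) ** 2:
                        continue
                    e = np.linalg.norm(q + [0, 0, 1 / LAMBDA]) - 1 / LAMBDA
                    if abs(e) > rlp:
                        continue
                    ray = q + [0, 0, 1 / LAMBDA]
                    if ray[2] <= 0:
                        continue
                    for panel in grid_detector.panels():
                        mid, f_ax, s_ax = panel.effective()
                        normal = np.cross(f_ax, s_ax)
                        t = (mid @ normal) / (ray @ normal)
                        hit = ray * t
                        fast = (hit - mid) @ f_ax / panel.pixel_size + panel.n_fast / 2
                        slow = (hit - mid) @ s_ax / panel.pixel_size + panel.n_slow / 2
                        if 0 <= fast <= panel.n_fast and 0 <= slow <= panel.n_slow:
                            expected.add((h, k, l))
        assert got == expected
        assert len(got) > 0

    def test_count_monotone_in_rlp_radius(self, grid_detector):
        lat = _lattice(11)
        counts = [len(predict_stills(lat, grid_detector, LAMBDA, r, 3.5))
                  for r in (1e-4, 3e-4, 9e-4)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_reprojection_recovers_q_pred(self, grid_detector):
        # back_project of the predicted pixel is the identity on q
        lat = _lattice(13)
        preds = predict_stills(lat, grid_detector, LAMBDA, 3e-4, 3.5)
        assert len(preds) > 0
        for n in range(len(preds)):
            panel = grid_detector.find(preds.panel_ids[n])
            pos = pixel_to_lab(panel, preds.pixel[n, 0], preds.pixel[n, 1])
            q_dir = back_project(pos, LAMBDA)
            # same direction; |q| differs by the off-sphere component of q_pred
            np.testing.assert_allclose(
                np.cross(q_dir + [0, 0, 1 / LAMBDA], preds.rays[n]),
                np.zeros(3), atol=1e-9,
            )

    def test_pairwise_dq_invariant_under_master_rotation(self, grid_detector):
        from sfxgeom.geometry import apply_noneuclidean

        lat = _lattice(17)
        p0 = predict_stills(lat, grid_detector, LAMBDA, 3e-4, 3.5)
        rotated = apply_noneuclidean(grid_detector, 0.002, -0.001, 0.003,
                                     axis=[0.0, 0.0, 1.0])
        p1 = predict_stills(lat, rotated, LAMBDA, 3e-4, 3.5)
        common = set(map(tuple, p0.miller)) & set(map(tuple, p1.miller))
        assert len(common) >= 2
        # q values are lattice points: identical regardless of geometry
        for m in common:
            q0 = p0.q[np.all(p0.miller == m, axis=1)][0]
            q1 = p1.q[np.all(p1.miller == m, axis=1)][0]
            np.testing.assert_allclose(q0, q1, atol=1e-10)


class TestLocalMaxSearch:
    @staticmethod
    def _grid(spots):
        return EvidenceGrid.from_spots(*(np.array(v, float) for v in zip(*spots)))

    def test_radius_zero_returns_anchor(self):
        grid = self._grid([(10.4, 20.6, 5.0)])
        offset, value = local_max_search(grid, (10.2, 20.9), 0)
        assert offset == (0, 0) and value == 5.0

    def test_constructed_peak_found(self):
        grid = self._grid([(13.5, 18.5, 9.0), (10.5, 20.5, 3.0)])
        offset, value = local_max_search(grid, (10.0, 20.0), 5)
        assert offset == (3, -2) and value == 9.0

    def test_tie_breaks_by_scan_order(self):
        # two equal maxima; exhaustive scan in (slow, fast) order wins
        grid = self._grid([(12.5, 19.5, 7.0), (8.5, 21.5, 7.0)])
        offset, _ = local_max_search(grid, (10.0, 20.0), 5)
        best = None
        for j in range(15, 26):
            for i in range(5, 16):
                cell = grid.spot(i, j)
                if cell and (best is None or cell[2] > best[2]):
                    best = (i - 10, j - 20, cell[2])
        assert offset == (best[0], best[1])

    def test_empty_window_returns_none(self):
        grid = self._grid([(50.5, 50.5, 1.0)])
        assert local_max_search(grid, (10.0, 10.0), 2) is None

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            local_max_search(self._grid([(1.5, 1.5, 1.0)]), (1.0, 1.0), -1)


class TestComputeOffsets:
    def _setup(self, grid_detector, jitter=0.0):
        lat = _lattice(19)
        preds = predict_stills(lat, grid_detector, LAMBDA, 3e-4, 3.5)
        evidence = {}
        for pid in set(preds.panel_ids.tolist()):
            sub = preds.for_panel(pid)
            evidence[pid] = EvidenceGrid.from_spots(
                sub.pixel[:, 0] + jitter, sub.pixel[:, 1], np.full(len(sub), 90.0)
            )
        return preds, evidence

    def test_exact_observation_gives_zero_offsets(self, grid_detector):
        preds, evidence = self._setup(grid_detector)
        offsets = compute_offsets(preds, evidence, grid_detector, LAMBDA)
        assert sum(len(o) for o in offsets) > 0
        for o in offsets:
            np.testing.assert_allclose(o.dpx, 0.0, atol=1e-12)
            np.testing.assert_allclose(o.dq, 0.0, atol=1e-12)

    def test_one_pixel_offset_matches_two_call_oracle(self, grid_detector):
        preds, evidence = self._setup(grid_detector, jitter=1.0)
        offsets = compute_offsets(preds, evidence, grid_detector, LAMBDA)
        o = offsets[0]
        panel = grid_detector.find(o.panel_id)
        keep = o.obs_pixel[:, 0] <= panel.n_fast  # jitter may leave the panel
        o.obs_pixel, o.pred_pixel = o.obs_pixel[keep], o.pred_pixel[keep]
        o.dpx, o.dq = o.dpx[keep], o.dq[keep]
        np.testing.assert_allclose(o.dpx[:, 0], 1.0, atol=1e-12)
        expected = back_project(
            pixel_to_lab(panel, o.obs_pixel[:, 0], o.obs_pixel[:, 1]), LAMBDA
        ) - back_project(
            pixel_to_lab(panel, o.pred_pixel[:, 0], o.pred_pixel[:, 1]), LAMBDA
        )
        np.testing.assert_allclose(o.dq, expected, atol=1e-10)

    def test_strong_classification_follows_sigma_model(self, grid_detector):
        # I/sigma = sqrt(I/gain) >= 0.67  <=>  I >= 0.67^2 * gain
        preds, _ = self._setup(grid_detector)
        pid = preds.panel_ids[0]
        sub = preds.for_panel(pid)
        threshold = 0.67**2 * 9.0
        values = np.full(len(sub), threshold - 1e-6)
        values[0] = threshold + 1e-6
        evidence = {pid: EvidenceGrid.from_spots(sub.pixel[:, 0], sub.pixel[:, 1],
                                                 values)}
        (o,) = compute_offsets(preds, evidence, grid_detector, LAMBDA)
        order = np.argsort(o.obs_value)
        assert not o.strong[order[:-1]].any()
        assert o.strong[order[-1]]
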