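"""Orientation-free geometry refinement from unindexed still patterns.

Spots on a still image obey a "lattice-like" structure even when no
orientation matrix is known: the joint distribution of (length, length,
angle) over pairs of back-projected inter-spot reciprocal vectors sharing a
spot is fixed by the unit-cell dimensions and centring alone — the unit-cell
fingerprint.  A 3D lookup grid (default 240 voxels per dimension, single
precision) scores any observed vector pair from 0 to 1 with a linear ascent
from the edge of the acceptable tolerance to the ideal value; length
tolerance is the reciprocal-lattice-point radius and the angle tolerance

    d_angle(l1, l2) = asin(min(1, r/l1)) + asin(min(1, r/l2))

widens for shorter vectors.  Spot triads contribute the product of their
three pair scores, and the refinement target is the sum over triads.

Vectors longer than 0.15 A^-1 are rejected throughout.  Per-panel Euclidean
movements are refined against intra-panel triads; panels are then locked to
one another by equal-and-opposite sphere rotations of sibling groups about
the axis through the sample toward the midpoint of the two group centres,
ascending the pairing hierarchy to the whole detector.  Absolute alignment
of the master detector to the beam is intentionally not refined here (the
divergence is bounded by the scattering angle of the lowest-resolution
reflection); the indexed path handles it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    DetectorGroup,
    MovementParams,
    Panel,
    absorb_offsets,
    lab_positions,
    sphere_rotation,
)
from .indexed import RefineConfig, _refine_modes
from .projection import back_project, centring_mask, reciprocal_basis

logger = logging.getLogger(__name__)

__all__ = [
    "VectorObs",
    "FingerprintLookup",
    "SpotTriad",
    "collect_vectors",
    "build_ideal_lookup",
    "triad_score",
    "refine_panel_euclidean_pre",
    "refine_pair_noneuclidean",
    "refine_preindex_full",
    "MAX_VECTOR_LEN",
]

MAX_VECTOR_LEN = 0.15  # A^-1 rejection cutoff for inter-spot vectors


@dataclass
class VectorObs:
    """One back-projected inter-spot vector on one image."""

    image_id: int
    spot_a: int
    spot_b: int
    v: np.ndarray  # A^-1
    kind: str  # "intra" | "inter"
    panels: tuple[str, ...]


@dataclass
class SpotTriad:
    """Three spots and the three closing vectors between them."""

    image_id: int
    spots: tuple[int, int, int]
    vectors: tuple[np.ndarray, np.ndarray, np.ndarray]  # ab, bc, ca; sum = 0


class FingerprintLookup:
    """3D (length, length, angle) score grid for observed vector pairs.

    Axes span [0, max_len] A^-1 for both lengths and [0, 90] degrees for the
    folded angle, half-open voxels, symmetric under swapping the lengths.
    Scores are in [0, 1]; queries outside the axes score 0.  ``score``
    interpolates trilinearly between voxel centres so the refinement target
    is piecewise smooth.
    """

    def __init__(self, grid: np.ndarray, max_len: float, cell, rlp_radius: float):
        self.grid = grid
        self.voxels = grid.shape[0]
        self.max_len = max_len
        self.cell = cell
        self.rlp_radius = rlp_radius
        self._dl = max_len / self.voxels
        self._da = 90.0 / self.voxels

    def score(self, l1, l2, angle_deg) -> np.ndarray:
        """Trilinearly interpolated pair scores; vectorized."""
        l1 = np.asarray(l1, dtype=float)
        l2 = np.asarray(l2, dtype=float)
        a = np.asarray(angle_deg, dtype=float)
        out_of_range = (l1 >= self.max_len) | (l2 >= self.max_len)
        ci = np.clip(l1 / self._dl - 0.5, 0.0, self.voxels - 1.0)
        cj = np.clip(l2 / self._dl - 0.5, 0.0, self.voxels - 1.0)
        ck = np.clip(a / self._da - 0.5, 0.0, self.voxels - 1.0)
        i0 = np.minimum(ci.astype(int), self.voxels - 2)
        j0 = np.minimum(cj.astype(int), self.voxels - 2)
        k0 = np.minimum(ck.astype(int), self.voxels - 2)
        fi, fj, fk = ci - i0, cj - j0, ck - k0
        g = self.grid
        val = np.zeros(np.broadcast(l1, l2, a).shape)
        for di, wi in ((0, 1 - fi), (1, fi)):
            for dj, wj in ((0, 1 - fj), (1, fj)):
                for dk, wk in ((0, 1 - fk), (1, fk)):
                    val += wi * wj * wk * g[i0 + di, j0 + dj, k0 + dk]
        return np.where(out_of_range, 0.0, val)


def _lattice_vectors(cell, centring: str, max_len: float) -> np.ndarray:
    bmat = reciprocal_basis(tuple(cell))
    smin = np.linalg.svd(bmat, compute_uv=False)[-1]
    hmax = int(np.ceil(max_len / smin))
    r = np.arange(-hmax, hmax + 1)
    h, k, l = np.meshgrid(r, r, r, indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    hkl = hkl[centring_mask(hkl, centring)]
    v = hkl @ bmat.T
    lens = np.linalg.norm(v, axis=1)
    keep = (lens > 0) & (lens <= max_len)
    return v[keep]


def angle_tolerance_deg(l1, l2, rlp_radius: float) -> np.ndarray:
    """Angle tolerance from the length tolerances; wider for shorter vectors."""
    t = np.arcsin(np.minimum(1.0, rlp_radius / np.asarray(l1))) + np.arcsin(
        np.minimum(1.0, rlp_radius / np.asarray(l2))
    )
    return np.degrees(t)


_LOOKUP_CACHE: dict[tuple, FingerprintLookup] = {}


def build_ideal_lookup(cell, centring: str = "P", rlp_radius: float = 0.002,
                       voxels: int = 240, max_len: float = MAX_VECTOR_LEN
                       ) -> FingerprintLookup:
    """Score grid from the ideal reciprocal lattice of (cell, centring).

    Every unordered pair of lattice vectors sharing the origin stamps a
    linear-ramp peak at (|v1|, |v2|, folded angle), with length tolerance
    ``rlp_radius`` and the length-dependent angle tolerance; the grid is
    symmetric in the two length axes.  Grids are memoized (read-only).
    """
    key = (tuple(cell), centring, float(rlp_radius), int(voxels), float(max_len))
    cached = _LOOKUP_CACHE.get(key)
    if cached is not None:
        return cached
    if voxels < 16:
        raise ValueError("need at least 16 voxels per dimension")
    if rlp_radius <= 0:
        raise ValueError("rlp_radius must be positive")
    vecs = _lattice_vectors(cell, centring, max_len)
    if len(vecs) == 0:
        raise ValueError("no reciprocal lattice vectors below the cutoff; "
                         "cell too large for max_len")
    lens = np.linalg.norm(vecs, axis=1)
    # distinct length classes (rounded well below voxel resolution)
    qlen = np.round(lens / 1e-9).astype(np.int64)
    classes, cls = np.unique(qlen, return_inverse=True)
    class_len = classes * 1e-9
    n_cls = len(class_len)
    da = 90.0 / voxels
    dl = max_len / voxels

    # representative exact angle per (class, class, angle-voxel)
    rep = np.full((n_cls, n_cls, voxels), -1.0, dtype=np.float64)
    unit = vecs / lens[:, None]
    for i in range(len(vecs) - 1):
        cosang = np.abs(unit[i + 1 :] @ unit[i])
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        av = np.minimum((ang / da).astype(int), voxels - 1)
        c1 = np.full(len(ang), cls[i])
        c2 = cls[i + 1 :]
        empty = rep[c1, c2, av] < 0
        rep[c1[empty], c2[empty], av[empty]] = ang[empty]
        rep[c2[empty], c1[empty], av[empty]] = ang[empty]

    grid = np.zeros((voxels, voxels, voxels), dtype=np.float32)
    centres_l = (np.arange(voxels) + 0.5) * dl
    centres_a = (np.arange(voxels) + 0.5) * da
    half_w = int(np.ceil(rlp_radius / dl)) + 1
    occupied = np.argwhere(np.any(rep >= 0, axis=2))
    for c1, c2 in occupied:
        if c1 > c2:
            continue  # symmetric partner stamped together
        ideals = rep[c1, c2]
        ang_vals = np.sort(ideals[ideals >= 0])
        l1c, l2c = class_len[c1], class_len[c2]
        tol_a = angle_tolerance_deg(l1c, l2c, rlp_radius)
        # linear ramp over the angle axis: distance to nearest ideal angle
        idx = np.searchsorted(ang_vals, centres_a)
        left = ang_vals[np.clip(idx - 1, 0, len(ang_vals) - 1)]
        right = ang_vals[np.clip(idx, 0, len(ang_vals) - 1)]
        dist = np.minimum(np.abs(centres_a - left), np.abs(centres_a - right))
        profile = np.maximum(0.0, 1.0 - dist / tol_a)
        nz = np.flatnonzero(profile)
        if len(nz) == 0:
            continue
        i1 = int(l1c / dl)
        i2 = int(l2c / dl)
        s1 = slice(max(0, i1 - half_w), min(voxels, i1 + half_w + 1))
        s2 = slice(max(0, i2 - half_w), min(voxels, i2 + half_w + 1))
        ramp1 = np.maximum(0.0, 1.0 - np.abs(centres_l[s1] - l1c) / rlp_radius)
        ramp2 = np.maximum(0.0, 1.0 - np.abs(centres_l[s2] - l2c) / rlp_radius)
        block = (ramp1[:, None, None] * ramp2[None, :, None] * profile[nz][None, None, :]).astype(
            np.float32
        )
        sub = grid[s1, s2][:, :, nz]
        grid[np.ix_(range(*s1.indices(voxels)), range(*s2.indices(voxels)), nz)] = np.maximum(
            sub, block
        )
        if c1 != c2:
            grid[np.ix_(range(*s2.indices(voxels)), range(*s1.indices(voxels)), nz)] = np.maximum(
                grid[s2, s1][:, :, nz], block.transpose(1, 0, 2)
            )
    result = FingerprintLookup(grid, max_len, tuple(cell), rlp_radius)
    _LOOKUP_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# Observed vectors and triads


def _spot_qs(detector: DetectorGroup, panel_ids, fast, slow, wavelength: float
             ) -> np.ndarray:
    """Back-projected reciprocal coordinates of spots on current geometry."""
    q = np.empty((len(fast), 3))
    panel_ids = np.asarray(panel_ids, dtype=object)
    for pid in set(panel_ids.tolist()):
        m = panel_ids == pid
        panel = detector.find(pid)
        mid, f_ax, s_ax = detector.panel_geometry(pid)
        lab = lab_positions(mid, f_ax, s_ax, panel.pixel_size, panel.n_fast,
                            panel.n_slow, np.asarray(fast)[m], np.asarray(slow)[m])
        q[m] = back_project(lab, wavelength)
    return q


def collect_vectors(spots, detector: DetectorGroup, wavelength: float,
                    max_len: float = MAX_VECTOR_LEN) -> list[VectorObs]:
    """All intra- and inter-panel spot-to-spot vectors within the cutoff.

    ``spots`` is a DataFrame with image_id, panel_id, fast, slow, value;
    spot indices in the result refer to row order within each image.
    """
    out: list[VectorObs] = []
    for img, sub in spots.groupby("image_id", sort=True):
        pids = sub["panel_id"].to_numpy(dtype=object)
        q = _spot_qs(detector, pids, sub["fast"].to_numpy(), sub["slow"].to_numpy(),
                     wavelength)
        n = len(sub)
        for i in range(n - 1):
            d = q[i + 1 :] - q[i]
            lens = np.linalg.norm(d, axis=1)
            for off in np.flatnonzero(lens <= max_len):
                j = i + 1 + off
                intra = pids[i] == pids[j]
                out.append(
                    VectorObs(
                        image_id=int(img),
                        spot_a=i,
                        spot_b=int(j),
                        v=d[off],
                        kind="intra" if intra else "inter",
                        panels=(str(pids[i]),) if intra else (str(pids[i]), str(pids[j])),
                    )
                )
    return out


def triad_score(triads: list[SpotTriad], lookup: FingerprintLookup) -> float:
    """Sum over triads of the product of the three pair scores."""
    if not triads:
        return 0.0
    v = np.array([[t.vectors[0], t.vectors[1], t.vectors[2]] for t in triads])
    return float(_score_triad_vectors(v[:, 0], v[:, 1], v[:, 2], lookup).sum())


# triad-scoring evaluations; the pre-indexing cost is linear in images
TRIAD_OPS = {"scored": 0}


def _score_triad_vectors(v1, v2, v3, lookup: FingerprintLookup) -> np.ndarray:
    """Product of pair scores for triad vector triples (vectorized)."""
    TRIAD_OPS["scored"] += np.shape(v1)[0] if np.ndim(v1) > 1 else 1
    total = None
    for a, b in ((v1, v2), (v2, v3), (v3, v1)):
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        cosang = np.abs(np.einsum("...i,...i->...", a, b)) / np.maximum(la * lb, 1e-30)
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        s = lookup.score(la, lb, ang)
        total = s if total is None else total * s
    return total


# ---------------------------------------------------------------------------
# Refinement data tables


class _SpotTable:
    """Flat arrays of the top-intensity spots of every image plus the triad
    index built on the starting geometry.

    Triad membership is frozen; vector geometry is recomputed on the fly
    from whatever panel geometry the evaluation supplies, and vectors that
    drift past the length cutoff score zero through the lookup bounds.
    """

    def __init__(self, spots, detector: DetectorGroup, wavelength: float,
                 max_len: float, top_per_image: int = 40):
        frames = []
        for _, sub in spots.groupby("image_id", sort=True):
            frames.append(sub.nlargest(top_per_image, "value"))
        table = pd.concat(frames, ignore_index=True)
        self.fast = table["fast"].to_numpy(dtype=float)
        self.slow = table["slow"].to_numpy(dtype=float)
        self.value = table["value"].to_numpy(dtype=float)
        self.image = table["image_id"].to_numpy(dtype=int)
        panel_ids = [p.id for p in detector.panels()]
        self.panel_index = {pid: i for i, pid in enumerate(panel_ids)}
        self.panel = np.array([self.panel_index[p] for p in table["panel_id"]])
        self.wavelength = wavelength
        self.max_len = max_len
        self.detector = detector
        self.triads = self._build_triads()

    def qs(self, detector: DetectorGroup, idx: np.ndarray) -> np.ndarray:
        pid_list = list(self.panel_index)
        q = np.empty((len(idx), 3))
        pnl = self.panel[idx]
        for p in np.unique(pnl):
            m = pnl == p
            pid = pid_list[p]
            panel = detector.find(pid)
            mid, f_ax, s_ax = detector.panel_geometry(pid)
            lab = lab_positions(mid, f_ax, s_ax, panel.pixel_size, panel.n_fast,
                                panel.n_slow, self.fast[idx][m], self.slow[idx][m])
            q[m] = back_project(lab, self.wavelength)
        return q

    def _build_triads(self) -> np.ndarray:
        """(K, 3) global spot indices whose three vectors pass the cutoff."""
        triads = []
        for img in np.unique(self.image):
            idx = np.flatnonzero(self.image == img)
            q = self.qs(self.detector, idx)
            n = len(idx)
            if n < 3:
                continue
            diff = q[:, None, :] - q[None, :, :]
            adj = np.linalg.norm(diff, axis=2) <= self.max_len
            np.fill_diagonal(adj, False)
            for i in range(n - 2):
                for j in np.flatnonzero(adj[i]):
                    if j <= i:
                        continue
                    ks = np.flatnonzero(adj[i] & adj[j])
                    for k in ks[ks > j]:
                        triads.append((idx[i], idx[j], idx[k]))
        if not triads:
            return np.empty((0, 3), dtype=int)
        return np.asarray(triads, dtype=int)


def _triad_vectors(q: np.ndarray, triads_local: np.ndarray):
    a, b, c = triads_local[:, 0], triads_local[:, 1], triads_local[:, 2]
    v1 = q[b] - q[a]
    v2 = q[c] - q[b]
    v3 = q[a] - q[c]
    return v1, v2, v3


# ---------------------------------------------------------------------------
# Refinement stages


def refine_panel_euclidean_pre(panel: Panel, table: _SpotTable,
                               lookup: FingerprintLookup, config: RefineConfig,
                               min_vectors: int = 30) -> bool:
    """Refine (d, alpha, beta) of one panel against its intra-panel triads.

    Returns False (and leaves the panel untouched) when the panel holds too
    little intra-panel vector-pair structure.
    """
    p_idx = table.panel_index[panel.id]
    mask = np.all(table.panel[table.triads] == p_idx, axis=1)
    triads = table.triads[mask]
    if 3 * len(triads) < min_vectors:
        logger.warning("panel %s: %d intra-panel triads, pre-indexing Euclidean "
                       "stage skipped", panel.id, len(triads))
        return False
    spot_idx = np.unique(triads)
    local = np.searchsorted(spot_idx, triads)
    fast, slow = table.fast[spot_idx], table.slow[spot_idx]

    def score():
        mid, f_ax, s_ax = panel.effective(euclidean_only=True)
        lab = lab_positions(mid, f_ax, s_ax, panel.pixel_size, panel.n_fast,
                            panel.n_slow, fast, slow)
        q = back_project(lab, table.wavelength)
        return float(_score_triad_vectors(*_triad_vectors(q, local), lookup).sum())

    return _refine_modes(panel, ("d", "alpha", "beta"), score, config)


class _PairProxy:
    """Holds the single (theta, phi, psi) triple shared by a sibling pair."""

    def __init__(self) -> None:
        self.pending = MovementParams()


def refine_pair_noneuclidean(group_a, group_b, table: _SpotTable,
                             lookup: FingerprintLookup, config: RefineConfig,
                             detector: DetectorGroup) -> bool:
    """Equal-and-opposite sphere refinement of two sibling groups.

    One (theta, phi, psi) triple is applied as +angles to ``group_a`` and
    -angles to ``group_b`` about the axis through the sample toward the
    midpoint of the two group centres, maximizing the fingerprint score of
    triads that touch both groups.  Returns False when no such triads exist.
    """
    ids_a = {table.panel_index[p.id] for p in _panels_of(group_a)}
    ids_b = {table.panel_index[p.id] for p in _panels_of(group_b)}
    tp = table.panel[table.triads]
    in_a = np.isin(tp, list(ids_a))
    in_b = np.isin(tp, list(ids_b))
    mask = np.all(in_a | in_b, axis=1) & np.any(in_a, axis=1) & np.any(in_b, axis=1)
    triads = table.triads[mask]
    if len(triads) == 0:
        logger.warning("groups %s/%s: no spanning triads, pair skipped",
                       _node_id(group_a), _node_id(group_b))
        return False
    spot_idx = np.unique(triads)
    local = np.searchsorted(spot_idx, triads)
    q0_lab = _spot_labs(detector, table, spot_idx)
    a_mask = np.isin(table.panel[spot_idx], list(ids_a))
    centre_a = _node_centre(group_a, detector)
    centre_b = _node_centre(group_b, detector)
    axis = (centre_a + centre_b) / 2.0
    axis = axis / np.linalg.norm(axis)
    proxy = _PairProxy()

    def score():
        p = proxy.pending
        rot = sphere_rotation(p.theta, p.phi, p.psi, axis)
        rot_b = sphere_rotation(-p.theta, -p.phi, -p.psi, axis)
        lab = np.where(a_mask[:, None], rot.apply(q0_lab), rot_b.apply(q0_lab))
        q = back_project(lab, table.wavelength)
        return float(_score_triad_vectors(*_triad_vectors(q, local), lookup).sum())

    # bracketing grid over the two lateral angles: the fingerprint score has
    # narrow basins flanked by sidelobes, and a simplex started outside the
    # true basin locks onto one; the grid guarantees a start inside whenever
    # the misalignment is within +/-pair_grid_px pixels
    r_mid = float(np.linalg.norm((centre_a + centre_b) / 2.0))
    px = _panels_of(group_a)[0].pixel_size
    half_width = config.pair_grid_px * px / r_mid
    grid = np.linspace(-half_width, half_width, config.pair_grid_points)
    best = (0.0, 0.0)
    best_score = score()
    for theta in grid:
        for phi in grid:
            proxy.pending.theta, proxy.pending.phi = float(theta), float(phi)
            s = score()
            if s > best_score:
                best_score, best = s, (float(theta), float(phi))
    proxy.pending.theta, proxy.pending.phi = best

    ok = _refine_modes(proxy, ("theta", "phi", "psi"), score, config)
    p = proxy.pending
    for node, sign in ((group_a, 1.0), (group_b, -1.0)):
        node.pending.theta = sign * p.theta
        node.pending.phi = sign * p.phi
        node.pending.psi = sign * p.psi
        node.ref_axis = axis.copy()
        absorb_offsets(node)
        node.ref_axis = None
    return ok


def _panels_of(node) -> list[Panel]:
    return [node] if isinstance(node, Panel) else node.panels()


def _node_id(node) -> str:
    return node.id


def _node_centre(node, detector: DetectorGroup) -> np.ndarray:
    mids = [detector.panel_geometry(p.id)[0] for p in _panels_of(node)]
    return np.mean(mids, axis=0)


def _spot_labs(detector: DetectorGroup, table: _SpotTable, idx: np.ndarray) -> np.ndarray:
    pid_list = list(table.panel_index)
    lab = np.empty((len(idx), 3))
    pnl = table.panel[idx]
    for p in np.unique(pnl):
        m = pnl == p
        pid = pid_list[p]
        panel = detector.find(pid)
        mid, f_ax, s_ax = detector.panel_geometry(pid)
        lab[m] = lab_positions(mid, f_ax, s_ax, panel.pixel_size, panel.n_fast,
                               panel.n_slow, table.fast[idx][m], table.slow[idx][m])
    return lab


def _pair_nodes_bottom_up(root: DetectorGroup) -> list[DetectorGroup]:
    """Groups with exactly two children, deepest level first."""
    levels: dict[int, list[DetectorGroup]] = {}

    def depth(node) -> int:
        if isinstance(node, Panel):
            return 0
        return 1 + max(depth(c) for c in node.children)

    for grp in root.groups():
        if len(grp.children) == 2:
            levels.setdefault(depth(grp), []).append(grp)
    out: list[DetectorGroup] = []
    for d in sorted(levels):
        out.extend(levels[d])
    return out


def refine_preindex_full(
    detector: DetectorGroup,
    spots,
    cell,
    centring: str = "P",
    wavelength: float = 1.46,
    config: RefineConfig | None = None,
    lookup: FingerprintLookup | None = None,
    lookup_tolerance: float = 0.002,
    coarse_tolerance: float | None = 0.006,
    top_per_image: int = 40,
    cycles: int = 1,
) -> DetectorGroup:
    """Full pre-indexing refinement: per-panel Euclidean stage on all leaves,
    then the equal-and-opposite pairwise sphere ascent, level by level.

    The ascent runs coarse-to-fine: a first pass against a wider-tolerance
    lookup (``coarse_tolerance``) whose score basin safely contains the
    starting misalignment, then a pass against the nominal lookup.  A single
    fine pass can land on a sidelobe of the fingerprint score when the
    relative group misalignment exceeds the narrow fine-tolerance basin.
    Set ``coarse_tolerance=None`` to skip the coarse pass.

    No orientation information is used; results are invariant to shuffling
    image labels.  Returns a refined copy of the detector.
    """
    config = config or RefineConfig()
    det = detector.copy()
    if lookup is None:
        lookup = build_ideal_lookup(cell, centring, lookup_tolerance)
    ascent_lookups = [lookup]
    if coarse_tolerance is not None and coarse_tolerance > lookup.rlp_radius:
        ascent_lookups.insert(
            0,
            build_ideal_lookup(lookup.cell, centring, coarse_tolerance,
                               max_len=lookup.max_len),
        )
    for _ in range(cycles):
        table = _SpotTable(spots, det, wavelength, lookup.max_len, top_per_image)
        for panel in det.panels():
            refine_panel_euclidean_pre(panel, table, lookup, config)
        absorb_offsets(det)
        for asc in ascent_lookups:
            table = _SpotTable(spots, det, wavelength, lookup.max_len, top_per_image)
            for grp in _pair_nodes_bottom_up(det):
                refine_pair_noneuclidean(grp.children[0], grp.children[1], table,
                                         asc, config, det)
    return det
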