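"""Pixels, laboratory rays and Ewald-sphere reciprocal coordinates.

For still (no-rotation) diffraction at wavelength lambda, a detector position
``pos`` back-projects onto the Ewald sphere as

    q = (1/lambda) * (pos/|pos| - z_hat)          [A^-1]

so that ``|q + z_hat/lambda| = 1/lambda`` exactly.  A reciprocal lattice
point q = UB.(h,k,l) is predicted to diffract when it lies within the
reciprocal-lattice-point (rlp) radius of the sphere; its diffracted ray has
direction ``q + z_hat/lambda`` and is intersected with the panel planes to
give a fractional pixel position.

Observed spots are matched to predictions by searching the surrounding
pixels (up to a configurable Chebyshev radius, 5 by default) for the highest
pixel value; offsets are carried both in pixels and in reciprocal
coordinates, with a strong/not-strong classification from an I/sigma(I)
equivalent under a Poisson photon-count model:

    sigma(I) = gain * sqrt(I / gain)  =>  I/sigma = sqrt(I_photons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import gemmi
import numpy as np

from .geometry import DetectorGroup, lab_positions

__all__ = [
    "Lattice",
    "PredictionSet",
    "OffsetSet",
    "back_project",
    "reciprocal_basis",
    "centring_mask",
    "miller_candidates",
    "predict_stills",
    "rays_to_panel_pixels",
    "EvidenceGrid",
    "local_max_search",
    "compute_offsets",
    "DEFAULT_GAIN",
    "DEFAULT_ISIGI_CUT",
]

DEFAULT_GAIN = 9.0  # ADU per photon
DEFAULT_ISIGI_CUT = 0.67


def back_project(pos: np.ndarray, wavelength: float) -> np.ndarray:
    """Back-project lab positions (mm, shape (..., 3)) onto the Ewald sphere.

    Returns reciprocal coordinates in A^-1.  Raises on zero-length positions.
    """
    pos = np.asarray(pos, dtype=float)
    norm = np.linalg.norm(pos, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise ValueError("cannot back-project a zero-length position")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    s_hat = pos / norm
    q = s_hat.copy()
    q[..., 2] -= 1.0
    return q / wavelength


def reciprocal_basis(cell: tuple[float, float, float, float, float, float]) -> np.ndarray:
    """Reciprocal-cell basis matrix B (columns a*, b*, c* in A^-1).

    Uses the crystallographic orthogonalization convention of gemmi:
    B = inv(O)^T with O the orthogonalization matrix.
    """
    uc = gemmi.UnitCell(*cell)
    orth = np.array(uc.orth.mat.tolist())
    return np.linalg.inv(orth).T


@dataclass
class Lattice:
    """One still's indexing solution.

    ``ub`` columns are the reciprocal cell basis vectors in the lab frame
    (A^-1); ``cell`` is (a, b, c, alpha, beta, gamma) in A / degrees.
    """

    image_id: int
    ub: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    centring: str = "P"

    def __post_init__(self) -> None:
        self.ub = np.asarray(self.ub, dtype=float)
        if self.ub.shape != (3, 3):
            raise ValueError("ub must be a 3x3 matrix")
        if abs(np.linalg.det(self.ub)) < 1e-15:
            raise ValueError("ub matrix is singular")
        if any(x <= 0 for x in self.cell):
            raise ValueError("cell parameters must be positive")
        if self.centring not in ("P", "I", "F", "C"):
            raise ValueError(f"unsupported centring {self.centring!r}")


def centring_mask(hkl: np.ndarray, centring: str) -> np.ndarray:
    """Boolean mask of Miller indices allowed by the lattice centring.

    Axial systematic absences are deliberately disregarded.
    """
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    if centring == "P":
        return np.ones(len(hkl), dtype=bool)
    if centring == "I":
        return (h + k + l) % 2 == 0
    if centring == "C":
        return (h + k) % 2 == 0
    if centring == "F":
        return ((h + k) % 2 == 0) & ((h + l) % 2 == 0)
    raise ValueError(f"unsupported centring {centring!r}")


@lru_cache(maxsize=8)
def _miller_grid(hmax: int) -> np.ndarray:
    r = np.arange(-hmax, hmax + 1)
    h, k, l = np.meshgrid(r, r, r, indexing="ij")
    return np.column_stack([h.ravel(), k.ravel(), l.ravel()])


def miller_candidates(cell, centring: str, max_resolution: float) -> np.ndarray:
    """All centring-allowed Miller indices with d-spacing >= max_resolution."""
    bmat = reciprocal_basis(tuple(cell))
    qmax = 1.0 / max_resolution
    smin = np.linalg.svd(bmat, compute_uv=False)[-1]
    hmax = int(np.ceil(qmax / smin))
    hkl = _miller_grid(hmax)
    hkl = hkl[centring_mask(hkl, centring)]
    q = hkl @ bmat.T
    keep = np.einsum("ij,ij->i", q, q) <= qmax * qmax
    return hkl[keep]


@dataclass
class PredictionSet:
    """Predicted still-diffraction spots for one image (array-of-struct view).

    ``rays`` are the diffracted-ray directions q + z_hat/lambda (A^-1, not
    normalized); ``pixel`` are fractional (fast, slow) panel coordinates.
    """

    image_id: int
    miller: np.ndarray  # (N, 3) int
    q: np.ndarray  # (N, 3) A^-1
    rays: np.ndarray  # (N, 3)
    panel_ids: np.ndarray  # (N,) str
    pixel: np.ndarray  # (N, 2) fractional (fast, slow)

    def __len__(self) -> int:
        return len(self.miller)

    def for_panel(self, panel_id: str) -> "PredictionSet":
        m = self.panel_ids == panel_id
        return PredictionSet(
            self.image_id, self.miller[m], self.q[m], self.rays[m],
            self.panel_ids[m], self.pixel[m],
        )


def rays_to_panel_pixels(rays: np.ndarray, mid, f_ax, s_ax, pixel_size, n_fast, n_slow):
    """Intersect rays from the sample with a panel plane.

    Returns (pixel (N,2), in_front (N,) bool); pixels may fall outside the
    active area (caller filters).  Rays parallel to the plane or hitting it
    from behind are flagged out.
    """
    normal = np.cross(f_ax, s_ax)
    denom = rays @ normal
    num = float(mid @ normal)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    ok = np.isfinite(t) & (t > 0)
    hit = rays * t[:, None]
    rel = hit - mid
    fast = rel @ f_ax / pixel_size + n_fast / 2.0
    slow = rel @ s_ax / pixel_size + n_slow / 2.0
    return np.column_stack([fast, slow]), ok


def predict_stills(
    lattice: Lattice,
    detector: DetectorGroup,
    wavelength: float,
    rlp_radius: float,
    max_resolution: float = 2.0,
) -> PredictionSet:
    """Predict spot positions for one still.

    Keeps exactly the centring-allowed Miller indices whose reciprocal point
    lies within ``rlp_radius`` of the Ewald sphere, whose diffracted ray
    intersects a panel's active area, and whose resolution is within
    ``max_resolution``.
    """
    if rlp_radius < 0:
        raise ValueError("rlp_radius must be >= 0")
    panels = detector.panels()
    if not panels:
        raise ValueError("empty detector")
    hkl = miller_candidates(lattice.cell, lattice.centring, max_resolution)
    q = hkl @ lattice.ub.T
    inv_lambda = 1.0 / wavelength
    centre_dist = np.sqrt(q[:, 0] ** 2 + q[:, 1] ** 2 + (q[:, 2] + inv_lambda) ** 2)
    near = np.abs(centre_dist - inv_lambda) <= rlp_radius
    nonzero = np.einsum("ij,ij->i", q, q) > 0
    sel = near & nonzero
    hkl, q = hkl[sel], q[sel]
    rays = q.copy()
    rays[:, 2] += inv_lambda
    fwd = rays[:, 2] > 0
    hkl, q, rays = hkl[fwd], q[fwd], rays[fwd]

    out_miller, out_q, out_rays, out_pid, out_pix = [], [], [], [], []
    for panel in panels:
        mid, f_ax, s_ax = detector.panel_geometry(panel.id)
        pix, ok = rays_to_panel_pixels(
            rays, mid, f_ax, s_ax, panel.pixel_size, panel.n_fast, panel.n_slow
        )
        on = (
            ok
            & (pix[:, 0] >= 0) & (pix[:, 0] <= panel.n_fast)
            & (pix[:, 1] >= 0) & (pix[:, 1] <= panel.n_slow)
        )
        if not np.any(on):
            continue
        out_miller.append(hkl[on])
        out_q.append(q[on])
        out_rays.append(rays[on])
        out_pid.append(np.full(int(on.sum()), panel.id, dtype=object))
        out_pix.append(pix[on])
    if not out_miller:
        empty3 = np.empty((0, 3))
        return PredictionSet(
            lattice.image_id, np.empty((0, 3), dtype=int), empty3, empty3.copy(),
            np.empty(0, dtype=object), np.empty((0, 2)),
        )
    return PredictionSet(
        lattice.image_id,
        np.vstack(out_miller),
        np.vstack(out_q),
        np.vstack(out_rays),
        np.concatenate(out_pid),
        np.vstack(out_pix),
    )


class EvidenceGrid:
    """Sparse per-panel pixel evidence built from an observed spot list.

    Spot values land in the integer pixel containing their (fast, slow)
    coordinate; when two spots share a pixel the higher value wins.  The
    original fractional coordinates are retained so sub-pixel offsets
    survive the integer-pixel local search.
    """

    def __init__(self) -> None:
        self._cells: dict[tuple[int, int], tuple[float, float, float]] = {}

    @classmethod
    def from_spots(cls, fast, slow, value) -> "EvidenceGrid":
        grid = cls()
        for f, s, v in zip(np.asarray(fast, float), np.asarray(slow, float), np.asarray(value, float)):
            key = (int(np.floor(f)), int(np.floor(s)))
            if key not in grid._cells or grid._cells[key][2] < v:
                grid._cells[key] = (f, s, v)
        return grid

    def value(self, i: int, j: int) -> float:
        cell = self._cells.get((i, j))
        return cell[2] if cell is not None else -np.inf

    def spot(self, i: int, j: int):
        return self._cells.get((i, j))


def local_max_search(evidence: EvidenceGrid, anchor: tuple[float, float], radius: int):
    """Highest pixel value within a Chebyshev ``radius`` of the anchor pixel.

    Returns ``(offset, value)`` with the integer offset from the anchor
    pixel, or ``None`` when no evidence lies in the window.  Ties resolve to
    the first pixel in (slow, fast) scan order; radius 0 inspects only the
    anchor pixel.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("search radius must be a non-negative integer")
    ai, aj = int(np.floor(anchor[0])), int(np.floor(anchor[1]))
    best = None
    for j in range(aj - radius, aj + radius + 1):  # slow-major scan order
        for i in range(ai - radius, ai + radius + 1):
            v = evidence.value(i, j)
            if v == -np.inf:
                continue
            if best is None or v > best[2]:
                best = (i, j, v)
    if best is None:
        return None
    return (best[0] - ai, best[1] - aj), best[2]


@dataclass
class OffsetSet:
    """Matched observation/prediction pairs for one (image, panel).

    ``dpx`` = observed - predicted in panel pixels; ``dq`` = back-projection
    difference in A^-1.  ``obs_pixel`` keeps the observed fractional
    coordinates and ``rays``/``q_pred`` the prediction's ray and reciprocal
    point so offsets can be re-evaluated under trial panel movements.
    """

    image_id: int
    panel_id: str
    obs_pixel: np.ndarray  # (N, 2)
    obs_value: np.ndarray  # (N,) ADU
    pred_pixel: np.ndarray  # (N, 2)
    rays: np.ndarray  # (N, 3)
    q_pred: np.ndarray  # (N, 3)
    miller: np.ndarray = field(default=None)  # type: ignore[assignment]  # (N, 3)
    dpx: np.ndarray = field(default=None)  # type: ignore[assignment]
    dq: np.ndarray = field(default=None)  # type: ignore[assignment]
    strong: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.obs_pixel)


def compute_offsets(
    predictions: PredictionSet,
    evidence_by_panel: dict[str, EvidenceGrid],
    detector: DetectorGroup,
    wavelength: float,
    gain: float = DEFAULT_GAIN,
    isigi_cut: float = DEFAULT_ISIGI_CUT,
    search_radius: int = 5,
) -> list[OffsetSet]:
    """Match observed spots to predictions and compute pixel/reciprocal offsets.

    For every prediction the surrounding area up to ``search_radius`` pixels
    away is searched for the highest observed pixel value; unmatched
    predictions are simply absent from the result.  Strong means
    I/sigma(I) >= ``isigi_cut`` under the Poisson gain model.
    """
    out: list[OffsetSet] = []
    for panel_id in sorted(set(predictions.panel_ids.tolist())):
        grid = evidence_by_panel.get(panel_id)
        if grid is None:
            continue
        preds = predictions.for_panel(panel_id)
        panel = detector.find(panel_id)
        mid, f_ax, s_ax = detector.panel_geometry(panel_id)
        obs_px, obs_val, pred_px, rays, q_pred, miller = [], [], [], [], [], []
        for n in range(len(preds)):
            hit = local_max_search(grid, tuple(preds.pixel[n]), search_radius)
            if hit is None:
                continue
            (di, dj), _ = hit
            ai, aj = int(np.floor(preds.pixel[n, 0])), int(np.floor(preds.pixel[n, 1]))
            f, s, v = grid.spot(ai + di, aj + dj)
            obs_px.append((f, s))
            obs_val.append(v)
            pred_px.append(preds.pixel[n])
            rays.append(preds.rays[n])
            q_pred.append(preds.q[n])
            miller.append(preds.miller[n])
        if not obs_px:
            continue
        obs_px = np.asarray(obs_px)
        obs_val = np.asarray(obs_val)
        pred_px = np.asarray(pred_px)
        rays = np.asarray(rays)
        q_pred = np.asarray(q_pred)
        miller = np.asarray(miller)
        obs_lab = lab_positions(
            mid, f_ax, s_ax, panel.pixel_size, panel.n_fast, panel.n_slow,
            obs_px[:, 0], obs_px[:, 1],
        )
        # both terms are back-projections onto the sphere: the prediction's
        # is its ray direction re-projected, not the (off-sphere) rlp itself
        dq = back_project(obs_lab, wavelength) - back_project(rays, wavelength)
        isigi = np.sqrt(np.maximum(obs_val, 0.0) / gain)
        out.append(
            OffsetSet(
                image_id=predictions.image_id,
                panel_id=panel_id,
                obs_pixel=obs_px,
                obs_value=obs_val,
                pred_pixel=pred_px,
                rays=rays,
                q_pred=q_pred,
                miller=miller,
                dpx=obs_px - pred_px,
                dq=dq,
                strong=isigi >= isigi_cut,
            )
        )
    return out
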