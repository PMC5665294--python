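"""Decoupling unit-cell dimensions from detector geometry.

Cell scale and detector distance are confounded: inflated cell dimensions
bend the apparent detector into a sphere of the wrong curvature.  To
separate them, reflections are over-predicted (an inflated Ewald-slab
tolerance) and located by a local maximum search, classified strong or not,
and each matched reciprocal point q is assigned the *implied wavelength* at
which it would sit exactly on the Ewald sphere:

    lambda_implied = -2 q_z / |q|^2

Scaling all cell lengths by s scales every q by 1/s and every implied
wavelength by s, so a one-parameter Nelder-Mead brings the median implied
wavelength of the strong reflections onto the nominal wavelength.  The
detector distance is then compensated by the reciprocal factor (deflating
the cell by f inflates the distance by about f), and orientation refinement
alternates with the cell scale until convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .geometry import DetectorGroup
from .projection import Lattice, PredictionSet, predict_stills
from .indexed import RefineConfig, match_all

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthSample",
    "over_predict",
    "implied_wavelength",
    "refine_cell_scale",
    "compensate_distance",
    "cell_geometry_loop",
    "deflation_percent",
]


@dataclass
class WavelengthSample:
    miller: tuple[int, int, int]
    lambda_implied: float  # Angstrom
    strong: bool

    def __post_init__(self) -> None:
        if self.lambda_implied <= 0:
            raise ValueError("implied wavelength must be positive")


def over_predict(lattice: Lattice, detector: DetectorGroup, wavelength: float,
                 rlp_radius: float, inflate: float = 3.0,
                 max_resolution: float = 2.0) -> PredictionSet:
    """Prediction with an inflated Ewald-slab tolerance (superset of nominal)."""
    if inflate < 1:
        raise ValueError("inflate must be >= 1")
    return predict_stills(lattice, detector, wavelength, rlp_radius * inflate,
                          max_resolution)


def implied_wavelength(q) -> np.ndarray | float:
    """Wavelength (A) at which reciprocal points lie exactly on the sphere.

    Requires forward scattering, i.e. q_z < 0 in the convention
    q = (1/lambda)(s_hat - z_hat); other samples are undefined and rejected.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 1
    q2 = np.atleast_2d(q)
    norm2 = np.einsum("ij,ij->i", q2, q2)
    if np.any(norm2 == 0.0) or np.any(q2[:, 2] >= 0.0):
        raise ValueError("implied wavelength undefined for q_z >= 0 or |q| = 0")
    lam = -2.0 * q2[:, 2] / norm2
    return float(lam[0]) if scalar else lam


def refine_cell_scale(samples: list[WavelengthSample], cell, nominal_wavelength: float):
    """Scalar cell-length scale s centring the strong implied wavelengths.

    Minimizes |median(lambda_implied under cell*s) - nominal| by 1-D
    Nelder-Mead; the median is used as the centring statistic for robustness
    to over-prediction outliers.  Returns (scaled cell, s).
    """
    lam = np.array([s.lambda_implied for s in samples if s.strong])
    if len(lam) < 10:
        raise ValueError(f"need >= 10 strong samples, got {len(lam)}")
    millers = {s.miller for s in samples if s.strong}
    if len(millers) < 2:
        raise ValueError("degenerate sample: all strong reflections share one index")
    med = float(np.median(lam))

    res = minimize(
        lambda x: abs(x[0] * med - nominal_wavelength),
        np.array([1.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    s = float(res.x[0])
    a, b, c, al, be, ga = cell
    return (a * s, b * s, c * s, al, be, ga), s


def compensate_distance(detector: DetectorGroup, s: float) -> DetectorGroup:
    """Scale every panel midpoint z-distance by 1/s (returns a copy).

    Deflating the cell by a fraction f inflates the distance by about f.
    """
    if not (0.9 < s < 1.1):
        raise ValueError("cell scale outside the supported 0.9-1.1 window")
    out = detector.copy()
    for panel in out.panels():
        panel.midpoint[2] /= s
    return out


def _refine_orientation(lattice: Lattice, offsets_dq: np.ndarray,
                        q_pred: np.ndarray) -> Lattice:
    """Small-rotation orientation refinement minimizing sum |dq|^2.

    Parameterized as two small rotations about the lab axes perpendicular to
    the beam (standard stills practice).
    """

    def cost(x):
        rot = Rotation.from_rotvec([x[0], 0, 0]) * Rotation.from_rotvec([0, x[1], 0])
        dq = offsets_dq + q_pred - rot.apply(q_pred)
        return float(np.sum(dq * dq))

    res = minimize(cost, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-18})
    rot = Rotation.from_rotvec([res.x[0], 0, 0]) * Rotation.from_rotvec([0, res.x[1], 0])
    return Lattice(lattice.image_id, rot.as_matrix() @ lattice.ub, lattice.cell,
                   lattice.centring)


def cell_geometry_loop(
    lattices: list[Lattice],
    detector: DetectorGroup,
    spots,
    wavelength: float,
    config: RefineConfig | None = None,
    inflate: float = 3.0,
    max_iter: int = 10,
    tol: float = 1e-4,
):
    """Alternate orientation refinement with cell-scale/distance refinement.

    Returns (cell', detector', lattices', history of s).  Convergence when
    the per-iteration scale changes by less than ``tol``; if the loop
    oscillates past ``max_iter`` the best-seen state is returned with a
    logged flag.
    """
    if not lattices:
        raise ValueError("indexing solutions are required")
    config = config or RefineConfig()
    det = detector.copy()
    lats = list(lattices)
    cell = lats[0].cell
    history: list[float] = []
    for it in range(max_iter):
        cfg = RefineConfig(
            k_pixel=config.k_pixel, k_recip=config.k_recip,
            search_radius=config.search_radius, gain=config.gain,
            isigi_cut=config.isigi_cut, rlp_radius=config.rlp_radius * inflate,
            max_resolution=config.max_resolution,
        )
        per_panel = match_all(det, lats, spots, wavelength, cfg)

        # (a) per-lattice orientation refinement
        by_img: dict[int, list] = {}
        for osets in per_panel.values():
            for o in osets:
                by_img.setdefault(o.image_id, []).append(o)
        new_lats = []
        for lat in lats:
            osets = by_img.get(lat.image_id)
            if not osets:
                new_lats.append(lat)
                continue
            dq = np.vstack([o.dq[o.strong] for o in osets if o.strong.any()] or
                           [np.empty((0, 3))])
            qp = np.vstack([o.q_pred[o.strong] for o in osets if o.strong.any()] or
                           [np.empty((0, 3))])
            if len(dq) < 3:
                new_lats.append(lat)
                continue
            new_lats.append(_refine_orientation(lat, dq, qp))
        lats = new_lats

        # (b) cell scale from strong implied wavelengths
        per_panel = match_all(det, lats, spots, wavelength, cfg)
        samples: list[WavelengthSample] = []
        for osets in per_panel.values():
            for o in osets:
                ok = o.q_pred[:, 2] < 0
                lam = implied_wavelength(o.q_pred[ok])
                for n, l in zip(np.flatnonzero(ok), np.atleast_1d(lam)):
                    samples.append(
                        WavelengthSample(tuple(int(v) for v in o.miller[n]),
                                         float(l), bool(o.strong[n]))
                    )
        cell, s = refine_cell_scale(samples, cell, wavelength)
        det = compensate_distance(det, s)
        lats = [Lattice(l.image_id, l.ub / s, cell, l.centring) for l in lats]
        history.append(s)
        if abs(s - 1.0) < tol:
            break
    else:
        logger.warning("cell/geometry loop did not converge in %d iterations", max_iter)
    return cell, det, lats, history


def deflation_percent(initial_edge: float, refined_edge: float) -> float:
    """Fractional change between two cell edges, in percent of the initial."""
    return 100.0 * (initial_edge - refined_edge) / initial_edge
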