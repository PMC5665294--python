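"""Two-stage per-panel geometry refinement from indexing solutions.

Stage 1 ("slip") refines the Euclidean movements (d, alpha, beta) of each
panel against a reward-based clustering score of the pixel offsets

    E = sum_i sum_{j != i} exp(-[(dx_i - dx_j)^2 + (dy_i - dy_j)^2] / k^2)

which is maximized, depends only on pairwise offset differences (so it is
independent of the origin of the offsets and robust to outliers, unlike a
least-squares penalty), and uses k = 5.0 pixels by default.

Stage 2 ("slide") refines the sphere movements (theta, phi, psi) against the
centring of the reciprocal offsets on the origin

    F = sum_i exp(-|dq_i|^2 / k^2),       k = 0.002 A^-1 by default,

an O(N) target maximal exactly when every reciprocal offset vanishes.

Each movement mode is refined independently per panel by 1-D Nelder-Mead
(three passes over the parameter list; a joint 3-parameter simplex is
available behind a config flag), with pending movements absorbed at the end
of every cycle.  Panels are refined independently of the hierarchy so that global
trends (overall tilt, distance) emerge unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    DetectorGroup,
    MovementParams,
    absorb_offsets,
    lab_positions,
)
from .projection import (
    DEFAULT_GAIN,
    DEFAULT_ISIGI_CUT,
    EvidenceGrid,
    Lattice,
    OffsetSet,
    back_project,
    compute_offsets,
    predict_stills,
    rays_to_panel_pixels,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RefineConfig",
    "PanelReport",
    "euclidean_target",
    "noneuclidean_target",
    "least_squares_target",
    "refine_panel_euclidean",
    "refine_panel_noneuclidean",
    "refine_indexed_cycle",
]


@dataclass
class RefineConfig:
    """Knobs of the indexed refinement protocol.

    ``k_pixel``/``k_recip`` are the reward scale constants (pixels / A^-1);
    ``search_radius`` is the local-max matching radius in pixels (0 for
    validation); ``nm_tol`` the simplex score tolerance; ``d_step`` (mm) and
    ``angle_step`` (rad) the initial simplex steps.
    """

    k_pixel: float = 5.0
    k_recip: float = 0.002
    search_radius: int = 5
    nm_tol: float = 1e-6
    max_cycles: int = 5
    seed: int = 0
    gain: float = DEFAULT_GAIN
    isigi_cut: float = DEFAULT_ISIGI_CUT
    rlp_radius: float = 3e-4
    max_resolution: float = 3.5
    joint_simplex: bool = False
    d_step: float = 0.2
    angle_step: float = np.deg2rad(0.05)
    param_passes: int = 3
    # pre-indexing pair stage: bracketing-grid half-width (px equivalent)
    # and points per axis used to seed the simplex in the best score basin
    pair_grid_px: float = 3.0
    pair_grid_points: int = 9

    def __post_init__(self) -> None:
        if self.k_pixel <= 0 or self.k_recip <= 0:
            raise ValueError("reward scale constants must be positive")


@dataclass
class PanelReport:
    """Before/after diagnostics for one panel in one refinement cycle."""

    panel_id: str
    n_offsets: int = 0
    E_before: float = 0.0
    E_after: float = 0.0
    F_before: float = 0.0
    F_after: float = 0.0
    px_spread_before: float = 0.0
    px_spread_after: float = 0.0
    mean_dq_before: float = 0.0
    mean_dq_after: float = 0.0
    params: MovementParams = field(default_factory=MovementParams)
    corner_shift: np.ndarray | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# Target functions


# instrumentation: pairwise/single kernel evaluations, for cost-scaling
# assertions (the indexed target is quadratic per panel, the sphere target
# linear)
OP_COUNT = {"pair_ops": 0, "single_ops": 0}


def euclidean_target(dpx: np.ndarray, k_pixel: float = 5.0) -> float:
    """Clustering reward E over pixel offsets (N, 2); maximized.

    Invariant to adding any constant vector to all offsets.  Identical
    offsets give E = N(N-1) (one exp(0) per ordered pair).
    """
    dpx = np.asarray(dpx, dtype=float)
    if dpx.ndim != 2 or dpx.shape[0] < 2:
        raise ValueError("need at least 2 offsets")
    OP_COUNT["pair_ops"] += dpx.shape[0] * (dpx.shape[0] - 1)
    dx = dpx[:, 0][:, None] - dpx[:, 0][None, :]
    dy = dpx[:, 1][:, None] - dpx[:, 1][None, :]
    e = np.exp(-(dx * dx + dy * dy) / (k_pixel * k_pixel))
    return float(e.sum() - len(dpx))  # remove the i == j diagonal


def noneuclidean_target(dq: np.ndarray, k_recip: float = 0.002) -> float:
    """Origin-centring reward F over reciprocal offsets (N, 3); maximized.

    O(N); equals N exactly when every offset is zero.
    """
    dq = np.asarray(dq, dtype=float)
    if dq.ndim != 2 or dq.shape[0] < 1:
        raise ValueError("need at least 1 offset")
    OP_COUNT["single_ops"] += dq.shape[0]
    r2 = np.einsum("ij,ij->i", dq, dq)
    return float(np.exp(-r2 / (k_recip * k_recip)).sum())


def least_squares_target(dpx: np.ndarray) -> float:
    """Mean squared pixel offset about the centroid (comparison oracle only).

    A conventional spread penalty, minimized; provided so the robustness of
    the reward-based score against outliers can be contrasted in tests.
    """
    dpx = np.asarray(dpx, dtype=float)
    centred = dpx - dpx.mean(axis=0)
    return float(np.mean(np.sum(centred * centred, axis=1)))


# ---------------------------------------------------------------------------
# Per-panel offset evaluation under trial movements


class _PanelOffsets:
    """Frozen matched observations for one panel, re-evaluable under trial
    pending parameters.

    The pixel-offset view intersects the (frozen) prediction rays with the
    panel in its Euclidean-only configuration, which makes the Euclidean
    reward exactly insensitive to sphere movements; the reciprocal view uses
    the full configuration.
    """

    def __init__(self, panel, offsets: list[OffsetSet], wavelength: float):
        self.panel = panel
        self.wavelength = wavelength
        strong = [o for o in offsets if o.strong.any()]
        if strong:
            self.obs_pixel = np.vstack([o.obs_pixel[o.strong] for o in strong])
            self.rays = np.vstack([o.rays[o.strong] for o in strong])
        else:
            self.obs_pixel = np.empty((0, 2))
            self.rays = np.empty((0, 3))
        # the prediction's on-sphere back-projection is fixed by its ray
        self.q_sphere = (
            back_project(self.rays, wavelength) if len(self.rays) else np.empty((0, 3))
        )

    def __len__(self) -> int:
        return len(self.obs_pixel)

    def dpx(self) -> np.ndarray:
        p = self.panel
        mid, f_ax, s_ax = p.effective(euclidean_only=True)
        pred, _ = rays_to_panel_pixels(
            self.rays, mid, f_ax, s_ax, p.pixel_size, p.n_fast, p.n_slow
        )
        return self.obs_pixel - pred

    def dq(self) -> np.ndarray:
        p = self.panel
        mid, f_ax, s_ax = p.effective()
        obs_lab = lab_positions(
            mid, f_ax, s_ax, p.pixel_size, p.n_fast, p.n_slow,
            self.obs_pixel[:, 0], self.obs_pixel[:, 1],
        )
        return back_project(obs_lab, self.wavelength) - self.q_sphere


def _nelder_mead_max(score, x0: np.ndarray, steps: np.ndarray, tol: float):
    """Maximize ``score`` by Nelder-Mead from x0 with given simplex steps."""
    n = len(x0)
    simplex = np.vstack([x0] + [x0 + steps * np.eye(n)[i] for i in range(n)])
    res = minimize(
        lambda x: -score(x),
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "fatol": tol,
            "xatol": 1e-8,
            "maxiter": 120 * n,
        },
    )
    return res.x, -res.fun, res.success


def _refine_modes(panel, names, score_of_params, config: RefineConfig) -> bool:
    """Sequential 1-D (or joint) Nelder-Mead over the named pending modes."""
    steps = {
        "d": config.d_step,
        "alpha": config.angle_step,
        "beta": config.angle_step,
        "theta": config.angle_step,
        "phi": config.angle_step,
        "psi": config.angle_step,
    }
    ok = True
    if config.joint_simplex:
        x0 = np.array([getattr(panel.pending, n) for n in names])

        def joint(x):
            for n, v in zip(names, x):
                setattr(panel.pending, n, float(v))
            return score_of_params()

        best_x, best_f, success = _nelder_mead_max(
            joint, x0, np.array([steps[n] for n in names]), config.nm_tol
        )
        start = joint(x0)
        if best_f >= start:
            joint(best_x)
        else:
            joint(x0)
        return success
    for _ in range(config.param_passes):
        for name in names:
            x0 = np.array([getattr(panel.pending, name)])

            def one(x, _name=name):
                setattr(panel.pending, _name, float(x[0]))
                return score_of_params()

            start = one(x0)
            best_x, best_f, success = _nelder_mead_max(
                one, x0, np.array([steps[name]]), config.nm_tol
            )
            if best_f >= start:  # keep best-seen, never regress
                one(best_x)
            else:
                one(x0)
            ok = ok and success
    return ok


def refine_panel_euclidean(panel, offsets: list[OffsetSet], wavelength: float,
                           config: RefineConfig) -> PanelReport:
    """Refine (d, alpha, beta) of one panel against the clustering reward.

    Operates on the panel's pending parameters; absorption is the caller's
    concern.  Panels with fewer than 2 strong offsets are skipped.
    """
    po = _PanelOffsets(panel, offsets, wavelength)
    report = PanelReport(panel_id=panel.id, n_offsets=len(po))
    if len(po) < 2:
        logger.warning("panel %s: %d strong offsets, Euclidean stage skipped",
                       panel.id, len(po))
        report.converged = False
        return report

    def score():
        return euclidean_target(po.dpx(), config.k_pixel)

    d0 = po.dpx()
    report.E_before = euclidean_target(d0, config.k_pixel)
    report.px_spread_before = float(np.sqrt(np.mean(np.sum((d0 - d0.mean(0)) ** 2, axis=1))))
    report.converged = _refine_modes(panel, ("d", "alpha", "beta"), score, config)
    d1 = po.dpx()
    report.E_after = euclidean_target(d1, config.k_pixel)
    report.px_spread_after = float(np.sqrt(np.mean(np.sum((d1 - d1.mean(0)) ** 2, axis=1))))
    return report


def refine_panel_noneuclidean(panel, offsets: list[OffsetSet], wavelength: float,
                              config: RefineConfig, report: PanelReport | None = None
                              ) -> PanelReport:
    """Refine (theta, phi, psi) of one panel against reciprocal centring."""
    po = _PanelOffsets(panel, offsets, wavelength)
    if report is None:
        report = PanelReport(panel_id=panel.id, n_offsets=len(po))
    if len(po) < 1:
        logger.warning("panel %s: no strong offsets, sphere stage skipped", panel.id)
        report.converged = False
        return report

    def score():
        return noneuclidean_target(po.dq(), config.k_recip)

    q0 = po.dq()
    report.F_before = noneuclidean_target(q0, config.k_recip)
    report.mean_dq_before = float(np.mean(np.linalg.norm(q0, axis=1)))
    ok = _refine_modes(panel, ("theta", "phi", "psi"), score, config)
    report.converged = report.converged and ok
    q1 = po.dq()
    report.F_after = noneuclidean_target(q1, config.k_recip)
    report.mean_dq_after = float(np.mean(np.linalg.norm(q1, axis=1)))
    report.params = panel.pending.copy()
    return report


def _evidence_maps(spots, detector: DetectorGroup):
    """Per-(image, panel) evidence grids from a spot-list DataFrame."""
    maps: dict[int, dict[str, EvidenceGrid]] = {}
    for (img, pid), sub in spots.groupby(["image_id", "panel_id"], sort=True):
        maps.setdefault(int(img), {})[str(pid)] = EvidenceGrid.from_spots(
            sub["fast"].to_numpy(), sub["slow"].to_numpy(), sub["value"].to_numpy()
        )
    return maps


def match_all(detector: DetectorGroup, lattices: list[Lattice], spots,
              wavelength: float, config: RefineConfig) -> dict[str, list[OffsetSet]]:
    """Predict every lattice on the current geometry and match observations.

    Returns offsets grouped per panel (the matched sets are then frozen for
    one refinement cycle).
    """
    maps = _evidence_maps(spots, detector)
    per_panel: dict[str, list[OffsetSet]] = {p.id: [] for p in detector.panels()}
    for lat in lattices:
        evidence = maps.get(int(lat.image_id))
        if not evidence:
            continue
        preds = predict_stills(lat, detector, wavelength, config.rlp_radius,
                               config.max_resolution)
        for oset in compute_offsets(preds, evidence, detector, wavelength,
                                    config.gain, config.isigi_cut,
                                    config.search_radius):
            per_panel[oset.panel_id].append(oset)
    return per_panel


def refine_indexed_cycle(
    detector: DetectorGroup,
    lattices: list[Lattice],
    spots,
    wavelength: float,
    config: RefineConfig | None = None,
) -> tuple[DetectorGroup, list[list[PanelReport]]]:
    """Full indexed refinement: per panel, Euclidean then sphere stage,
    absorbed each cycle, repeated to convergence or ``max_cycles``.

    ``spots`` is a DataFrame with columns image_id, panel_id, fast, slow,
    value.  Returns the refined detector (a copy) and per-cycle reports.
    """
    if not lattices:
        raise ValueError("need at least one indexing solution")
    config = config or RefineConfig()
    det = detector.copy()
    all_reports: list[list[PanelReport]] = []
    prev_score: float | None = None
    for cycle in range(config.max_cycles):
        per_panel = match_all(det, lattices, spots, wavelength, config)
        if all(len(v) == 0 for v in per_panel.values()):
            raise ValueError("no panel has matched offsets; check inputs")
        reports: list[PanelReport] = []
        for panel in det.panels():
            offsets = per_panel[panel.id]
            rep = refine_panel_euclidean(panel, offsets, wavelength, config)
            rep = refine_panel_noneuclidean(panel, offsets, wavelength, config, rep)
            reports.append(rep)
        absorb_offsets(det)
        all_reports.append(reports)
        total = sum(r.E_after + r.F_after for r in reports)
        if prev_score is not None and abs(total - prev_score) < config.nm_tol * max(
            1.0, abs(prev_score)
        ):
            break
        prev_score = total
    return det, all_reports
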