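"""Canonical validation experiments for the refinement protocol.

These are the self-contained synthetic studies used to qualify the method:
closed-form checks, perturb-and-recover runs for the indexed and
pre-indexing paths, the half-data-set correlation trend, and the outlier
robustness comparison between the reward-based target and a least-squares
variant.  They are the basis of both the test suite and the reproduction
script, so the study conditions live here in one place.
"""

from __future__ import annotations

import numpy as np

from .cell import deflation_percent
from .geometry import apply_euclidean, rms_corner_displacement
from .indexed import (
    RefineConfig,
    _PanelOffsets,
    _refine_modes,
    euclidean_target,
    least_squares_target,
    match_all,
    refine_indexed_cycle,
)
from .fingerprint import build_ideal_lookup, refine_preindex_full
from .io import half_set_correlation
from .projection import back_project
from .synthetic import PerturbBounds, SceneSpec, make_scene, perturb

__all__ = [
    "low_resolution_two_theta",
    "cell_deflation",
    "indexed_recovery",
    "preindex_recovery",
    "halfset_trend",
    "outlier_robustness",
]

WAVELENGTH = 1.46


def low_resolution_two_theta(a: float = 105.5, wavelength: float = WAVELENGTH,
                             distance: float = 90.0) -> float:
    """Scattering angle (deg) of the lowest-resolution allowed reflection of
    a body-centred cubic cell, recovered through the back-projection map.

    The lowest-order reflection passing the I-centring rule is (1,1,0) with
    d = a/sqrt(2); its ray is placed on a detector plane and back-projected,
    and the angle read off |q| = 2 sin(theta)/lambda.
    """
    d_min = a / np.sqrt(2.0)
    two_theta = 2.0 * np.arcsin(wavelength / (2.0 * d_min))
    r = distance * np.tan(two_theta)
    q = back_project(np.array([r, 0.0, distance]), wavelength)
    return float(np.degrees(2.0 * np.arcsin(wavelength * np.linalg.norm(q) / 2.0)))


def cell_deflation(initial_edge: float = 106.1, refined_edge: float = 105.5) -> float:
    """Percent deflation between an initial and a refined cubic cell edge."""
    return deflation_percent(initial_edge, refined_edge)


def indexed_recovery(n_images: int = 150, seed: int = 1, slide_px: float = 2.0,
                     tilt_deg: float = 0.2, d_px: float = 2.0,
                     max_cycles: int = 4) -> dict:
    """Perturb-and-recover study for the indexed two-stage path.

    A 16-panel scene of noise-free stills with known orientations; each
    panel is independently displaced by up to ``slide_px`` pixels
    (translation-equivalent, lateral and radial) and tilted by up to
    ``tilt_deg``.  Returns before/after RMS corner displacements and the
    mean reciprocal-offset reduction.
    """
    scene = make_scene(SceneSpec(n_images=n_images, seed=seed))
    bounds = PerturbBounds(d_mm=d_px * scene.spec.pixel_size / 2.0,
                           tilt_rad=np.deg2rad(tilt_deg), slide_px=slide_px)
    perturbed, _ = perturb(scene.detector, bounds, seed + 1)
    rms0 = rms_corner_displacement(perturbed, scene.detector)
    cfg = RefineConfig(max_cycles=max_cycles, seed=seed)
    refined, reports = refine_indexed_cycle(perturbed, scene.lattices, scene.spots,
                                            WAVELENGTH, cfg)
    rms1 = rms_corner_displacement(refined, scene.detector)
    dq_before = np.mean([r.mean_dq_before for r in reports[0] if r.n_offsets])
    dq_after = np.mean([r.mean_dq_after for r in reports[-1] if r.n_offsets])
    return {
        "rms_before_mm": rms0,
        "rms_after_mm": rms1,
        "reduction_pct": 100.0 * (1.0 - rms1 / rms0),
        "mean_dq_reduction_pct": 100.0 * (1.0 - dq_after / dq_before),
        "n_images": n_images,
    }


def preindex_recovery(n_images: int = 500, seed: int = 1, slide_px: float = 2.0,
                      lookup=None) -> dict:
    """Perturb-and-recover study for the orientation-free fingerprint path.

    Same detector, lateral/radial perturbations up to ``slide_px`` pixels,
    no orientations supplied.
    """
    scene = make_scene(SceneSpec(n_images=n_images, seed=seed))
    bounds = PerturbBounds(d_mm=slide_px * scene.spec.pixel_size / 2.0,
                           slide_px=slide_px)
    perturbed, _ = perturb(scene.detector, bounds, seed + 1)
    rms0 = rms_corner_displacement(perturbed, scene.detector)
    if lookup is None:
        lookup = build_ideal_lookup(scene.spec.cell, scene.spec.centring, 0.002)
    cfg = RefineConfig(seed=seed)
    refined = refine_preindex_full(perturbed, scene.spots, scene.spec.cell,
                                   scene.spec.centring, WAVELENGTH, cfg,
                                   lookup=lookup)
    rms1 = rms_corner_displacement(refined, scene.detector)
    return {
        "rms_before_mm": rms0,
        "rms_after_mm": rms1,
        "reduction_pct": 100.0 * (1.0 - rms1 / rms0),
        "n_images": n_images,
    }


def halfset_trend(images_per_half=(30, 150), n_seeds: int = 5, base_seed: int = 1,
                  noise_px: float = 0.3, outlier_frac: float = 0.05,
                  rlp_radius: float = 1.5e-4, max_cycles: int = 2) -> dict:
    """Median half-set corner-change correlation per half size.

    For each seed a noisy scene is split into odd/even image halves, both
    halves are refined independently from the same perturbed start, and the
    per-axis Pearson correlations of the corner changes are recorded.  The
    medians (over seeds, then axes) should not decrease with more images.
    """
    sizes = sorted(images_per_half)
    medians: dict[int, float] = {}
    per_size: dict[int, list[float]] = {n: [] for n in sizes}
    for s in range(n_seeds):
        seed = base_seed + 101 * s
        scene = make_scene(SceneSpec(n_images=2 * sizes[-1], seed=seed,
                                     noise_px=noise_px, outlier_frac=outlier_frac,
                                     rlp_radius=rlp_radius))
        perturbed, _ = perturb(
            scene.detector,
            PerturbBounds(slide_px=2.0, tilt_rad=np.deg2rad(0.2)),
            seed + 1,
        )
        cfg = RefineConfig(max_cycles=max_cycles, seed=seed)
        for n in sizes:
            lat_a = [l for l in scene.lattices if l.image_id % 2 == 0][:n]
            lat_b = [l for l in scene.lattices if l.image_id % 2 == 1][:n]
            det_a, _ = refine_indexed_cycle(perturbed, lat_a, scene.spots,
                                            WAVELENGTH, cfg)
            det_b, _ = refine_indexed_cycle(perturbed, lat_b, scene.spots,
                                            WAVELENGTH, cfg)
            rep = half_set_correlation(perturbed, det_a, det_b, n, n)
            per_size[n].append(float(np.median([rep.corr_x, rep.corr_y, rep.corr_z])))
    for n in sizes:
        medians[n] = float(np.median(per_size[n]))
    return {"median_correlation": medians, "per_seed": per_size}


def _contaminate(offsets, rng, frac: float = 0.10, bound: float = 10.0) -> None:
    """Replace ``frac`` of the pooled offsets with uniform +/-``bound`` px."""
    sizes = [len(o) for o in offsets]
    total = sum(sizes)
    flat = rng.choice(total, int(round(frac * total)), replace=False)
    start = 0
    for o, s in zip(offsets, sizes):
        sel = flat[(flat >= start) & (flat < start + s)] - start
        if len(sel):
            o.obs_pixel = o.obs_pixel.copy()
            o.obs_pixel[sel] = o.pred_pixel[sel] + rng.uniform(-bound, bound,
                                                               (len(sel), 2))
        start += s


def outlier_robustness(n_images: int = 40, scene_seed: int = 42,
                       noise_px: float = 0.2, tilt_deg: float = 0.2,
                       outlier_seeds=(5, 6, 7)) -> dict:
    """Tilt recovery with 10% uniform +/-10 px outlier offsets.

    A corner panel is tilted by ``tilt_deg`` and its tilt modes refined
    against the clustering reward on a lightly noisy scene; the clean-data
    recovery error is compared with the median error over outlier draws, for
    both the reward target and a least-squares spread (comparison oracle).
    """
    scene = make_scene(SceneSpec(n_images=n_images, seed=scene_seed,
                                 noise_px=noise_px))
    a_true = np.deg2rad(tilt_deg)

    def run(rng_seed, contaminated: bool, use_ls: bool) -> float:
        rng = np.random.default_rng(rng_seed)
        det = scene.detector.copy()
        panel = det.panels()[0]  # corner panel: strongest tilt leverage
        moved = apply_euclidean(panel, 0.0, -a_true, 0.0)
        panel.midpoint, panel.fast_axis, panel.slow_axis = (
            moved.midpoint, moved.fast_axis, moved.slow_axis,
        )
        cfg = RefineConfig()
        offsets = match_all(det, scene.lattices, scene.spots, WAVELENGTH,
                            cfg)[panel.id]
        if contaminated:
            _contaminate(offsets, rng)
        po = _PanelOffsets(panel, offsets, WAVELENGTH)
        if use_ls:
            target = lambda: -least_squares_target(po.dpx())  # noqa: E731
        else:
            target = lambda: euclidean_target(po.dpx(), cfg.k_pixel)  # noqa: E731
        _refine_modes(panel, ("alpha", "beta"), target, cfg)
        return abs(np.degrees(panel.pending.alpha) - tilt_deg)

    clean = run(0, False, False)
    reward = [run(s, True, False) for s in outlier_seeds]
    squares = [run(s, True, True) for s in outlier_seeds]
    return {
        "clean_error_deg": clean,
        "outlier_error_deg": float(np.median(reward)),
        "least_squares_error_deg": float(np.median(squares)),
        "ratio": float(np.median(reward)) / max(clean, 1e-12),
    }
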