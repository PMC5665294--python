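"""Seeded generator of synthetic still-diffraction scenes.

Emulates the inputs of a segmented-detector XFEL experiment: a multi-panel
detector with known truth geometry, per-image random crystal orientations of
a known unit cell, and observed spot lists derived from Ewald-slab
predictions with controllable positional noise and outliers.  Perturbing the
truth geometry with a replayable record makes geometry recovery scoreable.

Defaults mirror the study conditions this package targets: a 16-panel
(4 x 4) detector of 120 x 120 px panels with 0.11 mm pixels at 90.3 mm, a
body-centred cubic cell of a = 105.5 A at 1.46 A wavelength, and a detector
gain of 9.0 ADU/photon with log-normal photon counts chosen so roughly 80%
of spots pass the I/sigma >= 0.67 strong cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (
    DetectorGroup,
    Panel,
    absorb_offsets,
    build_hierarchy,
    panel_corners,
)
from .projection import DEFAULT_GAIN, Lattice, predict_stills, reciprocal_basis

__all__ = ["SceneSpec", "PerturbBounds", "PerturbationRecord", "Scene",
           "make_detector", "make_scene", "perturb", "replay"]

_CUBIC_I = (105.5, 105.5, 105.5, 90.0, 90.0, 90.0)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (all lengths mm unless noted)."""

    preset: str = "cspad_like_16"  # or "grid NxM"
    panel_px: int = 120
    pixel_size: float = 0.11
    gap_px: float = 18.0
    distance: float = 90.3
    wavelength: float = 1.46  # Angstrom
    cell: tuple = _CUBIC_I
    centring: str = "I"
    rlp_radius: float = 3e-4  # A^-1 Ewald slab half-width
    max_resolution: float = 3.5  # A; matches the detector's angular acceptance
    n_images: int = 150
    noise_px: float = 0.0  # Gaussian sigma on spot positions
    outlier_frac: float = 0.0
    photon_median: float = 2.0  # log-normal photon-count median
    photon_sigma: float = 1.5  # log-normal shape
    gain: float = DEFAULT_GAIN
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.outlier_frac <= 1.0):
            raise ValueError("outlier_frac must be in [0, 1]")
        for name in ("panel_px", "pixel_size", "distance", "wavelength",
                     "rlp_radius", "max_resolution", "n_images"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Scene:
    spec: SceneSpec
    detector: DetectorGroup  # truth geometry
    lattices: list[Lattice]
    spots: pd.DataFrame  # image_id, panel_id, fast, slow, value


def make_detector(spec: SceneSpec) -> DetectorGroup:
    """Planar multi-panel detector facing the beam, paired hierarchically.

    ``cspad_like_16`` is a 4 x 4 grid paired as adjacent pairs, foursomes,
    quadrant rows, halves, master; ``grid NxM`` pairs panels in reading
    order.
    """
    if spec.preset == "cspad_like_16":
        n_rows, n_cols = 4, 4
    elif spec.preset.startswith("grid"):
        n_rows, n_cols = (int(x) for x in spec.preset.split()[1].lower().split("x"))
    else:
        raise ValueError(f"unknown detector preset {spec.preset!r}")
    pitch = (spec.panel_px + spec.gap_px) * spec.pixel_size
    x0 = -pitch * (n_cols - 1) / 2.0
    y0 = -pitch * (n_rows - 1) / 2.0
    panels = []
    for r in range(n_rows):
        for c in range(n_cols):
            panels.append(
                Panel(
                    id=f"p{r}{c}",
                    midpoint=np.array([x0 + c * pitch, y0 + r * pitch, spec.distance]),
                    fast_axis=np.array([1.0, 0.0, 0.0]),
                    slow_axis=np.array([0.0, 1.0, 0.0]),
                    n_fast=spec.panel_px,
                    n_slow=spec.panel_px,
                    pixel_size=spec.pixel_size,
                )
            )
    return build_hierarchy(panels)


def _random_lattices(spec: SceneSpec, rng: np.random.Generator) -> list[Lattice]:
    bmat = reciprocal_basis(spec.cell)
    lattices = []
    for img in range(spec.n_images):
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        lattices.append(
            Lattice(image_id=img, ub=rot.as_matrix() @ bmat, cell=spec.cell,
                    centring=spec.centring)
        )
    return lattices


def make_scene(spec: SceneSpec) -> Scene:
    """Generate (truth detector, lattices, observed spot lists), seeded.

    Observed spots are the truth-geometry predictions plus Gaussian pixel
    noise, with uniform outlier spots mixed in at ``outlier_frac``.
    """
    rng = np.random.default_rng(spec.seed)
    detector = make_detector(spec)
    lattices = _random_lattices(spec, rng)
    rows = []
    n_spots = 0
    for lat in lattices:
        preds = predict_stills(lat, detector, spec.wavelength, spec.rlp_radius,
                               spec.max_resolution)
        n_spots += len(preds)
        photons = rng.lognormal(np.log(spec.photon_median), spec.photon_sigma,
                                size=len(preds))
        for n in range(len(preds)):
            pid = preds.panel_ids[n]
            panel = detector.find(pid)
            f = preds.pixel[n, 0] + rng.normal(0.0, spec.noise_px) if spec.noise_px else preds.pixel[n, 0]
            s = preds.pixel[n, 1] + rng.normal(0.0, spec.noise_px) if spec.noise_px else preds.pixel[n, 1]
            f = float(np.clip(f, 0.0, panel.n_fast - 1e-9))
            s = float(np.clip(s, 0.0, panel.n_slow - 1e-9))
            rows.append((lat.image_id, pid, f, s, spec.gain * photons[n]))
        if spec.outlier_frac > 0 and len(preds) > 0:
            n_out = rng.binomial(len(preds), spec.outlier_frac)
            panels = detector.panels()
            for _ in range(n_out):
                panel = panels[rng.integers(len(panels))]
                rows.append(
                    (
                        lat.image_id,
                        panel.id,
                        float(rng.uniform(0, panel.n_fast)),
                        float(rng.uniform(0, panel.n_slow)),
                        spec.gain * float(rng.lognormal(np.log(spec.photon_median),
                                                        spec.photon_sigma)),
                    )
                )
    if n_spots < spec.n_images:
        raise ValueError(
            "scene yields under one spot per image on average; "
            "increase rlp_radius or relax max_resolution"
        )
    spots = pd.DataFrame(rows, columns=["image_id", "panel_id", "fast", "slow", "value"])
    return Scene(spec=spec, detector=detector, lattices=lattices, spots=spots)


@dataclass
class PerturbBounds:
    """Uniform draw bounds for the six per-panel movement modes.

    ``slide_px`` bounds the lateral slide expressed in pixels at the panel
    distance (converted to theta/phi sphere angles); ``d_mm`` the spindle
    translation; ``tilt_rad`` alpha/beta; ``twist_rad`` psi.
    """

    d_mm: float = 0.0
    tilt_rad: float = 0.0
    slide_px: float = 0.0
    twist_rad: float = 0.0

    def __post_init__(self) -> None:
        if min(self.d_mm, self.tilt_rad, self.slide_px, self.twist_rad) < 0:
            raise ValueError("bounds must be non-negative")


@dataclass
class PerturbationRecord:
    """Injected per-panel movements and resulting corner displacements."""

    params: dict[str, dict[str, float]] = field(default_factory=dict)
    corner_shift_mm: dict[str, np.ndarray] = field(default_factory=dict)


def _apply_record_panel(panel: Panel, vals: dict[str, float]) -> None:
    panel.pending.d = vals["d"]
    panel.pending.alpha = vals["alpha"]
    panel.pending.beta = vals["beta"]
    panel.pending.theta = vals["theta"]
    panel.pending.phi = vals["phi"]
    panel.pending.psi = vals["psi"]
    absorb_offsets(panel)


def perturb(detector: DetectorGroup, bounds: PerturbBounds, seed: int
            ) -> tuple[DetectorGroup, PerturbationRecord]:
    """Independently perturb every panel within the bounds (seeded).

    Returns a new detector plus a record that :func:`replay` applies to the
    truth geometry to reproduce the perturbed one exactly.
    """
    rng = np.random.default_rng(seed)
    out = detector.copy()
    record = PerturbationRecord()
    for panel in out.panels():
        dist = float(np.linalg.norm(panel.midpoint))
        slide_rad = bounds.slide_px * panel.pixel_size / dist
        vals = {
            "d": float(rng.uniform(-bounds.d_mm, bounds.d_mm)),
            "alpha": float(rng.uniform(-bounds.tilt_rad, bounds.tilt_rad)),
            "beta": float(rng.uniform(-bounds.tilt_rad, bounds.tilt_rad)),
            "theta": float(rng.uniform(-slide_rad, slide_rad)),
            "phi": float(rng.uniform(-slide_rad, slide_rad)),
            "psi": float(rng.uniform(-bounds.twist_rad, bounds.twist_rad)),
        }
        before = panel_corners(out, panel.id)
        _apply_record_panel(panel, vals)
        record.params[panel.id] = vals
        record.corner_shift_mm[panel.id] = panel_corners(out, panel.id) - before
    return out, record


def replay(detector: DetectorGroup, record: PerturbationRecord) -> DetectorGroup:
    """Apply a perturbation record onto a (truth) detector copy."""
    out = detector.copy()
    for panel in out.panels():
        if panel.id in record.params:
            _apply_record_panel(panel, record.params[panel.id])
    return out
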