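"""Segmented-detector geometry model.

Laboratory frame: right-handed, origin at the sample, +Z along the beam from
sample to detector, +Y toward the ceiling, +X completing the system.  All
lengths are in millimetres, all angles in radians (degrees appear only at I/O
surfaces).

A detector is a recursive pairing hierarchy of :class:`DetectorGroup` nodes
whose leaves hold :class:`Panel` segments.  Each panel stores its midpoint,
unit fast-scan / slow-scan axes and pixel grid.  Two movement-mode families
act on panels and groups:

* *Euclidean* movements change the relative arrangement of back-projected
  rays: translation ``d`` along the spindle (the axis joining the sample to
  the panel midpoint) and tilts ``alpha``/``beta`` about the two orthonormal
  axes through the panel centre normal to the spindle.
* *Sphere* (non-Euclidean) movements rotate a panel or group rigidly about
  an axis through the sample: ``psi`` about the reference axis itself and
  ``theta``/``phi`` about the two completing orthonormal axes.  They preserve
  every sample-to-pixel distance and every pairwise angle between rays.

Movements accumulate as *pending* parameters and are baked into the stored
midpoint/axes by :func:`absorb_offsets`, which zeroes the pending set without
changing the pixel-to-lab map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "MovementParams",
    "Panel",
    "DetectorGroup",
    "pixel_to_lab",
    "apply_euclidean",
    "apply_noneuclidean",
    "absorb_offsets",
    "build_hierarchy",
    "spindle_frame",
    "axis_frame",
    "sphere_rotation",
    "euclidean_moved",
    "panel_corners",
    "rms_corner_displacement",
]

_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def spindle_frame(spindle: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal axes normal to *spindle* (unit), built deterministically.

    u1 = spindle x lab-Y (normalized), falling back to lab-X when the spindle
    is nearly parallel to Y; u2 = spindle x u1.
    """
    ref = _Y if np.linalg.norm(np.cross(spindle, _Y)) > 1e-6 else _X
    u1 = _unit(np.cross(spindle, ref))
    u2 = np.cross(spindle, u1)
    return u1, u2


def axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame (e1, e2, e3=axis) completing a sphere-rotation axis."""
    e3 = _unit(np.asarray(axis, dtype=float))
    e1, e2 = spindle_frame(e3)
    return e1, e2, e3


def sphere_rotation(theta: float, phi: float, psi: float, axis: np.ndarray) -> Rotation:
    """Rigid rotation about the sample for polar angles about *axis*.

    Composition order (fixed convention; refined angles are small so any fixed
    order serves): psi about the axis first, then theta about e1, then phi
    about e2, where (e1, e2) complete the axis deterministically.
    """
    e1, e2, e3 = axis_frame(axis)
    return (
        Rotation.from_rotvec(phi * e2)
        * Rotation.from_rotvec(theta * e1)
        * Rotation.from_rotvec(psi * e3)
    )


@dataclass
class MovementParams:
    """Pending movement parameters for one panel or group.

    ``d`` is in mm along the spindle; all angles are radians.  ``theta``,
    ``phi``, ``psi`` are sphere rotations about the owner's reference axis.
    """

    d: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    theta: float = 0.0
    phi: float = 0.0
    psi: float = 0.0

    def is_zero(self) -> bool:
        return (
            self.d == 0.0
            and self.alpha == 0.0
            and self.beta == 0.0
            and self.theta == 0.0
            and self.phi == 0.0
            and self.psi == 0.0
        )

    def copy(self) -> "MovementParams":
        return replace(self)


def euclidean_moved(
    midpoint: np.ndarray,
    fast: np.ndarray,
    slow: np.ndarray,
    d: float,
    alpha: float,
    beta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a Euclidean movement to raw (midpoint, fast, slow) geometry.

    Translation ``d`` along the spindle; tilts ``alpha`` then ``beta`` about
    the two spindle-normal axes through the (translated) midpoint.  The
    sample-to-midpoint direction is unchanged by the tilts.
    """
    if np.linalg.norm(midpoint) == 0.0:
        raise ValueError("degenerate spindle: panel midpoint coincides with the sample")
    spindle = _unit(midpoint)
    u1, u2 = spindle_frame(spindle)
    rot = Rotation.from_rotvec(beta * u2) * Rotation.from_rotvec(alpha * u1)
    return midpoint + d * spindle, rot.apply(fast), rot.apply(slow)


@dataclass
class Panel:
    """One rigid detector segment.

    ``midpoint`` is the geometric centre of the active pixel area (mm, lab
    frame); ``fast_axis``/``slow_axis`` are unit 3-vectors; continuous pixel
    coordinates run over [0, n_fast] x [0, n_slow] with the centre of integer
    pixel (i, j) at (i + 0.5, j + 0.5).
    """

    id: str
    midpoint: np.ndarray
    fast_axis: np.ndarray
    slow_axis: np.ndarray
    n_fast: int
    n_slow: int
    pixel_size: float
    pending: MovementParams = field(default_factory=MovementParams)
    ref_axis: np.ndarray | None = None  # sphere-rotation axis; default: spindle

    def __post_init__(self) -> None:
        self.midpoint = np.asarray(self.midpoint, dtype=float)
        self.fast_axis = np.asarray(self.fast_axis, dtype=float)
        self.slow_axis = np.asarray(self.slow_axis, dtype=float)
        if abs(np.linalg.norm(self.fast_axis) - 1.0) > 1e-12:
            raise ValueError(f"panel {self.id}: fast axis is not unit length")
        if abs(np.linalg.norm(self.slow_axis) - 1.0) > 1e-12:
            raise ValueError(f"panel {self.id}: slow axis is not unit length")
        if abs(float(self.fast_axis @ self.slow_axis)) > 1e-12:
            raise ValueError(f"panel {self.id}: fast/slow axes are not orthogonal")
        if self.pixel_size <= 0:
            raise ValueError(f"panel {self.id}: pixel size must be positive")
        if self.n_fast < 1 or self.n_slow < 1:
            raise ValueError(f"panel {self.id}: pixel counts must be >= 1")

    # -- geometry under pending movements -------------------------------

    def sphere_axis(self) -> np.ndarray:
        if self.ref_axis is not None:
            return _unit(np.asarray(self.ref_axis, dtype=float))
        return _unit(self.midpoint)

    def effective(self, *, euclidean_only: bool = False):
        """(midpoint, fast, slow) with pending movements applied.

        Euclidean movement first, then the sphere rotation about the panel's
        reference axis.  ``euclidean_only`` evaluates the Euclidean part alone
        (used by the clustering reward, which is insensitive to sphere moves
        by construction).
        """
        p = self.pending
        mid, fast, slow = self.midpoint, self.fast_axis, self.slow_axis
        if p.d != 0.0 or p.alpha != 0.0 or p.beta != 0.0:
            mid, fast, slow = euclidean_moved(mid, fast, slow, p.d, p.alpha, p.beta)
        if not euclidean_only and (p.theta != 0.0 or p.phi != 0.0 or p.psi != 0.0):
            rot = sphere_rotation(p.theta, p.phi, p.psi, self.sphere_axis())
            mid, fast, slow = rot.apply(mid), rot.apply(fast), rot.apply(slow)
        return mid, fast, slow

    def copy(self) -> "Panel":
        return Panel(
            id=self.id,
            midpoint=self.midpoint.copy(),
            fast_axis=self.fast_axis.copy(),
            slow_axis=self.slow_axis.copy(),
            n_fast=self.n_fast,
            n_slow=self.n_slow,
            pixel_size=self.pixel_size,
            pending=self.pending.copy(),
            ref_axis=None if self.ref_axis is None else np.asarray(self.ref_axis).copy(),
        )


@dataclass
class DetectorGroup:
    """Node in the recursive pairing hierarchy; the root is the detector.

    A pending sphere movement on a group moves all descendant panels rigidly;
    children inherit parent transforms (applied leaf-to-root).
    """

    id: str
    children: list  # DetectorGroup | Panel
    pending: MovementParams = field(default_factory=MovementParams)
    ref_axis: np.ndarray | None = None

    def panels(self) -> list[Panel]:
        out: list[Panel] = []
        for child in self.children:
            if isinstance(child, Panel):
                out.append(child)
            else:
                out.extend(child.panels())
        return out

    def groups(self) -> list["DetectorGroup"]:
        out = [self]
        for child in self.children:
            if isinstance(child, DetectorGroup):
                out.extend(child.groups())
        return out

    def find(self, target_id: str):
        for node in self.groups():
            if node.id == target_id:
                return node
            for child in node.children:
                if isinstance(child, Panel) and child.id == target_id:
                    return child
        raise KeyError(f"no panel or group named {target_id!r}")

    def centre(self) -> np.ndarray:
        """Mean of effective panel midpoints (mm)."""
        mids = [self.panel_geometry(p.id)[0] for p in self.panels()]
        return np.mean(mids, axis=0)

    def sphere_axis(self) -> np.ndarray:
        if self.ref_axis is not None:
            return _unit(np.asarray(self.ref_axis, dtype=float))
        mids = [p.midpoint for p in self.panels()]
        return _unit(np.mean(mids, axis=0))

    def _ancestry(self, panel_id: str) -> tuple[Panel, list["DetectorGroup"]]:
        """Panel and its chain of enclosing groups, innermost first."""
        for child in self.children:
            if isinstance(child, Panel):
                if child.id == panel_id:
                    return child, [self]
            else:
                try:
                    panel, chain = child._ancestry(panel_id)
                except KeyError:
                    continue
                return panel, chain + [self]
        raise KeyError(f"panel {panel_id!r} not in group {self.id!r}")

    def panel_geometry(self, panel_id: str, *, euclidean_only: bool = False):
        """Effective (midpoint, fast, slow) of a panel including inherited
        group transforms, innermost group applied first."""
        panel, chain = self._ancestry(panel_id)
        mid, fast, slow = panel.effective(euclidean_only=euclidean_only)
        if not euclidean_only:
            for grp in chain:
                p = grp.pending
                if p.theta != 0.0 or p.phi != 0.0 or p.psi != 0.0:
                    rot = sphere_rotation(p.theta, p.phi, p.psi, grp.sphere_axis())
                    mid, fast, slow = rot.apply(mid), rot.apply(fast), rot.apply(slow)
        return mid, fast, slow

    def copy(self) -> "DetectorGroup":
        return DetectorGroup(
            id=self.id,
            children=[c.copy() for c in self.children],
            pending=self.pending.copy(),
            ref_axis=None if self.ref_axis is None else np.asarray(self.ref_axis).copy(),
        )


# ---------------------------------------------------------------------------
# Operations


def pixel_to_lab(panel: Panel, fast, slow, *, euclidean_only: bool = False) -> np.ndarray:
    """Lab position (mm) of continuous pixel coordinates on a panel.

    Fractional coordinates are allowed; pending movements are applied.
    Accepts scalars or same-shaped arrays and broadcasts accordingly.
    """
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    if np.any(fast < 0) or np.any(fast > panel.n_fast) or np.any(slow < 0) or np.any(
        slow > panel.n_slow
    ):
        raise ValueError(
            f"pixel coordinates out of range for panel {panel.id} "
            f"([0, {panel.n_fast}] x [0, {panel.n_slow}])"
        )
    mid, f_ax, s_ax = panel.effective(euclidean_only=euclidean_only)
    return lab_positions(mid, f_ax, s_ax, panel.pixel_size, panel.n_fast, panel.n_slow, fast, slow)


def lab_positions(mid, f_ax, s_ax, pixel_size, n_fast, n_slow, fast, slow) -> np.ndarray:
    """Vectorized pixel->lab map from raw geometry (no range checks)."""
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    df = (fast - n_fast / 2.0) * pixel_size
    ds = (slow - n_slow / 2.0) * pixel_size
    return mid + np.multiply.outer(df, f_ax) + np.multiply.outer(ds, s_ax)


def apply_euclidean(panel: Panel, d: float, alpha: float, beta: float) -> Panel:
    """Return a new panel with a Euclidean movement baked into its geometry."""
    out = panel.copy()
    out.midpoint, out.fast_axis, out.slow_axis = euclidean_moved(
        panel.midpoint, panel.fast_axis, panel.slow_axis, d, alpha, beta
    )
    return out


def apply_noneuclidean(target, theta: float, phi: float, psi: float, axis=None):
    """Return a new panel/group rotated rigidly about the sample.

    ``axis`` defaults to the target's own reference axis (the spindle for a
    panel).  Every lab point keeps its distance from the sample.
    """
    out = target.copy()
    ax = out.sphere_axis() if axis is None else _unit(np.asarray(axis, dtype=float))
    rot = sphere_rotation(theta, phi, psi, ax)
    _rotate_baked(out, rot)
    return out


def _rotate_baked(node, rot: Rotation) -> None:
    if isinstance(node, Panel):
        node.midpoint = rot.apply(node.midpoint)
        node.fast_axis = rot.apply(node.fast_axis)
        node.slow_axis = rot.apply(node.slow_axis)
        if node.ref_axis is not None:
            node.ref_axis = rot.apply(np.asarray(node.ref_axis, dtype=float))
    else:
        for child in node.children:
            _rotate_baked(child, rot)


def absorb_offsets(target):
    """Bake pending movements into midpoints/axes and zero them (in place).

    The pixel-to-lab map is unchanged; after the call every pending parameter
    in the subtree is exactly zero.  Returns the target for chaining.
    """
    if isinstance(target, Panel):
        target.midpoint, target.fast_axis, target.slow_axis = target.effective()
        target.pending = MovementParams()
        return target
    for child in target.children:
        absorb_offsets(child)
    p = target.pending
    if not p.is_zero():
        rot = sphere_rotation(p.theta, p.phi, p.psi, target.sphere_axis())
        _rotate_baked(target, rot)
        target.pending = MovementParams()
    return target


def build_hierarchy(panels: list[Panel], pairing: list[list[tuple]] | None = None,
                    root_id: str = "master") -> DetectorGroup:
    """Assemble the recursive pairing hierarchy ending in a single root.

    ``pairing`` lists, per level, pairs of child ids (panel ids at the first
    level, group ids above).  Generated group ids are ``L{level}-{index}``.
    An unpaired id in an odd level is promoted unchanged to the next level.
    When ``pairing`` is None, ids are paired greedily in the given order.
    """
    ids = [p.id for p in panels]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate panel ids: {dupes}")
    nodes: dict[str, object] = {p.id: p for p in panels}
    if len(panels) == 1:
        return DetectorGroup(id=root_id, children=[panels[0]])

    if pairing is None:
        pairing = []
        level_ids = list(ids)
        level = 1
        while len(level_ids) > 1:
            pairs = [tuple(level_ids[i : i + 2]) for i in range(0, len(level_ids), 2)]
            pairing.append(pairs)
            level_ids = [
                pair[0] if len(pair) == 1 else f"L{level}-{j}"
                for j, pair in enumerate(pairs)
            ]
            level = level + 1

    current = dict(nodes)
    for level, pairs in enumerate(pairing, start=1):
        used: list[str] = []
        next_level: dict[str, object] = {}
        last = level == len(pairing)
        for j, pair in enumerate(pairs):
            for cid in pair:
                if cid not in current:
                    raise ValueError(f"unknown or already-consumed id {cid!r} at level {level}")
                if cid in used:
                    raise ValueError(f"id {cid!r} used twice at level {level}")
                used.append(cid)
            gid = root_id if (last and len(pairs) == 1) else f"L{level}-{j}"
            if len(pair) == 1:
                # odd-one-out: promote unchanged
                next_level[pair[0]] = current[pair[0]]
                continue
            next_level[gid] = DetectorGroup(id=gid, children=[current[c] for c in pair])
        orphans = sorted(set(current) - set(used))
        if orphans:
            raise ValueError(f"orphan ids not covered by pairing at level {level}: {orphans}")
        current = next_level
    if len(current) != 1:
        raise ValueError(f"pairing does not terminate in a single root: {sorted(current)}")
    (root,) = current.values()
    if isinstance(root, Panel):
        root = DetectorGroup(id=root_id, children=[root])
    elif root.id != root_id:
        root.id = root_id
    return root


def panel_corners(detector: DetectorGroup, panel_id: str) -> np.ndarray:
    """Lab positions (4, 3) of a panel's four pixel-area corners."""
    panel = detector.find(panel_id)
    mid, f_ax, s_ax = detector.panel_geometry(panel_id)
    nf, ns = panel.n_fast, panel.n_slow
    fast = np.array([0.0, nf, 0.0, nf])
    slow = np.array([0.0, 0.0, ns, ns])
    return lab_positions(mid, f_ax, s_ax, panel.pixel_size, nf, ns, fast, slow)


def rms_corner_displacement(detector: DetectorGroup, reference: DetectorGroup) -> float:
    """RMS over all panels/corners of the corner displacement norm (mm)."""
    sq = []
    for panel in detector.panels():
        d = panel_corners(detector, panel.id) - panel_corners(reference, panel.id)
        sq.extend(np.sum(d * d, axis=1))
    return float(np.sqrt(np.mean(sq)))
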