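"""File formats and validation diagnostics.

Geometry files use a CrystFEL-style dialect subset: per-panel keys ``fs``,
``ss`` (axis direction expressions such as ``+1.0x -0.0y +0.0z``),
``corner_x``/``corner_y`` (pixels), ``min_fs``/``max_fs``/``min_ss``/
``max_ss`` (pixel extents), ``res`` (pixels per metre), ``clen`` (metres)
and an optional ``group`` hierarchy path (root first, slash separated).
``corner_x``/``corner_y`` locate the outer corner of pixel (0, 0); the
panel midpoint is derived from the corner, the axes and the pixel extents.
Unsupported keys are preserved verbatim on write, so read -> write -> read
round trips are lossless for the supported subset.

Spot lists are CSV (image_id, panel_id, fast, slow, value) and orientation
sets are JSON (image_id, 3x3 ub row-major, cell, centring), both with
12-significant-digit floats.

The diagnostics mirror the validation practice for this protocol:
half-data-set corner-coordinate correlations, per-panel offset spreads, and
"iron filing" inter-panel vector usage counts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .geometry import DetectorGroup, Panel, build_hierarchy, panel_corners
from .projection import Lattice

__all__ = [
    "read_geom",
    "write_geom",
    "read_spots",
    "write_spots",
    "read_lattices",
    "write_lattices",
    "HalfSetReport",
    "half_set_correlation",
    "offset_spread_report",
    "iron_filing_counts",
]

_SUPPORTED = {"fs", "ss", "corner_x", "corner_y", "min_fs", "max_fs", "min_ss",
              "max_ss", "res", "clen", "group"}
_AXIS_RE = re.compile(r"([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)([xyz])")


def _parse_axis(expr: str, path: str, lineno: int) -> np.ndarray:
    vec = np.zeros(3)
    rest = expr
    for m in _AXIS_RE.finditer(expr):
        vec["xyz".index(m.group(2))] += float(m.group(1))
        rest = rest.replace(m.group(0), "", 1)
    if rest.strip() or not _AXIS_RE.search(expr):
        raise ValueError(f"{path}:{lineno}: malformed axis expression {expr!r}")
    return vec


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _fmt_axis(vec: np.ndarray) -> str:
    parts = []
    for comp, name in zip(vec, "xyz"):
        parts.append(f"{'+' if comp >= 0 else '-'}{_fmt(abs(comp))}{name}")
    return " ".join(parts)


def read_geom(path: str) -> DetectorGroup:
    """Read a geometry file; returns the detector with its hierarchy.

    Panels without ``group`` tags are paired greedily in file order.
    """
    raw: dict[str, dict[str, str]] = {}
    order: list[str] = []
    extras: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                extras.append(line.rstrip("\n"))
                continue
            if "=" not in stripped or "/" not in stripped.split("=")[0]:
                extras.append(line.rstrip("\n"))
                continue
            key, value = (s.strip() for s in stripped.split("=", 1))
            panel_name, attr = key.split("/", 1)
            if attr not in _SUPPORTED:
                extras.append(line.rstrip("\n"))
                continue
            if panel_name not in raw:
                raw[panel_name] = {}
                order.append(panel_name)
            raw[panel_name][attr] = value
            if attr in ("fs", "ss"):
                _parse_axis(value, path, lineno)  # validate with line number

    panels: list[Panel] = []
    groups: dict[str, str] = {}
    for name in order:
        entry = raw[name]
        fs = _parse_axis(entry["fs"], path, 0)
        ss = _parse_axis(entry["ss"], path, 0)
        res = float(entry["res"])  # pixels per metre
        ps = 1000.0 / res  # mm per pixel
        n_fast = int(entry.get("max_fs", 0)) - int(entry.get("min_fs", 0)) + 1
        n_slow = int(entry.get("max_ss", 0)) - int(entry.get("min_ss", 0)) + 1
        corner = np.array([
            float(entry["corner_x"]) * ps,
            float(entry["corner_y"]) * ps,
            float(entry["clen"]) * 1000.0,
        ])
        fs_u = fs / np.linalg.norm(fs)
        ss_u = ss / np.linalg.norm(ss)
        mid = corner + (n_fast / 2.0) * ps * fs_u + (n_slow / 2.0) * ps * ss_u
        panels.append(Panel(id=name, midpoint=mid, fast_axis=fs_u, slow_axis=ss_u,
                            n_fast=n_fast, n_slow=n_slow, pixel_size=ps))
        if "group" in entry:
            groups[name] = entry["group"]
    detector = _hierarchy_from_paths(panels, groups)
    detector._geom_extras = [raw, order, extras]  # type: ignore[attr-defined]
    return detector


def _hierarchy_from_paths(panels: list[Panel], paths: dict[str, str]) -> DetectorGroup:
    if not paths:
        return build_hierarchy(panels)
    root = DetectorGroup(id="master", children=[])
    nodes: dict[tuple, DetectorGroup] = {(): root}
    for panel in panels:
        parts = tuple(paths.get(panel.id, "").split("/")) if panel.id in paths else ()
        parts = tuple(p for p in parts if p)
        for i in range(1, len(parts) + 1):
            key = parts[:i]
            if key not in nodes:
                nodes[key] = DetectorGroup(id=parts[i - 1], children=[])
                nodes[key[:-1]].children.append(nodes[key])
        nodes[parts].children.append(panel)
    return root


def _group_path(detector: DetectorGroup, panel_id: str) -> str:
    _, chain = detector._ancestry(panel_id)
    return "/".join(g.id for g in reversed(chain) if g is not detector)


def write_geom(detector: DetectorGroup, path: str) -> None:
    """Write the detector in the supported dialect (12 sig. digit floats).

    Unsupported keys captured by a previous :func:`read_geom` are re-emitted
    verbatim.
    """
    raw, order, extras = getattr(detector, "_geom_extras", [{}, [], []])
    lines: list[str] = list(extras)
    ids = [p.id for p in detector.panels()]
    for pid in sorted(ids, key=lambda i: order.index(i) if i in order else len(order)):
        panel = detector.find(pid)
        mid, fs_u, ss_u = detector.panel_geometry(pid)
        ps = panel.pixel_size
        corner = mid - (panel.n_fast / 2.0) * ps * fs_u - (panel.n_slow / 2.0) * ps * ss_u
        lines.append(f"{pid}/fs = {_fmt_axis(fs_u)}")
        lines.append(f"{pid}/ss = {_fmt_axis(ss_u)}")
        lines.append(f"{pid}/corner_x = {_fmt(corner[0] / ps)}")
        lines.append(f"{pid}/corner_y = {_fmt(corner[1] / ps)}")
        lines.append(f"{pid}/min_fs = 0")
        lines.append(f"{pid}/max_fs = {panel.n_fast - 1}")
        lines.append(f"{pid}/min_ss = 0")
        lines.append(f"{pid}/max_ss = {panel.n_slow - 1}")
        lines.append(f"{pid}/res = {_fmt(1000.0 / ps)}")
        lines.append(f"{pid}/clen = {_fmt(corner[2] / 1000.0)}")
        gp = _group_path(detector, pid)
        if gp:
            lines.append(f"{pid}/group = {gp}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spot lists and orientations


def write_spots(spots: pd.DataFrame, path: str) -> None:
    spots.to_csv(path, index=False, float_format="%.12g")


def read_spots(path: str, detector: DetectorGroup | None = None) -> pd.DataFrame:
    spots = pd.read_csv(path)
    expected = ["image_id", "panel_id", "fast", "slow", "value"]
    if list(spots.columns) != expected:
        raise ValueError(f"spot list must have columns {expected}")
    if detector is not None:
        known = {p.id for p in detector.panels()}
        bad = spots.index[~spots["panel_id"].isin(known)]
        if len(bad):
            raise ValueError(
                f"unknown panel id {spots.loc[bad[0], 'panel_id']!r} in row {bad[0]}"
            )
    return spots


def write_lattices(lattices: list[Lattice], path: str) -> None:
    payload = [
        {
            "image_id": int(lat.image_id),
            "ub": [[float(f"{v:.12g}") for v in row] for row in lat.ub],
            "cell": [float(f"{v:.12g}") for v in lat.cell],
            "centring": lat.centring,
        }
        for lat in lattices
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_lattices(path: str) -> list[Lattice]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Lattice(image_id=int(e["image_id"]), ub=np.array(e["ub"]),
                cell=tuple(e["cell"]), centring=e.get("centring", "P"))
        for e in payload
    ]


# ---------------------------------------------------------------------------
# Diagnostics


@dataclass
class HalfSetReport:
    """Pearson correlations of per-corner coordinate changes between two
    half-data-set refinements, per lab axis."""

    corr_x: float
    corr_y: float
    corr_z: float
    n_images_a: int = 0
    n_images_b: int = 0

    def as_dict(self) -> dict:
        return {"X": self.corr_x, "Y": self.corr_y, "Z": self.corr_z,
                "n_images": [self.n_images_a, self.n_images_b]}


def half_set_correlation(start: DetectorGroup, refined_a: DetectorGroup,
                         refined_b: DetectorGroup, n_images_a: int = 0,
                         n_images_b: int = 0) -> HalfSetReport:
    """Correlate the corner-coordinate changes of two half refinements.

    Both halves must start from the same geometry; changes are the X/Y/Z
    coordinates of all four corners of every panel.
    """
    ids = [p.id for p in start.panels()]
    if len(ids) < 3:
        raise ValueError("half-set correlation undefined below 3 panels")
    da, db = [], []
    for pid in ids:
        base = panel_corners(start, pid)
        da.append(panel_corners(refined_a, pid) - base)
        db.append(panel_corners(refined_b, pid) - base)
    da = np.vstack(da)
    db = np.vstack(db)
    corr = [float(pearsonr(da[:, ax], db[:, ax]).statistic) for ax in range(3)]
    return HalfSetReport(*corr, n_images_a=n_images_a, n_images_b=n_images_b)


def offset_spread_report(offsets_by_panel: dict[str, list]) -> pd.DataFrame:
    """Per-panel pixel-offset standard deviation and mean |dq| (A^-1).

    ``offsets_by_panel`` maps panel id to OffsetSet lists as produced by the
    matching step.
    """
    rows = []
    for pid, osets in sorted(offsets_by_panel.items()):
        if not osets:
            continue
        dpx = np.vstack([o.dpx for o in osets])
        dq = np.vstack([o.dq for o in osets])
        centred = dpx - dpx.mean(axis=0)
        rows.append({
            "panel_id": pid,
            "n": len(dpx),
            "px_spread": float(np.sqrt(np.mean(np.sum(centred**2, axis=1)))),
            "mean_dq": float(np.mean(np.linalg.norm(dq, axis=1))),
        })
    return pd.DataFrame(rows, columns=["panel_id", "n", "px_spread", "mean_dq"])


def iron_filing_counts(vectors, panel_ids: list[str]) -> pd.DataFrame:
    """Symmetric usage-count matrix over panel pairs (diagonal = intra).

    ``vectors`` is an iterable of VectorObs; the result is a DataFrame
    indexed and columned by panel id, exportable as CSV for plotting.
    """
    idx = {pid: i for i, pid in enumerate(panel_ids)}
    mat = np.zeros((len(panel_ids), len(panel_ids)), dtype=int)
    for v in vectors:
        if len(v.panels) == 1:
            mat[idx[v.panels[0]], idx[v.panels[0]]] += 1
        else:
            a, b = (idx[p] for p in v.panels)
            mat[a, b] += 1
            mat[b, a] += 1
    return pd.DataFrame(mat, index=panel_ids, columns=panel_ids)
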