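"""Model/Results front-end over the refinement machinery.

Each model is constructed from data (detector, spot lists, optionally
indexing solutions) and ``fit()`` returns a results object carrying the
refined geometry, per-panel diagnostics and a ``summary()`` table, in the
style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import cell_geometry_loop
from .geometry import DetectorGroup, rms_corner_displacement
from .indexed import PanelReport, RefineConfig, refine_indexed_cycle
from .fingerprint import FingerprintLookup, refine_preindex_full
from .projection import Lattice

__all__ = [
    "IndexedGeometryRefinement",
    "PreIndexGeometryRefinement",
    "CellScaleRefinement",
    "GeometryResults",
    "CellScaleResults",
]


@dataclass
class GeometryResults:
    """Refined geometry plus diagnostics from a geometry model fit."""

    detector: DetectorGroup
    start: DetectorGroup
    reports: list[list[PanelReport]] = field(default_factory=list)
    method: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.reports)

    def corner_shift_rms(self) -> float:
        """RMS corner displacement from the starting geometry (mm)."""
        return rms_corner_displacement(self.detector, self.start)

    def panel_table(self) -> pd.DataFrame:
        """Per-panel diagnostics: first-cycle start vs last-cycle end."""
        if not self.reports:
            return pd.DataFrame()
        rows = []
        for first, last in zip(self.reports[0], self.reports[-1]):
            rows.append({
                "panel_id": first.panel_id,
                "n_offsets": last.n_offsets,
                "E_before": first.E_before,
                "E_after": last.E_after,
                "px_spread_before": first.px_spread_before,
                "px_spread_after": last.px_spread_after,
                "mean_dq_before": first.mean_dq_before,
                "mean_dq_after": last.mean_dq_after,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Geometry refinement ({self.method})",
            f"  cycles run:            {self.n_cycles}",
            f"  panels:                {len(self.detector.panels())}",
            f"  corner shift RMS (mm): {self.corner_shift_rms():.5f}",
        ]
        table = self.panel_table()
        if len(table):
            lines.append(
                "  mean px spread:        "
                f"{table['px_spread_before'].mean():.4f} -> {table['px_spread_after'].mean():.4f}"
            )
            mb, ma = table["mean_dq_before"].mean(), table["mean_dq_after"].mean()
            lines.append(f"  mean |dq| (A^-1):      {mb:.6f} -> {ma:.6f}")
            if mb > 0:
                lines.append(f"  mean |dq| reduction:   {100.0 * (1 - ma / mb):.1f}%")
        return "\n".join(lines)


class IndexedGeometryRefinement:
    """Two-stage per-panel refinement from indexing solutions.

    Parameters
    ----------
    detector : starting geometry (not modified)
    spots : DataFrame (image_id, panel_id, fast, slow, value)
    lattices : indexing solutions, one per usable image
    wavelength : Angstrom
    config : RefineConfig
    """

    def __init__(self, detector: DetectorGroup, spots: pd.DataFrame,
                 lattices: list[Lattice], wavelength: float,
                 config: RefineConfig | None = None):
        self.detector = detector
        self.spots = spots
        self.lattices = lattices
        self.wavelength = wavelength
        self.config = config or RefineConfig()

    def fit(self) -> GeometryResults:
        refined, reports = refine_indexed_cycle(
            self.detector, self.lattices, self.spots, self.wavelength, self.config
        )
        return GeometryResults(detector=refined, start=self.detector,
                               reports=reports, method="indexed, slip+slide")


class PreIndexGeometryRefinement:
    """Orientation-free refinement from the unit-cell fingerprint only."""

    def __init__(self, detector: DetectorGroup, spots: pd.DataFrame, cell,
                 centring: str = "P", wavelength: float = 1.46,
                 config: RefineConfig | None = None,
                 lookup: FingerprintLookup | None = None,
                 lookup_tolerance: float = 0.002,
                 coarse_tolerance: float | None = 0.006,
                 top_per_image: int = 40, cycles: int = 1):
        self.detector = detector
        self.spots = spots
        self.cell = cell
        self.centring = centring
        self.wavelength = wavelength
        self.config = config or RefineConfig()
        self.lookup = lookup
        self.lookup_tolerance = lookup_tolerance
        self.coarse_tolerance = coarse_tolerance
        self.top_per_image = top_per_image
        self.cycles = cycles

    def fit(self) -> GeometryResults:
        refined = refine_preindex_full(
            self.detector, self.spots, self.cell, self.centring, self.wavelength,
            self.config, lookup=self.lookup, lookup_tolerance=self.lookup_tolerance,
            coarse_tolerance=self.coarse_tolerance,
            top_per_image=self.top_per_image, cycles=self.cycles,
        )
        return GeometryResults(detector=refined, start=self.detector,
                               method="pre-indexing fingerprint")


@dataclass
class CellScaleResults:
    cell: tuple
    detector: DetectorGroup
    lattices: list[Lattice]
    scale_history: list[float]

    @property
    def total_scale(self) -> float:
        return float(np.prod(self.scale_history)) if self.scale_history else 1.0

    def summary(self) -> str:
        a0 = self.cell[0] / self.total_scale
        return "\n".join([
            "Cell-scale refinement",
            f"  iterations:        {len(self.scale_history)}",
            f"  total scale:       {self.total_scale:.6f}",
            f"  cell edge a (A):   {a0:.4f} -> {self.cell[0]:.4f}",
            f"  distance factor:   {1.0 / self.total_scale:.6f}",
        ])


class CellScaleRefinement:
    """Decouples unit-cell dimensions from detector geometry.

    Alternates per-image orientation refinement with a one-parameter cell
    rescale that centres the implied wavelengths of strong reflections on
    the nominal wavelength, compensating the detector distance.
    """

    def __init__(self, detector: DetectorGroup, spots: pd.DataFrame,
                 lattices: list[Lattice], wavelength: float,
                 config: RefineConfig | None = None, inflate: float = 3.0):
        self.detector = detector
        self.spots = spots
        self.lattices = lattices
        self.wavelength = wavelength
        self.config = config or RefineConfig()
        self.inflate = inflate

    def fit(self, max_iter: int = 10, tol: float = 1e-4) -> CellScaleResults:
        cell, det, lats, history = cell_geometry_loop(
            self.lattices, self.detector, self.spots, self.wavelength,
            self.config, self.inflate, max_iter, tol,
        )
        return CellScaleResults(cell=cell, detector=det, lattices=lats,
                                scale_history=history)
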