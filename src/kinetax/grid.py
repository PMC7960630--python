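"""Uniform cell-centered meshes in 1D Cartesian and axisymmetric geometry."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["Grid"]

Geometry = Literal["cartesian1d", "axisymmetric"]


@dataclass(frozen=True)
class Grid:
    """Uniform finite-volume mesh.

    Cells are the half-open intervals ``[x_min + i*dx, x_min + (i+1)*dx)``;
    unknowns live at cell centers, fluxes at the ``n_cells + 1`` faces.  In
    axisymmetric geometry the coordinate is the radius, ``x_min`` must be 0,
    and the cell volume weight is ``2*pi*R_i*dx`` with ``R_i`` the cell
    center (the face flux at R=0 vanishes identically, so the on-axis
    curvature singularity never enters).
    """

    geometry: Geometry
    x_min: float
    x_max: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.geometry not in ("cartesian1d", "axisymmetric"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.geometry == "axisymmetric" and self.x_min != 0.0:
            raise ValueError("axisymmetric grids must start at R=0")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.n_cells

    @property
    def face_positions(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.n_cells + 1)

    @property
    def cell_centers(self) -> np.ndarray:
        return self.x_min + self.dx * (np.arange(self.n_cells) + 0.5)

    @property
    def cell_volumes(self) -> np.ndarray:
        """Volume weight of each cell (length, or annulus area ``2*pi*R*dx``)."""
        if self.geometry == "cartesian1d":
            return np.full(self.n_cells, self.dx)
        return 2.0 * np.pi * self.cell_centers * self.dx

    def with_resolution(self, n_cells: int) -> "Grid":
        return Grid(self.geometry, self.x_min, self.x_max, n_cells)
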