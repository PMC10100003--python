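"""Grid geometry shared by the fine (Landsat-like) and coarse (L-VOD-like) lattices.

The package works on an abstract, perfectly nested pair of grids: each coarse
cell (nominally 0.25 degrees, the footprint of an L-VOD grid cell) is subdivided
into ``fine_per_coarse`` x ``fine_per_coarse`` fine pixels (nominally 30 m, the
resolution of annual land-cover maps).  No real CRS is required; rasters carry a
simple affine transform so that georeferenced data can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a scene: coarse-cell layout and fine subdivision.

    Parameters
    ----------
    nx, ny:
        Number of coarse cells along x (columns) and y (rows).
    fine_per_coarse:
        Fine pixels per coarse-cell edge (>= 4).
    pixel_edge_m:
        Fine-pixel edge length in metres (default 30 m analog).
    cell_deg:
        Angular size of a coarse cell, used only to convert the
        degree-radius parameters of the circular median filters into
        cell units (default 0.25 degrees).
    origin_deg:
        (x0, y0) of the upper-left corner in degree units.
    """

    nx: int
    ny: int
    fine_per_coarse: int
    pixel_edge_m: float = 30.0
    cell_deg: float = 0.25
    origin_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("zero-area scene: nx and ny must be >= 1")
        if self.fine_per_coarse < 4:
            raise ValueError("fine_per_coarse must be >= 4")

    # ------------------------------------------------------------------ sizes
    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def fine_shape(self) -> tuple[int, int]:
        """(rows, cols) of the fine raster."""
        return (self.ny * self.fine_per_coarse, self.nx * self.fine_per_coarse)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_edge_m**2 / 1e4

    @property
    def cell_area_ha(self) -> float:
        """Coarse-cell area as the exact sum of its fine-pixel areas."""
        return self.fine_per_coarse**2 * self.pixel_area_ha

    @property
    def total_area_ha(self) -> float:
        return self.n_cells * self.cell_area_ha

    # ----------------------------------------------------------- georeference
    @property
    def affine(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style affine of the fine raster (x0, dx, 0, y0, 0, -dy)."""
        dx = self.cell_deg / self.fine_per_coarse
        x0, y0 = self.origin_deg
        return (x0, dx, 0.0, y0, 0.0, -dx)

    def cell_centers_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """Coarse-cell center coordinates, each shaped (ny, nx)."""
        x0, y0 = self.origin_deg
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_deg
        ys = y0 - (np.arange(self.ny) + 0.5) * self.cell_deg
        return np.meshgrid(xs, ys)

    # ------------------------------------------------------------- indexing
    def cell_ids(self) -> np.ndarray:
        """Row-major coarse-cell ids, shaped (ny, nx)."""
        return np.arange(self.n_cells).reshape(self.ny, self.nx)

    def coarsen_sum(self, fine: np.ndarray) -> np.ndarray:
        """Sum a fine raster into coarse cells -> (ny, nx)."""
        f = self.fine_per_coarse
        return np.asarray(fine, dtype=float).reshape(self.ny, f, self.nx, f).sum(axis=(1, 3))

    def coarsen_mean(self, fine: np.ndarray) -> np.ndarray:
        return self.coarsen_sum(fine) / self.fine_per_coarse**2

    def cell_distance_deg(self) -> np.ndarray:
        """Pairwise center distances between coarse cells, (n_cells, n_cells)."""
        cx, cy = self.cell_centers_deg()
        pts = np.column_stack([cx.ravel(), cy.ravel()])
        d = pts[:, None, :] - pts[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])
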