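"""Raster grid geometry for the synthetic equal-area plane.

All rasters in the package share a simple axis-aligned grid on an abstract
equal-area Cartesian plane (declared CRS metadata ``"synthetic, unit = km"``).
Row 0 is the top of the map; cell centres are offset half a cell from the
edges, matching the usual north-up raster convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYNTHETIC_CRS = "synthetic, unit = km"


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: shape, cell size and placement on the plane.

    Parameters
    ----------
    shape:
        (rows, cols) of the raster.
    cell_size:
        Edge length of a (square) cell in plane units (km).
    x0:
        x coordinate of the left edge.
    y_top:
        y coordinate of the top edge. Defaults to ``rows * cell_size`` so the
        bottom edge sits at y = 0.
    crs:
        Free-text CRS declaration carried through file metadata.
    """

    shape: tuple[int, int]
    cell_size: float = 1.0
    x0: float = 0.0
    y_top: float | None = None
    crs: str = SYNTHETIC_CRS

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.y_top is None:
            object.__setattr__(self, "y_top", rows * self.cell_size)

    @property
    def rows(self) -> int:
        return self.shape[0]

    @property
    def cols(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.x0,
            self.y_top - self.rows * self.cell_size,
            self.x0 + self.cols * self.cell_size,
            self.y_top,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of shape ``shape`` with every cell centre."""
        cs = self.cell_size
        x = self.x0 + (np.arange(self.cols) + 0.5) * cs
        y = self.y_top - (np.arange(self.rows) + 0.5) * cs
        return np.meshgrid(x, y)

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "cell_size": self.cell_size,
            "x0": self.x0,
            "y_top": self.y_top,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(
            shape=tuple(d["shape"]),
            cell_size=float(d["cell_size"]),
            x0=float(d["x0"]),
            y_top=float(d["y_top"]),
            crs=d.get("crs", SYNTHETIC_CRS),
        )
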