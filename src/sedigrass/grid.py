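"""Co-registered raster stack describing a bay.

All layers are 2-D numpy arrays on the same grid.  Depth is metres, positive
down; land cells carry NaN in every float layer and False in the water mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BayGrid:
    """Static environmental layers for one bay.

    Attributes
    ----------
    depth : water depth (m, positive down); NaN on land.
    water_mask : True where the cell is water.
    hs : 90th-percentile significant wave height (m); NaN on land.
    cell_size : cell edge length (m).
    d_river : least-cost over-water distance (m) to the nearest river mouth.
    d_ocean : least-cost over-water distance (m) to the open ocean
        (cells at or beyond the deep-water cutoff).
    river_mouths : (row, col) cells acting as turbid-water sources.
    """

    depth: np.ndarray
    water_mask: np.ndarray
    hs: np.ndarray
    cell_size: float = 100.0
    d_river: np.ndarray | None = None
    d_ocean: np.ndarray | None = None
    river_mouths: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        self.depth = np.asarray(self.depth, dtype=float)
        self.hs = np.asarray(self.hs, dtype=float)
        if self.depth.shape != self.water_mask.shape or self.hs.shape != self.water_mask.shape:
            raise ValueError("depth, water_mask and hs must share one shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if np.any(self.hs[self.water_mask] < 0):
            raise ValueError("significant wave height must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.water_mask.shape

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares (1 ha for the default 100 m cells)."""
        return self.cell_size**2 / 1e4

    def require_distances(self) -> None:
        if self.d_river is None or self.d_ocean is None:
            raise ValueError(
                "distance layers not computed; run sedigrass.distance.add_distances first"
            )
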