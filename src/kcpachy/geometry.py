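"""Pixel-grid geometry shared by the whole pipeline.

The AS-OCT B-scans modelled here are 2-D grids with a lateral (column) pitch and
an axial (row) pitch, both in micrometres per pixel.  The default grid is
2648 x 640 pixels covering 8 mm laterally and 1.933 mm axially, which makes the
pixels nearly isotropic at ~3 um.

Coordinate conventions (used everywhere downstream):

* 0-based pixel indices; pixel *centres* sit at integer indices.
* x grows to the right (column direction), y grows *downward*, i.e. into tissue.
* Physical coordinates are pixel index times pitch, in um.
* Boundaries live on pixel edges, i.e. half-integer rows, so an n-pixel tissue
  band is exactly n * pitch_v thick.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

# Default field of view: 8 mm wide, 1.933 mm deep.
DEFAULT_WIDTH_PX = 2648
DEFAULT_HEIGHT_PX = 640
DEFAULT_WIDTH_UM = 8000.0
DEFAULT_DEPTH_UM = 1933.0


@dataclass(frozen=True)
class ImageGeometry:
    """Grid dimensions and physical pixel pitch of a B-scan.

    Parameters
    ----------
    width_px, height_px
        Grid size in pixels (columns, rows).
    pitch_h, pitch_v
        Lateral and axial pixel pitch in um/pixel.
    """

    width_px: int = DEFAULT_WIDTH_PX
    height_px: int = DEFAULT_HEIGHT_PX
    pitch_h: float = DEFAULT_WIDTH_UM / DEFAULT_WIDTH_PX
    pitch_v: float = DEFAULT_DEPTH_UM / DEFAULT_HEIGHT_PX

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_h <= 0 or self.pitch_v <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pitch_h

    @property
    def height_um(self) -> float:
        return self.height_px * self.pitch_v

    def column_x_um(self, col: np.ndarray | float) -> np.ndarray | float:
        """Physical x (um) of pixel-centre column indices."""
        return np.asarray(col, dtype=float) * self.pitch_h

    def row_y_um(self, row: np.ndarray | float) -> np.ndarray | float:
        """Physical y (um) of pixel-centre row indices."""
        return np.asarray(row, dtype=float) * self.pitch_v

    @property
    def center_x_um(self) -> float:
        """x of the central column (pixel-centre convention)."""
        return (self.width_px - 1) / 2.0 * self.pitch_h


class StageLabel(IntEnum):
    """Keratoconus stage group, ordered by severity.

    The ordinal coding (0..4) is what the zone-trend regression uses.
    """

    normal = 0
    mild = 1
    moderate = 2
    severe = 3
    scarring = 4

    @classmethod
    def from_name(cls, name: "str | StageLabel") -> "StageLabel":
        if isinstance(name, cls):
            return name
        try:
            return cls[str(name)]
        except KeyError:
            raise ValueError(
                f"unknown stage {name!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


STAGES: tuple[StageLabel, ...] = tuple(StageLabel)
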