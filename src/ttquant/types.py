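"""Core domain containers shared across the pipeline.

All rasters are numpy arrays indexed ``(channel, z, y, x)`` for image data and
``(z, y, x)`` (or ``(y, x)`` for single planes) for masks.  Physical voxel
sizes are carried explicitly in micrometres; nothing downstream ever guesses
physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


class TTQuantError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TTQuantError):
    """Invalid input data or parameters."""


@dataclass
class ImageVolume:
    """Multi-channel image stack with physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (channel, z, y, x)
        Intensity raster.  2D images have depth 1.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` in micrometres per pixel.
    bit_depth : int
        Integer depth of the source data (8 or 16 for typical TIFFs).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(
                f"image data must be (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValidationError("all image dimensions must be >= 1")
        dx, dy, dz = self.voxel_size
        if not (dx > 0 and dy > 0 and dz > 0):
            raise ValidationError(f"voxel size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)) or np.any(np.asarray(self.data) < 0):
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def depth(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, c: int) -> np.ndarray:
        """Return one channel as a (z, y, x) stack."""
        return self.data[c]


@dataclass
class CellAnnotation:
    """Manual per-cell annotation: long-axis endpoints and a rough outline.

    Coordinates are 0-based ``(y, x)`` pixel indices; polygon vertices sit at
    pixel centres.  This replaces interactive tracing with a reproducible,
    scriptable sidecar file.
    """

    cell_id: str
    axis: np.ndarray  # (2, 2) array of (y, x)
    outline: np.ndarray  # (n, 2) array of (y, x), closed implicitly

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.outline = np.asarray(self.outline, dtype=float)
        if self.axis.shape != (2, 2):
            raise ValidationError(f"axis must be two (y, x) points for {self.cell_id}")
        if np.allclose(self.axis[0], self.axis[1]):
            raise ValidationError(f"axis endpoints identical for cell {self.cell_id}")
        if self.outline.ndim != 2 or self.outline.shape[0] < 3 or self.outline.shape[1] != 2:
            raise ValidationError(
                f"outline must have >= 3 (y, x) points for cell {self.cell_id}"
            )
        poly = Polygon([(x, y) for y, x in self.outline])
        if not poly.is_valid:
            raise ValidationError(f"outline polygon self-intersects for cell {self.cell_id}")
        if poly.area <= 0:
            raise ValidationError(f"outline polygon has zero area for cell {self.cell_id}")


@dataclass
class MetricsReport:
    """Per-cell quantification summary written to the metrics table."""

    cell_id: str
    mode: str  # "2D" or "3D"
    density_raw: float
    density_skeleton: float
    fraction_transverse: float
    fraction_longitudinal: float
    fraction_ambiguous: float
    distance_mean: float
    distance_median: float
    distance_max: float
    distance_sd: float
    flags: str = ""
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        fracs = (
            self.density_raw,
            self.density_skeleton,
            self.fraction_transverse,
            self.fraction_longitudinal,
            self.fraction_ambiguous,
        )
        for f in fracs:
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"fraction out of [0, 1] for cell {self.cell_id}: {f}")
        if self.fraction_transverse + self.fraction_longitudinal > 1.0 + 1e-9:
            raise ValidationError(f"orientation fractions exceed 1 for {self.cell_id}")
        stats = (self.distance_mean, self.distance_median, self.distance_max, self.distance_sd)
        if any(s < 0 for s in stats):
            raise ValidationError(f"negative distance statistic for {self.cell_id}")
        if self.distance_median > self.distance_max + 1e-12:
            raise ValidationError(f"median exceeds max distance for {self.cell_id}")
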