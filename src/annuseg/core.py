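"""Core data structures shared across the annulus-sizing pipeline.

Coordinate convention
---------------------
Raster values are stored row-major: ``values[i, j]`` with ``i`` the row
(y direction) and ``j`` the column (x direction).  Continuous positions are
always (x, y) pairs in millimetres.  The centre of pixel ``(i, j)`` sits at

    x = origin[0] + j * spacing[1]
    y = origin[1] + i * spacing[0]

``spacing`` is stored in row-major order ``(sy, sx)``; a grid is isotropic
when the two entries are equal.  Contour vertices, origins and annulus
centres are (x_mm, y_mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import shapely

__all__ = [
    "AnnularPlane",
    "BinaryMask",
    "ProbabilityMap",
    "AnnulusContour",
    "Measurement",
    "ValidationError",
    "NoAnnulusDetectedError",
    "OpenContourError",
    "StageError",
]


class ValidationError(ValueError):
    """An input object violates one of its documented invariants."""


class NoAnnulusDetectedError(RuntimeError):
    """The probability map contains no region above the detection threshold."""


class OpenContourError(RuntimeError):
    """Edge detection produced no closable loop around a candidate region."""


class StageError(RuntimeError):
    """Wraps a failure inside the end-to-end pipeline with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _as_pair(value, name: str) -> tuple[float, float]:
    try:
        a, b = (float(value[0]), float(value[1]))
    except (TypeError, IndexError) as exc:  # pragma: no cover - defensive
        raise ValidationError(f"{name} must be a pair of floats") from exc
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return (a, b)


@dataclass
class AnnularPlane:
    """A 2-D cross-section through the aortic annulus in Hounsfield units.

    Parameters
    ----------
    values : ndarray
        2-D HU raster.
    spacing : (float, float)
        Pixel spacing in mm, row-major ``(sy, sx)``.
    origin : (float, float)
        (x, y) mm position of the centre of pixel ``(0, 0)``.
    annulus_center : (float, float)
        (x, y) mm position of the annulus centre; supplied by the
        plane-extraction step (or exactly known for phantoms).
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    annulus_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("plane raster must be a non-empty 2-D array")
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing), float(self.spacing))
        else:
            self.spacing = _as_pair(self.spacing, "spacing")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError(f"spacing must be > 0, got {self.spacing}")
        self.origin = _as_pair(self.origin, "origin")
        self.annulus_center = _as_pair(self.annulus_center, "annulus_center")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        return math.isclose(self.spacing[0], self.spacing[1], rel_tol=1e-9)

    def x_coords(self) -> np.ndarray:
        """x (mm) of every column's pixel centres."""
        return self.origin[0] + np.arange(self.shape[1]) * self.spacing[1]

    def y_coords(self) -> np.ndarray:
        """y (mm) of every row's pixel centres."""
        return self.origin[1] + np.arange(self.shape[0]) * self.spacing[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-centre (x, y) coordinates, each of `shape`."""
        xx, yy = np.meshgrid(self.x_coords(), self.y_coords())
        return xx, yy


@dataclass
class BinaryMask:
    """Boolean raster aligned with an :class:`AnnularPlane` grid."""

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("mask raster must be a non-empty 2-D array")
        if self.values.dtype != bool:
            self.values = self.values.astype(bool)
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing), float(self.spacing))
        else:
            self.spacing = _as_pair(self.spacing, "spacing")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError(f"spacing must be > 0, got {self.spacing}")
        self.origin = _as_pair(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def area_mm2(self) -> float:
        """Pixel-counting area: true-pixel count times the pixel area."""
        return float(self.values.sum()) * self.spacing[0] * self.spacing[1]


@dataclass
class ProbabilityMap:
    """Raster of per-pixel annulus probabilities in [0, 1]."""

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("probability raster must be a non-empty 2-D array")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValidationError(
                f"probability values must lie in [0, 1]; observed [{lo}, {hi}]"
            )
        np.clip(self.values, 0.0, 1.0, out=self.values)
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing), float(self.spacing))
        else:
            self.spacing = _as_pair(self.spacing, "spacing")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError(f"spacing must be > 0, got {self.spacing}")
        self.origin = _as_pair(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[1]) * self.spacing[1]

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[0]) * self.spacing[0]


@dataclass
class AnnulusContour:
    """Ordered, closed, simple polygon outlining the annulus in mm.

    ``vertices`` is an (N, 2) array of (x_mm, y_mm); closure is implicit
    (the first vertex is not repeated at the end).
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an (N, 2) array")
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValidationError("contour needs at least 3 distinct vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour vertices must be finite")
        self.vertices = v

    def validate_simple(self) -> None:
        """Raise if the polygon self-intersects (shapely validity check)."""
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise ValidationError("contour polygon is self-intersecting or degenerate")

    def signed_area(self) -> float:
        """Shoelace signed area; positive for counterclockwise ordering."""
        x = self.vertices[:, 0]
        y = self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def counterclockwise(self) -> "AnnulusContour":
        if self.signed_area() < 0:
            return AnnulusContour(self.vertices[::-1].copy())
        return self

    def centroid(self) -> tuple[float, float]:
        c = shapely.Polygon(self.vertices).centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class Measurement:
    """Final annulus measurement: area (mm^2) and perimeter (mm)."""

    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.perimeter > 0):
            raise ValidationError(
                f"area and perimeter must be positive, got {self.area}, {self.perimeter}"
            )
        # Isoperimetric sanity: no closed curve can beat the circle.  The
        # 0.5% slack admits near-circular measurements quoted at 0.1 mm
        # precision while still flagging pathological contours.
        if self.perimeter**2 < 4 * math.pi * self.area * (1 - 5e-3):
            raise ValidationError(
                "isoperimetric inequality violated: "
                f"P^2={self.perimeter**2:.3f} < 4*pi*A={4 * math.pi * self.area:.3f}"
            )
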