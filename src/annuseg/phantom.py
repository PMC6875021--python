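"""Synthetic contrast-CT annular-plane phantoms with analytic ground truth.

Each phantom emulates the appearance of a contrast-enhanced CT cross-section
through the aortic annulus: a bright elliptical blood pool (the lumen), a
darker vessel-wall ring around it, soft-tissue background, optional
calcification blobs sitting on the lumen rim, and additive Gaussian noise.
The lumen boundary is known analytically, so every phantom carries an exact
ground-truth contour, area and perimeter for parameter-recovery experiments.

A pixel's noise-free value is decided by the analytic region its *centre*
falls in; noise is added afterwards.  Identical ``(spec, seed)`` pairs give
bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
import math

import numpy as np
from scipy.special import ellipe

from .core import AnnularPlane, AnnulusContour, ValidationError

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "ellipse_perimeter",
    "ellipse_contour",
    "DEFAULT_COHORT_RANGES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic annular plane.

    Lengths are mm, intensities Hounsfield units.  ``rotation`` is the
    angle of the ellipse major axis in radians, ``center_offset`` the
    annulus-centre displacement from the image centre.
    """

    semi_axis_a: float = 11.5
    semi_axis_b: float = 9.5
    rotation: float = 0.0
    center_offset: tuple[float, float] = (0.0, 0.0)
    lumen_hu: float = 400.0
    background_hu: float = 40.0
    wall_hu: float = 120.0
    wall_thickness: float = 2.0
    n_calcifications: int = 0
    calcification_hu: float = 900.0
    noise_sd: float = 20.0
    field_of_view: float = 100.0
    native_spacing: float = 0.7

    def validate(self) -> None:
        if not (self.semi_axis_a >= self.semi_axis_b > 0):
            raise ValidationError(
                "invariant semi_axis_a >= semi_axis_b > 0 violated: "
                f"a={self.semi_axis_a}, b={self.semi_axis_b}"
            )
        if self.wall_thickness < 0:
            raise ValidationError(f"invariant wall_thickness >= 0 violated: {self.wall_thickness}")
        if self.noise_sd < 0:
            raise ValidationError(f"invariant noise_sd >= 0 violated: {self.noise_sd}")
        if not self.field_of_view > 2 * self.semi_axis_a:
            raise ValidationError(
                "invariant field_of_view > 2*semi_axis_a violated: "
                f"fov={self.field_of_view}, a={self.semi_axis_a}"
            )
        if self.native_spacing <= 0:
            raise ValidationError(f"invariant native_spacing > 0 violated: {self.native_spacing}")
        if self.n_calcifications < 0:
            raise ValidationError(f"n_calcifications must be >= 0: {self.n_calcifications}")


@dataclass(frozen=True)
class PhantomSample:
    """A generated plane plus its exact analytic ground truth."""

    plane: AnnularPlane
    truth_contour: AnnulusContour
    truth_area: float
    truth_perimeter: float
    spec: PhantomSpec
    seed: int


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse circumference 4*a*E(e^2) via the complete elliptic integral."""
    if not a >= b > 0:
        raise ValidationError(f"need a >= b > 0, got a={a}, b={b}")
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(m))


def ellipse_contour(
    a: float,
    b: float,
    rotation: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    n_vertices: int = 720,
) -> AnnulusContour:
    """Counterclockwise polygonal sampling of an ellipse boundary."""
    if n_vertices < 3:
        raise ValidationError("n_vertices must be >= 3")
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = math.cos(rotation), math.sin(rotation)
    xr = c * x - s * y + center[0]
    yr = s * x + c * y + center[1]
    return AnnulusContour(np.column_stack([xr, yr]))


def _ellipse_interior(xx, yy, a, b, rotation, center):
    """Boolean mask of points with normalised elliptic radius < 1."""
    dx = xx - center[0]
    dy = yy - center[1]
    c, s = math.cos(rotation), math.sin(rotation)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / a) ** 2 + (v / b) ** 2 < 1.0


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomSample:
    """Render one synthetic annular plane.

    The raster is painted background -> wall ring -> lumen -> calcification
    blobs, then i.i.d. Gaussian noise of ``spec.noise_sd`` HU is added.
    Calcifications are discs of 1-3 mm radius centred on the lumen boundary,
    mimicking rim calcium; the ground-truth contour remains the analytic
    lumen ellipse.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    n = int(round(spec.field_of_view / spec.native_spacing))
    half = (n - 1) / 2.0 * spec.native_spacing
    origin = (-half, -half)  # image centre at (0, 0) mm
    plane_vals = np.full((n, n), spec.background_hu, dtype=np.float64)

    xs = origin[0] + np.arange(n) * spec.native_spacing
    ys = origin[1] + np.arange(n) * spec.native_spacing
    xx, yy = np.meshgrid(xs, ys)

    cx, cy = spec.center_offset
    a, b, rot = spec.semi_axis_a, spec.semi_axis_b, spec.rotation
    wall = _ellipse_interior(
        xx, yy, a + spec.wall_thickness, b + spec.wall_thickness, rot, (cx, cy)
    )
    plane_vals[wall] = spec.wall_hu
    lumen = _ellipse_interior(xx, yy, a, b, rot, (cx, cy))
    plane_vals[lumen] = spec.lumen_hu

    for _ in range(spec.n_calcifications):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        radius = rng.uniform(1.0, 3.0)
        # point on the lumen boundary ellipse
        px = a * math.cos(theta)
        py = b * math.sin(theta)
        c, s = math.cos(rot), math.sin(rot)
        bx = c * px - s * py + cx
        by = s * px + c * py + cy
        blob = (xx - bx) ** 2 + (yy - by) ** 2 < radius**2
        plane_vals[blob] = spec.calcification_hu

    if spec.noise_sd > 0:
        plane_vals += rng.normal(0.0, spec.noise_sd, size=plane_vals.shape)

    plane = AnnularPlane(
        values=plane_vals,
        spacing=(spec.native_spacing, spec.native_spacing),
        origin=origin,
        annulus_center=(cx, cy),
    )
    return PhantomSample(
        plane=plane,
        truth_contour=ellipse_contour(a, b, rot, (cx, cy)),
        truth_area=math.pi * a * b,
        truth_perimeter=ellipse_perimeter(a, b),
        spec=spec,
        seed=int(seed),
    )


#: Study conditions for cohort generation: uniform ranges per spec field.
#: Geometry spans clinically plausible annuli (area ~200-530 mm^2,
#: perimeter ~51-82 mm); intensities span typical contrast-CT appearance.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "semi_axis_a": (9.0, 14.0),
    "semi_axis_b": (7.0, 12.0),
    "rotation": (0.0, math.pi),
    "center_offset_x": (-3.0, 3.0),
    "center_offset_y": (-3.0, 3.0),
    "lumen_hu": (350.0, 500.0),
    "background_hu": (0.0, 80.0),
    "wall_hu": (80.0, 160.0),
    "wall_thickness": (1.5, 3.0),
    "n_calcifications": (0, 3),
    "calcification_hu": (700.0, 1100.0),
    "noise_sd": (10.0, 30.0),
    "field_of_view": (90.0, 110.0),
    "native_spacing": (0.6, 0.9),
}


def generate_cohort(
    n: int,
    spec_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[list[PhantomSample], list[PhantomSpec]]:
    """Draw ``n`` phantoms with spec fields sampled uniformly from ranges.

    ``spec_ranges`` overrides entries of :data:`DEFAULT_COHORT_RANGES`.
    If the drawn semi-axes come out with b > a they are swapped, keeping the
    major/minor invariant while sampling both ranges independently.
    Returns the samples and the drawn specs (for audit); deterministic under
    a fixed seed.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if spec_ranges:
        unknown = set(spec_ranges) - set(ranges)
        if unknown:
            raise ValidationError(f"unknown spec range fields: {sorted(unknown)}")
        ranges.update(spec_ranges)
    for name, (lo, hi) in ranges.items():
        if not hi >= lo:
            raise ValidationError(f"empty range for {name}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    specs: list[PhantomSpec] = []
    for _ in range(n):
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        a, b = draw["semi_axis_a"], draw["semi_axis_b"]
        if b > a:
            a, b = b, a
        spec = PhantomSpec(
            semi_axis_a=a,
            semi_axis_b=b,
            rotation=draw["rotation"],
            center_offset=(draw["center_offset_x"], draw["center_offset_y"]),
            lumen_hu=draw["lumen_hu"],
            background_hu=draw["background_hu"],
            wall_hu=draw["wall_hu"],
            wall_thickness=draw["wall_thickness"],
            n_calcifications=int(
                rng.integers(
                    int(ranges["n_calcifications"][0]),
                    int(ranges["n_calcifications"][1]) + 1,
                )
            ),
            calcification_hu=draw["calcification_hu"],
            noise_sd=draw["noise_sd"],
            field_of_view=draw["field_of_view"],
            native_spacing=draw["native_spacing"],
        )
        sample_seed = int(rng.integers(0, 2**31 - 1))
        samples.append(generate_phantom(spec, sample_seed))
        specs.append(spec)
    return samples, specs
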