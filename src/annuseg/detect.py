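"""Detection phase: probability fusion, contour extraction, measurement.

The two resolution models each emit a probability map; the coarse (1.0 mm)
map is bilinearly resampled onto the fine (0.5 mm) grid and the two are
averaged into one fused map.  The annulus contour is located on the fused
map with canny edge detection: edge pixels are grouped into connected
components, components that close into a loop are identified by hole
filling, and the loop enclosing the greatest area is kept.  Its edge-pixel
centres, ordered counterclockwise around the enclosed region's centroid,
form the contour polygon; a short periodic moving average of the radius
suppresses the one-pixel digitisation staircase that would otherwise
inflate the perimeter.  Area (shoelace) and perimeter (closed polyline
length) derived from this contour are the method's final output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_closing, binary_fill_holes, label
from skimage.feature import canny

from .core import (
    AnnularPlane,
    AnnulusContour,
    Measurement,
    NoAnnulusDetectedError,
    OpenContourError,
    ProbabilityMap,
    StageError,
    ValidationError,
)
from .model import TrainedModel, predict
from .preprocess import PreparedSample, prepare_sample

__all__ = [
    "fuse_probability_maps",
    "extract_contour",
    "measure_contour",
    "detect",
    "DetectionResult",
    "CannyParams",
]


@dataclass(frozen=True)
class CannyParams:
    """Edge-detector settings on the gradient-magnitude scale of a [0,1] map."""

    sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2


def fuse_probability_maps(
    coarse: ProbabilityMap, fine: ProbabilityMap, mode: str = "mean"
) -> ProbabilityMap:
    """Combine the two models' outputs into one map on the fine grid.

    The coarse map is bilinearly resampled onto the fine pixel centres over
    the shared extent; the fused value is the arithmetic mean of the two,
    clamped to [0, 1].  ``mode="minmax"`` rescales each map to its own
    [min, max] range before averaging (an alternative reading of output
    normalisation); ``"mean"`` is the default.  The maps must be concentric
    (shared annulus-centre alignment) to within one coarse pixel.
    """
    if mode not in ("mean", "minmax"):
        raise ValidationError(f"unknown fusion mode {mode!r}")
    cc = (
        coarse.origin[0] + (coarse.shape[1] - 1) / 2.0 * coarse.spacing[1],
        coarse.origin[1] + (coarse.shape[0] - 1) / 2.0 * coarse.spacing[0],
    )
    cf = (
        fine.origin[0] + (fine.shape[1] - 1) / 2.0 * fine.spacing[1],
        fine.origin[1] + (fine.shape[0] - 1) / 2.0 * fine.spacing[0],
    )
    tol = max(coarse.spacing)
    if abs(cc[0] - cf[0]) > tol or abs(cc[1] - cf[1]) > tol:
        raise ValidationError(
            f"probability grids are not concentric: coarse centre {cc}, fine centre {cf}"
        )

    interp = RegularGridInterpolator(
        (coarse.y_coords(), coarse.x_coords()),
        coarse.values,
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    xx, yy = np.meshgrid(fine.x_coords(), fine.y_coords())
    coarse_on_fine = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(fine.shape)

    a, b = coarse_on_fine, np.asarray(fine.values)
    if mode == "minmax":
        def rescale(v):
            lo, hi = float(v.min()), float(v.max())
            return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        a, b = rescale(a), rescale(b)
    fused = np.clip(0.5 * (a + b), 0.0, 1.0)
    return ProbabilityMap(values=fused, spacing=fine.spacing, origin=fine.origin)


_SMOOTH_WINDOW = 5  # vertices; periodic radius smoothing of the pixel staircase


def _loop_to_contour(component: np.ndarray, region: np.ndarray, grid: ProbabilityMap) -> AnnulusContour:
    """Order a closed edge-pixel loop into a CCW polygon in mm."""
    ii, jj = np.nonzero(component)
    x = grid.origin[0] + jj * grid.spacing[1]
    y = grid.origin[1] + ii * grid.spacing[0]
    ri, rj = np.nonzero(region)
    cx = grid.origin[0] + rj.mean() * grid.spacing[1]
    cy = grid.origin[1] + ri.mean() * grid.spacing[0]

    theta = np.arctan2(y - cy, x - cx)
    order = np.argsort(theta, kind="stable")
    theta = theta[order]
    radius = np.hypot(x[order] - cx, y[order] - cy)

    w = min(_SMOOTH_WINDOW, len(radius))
    if w >= 3:
        kernel = np.ones(w) / w
        wrapped = np.concatenate([radius[-w:], radius, radius[:w]])
        radius = np.convolve(wrapped, kernel, mode="same")[w:-w]

    verts = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    # drop duplicate angles collapsed to identical points
    keep = np.ones(len(verts), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(verts, axis=0)) > 1e-12, axis=1)
    return AnnulusContour(verts[keep]).counterclockwise()


def extract_contour(prob: ProbabilityMap, params: CannyParams = CannyParams()) -> AnnulusContour:
    """Locate the annulus contour on a probability map via canny edges.

    Raises :class:`NoAnnulusDetectedError` when no probability reaches 0.5
    and :class:`OpenContourError` when no edge component closes into a loop.
    """
    values = np.asarray(prob.values, dtype=np.float64)
    if float(values.max()) < 0.5:
        raise NoAnnulusDetectedError(
            f"no annulus detected: max probability {values.max():.3f} < 0.5"
        )
    edges = canny(
        values,
        sigma=params.sigma,
        low_threshold=params.low_threshold,
        high_threshold=params.high_threshold,
    )
    if not edges.any():
        raise OpenContourError("canny produced no edge pixels")

    def largest_loop(edge_map):
        labels, n_comp = label(edge_map, structure=np.ones((3, 3), dtype=bool))
        best_area = 0
        best = None
        for k in range(1, n_comp + 1):
            component = labels == k
            filled = binary_fill_holes(component)
            n_enclosed = int((filled & ~component).sum())
            if n_enclosed > best_area:
                best_area = n_enclosed
                best = (component, filled)
        return best, best_area

    best, enclosed = largest_loop(edges)
    # if the ridge did not close around the detected region, link
    # nearly-touching edge pixels by closing one-pixel gaps and retry
    n_region = int((values >= 0.5).sum())
    if best is None or enclosed < 0.25 * n_region:
        linked, linked_area = largest_loop(
            binary_closing(edges, structure=np.ones((3, 3), dtype=bool))
        )
        if linked is not None and linked_area > enclosed:
            best = linked
    if best is None:
        raise OpenContourError("no edge component closes into a loop")
    return _loop_to_contour(best[0], best[1], prob)


def measure_contour(contour: AnnulusContour) -> Measurement:
    """Shoelace area and closed-polyline perimeter of a contour, in mm units."""
    contour.validate_simple()
    area = contour.area()
    if area <= 0:
        raise ValidationError("degenerate zero-area contour")
    return Measurement(area=area, perimeter=contour.perimeter())


@dataclass
class DetectionResult:
    """End-to-end detection output with every intermediate kept for audit."""

    prepared: PreparedSample
    prob_coarse: ProbabilityMap
    prob_fine: ProbabilityMap
    fused: ProbabilityMap
    contour: AnnulusContour
    measurement: Measurement


def detect(
    plane: AnnularPlane,
    model_1mm: TrainedModel,
    model_05mm: TrainedModel,
    canny_params: CannyParams = CannyParams(),
    fusion_mode: str = "mean",
) -> DetectionResult:
    """Run the full detection pipeline on one raw annular plane.

    Composes resample/clip preparation, both models' inference, probability
    fusion, contour extraction and measurement; deterministic for fixed
    weights.  Any failure is re-raised as a :class:`StageError` naming the
    stage.
    """
    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    prepared = _stage("prepare", lambda: prepare_sample(plane))
    prob_c = _stage("predict_1mm", lambda: predict(model_1mm, prepared.plane_1mm))
    prob_f = _stage("predict_05mm", lambda: predict(model_05mm, prepared.plane_05mm))
    fused = _stage("fuse", lambda: fuse_probability_maps(prob_c, prob_f, mode=fusion_mode))
    contour = _stage("extract_contour", lambda: extract_contour(fused, canny_params))
    measurement = _stage("measure", lambda: measure_contour(contour))
    return DetectionResult(prepared, prob_c, prob_f, fused, contour, measurement)
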