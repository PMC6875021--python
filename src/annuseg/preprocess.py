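"""Preparation of network-ready inputs from raw annular planes.

The pipeline feeds each plane to two segmentation models, one per
resolution: the plane is resampled to isotropic 1.0 mm and 0.5 mm grids by
separable cubic-spline interpolation (preserving Hounsfield units), then a
128 x 128 window is clipped around the annulus centre at each resolution.
The 0.5 mm window therefore covers the central 64 x 64 mm of the 1.0 mm
window's 128 x 128 mm field of view, doubling the segmentation detail where
the annulus lives.  Ground-truth contours are rasterised to binary masks on
the same grids for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.interpolate import RectBivariateSpline

from .core import AnnularPlane, AnnulusContour, BinaryMask, ValidationError

__all__ = [
    "resample_plane",
    "clip_plane",
    "rasterize_mask",
    "prepare_sample",
    "PreparedSample",
    "PAD_HU",
    "WINDOW_PX",
]

#: Fill value for clipped regions outside the source extent (air).
PAD_HU = -1024.0
#: Side length of the network input window, pixels.
WINDOW_PX = 128


def resample_plane(plane: AnnularPlane, target_spacing: float) -> AnnularPlane:
    """Resample a plane onto an isotropic grid at ``target_spacing`` mm.

    Uses a separable bicubic spline on the source grid, which retains the
    original Hounsfield units (exact on constants and affine ramps).  The
    output grid covers the source extent without extrapolating beyond it;
    origin and annulus centre are preserved in mm coordinates.
    """
    if not target_spacing > 0:
        raise ValidationError(f"target_spacing must be > 0, got {target_spacing}")
    if plane.shape[0] < 4 or plane.shape[1] < 4:
        raise ValidationError(
            f"raster {plane.shape} too small for cubic-spline resampling (need >= 4x4)"
        )
    ys, xs = plane.y_coords(), plane.x_coords()
    spline = RectBivariateSpline(ys, xs, np.asarray(plane.values, dtype=np.float64), kx=3, ky=3)

    ny = int(np.floor((ys[-1] - ys[0]) / target_spacing)) + 1
    nx = int(np.floor((xs[-1] - xs[0]) / target_spacing)) + 1
    new_y = ys[0] + np.arange(ny) * target_spacing
    new_x = xs[0] + np.arange(nx) * target_spacing
    values = spline(new_y, new_x)
    return AnnularPlane(
        values=values,
        spacing=(target_spacing, target_spacing),
        origin=(float(new_x[0]), float(new_y[0])),
        annulus_center=plane.annulus_center,
    )


def clip_plane(plane: AnnularPlane, size_px: int = WINDOW_PX) -> AnnularPlane:
    """Clip a ``size_px`` square window centred on the annulus centre.

    The pixel nearest the annulus centre lands at index
    ``(size_px // 2, size_px // 2)``; window regions outside the source
    extent are padded with air (-1024 HU).  Idempotent: clipping an already
    clipped plane returns it unchanged.
    """
    if not plane.is_isotropic:
        raise ValidationError(f"clip_plane requires an isotropic plane, spacing={plane.spacing}")
    s = plane.spacing[0]
    xc, yc = plane.annulus_center
    jc = int(round((xc - plane.origin[0]) / s))
    ic = int(round((yc - plane.origin[1]) / s))
    i0 = ic - size_px // 2
    j0 = jc - size_px // 2

    out = np.full((size_px, size_px), PAD_HU, dtype=np.float64)
    src_i0, src_i1 = max(i0, 0), min(i0 + size_px, plane.shape[0])
    src_j0, src_j1 = max(j0, 0), min(j0 + size_px, plane.shape[1])
    if src_i0 < src_i1 and src_j0 < src_j1:
        out[src_i0 - i0 : src_i1 - i0, src_j0 - j0 : src_j1 - j0] = plane.values[
            src_i0:src_i1, src_j0:src_j1
        ]
    return AnnularPlane(
        values=out,
        spacing=(s, s),
        origin=(plane.origin[0] + j0 * s, plane.origin[1] + i0 * s),
        annulus_center=plane.annulus_center,
    )


def rasterize_mask(contour: AnnulusContour, grid: AnnularPlane) -> BinaryMask:
    """Rasterise a closed contour: a pixel is true iff its centre lies inside.

    Containment follows the even-odd rule; for the simple polygons accepted
    here it coincides with strict interior membership, so boundary-touching
    pixel centres are excluded.
    """
    contour.validate_simple()
    poly = shapely.Polygon(contour.vertices)
    xx, yy = grid.pixel_centers()
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(grid.shape)
    return BinaryMask(values=inside, spacing=grid.spacing, origin=grid.origin)


@dataclass(frozen=True)
class PreparedSample:
    """Dual-resolution network inputs for one case."""

    plane_1mm: AnnularPlane
    plane_05mm: AnnularPlane
    mask_1mm: BinaryMask | None = None
    mask_05mm: BinaryMask | None = None


def prepare_sample(
    plane: AnnularPlane,
    contour: AnnulusContour | None = None,
    size_px: int = WINDOW_PX,
) -> PreparedSample:
    """Resample-and-clip a raw plane into the dual-resolution input pair.

    Returns the 1.0 mm and 0.5 mm ``size_px`` x ``size_px`` windows and,
    when a ground-truth contour is given, the binary masks rasterised on
    each window's grid.
    """
    coarse = clip_plane(resample_plane(plane, 1.0), size_px)
    fine = clip_plane(resample_plane(plane, 0.5), size_px)
    mask_c = rasterize_mask(contour, coarse) if contour is not None else None
    mask_f = rasterize_mask(contour, fine) if contour is not None else None
    return PreparedSample(coarse, fine, mask_c, mask_f)
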