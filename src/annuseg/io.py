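"""Reading and writing planes, contours and manifests.

Planes travel as NIfTI (pixel spacing in the header, uncompressed ``.nii``
so repeated runs are byte-identical) with a small JSON sidecar carrying the
in-plane origin and annulus-centre metadata, or as 16-bit PNG plus the same
sidecar.  Contours are two-column CSV files ``x_mm,y_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .core import AnnularPlane, AnnulusContour, ProbabilityMap, ValidationError

__all__ = [
    "write_plane",
    "read_plane",
    "write_probability_map",
    "write_contour_csv",
    "read_contour_csv",
]

_PNG_HU_OFFSET = 1024  # stored = HU + offset, keeping air non-negative in uint16


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".png"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_plane(path, plane: AnnularPlane) -> None:
    """Write a plane as NIfTI (.nii/.nii.gz) or 16-bit PNG, plus sidecar."""
    path = Path(path)
    sidecar = {
        "spacing_mm": list(plane.spacing),
        "origin_mm": list(plane.origin),
        "annulus_center_mm": list(plane.annulus_center),
    }
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([plane.spacing[1], plane.spacing[0], 1.0, 1.0])
        affine[0, 3], affine[1, 3] = plane.origin
        img = nib.Nifti1Image(
            np.asarray(plane.values, dtype=np.float32).T[:, :, None], affine
        )
        img.header.set_zooms((plane.spacing[1], plane.spacing[0], 1.0))
        nib.save(img, path)
    elif path.suffix == ".png":
        stored = np.clip(np.rint(plane.values) + _PNG_HU_OFFSET, 0, 65535).astype(np.uint16)
        Image.fromarray(stored, mode="I;16").save(path)
        sidecar["hu_offset"] = _PNG_HU_OFFSET
        sidecar["center_px"] = [
            (plane.annulus_center[0] - plane.origin[0]) / plane.spacing[1],
            (plane.annulus_center[1] - plane.origin[1]) / plane.spacing[0],
        ]
    else:
        raise ValidationError(f"unsupported plane format: {path.name}")
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_plane(path) -> AnnularPlane:
    """Read a plane written by :func:`write_plane`."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        values = np.asarray(img.dataobj)[:, :, 0].T.astype(np.float64)
    elif path.suffix == ".png":
        stored = np.asarray(Image.open(path), dtype=np.float64)
        values = stored - meta.get("hu_offset", _PNG_HU_OFFSET)
    else:
        raise ValidationError(f"unsupported plane format: {path.name}")
    return AnnularPlane(
        values=values,
        spacing=tuple(meta["spacing_mm"]),
        origin=tuple(meta["origin_mm"]),
        annulus_center=tuple(meta["annulus_center_mm"]),
    )


def write_probability_map(path, prob: ProbabilityMap) -> None:
    path = Path(path)
    affine = np.diag([prob.spacing[1], prob.spacing[0], 1.0, 1.0])
    affine[0, 3], affine[1, 3] = prob.origin
    img = nib.Nifti1Image(np.asarray(prob.values, dtype=np.float32).T[:, :, None], affine)
    nib.save(img, path)


def write_contour_csv(path, contour: AnnulusContour) -> None:
    pd.DataFrame(contour.vertices, columns=["x_mm", "y_mm"]).to_csv(path, index=False)


def read_contour_csv(path) -> AnnulusContour:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["x_mm", "y_mm"]:
        raise ValidationError(f"contour CSV must have header x_mm,y_mm, got {list(df.columns)}")
    return AnnulusContour(df[["x_mm", "y_mm"]].to_numpy())
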