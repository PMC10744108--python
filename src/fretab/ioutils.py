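"""Shared on-disk dialect: TIFF channels plus a JSON ROI sidecar.

Regions are named shapes in 0-based pixel coordinates (``x`` = column,
``y`` = row): circles ``{"type": "circle", "cx", "cy", "r"}`` and axis-aligned
rectangles ``{"type": "rect", "x0", "y0", "x1", "y1"}`` with inclusive bounds.
Masks are rasterized centre-in: a pixel belongs to a shape iff its integer
centre does.  The sidecar also carries the pixel size and, for synthetic
data, the generating ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "rasterize",
    "write_acquisition",
    "read_acquisition",
    "read_panel",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("donor_pre", "donor_post", "acceptor_pre", "acceptor_post")


def rasterize(shape_def: dict, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a circle or rectangle, centre-in convention."""
    rows, cols = np.ogrid[0 : image_shape[0], 0 : image_shape[1]]
    kind = shape_def.get("type")
    if kind == "circle":
        cx, cy, r = shape_def["cx"], shape_def["cy"], shape_def["r"]
        return (cols - cx) ** 2 + (rows - cy) ** 2 <= r**2
    if kind == "rect":
        x0, y0, x1, y1 = (shape_def[k] for k in ("x0", "y0", "x1", "y1"))
        return (cols >= x0) & (cols <= x1) & (rows >= y0) & (rows <= y1)
    raise ValueError(f"unknown shape type {kind!r}")


def write_acquisition(
    outdir: str | Path,
    basename: str,
    images: dict[str, np.ndarray],
    sidecar: dict,
) -> dict[str, Path]:
    """Write one TIFF per channel plus ``<basename>_rois.json``.

    Returns the paths written, keyed by channel name plus ``"rois"``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in CHANNEL_NAMES:
        if name not in images:
            raise ValueError(f"missing channel {name!r}")
        path = outdir / f"{basename}_{name}.tif"
        tifffile.imwrite(path, np.asarray(images[name]))
        paths[name] = path
    roi_path = outdir / f"{basename}_rois.json"
    roi_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    paths["rois"] = roi_path
    return paths


def read_acquisition(outdir: str | Path, basename: str):
    """Read the four channel TIFFs and the ROI sidecar back.

    Returns ``(images, sidecar)`` where ``images`` maps channel names to
    arrays.
    """
    outdir = Path(outdir)
    images = {
        name: tifffile.imread(outdir / f"{basename}_{name}.tif") for name in CHANNEL_NAMES
    }
    sidecar = json.loads((outdir / f"{basename}_rois.json").read_text())
    return images, sidecar


def read_panel(sidecar: dict, image_shape: tuple[int, int]):
    """Build a :class:`fretab.fretquant.RoiPanel` from a sidecar dict."""
    from .fretquant import RoiPanel

    rois = sidecar["rois"]
    measurement = {
        name: rasterize(shape, image_shape)
        for name, shape in rois.items()
        if name.startswith("roi_")
    }
    return RoiPanel(
        bleach_region=rasterize(rois["bleach_region"], image_shape),
        measurement_rois=measurement,
        unbleached_roi=rasterize(rois["unbleached"], image_shape),
        pixel_size_um=float(sidecar["pixel_size_um"]),
    )
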