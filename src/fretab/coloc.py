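"""Co-localization metrics: masked Pearson correlation and line profiles.

The Pearson coefficient R of paired pixel intensities over a mask (typically
the whole nucleus) is the standard co-localization readout for two
fluorescence channels; no thresholding is applied.  Intensity profiles sample
the channels along a polyline by bilinear interpolation, with the distance
axis in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

__all__ = ["ProfilePath", "pearson_coefficient", "intensity_profile"]


@dataclass(frozen=True)
class ProfilePath:
    """Ordered polyline in pixel coordinates (x = column, y = row).

    ``step_px`` is the sampling step along the path, in pixels.
    """

    vertices: tuple[tuple[float, float], ...]
    step_px: float = 1.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a profile path needs at least two vertices")
        if not self.step_px > 0:
            raise ValueError("sampling step must be positive")

    def sample_points(self) -> np.ndarray:
        """(n, 2) array of (x, y) samples at ``step_px`` spacing, endpoints included."""
        pts = [np.asarray(self.vertices[0], dtype=float)]
        for a, b in zip(self.vertices[:-1], self.vertices[1:]):
            a, b = np.asarray(a, float), np.asarray(b, float)
            seg = b - a
            length = float(np.hypot(*seg))
            if length == 0:
                continue
            n_steps = int(np.floor(length / self.step_px + 1e-9))
            for k in range(1, n_steps + 1):
                pts.append(a + seg * (k * self.step_px / length))
            if not np.allclose(pts[-1], b):
                pts.append(b)
        return np.asarray(pts)


def pearson_coefficient(channel_a, channel_b, mask) -> float:
    """Sample Pearson correlation of paired pixel intensities under a mask."""
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("channels and mask must share one shape")
    if not m.any():
        raise ValueError("mask is empty")
    xa, xb = a[m], b[m]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("zero variance under the mask in at least one channel")
    return float(sps.pearsonr(xa, xb).statistic)


def intensity_profile(
    channels: dict[str, np.ndarray], path: ProfilePath, pixel_size_um: float = 1.0
) -> pd.DataFrame:
    """Bilinearly interpolated intensities along a polyline.

    Returns a frame with ``distance_um`` plus one column per channel.  Every
    vertex must lie within the image bounds.
    """
    if not channels:
        raise ValueError("no channels given")
    shape = next(iter(channels.values())).shape
    for name, im in channels.items():
        if np.asarray(im).shape != shape:
            raise ValueError(f"channel {name!r} shape differs")
    for x, y in path.vertices:
        if not (0 <= x <= shape[1] - 1 and 0 <= y <= shape[0] - 1):
            raise ValueError(f"vertex ({x}, {y}) outside image bounds {shape}")

    pts = path.sample_points()
    # cumulative arc length along the sampled points
    deltas = np.diff(pts, axis=0)
    dist = np.concatenate([[0.0], np.cumsum(np.hypot(deltas[:, 0], deltas[:, 1]))])
    coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col) order
    data = {"distance_um": dist * pixel_size_um}
    for name, im in channels.items():
        data[name] = ndimage.map_coordinates(
            np.asarray(im, dtype=float), coords, order=1, mode="nearest"
        )
    return pd.DataFrame(data)
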