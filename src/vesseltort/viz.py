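"""Tortuosity heatmap rendering.

Paints every vessel pixel with the per-point metric value of the nearest
centerline sample, min-max normalized per image; lighter = more tortuous,
background black.
"""

from __future__ import annotations

from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from scipy.spatial import cKDTree

from .errors import InvalidInputError
from .geometry import SegmentationMap


def heatmap_array(seg_map: SegmentationMap,
                  centerline_points: np.ndarray,
                  per_point: np.ndarray,
                  colormap: str = "magma") -> np.ndarray:
    """RGB uint8 heatmap of per-point tortuosity over the vessel mask.

    ``centerline_points`` is an (N, 2) array of (x, y) centerline samples
    and ``per_point`` the aligned metric contributions (finite values).
    """
    pts = np.asarray(centerline_points, float)
    vals = np.asarray(per_point, float)
    if len(vals) == 0 or len(pts) == 0:
        raise InvalidInputError("empty per-point values")
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) != len(vals):
        raise InvalidInputError("per-point values misaligned with centerline")
    vals = np.nan_to_num(vals, nan=0.0)

    lo, hi = vals.min(), vals.max()
    norm = np.zeros_like(vals) if hi - lo < 1e-12 else (vals - lo) / (hi - lo)

    fg_r, fg_c = np.nonzero(seg_map.pixels)
    tree = cKDTree(pts)
    _, nearest = tree.query(np.column_stack([fg_c, fg_r]))
    cmap = colormaps[colormap]
    rgba = cmap(norm[nearest])
    out = np.zeros((*seg_map.pixels.shape, 3), dtype=np.uint8)
    out[fg_r, fg_c] = (rgba[:, :3] * 255).astype(np.uint8)
    return out


def render_heatmap(seg_map: SegmentationMap,
                   centerline_points: np.ndarray,
                   per_point: np.ndarray,
                   out_path,
                   colormap: str = "magma") -> None:
    """Render and save a PNG heatmap (see ``heatmap_array``)."""
    iio.imwrite(out_path, heatmap_array(seg_map, centerline_points,
                                        per_point, colormap))
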