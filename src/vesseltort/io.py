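"""Reading masks and writing result tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import SegmentationMap, VesselSegment
from .metrics import ImageTortuositySummary


def load_mask(path, label_path=None) -> SegmentationMap:
    """Load a binary vessel mask (PNG/TIFF); any nonzero pixel is foreground.

    ``label_path`` optionally supplies an artery/vein raster with values
    0 (background) / 1 (artery) / 2 (vein).
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise InvalidInputError(f"{path}: expected a 2-D raster")
    pixels = (arr > 0).astype(np.uint8)
    labels = None
    if label_path is not None:
        larr = iio.imread(label_path)
        if larr.ndim == 3:
            larr = larr[..., :3].max(axis=-1)
        if larr.shape != pixels.shape:
            raise InvalidInputError(f"{label_path}: label shape mismatch")
        labels = np.clip(larr, 0, 2).astype(np.uint8)
        labels[pixels == 0] = 0
    return SegmentationMap(pixels=pixels, label_pixels=labels)


def save_mask(seg_map: SegmentationMap, path) -> None:
    iio.imwrite(path, (seg_map.pixels * 255).astype(np.uint8))
    if seg_map.label_pixels is not None:
        p = Path(path)
        iio.imwrite(p.with_name(p.stem + "_labels" + p.suffix),
                    seg_map.label_pixels.astype(np.uint8))


def segments_to_csv(segments: Sequence[VesselSegment], path) -> None:
    """Write segments point-by-point: one row per centerline sample."""
    rows = []
    for seg in segments:
        for i, (x, y) in enumerate(seg.curve.points):
            rows.append({"segment_id": seg.segment_id, "image_id": seg.image_id,
                         "vessel_class": seg.vessel_class, "point_index": i,
                         "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def segment_results_to_csv(rows: Iterable[dict], path) -> None:
    """Per-segment metric values: image, segment, class, metric, value."""
    df = pd.DataFrame(list(rows), columns=[
        "image_id", "segment_id", "vessel_class", "metric", "value",
        "n_samples", "arc_length_px"])
    df.to_csv(path, index=False)


def summaries_to_csv(summaries: Sequence[ImageTortuositySummary], path) -> None:
    """Per-image summary in the arteries/veins/vessels column layout."""
    rows = []
    for s in summaries:
        for metric, per_class in s.values.items():
            rows.append({"image_id": s.image_id, "metric": metric,
                         "arteries": per_class.get("arteries"),
                         "veins": per_class.get("veins"),
                         "vessels": per_class.get("vessels")})
    pd.DataFrame(rows).to_csv(path, index=False)
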