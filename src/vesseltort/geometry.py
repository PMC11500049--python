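"""Vessel centerline geometry.

Extracts junction-free centerline segments from binary vessel segmentation
maps and provides the differential-geometry primitives (arc-length
resampling, Gaussian smoothing, derivatives, signed curvature, inflection
detection) that every tortuosity metric builds on.

Coordinate convention: points are (x, y) with x = column index and
y = row index, 0-based, pixel centers at integer coordinates. All arc
lengths and curvatures are in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    DegenerateSpeedError,
    EmptyMaskError,
    InvalidInputError,
    TooShortError,
)

# Default processing parameters. Chosen so a straight rasterized vessel
# yields curvature ~0 despite pixel aliasing (see docs/methods.md).
DEFAULT_SPACING_PX = 1.0
DEFAULT_SIGMA_PX = 2.0
DEFAULT_MIN_LENGTH_PX = 20.0
DEFAULT_NOISE_THRESHOLD = 1e-3

VESSEL_CLASSES = ("artery", "vein", "unknown")

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationMap:
    """Binary vessel map; foreground = vessel.

    ``label_pixels`` optionally classifies foreground pixels as
    artery (1) or vein (2); it must be 0 wherever ``pixels`` is 0.
    """

    pixels: np.ndarray
    label_pixels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvalidInputError("segmentation map must be a 2-D raster")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise InvalidInputError("segmentation map must contain only 0/1")
        self.pixels = self.pixels.astype(np.uint8)
        if self.label_pixels is not None:
            self.label_pixels = np.asarray(self.label_pixels)
            if self.label_pixels.shape != self.pixels.shape:
                raise InvalidInputError("label raster shape mismatch")
            if not np.isin(np.unique(self.label_pixels), (0, 1, 2)).all():
                raise InvalidInputError("label raster must contain only 0/1/2")
            if (self.label_pixels[self.pixels == 0] != 0).any():
                raise InvalidInputError("labels present on background pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


class PlanarCurve:
    """An ordered, open 2-D centerline curve in pixel coordinates.

    Stores sample points (x, y) and their cumulative arc length. Consecutive
    duplicate points are rejected; pass ``dedupe=True`` to drop them instead.
    """

    __slots__ = ("points", "cumulative_arclength")

    def __init__(self, points: np.ndarray, dedupe: bool = False) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError("points must be an (N, 2) array")
        if not np.isfinite(pts).all():
            raise InvalidInputError("curve coordinates must be finite")
        if dedupe and len(pts) > 1:
            keep = np.r_[True, (np.diff(pts, axis=0) != 0).any(axis=1)]
            pts = pts[keep]
        if len(pts) < 2:
            raise TooShortError("a curve needs at least 2 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if (steps == 0).any():
            raise InvalidInputError("consecutive curve points must be distinct")
        self.points = pts
        self.cumulative_arclength = np.concatenate(([0.0], np.cumsum(steps)))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total discrete arc length (sum of Euclidean steps)."""
        return float(self.cumulative_arclength[-1])

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def chord(self) -> float:
        """Euclidean distance between the curve's endpoints."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def reversed(self) -> "PlanarCurve":
        return PlanarCurve(self.points[::-1].copy())

    def transformed(self, rotation_rad: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0),
                    scale: float = 1.0) -> "PlanarCurve":
        """Similarity transform (rotate, scale, then translate)."""
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        return PlanarCurve(scale * self.points @ rot.T + np.asarray(translation, float))


@dataclass
class DerivativeField:
    """First/second derivatives of a curve w.r.t. its arc-length parameter."""

    d1: np.ndarray      # (N, 2) tangent (x', y')
    d2: np.ndarray      # (N, 2) (x'', y'')
    speed: np.ndarray   # (N,)   sqrt(x'^2 + y'^2)


@dataclass
class VesselSegment:
    """A junction-free centerline path with its artery/vein class."""

    curve: PlanarCurve
    vessel_class: str = "unknown"
    segment_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.vessel_class not in VESSEL_CLASSES:
            raise InvalidInputError(
                f"vessel_class must be one of {VESSEL_CLASSES}")


@dataclass
class InflectionPartition:
    """Breakpoints splitting a curve into constant-curvature-sign pieces.

    ``breakpoint_indices`` always starts at the first and ends at the last
    sample; ``piece_lengths`` are the arc lengths of the pieces between
    consecutive breakpoints.
    """

    breakpoint_indices: np.ndarray
    piece_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_pieces(self) -> int:
        return len(self.breakpoint_indices) - 1


# ---------------------------------------------------------------------------
# raster operations
# ---------------------------------------------------------------------------

def skeletonize_map(seg_map: SegmentationMap) -> np.ndarray:
    """Thin a binary vessel map to a 1-pixel-wide centerline raster.

    Uses morphological thinning (Zhang-Suen style, via scikit-image).
    Every skeleton pixel is guaranteed to have been foreground.
    """
    if seg_map.pixels.sum() == 0:
        raise EmptyMaskError("no vessels: segmentation map foreground is empty")
    skel = _sk_skeletonize(seg_map.pixels.astype(bool))
    return skel.astype(np.uint8)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """8-neighbour count of each skeleton pixel within the skeleton."""
    sk = skel.astype(np.uint8)
    counts = ndimage.convolve(sk, _EIGHT, mode="constant", cval=0) - sk
    return counts * sk


def extract_segments(
    skeleton: np.ndarray,
    label_pixels: Optional[np.ndarray] = None,
    min_length_px: float = DEFAULT_MIN_LENGTH_PX,
    image_id: str = "",
) -> list[VesselSegment]:
    """Decompose a skeleton into ordered junction-free vessel segments.

    Pixels with >= 3 skeleton neighbours are treated as junctions and
    assigned to no segment; the remaining pixels are traversed end-to-end.
    Segments shorter than ``min_length_px`` (arc length) are discarded.
    Vessel class is the majority vote of ``label_pixels`` along the path.
    """
    skel = skeleton.astype(bool)
    counts = _neighbor_counts(skel)
    junctions = counts >= 3
    paths = skel & ~junctions

    labeled, n_comp = ndimage.label(paths, structure=_EIGHT)
    segments: list[VesselSegment] = []
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labeled == comp)
        if len(rows) < 2:
            continue
        order = _trace_path(rows, cols)
        pts = np.column_stack((cols[order], rows[order])).astype(float)
        curve = PlanarCurve(pts)
        if curve.length < min_length_px:
            continue
        vessel_class = "unknown"
        if label_pixels is not None:
            labs = label_pixels[rows[order], cols[order]]
            labs = labs[labs > 0]
            if len(labs):
                n_art = int((labs == 1).sum())
                n_vein = int((labs == 2).sum())
                if n_art > n_vein:
                    vessel_class = "artery"
                elif n_vein > n_art:
                    vessel_class = "vein"
        segments.append(VesselSegment(curve=curve, vessel_class=vessel_class,
                                      image_id=image_id))
    # Deterministic ordering: by start coordinate (y, x).
    segments.sort(key=lambda s: (s.curve.points[0, 1], s.curve.points[0, 0]))
    for i, seg in enumerate(segments):
        seg.segment_id = f"{image_id}:{i}" if image_id else str(i)
    return segments


def _trace_path(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Order the pixels of one junction-free component end-to-end.

    Starts at the endpoint with the smallest (y, x); a pure cycle starts at
    its smallest pixel. Returns indices into ``rows``/``cols``.
    """
    n = len(rows)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    nbrs[i].append(j)

    degree = np.array([len(v) for v in nbrs])
    candidates = np.nonzero(degree <= 1)[0]
    if len(candidates) == 0:      # cycle
        candidates = np.arange(n)
    start = min(candidates, key=lambda i: (rows[i], cols[i]))

    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    cur = start
    while True:
        nxt = [j for j in nbrs[cur] if not visited[j]]
        if not nxt:
            break
        # Prefer 4-connected steps so diagonal shortcuts around a corner
        # pixel do not skip path pixels; break remaining ties by (y, x).
        nxt.sort(key=lambda j: (abs(int(rows[j]) - int(rows[cur]))
                                + abs(int(cols[j]) - int(cols[cur])),
                                rows[j], cols[j]))
        cur = nxt[0]
        visited[cur] = True
        order.append(cur)
    return np.array(order)


# ---------------------------------------------------------------------------
# curve operations
# ---------------------------------------------------------------------------

def smooth_points(points: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Gaussian-smooth curve coordinates, padding by point reflection.

    Point reflection through the endpoints keeps straight lines exactly
    straight and preserves the endpoint positions to first order. The
    sample count is unchanged.
    """
    xy = np.asarray(points, float)
    n = len(xy)
    if sigma_samples <= 0 or n < 3:
        return xy.copy()
    pad = min(int(np.ceil(4 * sigma_samples)) + 1, n - 1)
    top = 2 * xy[0] - xy[pad:0:-1]
    bot = 2 * xy[-1] - xy[-2:-pad - 2:-1]
    ext = np.vstack([top, xy, bot])
    sm = gaussian_filter1d(ext, sigma=sigma_samples, axis=0, mode="nearest")
    return sm[pad:pad + n]


def resample_smooth(
    curve: PlanarCurve,
    spacing_px: float = DEFAULT_SPACING_PX,
    sigma_px: float = DEFAULT_SIGMA_PX,
) -> PlanarCurve:
    """Resample a curve to uniform arc-length spacing and Gaussian-smooth it.

    The curve is linearly interpolated at uniform arc-length steps of
    approximately ``spacing_px`` (endpoints kept exactly on the original
    endpoints before smoothing), then each coordinate is convolved with a
    Gaussian of standard deviation ``sigma_px`` expressed in samples.
    Endpoint neighbourhoods are padded by point reflection through the
    endpoints, which keeps straight lines exactly straight.
    """
    if spacing_px <= 0:
        raise InvalidInputError("spacing_px must be positive")
    if sigma_px < 0:
        raise InvalidInputError("sigma_px must be nonnegative")
    total = curve.length
    if total < 2 * spacing_px:
        raise TooShortError(
            f"curve of length {total:.3g} px too short for spacing {spacing_px}")
    n = int(round(total / spacing_px)) + 1
    s_new = np.linspace(0.0, total, n)
    s_old = curve.cumulative_arclength
    xy = np.column_stack([
        np.interp(s_new, s_old, curve.points[:, 0]),
        np.interp(s_new, s_old, curve.points[:, 1]),
    ])
    xy = smooth_points(xy, sigma_px)
    return PlanarCurve(xy, dedupe=True)


def derivatives(curve: PlanarCurve) -> DerivativeField:
    """First and second derivatives w.r.t. arc length by finite differences.

    Central differences at interior samples, one-sided at the endpoints.
    Requires a (roughly) uniformly resampled curve with >= 5 points.
    """
    if len(curve) < 5:
        raise TooShortError("derivatives need at least 5 samples")
    s = curve.cumulative_arclength
    d1 = np.column_stack([np.gradient(curve.points[:, 0], s),
                          np.gradient(curve.points[:, 1], s)])
    d2 = np.column_stack([np.gradient(d1[:, 0], s),
                          np.gradient(d1[:, 1], s)])
    speed = np.linalg.norm(d1, axis=1)
    if (speed < 1e-12).any():
        raise DegenerateSpeedError("zero speed sample: degenerate parameterization")
    return DerivativeField(d1=d1, d2=d2, speed=speed)


def curvature(curve: PlanarCurve) -> np.ndarray:
    """Signed curvature kappa = (x'y'' - x''y') / (x'^2 + y'^2)^(3/2).

    The sign encodes the local turning direction (counterclockwise positive
    in the (x, y) frame).
    """
    d = derivatives(curve)
    num = d.d1[:, 0] * d.d2[:, 1] - d.d2[:, 0] * d.d1[:, 1]
    return num / d.speed ** 3


def find_inflections(
    curve: PlanarCurve,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> InflectionPartition:
    """Partition a curve at its inflection points.

    A breakpoint is placed between two runs of opposite curvature sign when
    |kappa| exceeds ``noise_threshold`` on both sides (hysteresis), at the
    sample of minimal |kappa| in the intervening gap. The first and last
    samples are always breakpoints; a curve without a qualifying sign change
    is a single piece.
    """
    kappa = curvature(curve)
    n = len(kappa)
    sig = np.zeros(n, dtype=int)
    sig[kappa > noise_threshold] = 1
    sig[kappa < -noise_threshold] = -1

    breaks = [0]
    last_sign = 0
    last_idx = 0
    for i in np.nonzero(sig)[0]:
        if last_sign != 0 and sig[i] != last_sign:
            gap = np.abs(kappa[last_idx:i + 1])
            bp = last_idx + int(np.argmin(gap))
            if 0 < bp < n - 1 and bp > breaks[-1]:
                breaks.append(bp)
        last_sign = sig[i]
        last_idx = int(i)
    if breaks[-1] != n - 1:
        breaks.append(n - 1)
    idx = np.array(breaks)
    s = curve.cumulative_arclength
    return InflectionPartition(breakpoint_indices=idx,
                               piece_lengths=np.diff(s[idx]))
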