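"""Tortuosity metrics for retinal vessel centerlines.

Seven metrics, each returning a scalar per vessel segment plus per-sample
contributions for heatmapping:

- arc_over_chord: arc/chord ratio over fixed-arc-length windows
- distance_tortuosity: arc/chord ratio over inflection-bounded pieces
- angle_tortuosity: length-weighted angular deviation at inflection pieces
- tortuosity_density: Grisan-style density over constant-sign-curvature pieces
- squared_curvature_tortuosity: integral of squared curvature over arc length
- inverse_radius_tortuosity: mean reciprocal osculating-circle radius
- vci: "VCI-open", a windowed mean |dL/dt| of planar angular momentum — an
  open reconstruction of the proprietary vascular curvature index, built
  from the published physics sketch (L = I*omega, dL/dt = m*v*r'(t)). It is
  documented as a reconstruction, not the original formula.

All metrics operate on resampled/smoothed ``PlanarCurve`` objects in pixel
units. Straight lines attain every metric's lower bound (1 for the
arc-over-chord family, 0 otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import DegenerateChordError, InvalidInputError, TooShortError
from .geometry import (
    InflectionPartition,
    PlanarCurve,
    VesselSegment,
    curvature,
    derivatives,
)

METRIC_NAMES = (
    "arc_over_chord",
    "distance_tortuosity",
    "angle_tortuosity",
    "tortuosity_density",
    "squared_curvature",
    "inverse_radius",
    "vci",
)

DEFAULT_WINDOW_PX = 50.0

_CHORD_TOL = 1e-9


@dataclass
class TortuosityResult:
    """A metric value for one segment, with optional per-sample contributions."""

    metric_name: str
    value: float
    per_point: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise InvalidInputError(f"unknown metric {self.metric_name!r}")
        if not np.isfinite(self.value):
            raise InvalidInputError(f"{self.metric_name}: non-finite value")


@dataclass
class VCIParams:
    """Parameters of the VCI-open reconstruction.

    ``window_halfwidth_samples`` (w) sets the local window [i-w, i+w] over
    which angular momentum is tracked; ``mass`` and ``speed`` are the
    dimensionless m and v of the physics sketch (both 1 by default);
    ``reference_rule`` chooses the reference point O for the angular
    momentum: the midpoint of the local window's chord (default) or of the
    whole segment's chord. ``smoothing_sigma_samples`` is the metric's own
    internal Gaussian smoothing scale, part of the reconstruction's
    noise-resistance design: it suppresses residual pixel-scale wiggle
    before angular momentum is differentiated.
    """

    window_halfwidth_samples: int = 5
    mass: float = 1.0
    speed: float = 1.0
    reference_rule: str = "window_chord_midpoint"
    smoothing_sigma_samples: float = 4.0

    def __post_init__(self) -> None:
        if self.window_halfwidth_samples < 2:
            raise InvalidInputError("window halfwidth w must be >= 2")
        if self.smoothing_sigma_samples < 0:
            raise InvalidInputError("smoothing sigma must be nonnegative")
        if self.mass <= 0 or self.speed <= 0:
            raise InvalidInputError("mass and speed must be positive")
        if self.reference_rule not in ("window_chord_midpoint",
                                       "segment_chord_midpoint"):
            raise InvalidInputError("unknown reference_rule")


@dataclass
class ImageTortuositySummary:
    """Per-image, per-class aggregated metric values (Tables-style layout)."""

    image_id: str
    values: Dict[str, Dict[str, float]] = field(default_factory=dict)
    n_segments: Dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _piece_arc_chord(curve: PlanarCurve, i0: int, i1: int) -> tuple[float, float]:
    s = curve.cumulative_arclength
    arc = float(s[i1] - s[i0])
    chord = float(np.linalg.norm(curve.points[i1] - curve.points[i0]))
    return arc, chord


def _window_boundaries(curve: PlanarCurve, window_px: float) -> np.ndarray:
    """Sample indices of equal-arc-length window boundaries.

    The window count applies the merge rule: a final remainder shorter than
    half a window joins the previous window; otherwise it becomes its own
    window. Equal-length windows keep the partition symmetric under
    orientation reversal.
    """
    if window_px <= 0:
        raise InvalidInputError("window_px must be positive")
    total = curve.length
    n_full = int(total // window_px)
    rem = total - n_full * window_px
    n_win = max(n_full + (1 if rem >= window_px / 2 else 0), 1)
    s = curve.cumulative_arclength
    targets = np.linspace(0.0, total, n_win + 1)
    idx = np.searchsorted(s, targets)
    idx = np.clip(idx, 0, len(s) - 1)
    # snap to nearest sample
    for k in range(1, n_win):
        i = idx[k]
        if i > 0 and abs(s[i - 1] - targets[k]) < abs(s[i] - targets[k]):
            idx[k] = i - 1
    idx[0], idx[-1] = 0, len(s) - 1
    idx = np.unique(idx)
    return idx


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def arc_over_chord(curve: PlanarCurve,
                   window_px: float = DEFAULT_WINDOW_PX) -> TortuosityResult:
    """Arc-over-chord ratio across fixed arc-length windows.

    The curve is cut into consecutive windows of (equal) arc length close to
    ``window_px``; per window the discrete arc length is divided by the
    Euclidean chord of the window endpoints, and the value is the
    arc-length-weighted mean of the window ratios. Straight segments give
    exactly 1.
    """
    bounds = _window_boundaries(curve, window_px)
    ratios, weights = [], []
    per_point = np.empty(len(curve))
    for k in range(len(bounds) - 1):
        i0, i1 = bounds[k], bounds[k + 1]
        arc, chord = _piece_arc_chord(curve, i0, i1)
        if chord < _CHORD_TOL:
            raise DegenerateChordError(
                "window chord is (near) zero — closed or self-returning curve")
        ratios.append(arc / chord)
        weights.append(arc)
        per_point[i0:i1 + 1] = arc / chord
    value = float(np.average(ratios, weights=weights))
    return TortuosityResult("arc_over_chord", value, per_point)


def distance_tortuosity(curve: PlanarCurve,
                        partition: InflectionPartition) -> TortuosityResult:
    """Arc-over-chord ratio with dynamically selected (inflection) points.

    Each piece between consecutive inflection points contributes its
    arc/chord ratio; the value is the arc-length-weighted mean over pieces.
    """
    idx = partition.breakpoint_indices
    ratios, weights = [], []
    per_point = np.empty(len(curve))
    for k in range(len(idx) - 1):
        i0, i1 = idx[k], idx[k + 1]
        arc, chord = _piece_arc_chord(curve, i0, i1)
        if chord < _CHORD_TOL:
            raise DegenerateChordError("degenerate chord within a piece")
        ratios.append(arc / chord)
        weights.append(arc)
        per_point[i0:i1 + 1] = arc / chord
    value = float(np.average(ratios, weights=weights))
    return TortuosityResult("distance_tortuosity", value, per_point)


def angular_deviation(p_start: Sequence[float], p_mid: Sequence[float],
                      p_end: Sequence[float]) -> float:
    """Angular deviation at a midpoint: pi - angle(a, b).

    a points from the midpoint to the piece start, b from the midpoint to
    the piece end; a straight path (a, b antiparallel) gives 0, a right-angle
    elbow gives pi/2.
    """
    a = np.asarray(p_start, float) - np.asarray(p_mid, float)
    b = np.asarray(p_end, float) - np.asarray(p_mid, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _CHORD_TOL or nb < _CHORD_TOL:
        raise DegenerateChordError("zero-length arm in angular deviation")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.pi - np.arccos(cosang))


def angle_tortuosity(curve: PlanarCurve, partition: InflectionPartition,
                     denominator: str = "sum_lengths") -> TortuosityResult:
    """Length-weighted angular deviation between consecutive inflection points.

    For each piece (t_i, t_{i+1}) the deviation is measured at the point
    midway (in arc length) between the breakpoints, interpolated on the
    curve so the measurement is exactly symmetric under orientation
    reversal. ``denominator`` selects the true length-weighted mean
    (``"sum_lengths"``, default) or division by the piece count (``"n"``).
    """
    if denominator not in ("sum_lengths", "n"):
        raise InvalidInputError("denominator must be 'sum_lengths' or 'n'")
    idx = partition.breakpoint_indices
    pts = curve.points
    s = curve.cumulative_arclength
    per_point = np.zeros(len(curve))
    thetas, lengths = [], []
    for k in range(len(idx) - 1):
        i0, i1 = int(idx[k]), int(idx[k + 1])
        s_mid = 0.5 * (s[i0] + s[i1])
        mid = np.array([np.interp(s_mid, s, pts[:, 0]),
                        np.interp(s_mid, s, pts[:, 1])])
        try:
            dtheta = angular_deviation(pts[i0], mid, pts[i1])
        except DegenerateChordError:
            warnings.warn(f"angle_tortuosity: skipping degenerate piece {k}",
                          stacklevel=2)
            continue
        length = float(partition.piece_lengths[k])
        thetas.append(dtheta)
        lengths.append(length)
        per_point[i0:i1 + 1] = dtheta
    if not thetas:
        raise DegenerateChordError("all pieces degenerate in angle_tortuosity")
    num = float(np.dot(lengths, thetas))
    den = float(np.sum(lengths)) if denominator == "sum_lengths" else len(thetas)
    return TortuosityResult("angle_tortuosity", num / den, per_point)


def tortuosity_density(curve: PlanarCurve,
                       partition: InflectionPartition) -> TortuosityResult:
    """Grisan-style tortuosity density over constant-sign-curvature pieces.

    value = ((n-1)/n) * (1 / sum_i chord(C_i)) * sum_i (arc(C_i)/chord(C_i) - 1)

    A curve with a single piece (no inflections) has density 0.
    """
    idx = partition.breakpoint_indices
    n = partition.n_pieces
    per_point = np.zeros(len(curve))
    if n <= 1:
        return TortuosityResult("tortuosity_density", 0.0, per_point)
    excess_sum = 0.0
    chord_sum = 0.0
    for k in range(len(idx) - 1):
        i0, i1 = idx[k], idx[k + 1]
        arc, chord = _piece_arc_chord(curve, i0, i1)
        if chord < _CHORD_TOL:
            raise DegenerateChordError("degenerate chord within a piece")
        excess_sum += arc / chord - 1.0
        chord_sum += chord
        per_point[i0:i1 + 1] = arc / chord - 1.0
    value = (n - 1) / n * excess_sum / chord_sum
    return TortuosityResult("tortuosity_density", float(value), per_point)


def squared_curvature_tortuosity(curve: PlanarCurve,
                                 power: int = 2) -> TortuosityResult:
    """Integral of |curvature|^power over arc length (power 2 by default).

    The squared integrand amplifies pronounced bends; ``power=1`` integrates
    |kappa| instead (total absolute turning).
    """
    if power not in (1, 2):
        raise InvalidInputError("power must be 1 or 2")
    kappa = curvature(curve)
    integrand = np.abs(kappa) ** power
    value = float(np.trapezoid(integrand, curve.cumulative_arclength))
    return TortuosityResult("squared_curvature", value, integrand)


def inverse_radius_tortuosity(curve: PlanarCurve) -> TortuosityResult:
    """Mean reciprocal of the osculating-circle radius, i.e. mean |kappa|."""
    kappa = np.abs(curvature(curve))
    return TortuosityResult("inverse_radius", float(kappa.mean()), kappa)


def vci(curve: PlanarCurve,
        params: Optional[VCIParams] = None) -> TortuosityResult:
    """VCI-open: windowed mean |dL/dt| of planar angular momentum.

    The curve is treated as the trajectory of a unit-mass point moving at
    unit speed. The coordinates are first smoothed at the metric's own
    internal scale (``params.smoothing_sigma_samples``); then for each
    interior sample i, over the window [i-w, i+w], the scalar angular
    momentum L = m * (r x v) is computed about the reference point O (by
    default the midpoint of the window's chord), and the per-sample
    contribution is the window mean of |dL/ds| by finite differences. The
    value is the mean contribution over interior samples; a straight line
    gives exactly 0.

    This is an open reconstruction of the proprietary vascular curvature
    index from its published physics sketch; exact numeric agreement with
    the original is not claimed.
    """
    from .geometry import smooth_points

    if params is None:
        params = VCIParams()
    w = params.window_halfwidth_samples
    n = len(curve)
    if n < 2 * w + 1:
        raise TooShortError(f"VCI needs at least {2 * w + 1} samples, got {n}")
    work = curve
    if params.smoothing_sigma_samples > 0:
        work = PlanarCurve(
            smooth_points(curve.points, params.smoothing_sigma_samples),
            dedupe=True)
        if len(work) != n:  # duplicate collapse is pathological; keep alignment
            work = curve
    d = derivatives(work)
    v_unit = d.d1 / d.speed[:, None]
    pts = work.points
    s = work.cumulative_arclength
    mv = params.mass * params.speed
    seg_mid = 0.5 * (pts[0] + pts[-1])

    per_point = np.full(n, np.nan)
    for i in range(w, n - w):
        lo, hi = i - w, i + w
        if params.reference_rule == "window_chord_midpoint":
            origin = 0.5 * (pts[lo] + pts[hi])
        else:
            origin = seg_mid
        r = pts[lo:hi + 1] - origin
        vv = v_unit[lo:hi + 1]
        L = mv * (r[:, 0] * vv[:, 1] - r[:, 1] * vv[:, 0])
        dL = np.gradient(L, s[lo:hi + 1])
        per_point[i] = np.mean(np.abs(dL))
    value = float(np.nanmean(per_point[w:n - w]))
    # pad the edge samples for heatmap alignment
    per_point[:w] = per_point[w]
    per_point[n - w:] = per_point[n - w - 1]
    return TortuosityResult("vci", value, per_point)


# ---------------------------------------------------------------------------
# pipeline conveniences
# ---------------------------------------------------------------------------

def compute_all_metrics(
    curve: PlanarCurve,
    window_px: float = DEFAULT_WINDOW_PX,
    noise_threshold: float = 1e-3,
    vci_params: Optional[VCIParams] = None,
    angle_denominator: str = "sum_lengths",
    curvature_power: int = 2,
) -> Dict[str, TortuosityResult]:
    """All seven metrics on one (already resampled/smoothed) curve."""
    from .geometry import find_inflections

    part = find_inflections(curve, noise_threshold)
    return {
        "arc_over_chord": arc_over_chord(curve, window_px),
        "distance_tortuosity": distance_tortuosity(curve, part),
        "angle_tortuosity": angle_tortuosity(curve, part, angle_denominator),
        "tortuosity_density": tortuosity_density(curve, part),
        "squared_curvature": squared_curvature_tortuosity(curve, curvature_power),
        "inverse_radius": inverse_radius_tortuosity(curve),
        "vci": vci(curve, vci_params),
    }


def summarize_image(
    segments: Sequence[VesselSegment],
    metric_values: Sequence[Dict[str, float]],
    image_id: str = "",
    weighted: bool = True,
) -> ImageTortuositySummary:
    """Aggregate per-segment metric values to per-class image values.

    Classes: "arteries" (artery segments), "veins" (vein segments) and
    "vessels" (all segments, unknown included). Aggregation is the
    arc-length-weighted mean of segment values (unweighted behind the flag).
    Classes with no segments are omitted.
    """
    if len(segments) == 0:
        raise InvalidInputError("summarize_image needs at least one segment")
    if len(segments) != len(metric_values):
        raise InvalidInputError("segments and metric_values length mismatch")

    groups = {
        "arteries": [i for i, s in enumerate(segments) if s.vessel_class == "artery"],
        "veins": [i for i, s in enumerate(segments) if s.vessel_class == "vein"],
        "vessels": list(range(len(segments))),
    }
    metrics_present = list(metric_values[0].keys())
    summary = ImageTortuositySummary(image_id=image_id)
    for cls, idxs in groups.items():
        if not idxs:
            continue
        summary.n_segments[cls] = len(idxs)
        lengths = np.array([segments[i].curve.length for i in idxs]) \
            if weighted else np.ones(len(idxs))
        for m in metrics_present:
            vals = np.array([metric_values[i][m] for i in idxs])
            summary.values.setdefault(m, {})[cls] = float(
                np.average(vals, weights=lengths))
    return summary
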