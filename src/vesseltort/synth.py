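"""Synthetic vasculature and retest-cohort generation.

Everything the rest of the package needs to be tested without real fundus
images: parametric curves with closed-form arc length and curvature,
rasterized vessel maps with controllable segmentation noise, and seeded
paired test/retest cohorts emulating a repeated-acquisition study design
(44 subjects, both eyes, two acquisitions minutes apart).

All generators are bit-reproducible given (spec, seed): RNG streams are
derived from the master seed per (subject, eye, session), so adding
subjects never perturbs earlier subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, ndimage

from .errors import InvalidInputError
from .geometry import (
    PlanarCurve,
    SegmentationMap,
    extract_segments,
    resample_smooth,
    skeletonize_map,
)
from .metrics import METRIC_NAMES, compute_all_metrics, summarize_image

CURVE_FAMILIES = ("line", "circular_arc", "sinusoid", "spiral", "piecewise_arcs")


@dataclass
class CurveSpec:
    """Recipe for one analytic curve.

    Families and their parameters:
    - line: length
    - circular_arc: radius, span (radians)
    - sinusoid: amplitude, wavelength, n_half_periods
    - spiral: radius (start), growth (px per radian), span
    - piecewise_arcs: radii (tuple), span (per arc, radians, alternating turn)
    """

    family: str = "sinusoid"
    length: float = 100.0
    radius: float = 50.0
    radii: Tuple[float, ...] = (10.0, 20.0)
    span: float = np.pi
    amplitude: float = 1.0
    wavelength: float = 2 * np.pi
    n_half_periods: int = 2
    growth: float = 2.0
    spacing: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in CURVE_FAMILIES:
            raise InvalidInputError(f"unknown curve family {self.family!r}")
        if self.spacing <= 0:
            raise InvalidInputError("sampling spacing must be positive")
        for name in ("length", "radius", "span", "amplitude", "wavelength",
                     "growth"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.n_half_periods < 1:
            raise InvalidInputError("n_half_periods must be >= 1")
        if any(r <= 0 for r in self.radii):
            raise InvalidInputError("radii must be positive")


@dataclass
class CurveTruth:
    """Closed-form ground truth attached to a generated curve."""

    arc_length: float
    curvature_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    max_abs_curvature: float = 0.0


@dataclass
class CohortSpec:
    """Design of a synthetic paired test/retest cohort.

    Defaults emulate the repeated-acquisition study design this package
    targets: 44 subjects, both eyes imaged twice within minutes. Noise
    parameters model segmentation variability between the two acquisitions
    (sub-pixel field shift, smooth elastic deformation of the vessel paths,
    boundary pixel flips, small segmentation drop-out gaps); they are
    calibrated so that established metrics land in the retest-correlation
    range reported for fundus tortuosity (see docs/methods.md).
    """

    n_subjects: int = 44
    eyes_per_subject: int = 2
    vessels_per_eye: int = 4
    jitter_sigma_px: float = 0.5
    flip_probability: float = 0.05
    deform_amplitude_px: float = 4.0
    deform_corr_px: float = 12.0
    gap_rate: float = 3.0
    amplitude_sigma: float = 0.4       # lognormal sd of per-subject multiplier
    image_shape: Tuple[int, int] = (168, 220)
    vessel_width_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise InvalidInputError("cohort needs at least 3 subjects")
        if self.jitter_sigma_px < 0 or not (0 <= self.flip_probability < 1) \
                or self.deform_amplitude_px < 0 or self.deform_corr_px <= 0 \
                or self.gap_rate < 0:
            raise InvalidInputError("invalid noise parameters")
        if self.eyes_per_subject not in (1, 2):
            raise InvalidInputError("eyes_per_subject must be 1 or 2")


# ---------------------------------------------------------------------------
# analytic curves
# ---------------------------------------------------------------------------

def make_curve(spec: CurveSpec) -> Tuple[PlanarCurve, CurveTruth]:
    """Sample an analytic curve and return it with its closed-form truth."""
    h = spec.spacing
    if spec.family == "line":
        n = max(int(round(spec.length / h)) + 1, 2)
        t = np.linspace(0.0, spec.length, n)
        pts = np.column_stack([t, np.zeros_like(t)])
        truth = CurveTruth(arc_length=spec.length,
                           curvature_fn=lambda s: np.zeros_like(s))
    elif spec.family == "circular_arc":
        arc_len = spec.radius * spec.span
        n = max(int(round(arc_len / h)) + 1, 8)
        theta = np.linspace(0.0, spec.span, n)
        pts = spec.radius * np.column_stack([np.cos(theta), np.sin(theta)])
        k = 1.0 / spec.radius
        truth = CurveTruth(arc_length=arc_len,
                           curvature_fn=lambda s, k=k: np.full_like(s, k),
                           max_abs_curvature=k)
    elif spec.family == "sinusoid":
        omega = 2 * np.pi / spec.wavelength
        x_end = spec.n_half_periods * spec.wavelength / 2.0
        # sample uniformly in x at a density matching the requested spacing
        n = max(int(round(x_end * np.hypot(1, spec.amplitude * omega) / h)) + 1, 16)
        x = np.linspace(0.0, x_end, n)
        pts = np.column_stack([x, spec.amplitude * np.sin(omega * x)])
        arc_len = float(integrate.quad(
            lambda u: np.hypot(1.0, spec.amplitude * omega * np.cos(omega * u)),
            0.0, x_end, limit=200)[0])

        def kfn(x, A=spec.amplitude, w=omega):
            yp = A * w * np.cos(w * x)
            ypp = -A * w * w * np.sin(w * x)
            return ypp / (1 + yp ** 2) ** 1.5

        truth = CurveTruth(arc_length=arc_len, curvature_fn=kfn,
                           max_abs_curvature=spec.amplitude * omega ** 2)
    elif spec.family == "spiral":
        # Archimedean spiral r = a + b*theta
        a, b = spec.radius, spec.growth
        n = max(int(round((a + b * spec.span) * spec.span / h)) + 1, 32)
        theta = np.linspace(0.0, spec.span, n)
        r = a + b * theta
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        arc_len = float(integrate.quad(
            lambda th: np.hypot(a + b * th, b), 0.0, spec.span, limit=200)[0])
        truth = CurveTruth(arc_length=arc_len)
    else:  # piecewise_arcs: tangent-continuous arcs of alternating turn
        segs = []
        pos = np.zeros(2)
        heading = 0.0
        total = 0.0
        for j, r in enumerate(spec.radii):
            n = max(int(round(r * spec.span / h)) + 1, 8)
            phi = np.linspace(0.0, spec.span, n)
            sign = 1.0 if j % 2 == 0 else -1.0
            # arc of radius r starting at pos with tangent direction heading
            center = pos + r * np.array([-np.sin(heading) * sign,
                                         np.cos(heading) * sign])
            ang0 = np.arctan2(pos[1] - center[1], pos[0] - center[0])
            ang = ang0 + sign * phi
            arc = center + r * np.column_stack([np.cos(ang), np.sin(ang)])
            segs.append(arc if not segs else arc[1:])
            pos = arc[-1]
            heading += sign * spec.span
            total += r * spec.span
        pts = np.vstack(segs)
        truth = CurveTruth(arc_length=total,
                           max_abs_curvature=1.0 / min(spec.radii))
    return PlanarCurve(pts, dedupe=True), truth


# ---------------------------------------------------------------------------
# rasterization and retest noise
# ---------------------------------------------------------------------------

def rasterize(curve: PlanarCurve, width_px: float,
              shape: Tuple[int, int],
              label: int = 0,
              canvas: Optional[SegmentationMap] = None) -> SegmentationMap:
    """Rasterize a curve as a vessel of the given width.

    Foreground = all pixels within width_px/2 of the polyline. If ``canvas``
    is given, the vessel is painted onto it (labels merged); otherwise a
    fresh map is created. ``label`` 1 (artery) or 2 (vein) populates the
    label raster.
    """
    if width_px <= 0:
        raise InvalidInputError("width_px must be positive")
    margin = width_px
    xs, ys = curve.points[:, 0], curve.points[:, 1]
    h, w = shape
    if (xs.min() < margin or ys.min() < margin
            or xs.max() > w - 1 - margin or ys.max() > h - 1 - margin):
        raise InvalidInputError("curve out of bounds for the requested shape")

    # mark the polyline at sub-pixel density, then threshold the EDT
    dense = resample_smooth(curve, spacing_px=0.25, sigma_px=0.0) \
        if curve.length >= 1 else curve
    grid = np.ones(shape, dtype=bool)
    rr = np.clip(np.round(dense.points[:, 1]).astype(int), 0, h - 1)
    cc = np.clip(np.round(dense.points[:, 0]).astype(int), 0, w - 1)
    grid[rr, cc] = False
    dist = ndimage.distance_transform_edt(grid)
    mask = dist <= width_px / 2.0

    if canvas is None:
        pixels = mask.astype(np.uint8)
        labels = np.zeros(shape, dtype=np.uint8)
    else:
        pixels = (canvas.pixels.astype(bool) | mask).astype(np.uint8)
        labels = (canvas.label_pixels.copy() if canvas.label_pixels is not None
                  else np.zeros(shape, dtype=np.uint8))
    if label:
        labels[mask] = label
    return SegmentationMap(pixels=pixels, label_pixels=labels)


def perturb_retest(seg_map: SegmentationMap,
                   jitter_sigma_px: float = 0.5,
                   flip_probability: float = 0.05,
                   deform_amplitude_px: float = 0.0,
                   deform_corr_px: float = 12.0,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None) -> SegmentationMap:
    """Simulate re-acquisition noise on a segmentation map.

    Three seeded components, each re-binarized at 0.5:

    - a sub-pixel field translation (bilinear shift of the binary map),
    - a smooth random elastic deformation (Gaussian-correlated displacement
      field of rms amplitude ``deform_amplitude_px`` and correlation length
      ``deform_corr_px``), modelling low-spatial-frequency differences in
      the segmented vessel path between acquisitions,
    - independent flips of boundary pixels at ``flip_probability``,
      modelling pixel-scale segmentation/thresholding noise.

    Labels are carried along with the same geometric transforms.
    Deterministic per seed; zero noise returns an identical map.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pixels = seg_map.pixels.astype(float)
    labels = seg_map.label_pixels

    if jitter_sigma_px > 0:
        dy, dx = rng.normal(0.0, jitter_sigma_px, size=2)
        pixels = ndimage.shift(pixels, (dy, dx), order=1, mode="constant")
        if labels is not None:
            labels = ndimage.shift(labels, (dy, dx), order=0, mode="constant")

    if deform_amplitude_px > 0:
        shape = pixels.shape
        dy = ndimage.gaussian_filter(rng.normal(size=shape), deform_corr_px)
        dx = ndimage.gaussian_filter(rng.normal(size=shape), deform_corr_px)
        dy *= deform_amplitude_px / max(dy.std(), 1e-12)
        dx *= deform_amplitude_px / max(dx.std(), 1e-12)
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        coords = np.array([rr + dy, cc + dx])
        pixels = ndimage.map_coordinates(pixels, coords, order=1,
                                         mode="constant")
        if labels is not None:
            labels = ndimage.map_coordinates(labels, coords, order=0,
                                             mode="constant")
    out = (pixels >= 0.5).astype(np.uint8)

    if flip_probability > 0:
        fg = out.astype(bool)
        eroded = ndimage.binary_erosion(fg)
        dilated = ndimage.binary_dilation(fg)
        boundary = (fg & ~eroded) | (dilated & ~fg)
        flips = boundary & (rng.random(out.shape) < flip_probability)
        out[flips] = 1 - out[flips]

    if labels is not None:
        labels = labels.copy()
        labels[out == 0] = 0
    return SegmentationMap(pixels=out, label_pixels=labels)


def add_segmentation_gaps(seg_map: SegmentationMap, gap_rate: float,
                          rng: np.random.Generator,
                          radius_range: Tuple[float, float] = (2.0, 4.0),
                          ) -> SegmentationMap:
    """Punch small drop-out holes into the vessel map.

    Segmentation pipelines intermittently lose short stretches of vessel
    (low contrast, crossings); this models that as a Poisson number
    (mean ``gap_rate``) of disks of radius 2-4 px centred on random
    foreground pixels, set to background.
    """
    out = seg_map.pixels.copy()
    n = int(rng.poisson(gap_rate)) if gap_rate > 0 else 0
    fg = np.argwhere(out > 0)
    if n and len(fg):
        idx = rng.integers(0, len(fg), size=n)
        h, w = out.shape
        rr, cc = np.ogrid[:h, :w]
        for r0, c0 in fg[idx]:
            rad = rng.uniform(*radius_range)
            out[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2] = 0
    labels = seg_map.label_pixels
    if labels is not None:
        labels = labels.copy()
        labels[out == 0] = 0
    return SegmentationMap(pixels=out, label_pixels=labels)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def make_eye_map(spec: CohortSpec, subject: int, eye: int) -> SegmentationMap:
    """Clean (noise-free) segmentation map for one eye: the 'anatomy'.

    Sinusoidal vessels in horizontal bands plus one vessel running
    vertically across them, so the tree contains the artery/vein crossings
    that real fundus vasculature has (crossings create skeleton junctions,
    whose decomposition is sensitive to acquisition noise). The per-subject
    tortuosity level is a lognormal multiplier on the amplitudes, giving
    the between-subject spread that retest correlations need.
    """
    h, w = spec.image_shape
    subj_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 101, subject]))
    tort_level = float(np.exp(subj_rng.normal(0.0, spec.amplitude_sigma)))
    eye_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 202, subject, eye]))

    def draw_amplitude() -> float:
        return float(np.clip(tort_level * eye_rng.uniform(2.0, 4.0), 0.5, 12.0))

    n_bands = max(spec.vessels_per_eye - 1, 1)
    band = (h - 40) / n_bands
    canvas = None
    for v in range(n_bands):
        cs = CurveSpec(family="sinusoid", amplitude=draw_amplitude(),
                       wavelength=float(eye_rng.uniform(45.0, 75.0)),
                       n_half_periods=int(eye_rng.integers(4, 7)),
                       spacing=0.5)
        curve, _ = make_curve(cs)
        pts = curve.points.copy()
        # centre horizontally, stack vertically, alternate artery/vein
        pts[:, 0] += 20.0
        pts[:, 1] += 20.0 + band * v + band / 2.0
        scale = min(1.0, (w - 40.0) / max(pts[:, 0].max() - 20.0, 1.0))
        pts[:, 0] = 20.0 + (pts[:, 0] - 20.0) * scale
        canvas = rasterize(PlanarCurve(pts), spec.vessel_width_px, (h, w),
                           label=1 if v % 2 == 0 else 2, canvas=canvas)
    if spec.vessels_per_eye > 1:
        cs = CurveSpec(family="sinusoid", amplitude=draw_amplitude(),
                       wavelength=float(eye_rng.uniform(45.0, 75.0)),
                       n_half_periods=5, spacing=0.5)
        curve, _ = make_curve(cs)
        pts = curve.points.copy()
        scale = (h - 40.0) / max(pts[:, 0].max(), 1.0)
        x0 = float(eye_rng.uniform(60.0, w - 60.0))
        placed = np.column_stack([x0 + pts[:, 1], 20.0 + pts[:, 0] * scale])
        canvas = rasterize(PlanarCurve(placed), spec.vessel_width_px, (h, w),
                           label=2, canvas=canvas)
    return canvas


def measure_map(seg_map: SegmentationMap,
                min_length_px: float = 20.0,
                spacing_px: float = 1.0,
                sigma_px: float = 2.0,
                image_id: str = "") -> Dict[str, Dict[str, float]]:
    """Full pipeline on one map: skeleton -> segments -> metrics -> summary.

    Returns {metric: {class: value}} for classes present in the image.
    """
    skel = skeletonize_map(seg_map)
    segments = extract_segments(skel, seg_map.label_pixels,
                                min_length_px=min_length_px, image_id=image_id)
    kept, values = [], []
    for seg in segments:
        try:
            curve = resample_smooth(seg.curve, spacing_px, sigma_px)
            res = compute_all_metrics(curve)
        except Exception:
            continue  # segments too short/degenerate after processing
        kept.append(seg)
        values.append({m: r.value for m, r in res.items()})
    if not kept:
        return {}
    return summarize_image(kept, values, image_id=image_id).values


def make_cohort(spec: CohortSpec) -> Tuple["pd.DataFrame", Dict]:
    """Generate a paired test/retest cohort through the full raster pipeline.

    For every (subject, eye), the clean anatomy map is perturbed twice with
    independent session noise (emulating two acquisitions minutes apart),
    each acquisition is measured end-to-end, and per-class metric values are
    paired into long-format records. Returns (records DataFrame compatible
    with RetestDataset, info dict with the layout specs).

    Deterministic per spec.seed; with zero noise both sessions are
    identical and every retest correlation is exactly 1.
    """
    rows = []
    info: Dict = {"n_subjects": spec.n_subjects, "seed": spec.seed}
    eyes = ["OD", "OS"][: spec.eyes_per_subject]
    for subject in range(spec.n_subjects):
        sid = f"S{subject:03d}"
        for e_idx, eye in enumerate(eyes):
            clean = make_eye_map(spec, subject, e_idx)
            sessions = {}
            for s_idx, session in enumerate(("test", "retest")):
                rng = np.random.default_rng(np.random.SeedSequence(
                    [spec.seed, 303, subject, e_idx, s_idx]))
                noisy = perturb_retest(
                    clean, spec.jitter_sigma_px, spec.flip_probability,
                    spec.deform_amplitude_px, spec.deform_corr_px, rng=rng)
                if spec.gap_rate > 0:
                    noisy = add_segmentation_gaps(noisy, spec.gap_rate, rng)
                sessions[session] = measure_map(
                    noisy, image_id=f"{sid}_{eye}_{session}")
            for metric in METRIC_NAMES:
                for cls in ("arteries", "veins", "vessels"):
                    vt = sessions["test"].get(metric, {}).get(cls)
                    vr = sessions["retest"].get(metric, {}).get(cls)
                    if vt is None or vr is None:
                        continue
                    rows.append({"subject_id": sid, "eye": eye,
                                 "vessel_class": cls, "metric": metric,
                                 "value_test": vt, "value_retest": vr})
    return pd.DataFrame(rows), info


# ---------------------------------------------------------------------------
# table-level stability simulation (for power / type-I studies)
# ---------------------------------------------------------------------------

def simulate_stability_pvalue(n_subjects: int = 44,
                              noise_ratio: float = 1.0,
                              base_noise_sd: float = 0.05,
                              between_sd: float = 0.4,
                              seed: int = 0) -> float:
    """One simulated two-metric stability comparison; returns the one-sided p.

    Subjects get lognormal true tortuosity levels; metric A's test/retest
    values carry measurement noise of sd ``base_noise_sd`` and metric B's
    noise is ``noise_ratio`` times larger. The full protocol (per-metric
    Box-Cox z-scores of the pooled values, absolute z-score difference per
    subject, paired one-sided t-test of "A more stable than B") is applied.
    With noise_ratio = 1 the null holds.
    """
    from .stats import boxcox_zscores, paired_onesided_ttest

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    truth = np.exp(rng.normal(0.0, between_sd, size=n_subjects))
    # multiplicative (lognormal) measurement noise keeps values positive,
    # as tortuosity metrics are
    a_test = truth * np.exp(rng.normal(0.0, base_noise_sd, n_subjects))
    a_retest = truth * np.exp(rng.normal(0.0, base_noise_sd, n_subjects))
    b_test = truth * np.exp(rng.normal(0.0, base_noise_sd * noise_ratio, n_subjects))
    b_retest = truth * np.exp(rng.normal(0.0, base_noise_sd * noise_ratio, n_subjects))
    _, z_a = boxcox_zscores(np.concatenate([a_test, a_retest]))
    _, z_b = boxcox_zscores(np.concatenate([b_test, b_retest]))
    dz_a = np.abs(z_a[:n_subjects] - z_a[n_subjects:])
    dz_b = np.abs(z_b[:n_subjects] - z_b[n_subjects:])
    _, p = paired_onesided_ttest(dz_a, dz_b)
    return p
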