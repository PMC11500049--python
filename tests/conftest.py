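import numpy as np
import pytest

from vesseltort import CurveSpec, PlanarCurve, make_curve, resample_smooth


@pytest.fixture
def line_curve():
    """Analytic straight line, 200 px, unit spacing."""
    curve, _ = make_curve(CurveSpec(family="line", length=200.0, spacing=1.0))
    return curve


def circle_curve(radius, span=2 * np.pi, spacing=0.2, closed=False):
    theta = np.arange(0.0, span, spacing / radius)
    if not closed:
        theta = np.linspace(0.0, span, max(len(theta), 16))
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return PlanarCurve(pts, dedupe=True)


def sinusoid_curve(amplitude, wavelength=2 * np.pi, n_half=2, spacing=0.05):
    curve, truth = make_curve(CurveSpec(
        family="sinusoid", amplitude=amplitude, wavelength=wavelength,
        n_half_periods=n_half, spacing=spacing))
    return curve, truth


def random_smooth_curve(seed, n_terms=4, length=150.0, spacing=1.0,
                        sigma=2.0):
    """Seeded random low-frequency Fourier curve, pipeline-processed.

    Smooth by construction (few low-frequency terms, gentle amplitudes) so
    curvature is well resolved at the default spacing.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length, 0.5)
    y = np.zeros_like(x)
    for k in range(1, n_terms + 1):
        amp = rng.uniform(0.5, 3.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        y += amp * np.sin(2 * np.pi * k * x / length + phase)
    curve = PlanarCurve(np.column_stack([x, y]))
    return resample_smooth(curve, spacing_px=spacing, sigma_px=sigma)
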