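"""Independent naive re-implementations used as oracles.

Coded as plain loops directly from the mathematical definitions; they stay
independent of the (vectorized) library code paths they are used to check.
"""

import numpy as np

from vesseltort.geometry import curvature, derivatives, find_inflections


def nonuniform_gradient(y, x):
    """Second-order finite differences on a possibly nonuniform grid."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    out = np.empty(n)
    out[0] = (y[1] - y[0]) / (x[1] - x[0])
    out[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    for j in range(1, n - 1):
        hs = x[j] - x[j - 1]
        hd = x[j + 1] - x[j]
        out[j] = (hs ** 2 * y[j + 1] + (hd ** 2 - hs ** 2) * y[j]
                  - hd ** 2 * y[j - 1]) / (hs * hd * (hd + hs))
    return out


def window_bounds(curve, window_px):
    total = curve.length
    n_full = int(total // window_px)
    rem = total - n_full * window_px
    n_win = max(n_full + (1 if rem >= window_px / 2 else 0), 1)
    s = curve.cumulative_arclength
    targets = np.linspace(0.0, total, n_win + 1)
    idx = []
    for t in targets:
        idx.append(int(np.argmin(np.abs(s - t))))
    idx[0], idx[-1] = 0, len(s) - 1
    return sorted(set(idx))


def naive_arc_over_chord(curve, window_px=50.0):
    bounds = window_bounds(curve, window_px)
    num = den = 0.0
    for k in range(len(bounds) - 1):
        i0, i1 = bounds[k], bounds[k + 1]
        arc = 0.0
        for j in range(i0, i1):
            arc += float(np.hypot(*(curve.points[j + 1] - curve.points[j])))
        chord = float(np.hypot(*(curve.points[i1] - curve.points[i0])))
        num += arc * (arc / chord)
        den += arc
    return num / den


def piece_arcs_chords(curve, partition):
    s = curve.cumulative_arclength
    idx = list(partition.breakpoint_indices)
    arcs = [float(s[idx[k + 1]] - s[idx[k]]) for k in range(len(idx) - 1)]
    chords = [float(np.hypot(*(curve.points[idx[k + 1]] - curve.points[idx[k]])))
              for k in range(len(idx) - 1)]
    return arcs, chords


def naive_distance_tortuosity(curve, partition):
    arcs, chords = piece_arcs_chords(curve, partition)
    num = sum(a * (a / c) for a, c in zip(arcs, chords))
    return num / sum(arcs)


def naive_angle_tortuosity(curve, partition):
    idx = list(partition.breakpoint_indices)
    s = curve.cumulative_arclength
    num = den = 0.0
    for k in range(len(idx) - 1):
        i0, i1 = int(idx[k]), int(idx[k + 1])
        s_mid = (s[i0] + s[i1]) / 2.0
        mid = np.array([np.interp(s_mid, s, curve.points[:, 0]),
                        np.interp(s_mid, s, curve.points[:, 1])])
        a = curve.points[i0] - mid
        b = curve.points[i1] - mid
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-9 or nb < 1e-9:
            continue
        dtheta = np.pi - np.arccos(np.clip(np.dot(a, b) / (na * nb), -1, 1))
        length = float(partition.piece_lengths[k])
        num += length * dtheta
        den += length
    return num / den


def naive_tortuosity_density(curve, partition):
    n = partition.n_pieces
    if n <= 1:
        return 0.0
    arcs, chords = piece_arcs_chords(curve, partition)
    return ((n - 1) / n) * sum(a / c - 1.0 for a, c in zip(arcs, chords)) \
        / sum(chords)


def naive_squared_curvature(curve, power=2):
    kappa = naive_curvature(curve)
    s = curve.cumulative_arclength
    total = 0.0
    for j in range(len(s) - 1):
        f0 = abs(kappa[j]) ** power
        f1 = abs(kappa[j + 1]) ** power
        total += 0.5 * (f0 + f1) * (s[j + 1] - s[j])
    return total


def naive_inverse_radius(curve):
    kappa = naive_curvature(curve)
    return float(np.mean(np.abs(kappa)))


def naive_curvature(curve):
    s = curve.cumulative_arclength
    x1 = nonuniform_gradient(curve.points[:, 0], s)
    y1 = nonuniform_gradient(curve.points[:, 1], s)
    x2 = nonuniform_gradient(x1, s)
    y2 = nonuniform_gradient(y1, s)
    return (x1 * y2 - x2 * y1) / (x1 ** 2 + y1 ** 2) ** 1.5


def naive_vci(curve, w=5, smoothing_sigma=4.0):
    from vesseltort.geometry import PlanarCurve, smooth_points

    if smoothing_sigma > 0:
        curve = PlanarCurve(smooth_points(curve.points, smoothing_sigma))
    s = curve.cumulative_arclength
    x1 = nonuniform_gradient(curve.points[:, 0], s)
    y1 = nonuniform_gradient(curve.points[:, 1], s)
    speed = np.hypot(x1, y1)
    vx, vy = x1 / speed, y1 / speed
    n = len(curve.points)
    contributions = []
    for i in range(w, n - w):
        lo, hi = i - w, i + w
        origin = (curve.points[lo] + curve.points[hi]) / 2.0
        L = []
        for j in range(lo, hi + 1):
            rx, ry = curve.points[j] - origin
            L.append(rx * vy[j] - ry * vx[j])
        dL = nonuniform_gradient(L, s[lo:hi + 1])
        contributions.append(float(np.mean(np.abs(dL))))
    return float(np.mean(contributions))


def naive_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))


def average_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def naive_spearman(x, y):
    return naive_pearson(average_ranks(x), average_ranks(y))


def naive_skewness(v):
    v = np.asarray(v, float)
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    m3 = np.mean((v - m) ** 3)
    return float(m3 / m2 ** 1.5)


def naive_paired_t(a, b):
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    sd = np.sqrt(np.sum((d - d.mean()) ** 2) / (n - 1))
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), float(tdist.cdf(t, n - 1))
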