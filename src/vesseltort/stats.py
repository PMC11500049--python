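"""Test-retest reliability statistics for tortuosity metrics.

Implements the reliability protocol used to compare tortuosity metrics on a
paired test/retest cohort: Pearson and Spearman retest correlations per
metric and vessel class, paired one-sided t-tests on Box-Cox-transformed
z-scores of absolute test-retest differences, Fisher-Pearson skewness
diagnostics, and cross-metric correlation matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .errors import InvalidInputError, ZeroVarianceError
from .metrics import METRIC_NAMES

CLASSES = ("arteries", "veins", "vessels")

_REQUIRED_COLS = ("subject_id", "eye", "vessel_class", "metric",
                  "value_test", "value_retest")


@dataclass
class RetestDataset:
    """Long-format paired test/retest measurements.

    One row per (subject, eye, vessel_class, metric) with the value from
    each imaging session. Mirrors a repeated-acquisition design where both
    eyes are photographed twice within minutes.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _REQUIRED_COLS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"missing columns: {missing}")
        if len(df) == 0:
            raise InvalidInputError("empty retest dataset")
        if not np.isfinite(df["value_test"]).all() or \
                not np.isfinite(df["value_retest"]).all():
            raise InvalidInputError("non-finite measurement values")
        key = ["subject_id", "eye", "vessel_class", "metric"]
        if df.duplicated(subset=key).any():
            raise InvalidInputError("duplicate (subject, eye, class, metric) rows")

    @classmethod
    def from_csv(cls, path) -> "RetestDataset":
        df = pd.read_csv(path)
        return cls(df)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def metrics(self) -> list[str]:
        present = self.records["metric"].unique().tolist()
        return [m for m in METRIC_NAMES if m in present] + \
               [m for m in present if m not in METRIC_NAMES]


@dataclass
class ReliabilityReport:
    """All reliability analyses for one cohort.

    ``retest_pearson``/``retest_spearman``: DataFrames indexed by metric with
    one column per vessel class. ``pairwise_ttest``: one row per ordered
    metric pair (t statistic, one-sided p, Box-Cox lambdas). ``skewness``:
    per-metric Fisher-Pearson g1. ``cross_metric_*``: square correlation
    matrices over metrics (test-session values).
    """

    retest_pearson: pd.DataFrame
    retest_spearman: pd.DataFrame
    pairwise_ttest: pd.DataFrame
    skewness: pd.Series
    cross_metric_pearson: pd.DataFrame
    cross_metric_spearman: pd.DataFrame
    boxcox_lambdas: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "retest_pearson": _df_to_dict(self.retest_pearson),
            "retest_spearman": _df_to_dict(self.retest_spearman),
            "pairwise_ttest": self.pairwise_ttest.to_dict(orient="records"),
            "skewness": {k: _nan_to_none(v) for k, v in self.skewness.items()},
            "cross_metric_pearson": _df_to_dict(self.cross_metric_pearson),
            "cross_metric_spearman": _df_to_dict(self.cross_metric_spearman),
            "boxcox_lambdas": self.boxcox_lambdas,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _nan_to_none(v):
    return None if (v is None or (isinstance(v, float) and np.isnan(v))) else float(v)

def _df_to_dict(df: pd.DataFrame) -> dict:
    return {str(r): {str(c): _nan_to_none(df.loc[r, c]) for c in df.columns}
            for r in df.index}


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise InvalidInputError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation; ties receive average ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise InvalidInputError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def fisher_pearson_skewness(values, adjusted: bool = False) -> float:
    """Fisher-Pearson coefficient of skewness g1 = m3 / m2^(3/2).

    Population (biased) form by default; ``adjusted=True`` applies the
    sample-size correction factor.
    """
    v = np.asarray(values, float)
    if len(v) < 3:
        raise InvalidInputError("skewness needs at least 3 values")
    if np.allclose(v, v[0]):
        raise ZeroVarianceError("skewness undefined for constant input")
    return float(sps.skew(v, bias=not adjusted))


def boxcox_zscores(differences, shift_zeros: bool = True,
                   lam_bounds: Tuple[float, float] = (-5.0, 5.0),
                   ) -> Tuple[float, np.ndarray]:
    """Box-Cox transform positive values and standardize to z-scores.

    lambda maximizes the Box-Cox profile log-likelihood on ``lam_bounds``.
    Zero values are shifted up by half the smallest positive value when
    ``shift_zeros`` is enabled (the transform requires positive inputs);
    negative values are always an error.

    Returns (lambda, z-scores with mean 0 and sd 1).
    """
    d = np.asarray(differences, float)
    if len(d) < 5:
        raise InvalidInputError("Box-Cox needs at least 5 values")
    if (d < 0).any():
        raise InvalidInputError("Box-Cox requires nonnegative inputs")
    if (d == 0).any():
        if not shift_zeros:
            raise InvalidInputError("zero values present and shift policy disabled")
        pos = d[d > 0]
        if len(pos) == 0:
            raise ZeroVarianceError("all differences are zero")
        d = d + pos.min() / 2.0
    if np.allclose(d, d[0]):
        raise ZeroVarianceError("no variance in differences")
    res = optimize.minimize_scalar(
        lambda lam: -sps.boxcox_llf(lam, d),
        bounds=lam_bounds, method="bounded")
    lam = float(res.x)
    t = special.boxcox(d, lam)
    sd = t.std()
    if sd == 0:
        raise ZeroVarianceError("transformed values have no variance")
    return lam, (t - t.mean()) / sd


def paired_onesided_ttest(z_a, z_b) -> Tuple[float, float]:
    """Paired one-sided t-test for "A more stable than B".

    t is computed on the paired differences z_a - z_b with df = n - 1; the
    one-sided p-value is P(T <= t) under the null, i.e. small p supports the
    alternative that A's (transformed absolute) test-retest differences are
    smaller than B's.
    """
    a = np.asarray(z_a, float)
    b = np.asarray(z_b, float)
    if len(a) != len(b):
        raise InvalidInputError("paired t-test needs equal-length inputs")
    if len(a) < 3:
        raise InvalidInputError("paired t-test needs at least 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, 0.5  # exact tie: no evidence either way
        raise ZeroVarianceError("zero variance of paired differences")
    n = len(diff)
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(sps.t.cdf(t, df=n - 1))
    return float(t), p


# ---------------------------------------------------------------------------
# cohort-level analyses
# ---------------------------------------------------------------------------

def retest_correlations(data: RetestDataset,
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson and Spearman test-retest correlation per (metric, class)."""
    metrics = data.metrics()
    pear = pd.DataFrame(index=metrics, columns=list(CLASSES), dtype=float)
    spear = pd.DataFrame(index=metrics, columns=list(CLASSES), dtype=float)
    for m in metrics:
        for cls in CLASSES:
            sub = data.records.query(
                "metric == @m and vessel_class == @cls")
            if len(sub) < 3:
                continue
            try:
                pear.loc[m, cls] = pearson(sub["value_test"], sub["value_retest"])
                spear.loc[m, cls] = spearman(sub["value_test"], sub["value_retest"])
            except ZeroVarianceError:
                warnings.warn(
                    f"retest correlation undefined for ({m}, {cls}): "
                    "constant column", stacklevel=2)
    return pear, spear


def absolute_zscore_differences(data: RetestDataset,
                                vessel_class: str = "vessels",
                                shift_zeros: bool = True,
                                ) -> tuple[pd.DataFrame, Dict[str, float]]:
    """Per metric: |z_test - z_retest| on the Box-Cox z-score scale.

    Each metric's test and retest values are pooled, Box-Cox transformed
    with a per-metric lambda and standardized, and the absolute difference
    between the two sessions' z-scores is taken per (subject, eye). The
    z-score scale makes the absolute differences comparable across metrics
    with entirely different units and spreads.

    Returns (table indexed by (subject, eye) with one column per metric,
    per-metric lambdas).
    """
    sub = data.records[data.records["vessel_class"] == vessel_class]
    wide_t = sub.pivot_table(index=["subject_id", "eye"], columns="metric",
                             values="value_test").dropna()
    wide_r = sub.pivot_table(index=["subject_id", "eye"], columns="metric",
                             values="value_retest").dropna()
    common = wide_t.index.intersection(wide_r.index)
    wide_t, wide_r = wide_t.loc[common], wide_r.loc[common]
    metrics = [m for m in data.metrics() if m in wide_t.columns]
    out = pd.DataFrame(index=common)
    lambdas: Dict[str, float] = {}
    n = len(common)
    for m in metrics:
        pooled = np.concatenate([wide_t[m].to_numpy(), wide_r[m].to_numpy()])
        lam, z = boxcox_zscores(pooled, shift_zeros=shift_zeros)
        lambdas[m] = lam
        out[m] = np.abs(z[:n] - z[n:])
    return out, lambdas


def pairwise_stability_ttests(data: RetestDataset,
                              vessel_class: str = "vessels",
                              shift_zeros: bool = True,
                              holm: bool = False) -> tuple[pd.DataFrame, Dict[str, float]]:
    """One-sided paired t-tests of Box-Cox z-score |test - retest| gaps.

    For every ordered metric pair (A, B), the paired one-sided test asks
    whether A's absolute test-retest differences — measured on each
    metric's own Box-Cox z-score scale, see
    :func:`absolute_zscore_differences` — are smaller than B's, i.e.
    whether A is more retest-stable. Raw p-values by default; ``holm=True``
    adds Holm-adjusted p-values.
    """
    wide, lambdas = absolute_zscore_differences(
        data, vessel_class=vessel_class, shift_zeros=shift_zeros)
    metrics = list(wide.columns)
    rows = []
    for a in metrics:
        for b in metrics:
            if a == b:
                continue
            try:
                t, p = paired_onesided_ttest(wide[a], wide[b])
            except ZeroVarianceError:
                t, p = np.nan, np.nan
            rows.append({"metric_a": a, "metric_b": b, "t": t, "p": p,
                         "lambda_a": lambdas[a], "lambda_b": lambdas[b],
                         "n": len(wide)})
    table = pd.DataFrame(rows)
    if holm and len(table):
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[i])
            adj[i] = min(running, 1.0)
        table["p_holm"] = adj
    return table, lambdas


def skewness_by_metric(data: RetestDataset,
                       vessel_class: str = "vessels") -> pd.Series:
    """Fisher-Pearson skewness of each metric's test-session distribution."""
    sub = data.records[data.records["vessel_class"] == vessel_class]
    out = {}
    for m in data.metrics():
        vals = sub.loc[sub["metric"] == m, "value_test"].to_numpy()
        try:
            out[m] = fisher_pearson_skewness(vals)
        except (InvalidInputError, ZeroVarianceError):
            out[m] = np.nan
    return pd.Series(out, name="skewness")


def cross_metric_correlations(data: RetestDataset,
                              vessel_class: str = "vessels",
                              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson/Spearman correlation matrices across metrics (test session)."""
    sub = data.records[data.records["vessel_class"] == vessel_class]
    wide = sub.pivot_table(index=["subject_id", "eye"], columns="metric",
                           values="value_test").dropna()
    metrics = [m for m in data.metrics() if m in wide.columns]
    wide = wide[metrics]
    constant = [m for m in metrics if np.std(wide[m]) == 0]
    if constant:
        warnings.warn(f"constant metric columns {constant}: correlations "
                      "reported as missing", stacklevel=2)
    pear = wide.corr(method="pearson")
    spear = wide.corr(method="spearman")
    for m in constant:
        pear.loc[m, :] = pear.loc[:, m] = np.nan
        spear.loc[m, :] = spear.loc[:, m] = np.nan
    for m in metrics:  # unit diagonal by convention, even for constants
        pear.loc[m, m] = spear.loc[m, m] = 1.0
    return pear, spear


def build_report(data: RetestDataset,
                 ttest_class: str = "vessels",
                 shift_zeros: bool = True,
                 holm: bool = False) -> ReliabilityReport:
    """Run the full reliability protocol on a paired cohort."""
    # row-order invariance: analyses operate on a canonically sorted copy
    df = data.records.sort_values(
        ["metric", "vessel_class", "subject_id", "eye"]).reset_index(drop=True)
    canon = RetestDataset(df)
    pear, spear = retest_correlations(canon)
    ttests, lambdas = pairwise_stability_ttests(
        canon, vessel_class=ttest_class, shift_zeros=shift_zeros, holm=holm)
    skew = skewness_by_metric(canon, vessel_class=ttest_class)
    xp, xs = cross_metric_correlations(canon, vessel_class=ttest_class)
    return ReliabilityReport(
        retest_pearson=pear, retest_spearman=spear, pairwise_ttest=ttests,
        skewness=skew, cross_metric_pearson=xp, cross_metric_spearman=xs,
        boxcox_lambdas=lambdas)
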