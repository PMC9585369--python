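"""Instar validation statistics.

Given a partition of larvae into putative instars, this module computes
the classical checks that the partition behaves like a true instar
series:

* per-instar per-feature summary statistics (n, mean, SD, observed
  range, CV);
* Brooks-Dyar indices — ratios of successive instar means.  Dyar's rule
  says sclerotized head structures grow geometrically between molts, so
  a valid series has roughly constant ratios;
* Crosby indices — the relative change between successive Brooks-Dyar
  indices; |C| below ~10% indicates no instar was missed or split;
* the Brooks-Dyar regression — OLS of ln(size) on instar number; its
  slope b gives the overall growth-rate constant e^b;
* size-frequency analysis — per-instar histograms and observed-range
  overlap between adjacent instars (a clean series has none);
* a PCA projection of the three features for visual separation.

Units: tables store cm; the regression is computed on mm (the scale on
which the published growth constants and intercepts live).  Noise
points (label 0) are excluded from every statistic.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FEATURE_COLUMNS, MeasurementTable
from .partition import NOISE, Partition

#: default Crosby acceptance threshold (|C| < 10%)
CROSBY_THRESHOLD = 0.10

#: default histogram bin widths (cm) per feature, about half the
#: smallest within-instar SD
DEFAULT_BIN_WIDTHS_CM: Mapping[str, float] = {
    "head_capsule_length_cm": 0.02,
    "head_capsule_width_cm": 0.02,
    "mandible_width_cm": 0.01,
}

CM_TO_MM = 10.0


@dataclasses.dataclass(frozen=True)
class InstarSummary:
    """Per-instar per-feature statistics — the machine twin of a
    classical instar table.

    ``table`` has a (feature, instar) MultiIndex and columns
    ``n, mean_cm, sd_cm, min_cm, max_cm, cv_pct, dyar_index,
    crosby_index``.  Dyar is defined from instar 2 on; Crosby from
    instar 3 on (it compares successive Dyar indices and is aligned
    with the later instar, matching the usual table layout).
    """

    table: pd.DataFrame

    @property
    def n_instars(self) -> int:
        return self.table.index.get_level_values("instar").nunique()

    def means(self, feature: str) -> np.ndarray:
        return self.table.loc[feature, "mean_cm"].to_numpy()

    def dyar(self, feature: str) -> np.ndarray:
        return self.table.loc[feature, "dyar_index"].dropna().to_numpy()

    def crosby(self, feature: str) -> np.ndarray:
        return self.table.loc[feature, "crosby_index"].dropna().to_numpy()


def summarize_instars(table: MeasurementTable,
                      partition: Partition) -> InstarSummary:
    """Summary statistics of every (instar, feature) cell.

    Instars are numbered 1..K by ascending mean of the first feature;
    noise points are excluded.  SD is the sample standard deviation
    (ddof=1, 0 for singleton groups); CV = 100 * SD / mean.
    """
    labels = partition.labels
    if (labels != NOISE).sum() == 0:
        raise ValueError("partition contains no non-noise specimens")
    X = table.features
    # order instars by ascending mean of feature 1
    uniq = sorted(
        (u for u in np.unique(labels) if u != NOISE),
        key=lambda u: X[labels == u, 0].mean(),
    )
    rows = []
    for fj, feature in enumerate(FEATURE_COLUMNS):
        means = []
        for rank, u in enumerate(uniq, start=1):
            vals = X[labels == u, fj]
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            means.append(mean)
            rows.append({
                "feature": feature, "instar": rank, "n": len(vals),
                "mean_cm": mean, "sd_cm": sd,
                "min_cm": vals.min(), "max_cm": vals.max(),
                "cv_pct": 100.0 * sd / mean,
                "dyar_index": np.nan, "crosby_index": np.nan,
            })
        means = np.asarray(means)
        if len(means) >= 2:
            dyar = brooks_dyar_indices(means)
            for i, b in enumerate(dyar):
                rows[-len(means) + 1 + i]["dyar_index"] = b
            if len(dyar) >= 2:
                crosby, _ = crosby_indices(dyar)
                for i, c in enumerate(crosby):
                    rows[-len(means) + 2 + i]["crosby_index"] = c
    frame = pd.DataFrame(rows).set_index(["feature", "instar"])
    return InstarSummary(frame)


def brooks_dyar_indices(means: Sequence[float]) -> np.ndarray:
    """Successive growth ratios ``mean[i+1] / mean[i]`` of instar means."""
    means = np.asarray(means, dtype=float)
    if len(means) < 2:
        raise ValueError("need at least 2 instar means")
    if (means <= 0).any():
        raise ValueError("means must be strictly positive")
    return means[1:] / means[:-1]


def crosby_indices(dyar: Sequence[float],
                   threshold: float = CROSBY_THRESHOLD
                   ) -> tuple[np.ndarray, bool]:
    """Relative change between successive Brooks-Dyar indices.

    ``C_i = (b_{i+1} - b_i) / b_i``.  The pass flag is true when every
    |C_i| is below ``threshold`` (default 10%), the usual criterion for
    a consistent instar series with no missing or split stage.
    """
    dyar = np.asarray(dyar, dtype=float)
    if len(dyar) < 2:
        raise ValueError("need at least 2 Brooks-Dyar indices")
    crosby = np.diff(dyar) / dyar[:-1]
    return crosby, bool((np.abs(crosby) < threshold).all())


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """Brooks-Dyar log-linear fit: ln(size in mm) on instar number."""

    feature: str
    slope: float
    intercept: float
    growth_rate: float           # e^slope
    r_squared: float
    rss: float
    df: int                      # n - 2
    p_value: float               # two-sided t-test on the slope
    n: int


def dyar_regression(table: MeasurementTable, partition: Partition,
                    feature: str) -> RegressionFit:
    """OLS of ln(measurement in mm) on instar number over all specimens.

    Instars are coded 1..K (smallest first); noise is excluded.  The
    exponential of the slope is the growth-rate constant, the overall
    geometric growth ratio of the series.
    """
    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}")
    labels = partition.labels
    keep = labels != NOISE
    if keep.sum() < 3:
        raise ValueError("need at least 3 non-noise specimens")
    if len(set(labels[keep])) < 2:
        raise ValueError("regression needs at least 2 instars")
    fj = FEATURE_COLUMNS.index(feature)
    x = labels[keep].astype(float)
    y = np.log(table.features[keep, fj] * CM_TO_MM)
    res = sps.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return RegressionFit(
        feature=feature,
        slope=float(res.slope),
        intercept=float(res.intercept),
        growth_rate=float(np.exp(res.slope)),
        r_squared=float(res.rvalue ** 2),
        rss=float((resid ** 2).sum()),
        df=int(len(x) - 2),
        p_value=float(res.pvalue),
        n=int(len(x)),
    )


@dataclasses.dataclass(frozen=True)
class FrequencyAnalysis:
    """Per-feature size-frequency histograms and adjacent-range overlap.

    ``histograms[feature]`` is ``(bin_edges, counts)`` with one count
    row per instar on a shared grid; ``overlaps_cm[feature]`` holds the
    overlap length of each adjacent instar pair's observed range
    (max(0, min of maxima - max of minima)); ``any_overlap`` is true if
    any pair overlaps — a clean instar series has none.
    """

    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    overlaps_cm: dict[str, np.ndarray]
    any_overlap: bool


def range_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Overlap length of two closed intervals (0 when disjoint)."""
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def frequency_analysis(table: MeasurementTable, partition: Partition,
                       bin_widths: Mapping[str, float] | None = None
                       ) -> FrequencyAnalysis:
    """Size-frequency distributions of each instar on a shared grid."""
    if bin_widths is None:
        bin_widths = DEFAULT_BIN_WIDTHS_CM
    labels = partition.labels
    keep = labels != NOISE
    if keep.sum() == 0:
        raise ValueError("partition contains no non-noise specimens")
    X = table.features
    instars = sorted(
        (u for u in np.unique(labels) if u != NOISE),
        key=lambda u: X[labels == u, 0].mean(),
    )
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    overlaps: dict[str, np.ndarray] = {}
    any_overlap = False
    for fj, feature in enumerate(FEATURE_COLUMNS):
        width = float(bin_widths.get(feature, 0.02))
        lo = X[keep, fj].min()
        hi = X[keep, fj].max()
        nbins = max(int(np.ceil((hi - lo) / width)), 1)
        edges = lo + width * np.arange(nbins + 1)
        counts = np.vstack([
            np.histogram(X[labels == u, fj], bins=edges)[0] for u in instars
        ])
        histograms[feature] = (edges, counts)
        ranges = [(X[labels == u, fj].min(), X[labels == u, fj].max())
                  for u in instars]
        ovl = np.array([
            range_overlap(ranges[i], ranges[i + 1])
            for i in range(len(ranges) - 1)
        ])
        overlaps[feature] = ovl
        if (ovl > 0).any():
            any_overlap = True
    return FrequencyAnalysis(histograms=histograms, overlaps_cm=overlaps,
                             any_overlap=any_overlap)


@dataclasses.dataclass(frozen=True)
class PcaProjection:
    """Scores on the top two principal axes of the centered features."""

    scores: np.ndarray                 # (n, 2)
    explained_variance_ratio: np.ndarray  # (2,)
    components: np.ndarray             # (2, n_features) loadings


def pca_projection(table) -> PcaProjection:
    """Project the 3 features onto their top 2 principal components.

    Eigen-decomposition of the feature covariance after centering (no
    scaling — the features share units).  Variance-explained fractions
    are eigenvalues over the total variance.
    """
    X = table.features if isinstance(table, MeasurementTable) \
        else np.asarray(table, dtype=float)
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 points")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = vals.sum()
    ratio = vals[:2] / total if total > 0 else np.zeros(2)
    # sign convention: largest-magnitude loading of each axis positive
    for j in range(2):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Xc @ vecs[:, :2]
    return PcaProjection(scores=scores, explained_variance_ratio=ratio,
                         components=vecs[:, :2].T)
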