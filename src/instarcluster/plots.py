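"""Diagnostic plots: reachability profile, k-NN knee, BIC curves,
size-frequency histograms, Brooks-Dyar regression, PCA scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .density import KnnDistanceProfile, OpticsResult
from .io import FEATURE_COLUMNS, MeasurementTable
from .partition import NOISE, Partition
from .stats import CM_TO_MM, FrequencyAnalysis, RegressionFit, PcaProjection


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def reachability_plot(res: OpticsResult, path: str | Path,
                      partition: Partition | None = None,
                      eps_cl: float | None = None) -> Path:
    """Reachability-distance vs visit order; valleys are clusters."""
    r = res.reachability_in_order.copy()
    finite = np.isfinite(r)
    top = r[finite].max() * 1.1 if finite.any() else 1.0
    r[~finite] = top
    colors = None
    if partition is not None:
        labels = partition.labels[res.order]
        cmap = plt.get_cmap("tab10")
        colors = [("0.6" if l == NOISE else cmap((l - 1) % 10))
                  for l in labels]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(np.arange(len(r)), r, width=1.0, color=colors or "C0")
    if eps_cl is not None:
        ax.axhline(eps_cl, color="k", ls="--", lw=1,
                   label=f"eps_cl = {eps_cl:.3g}")
        ax.legend()
    ax.set_xlabel("OPTICS order")
    ax.set_ylabel("reachability (cm)")
    return _save(fig, path)


def knn_plot(profile: KnnDistanceProfile, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.sorted_distances, lw=1.5)
    ax.axhline(profile.knee, color="k", ls="--", lw=1,
               label=f"knee = {profile.knee:.3g}")
    ax.set_xlabel("points (sorted)")
    ax.set_ylabel(f"{profile.k}-NN distance (cm)")
    ax.legend()
    return _save(fig, path)


def bic_plot(bic_table, path: str | Path) -> Path:
    """BIC vs number of components, one curve per covariance family."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for family in bic_table.columns:
        ax.plot(bic_table.index, bic_table[family], marker="o", ms=3,
                label=family)
    ax.set_xlabel("number of components")
    ax.set_ylabel("BIC (larger is better)")
    ax.legend(fontsize=7)
    return _save(fig, path)


def frequency_plot(freq: FrequencyAnalysis, path: str | Path) -> Path:
    fig, axes = plt.subplots(1, len(freq.histograms), figsize=(12, 3))
    for ax, (feature, (edges, counts)) in zip(np.atleast_1d(axes),
                                              freq.histograms.items()):
        bottom = np.zeros(len(edges) - 1)
        for i, row in enumerate(counts):
            ax.bar(edges[:-1], row, width=np.diff(edges), align="edge",
                   bottom=bottom, label=f"instar {i + 1}")
            bottom += row
        ax.set_title(feature.replace("_", " "), fontsize=8)
        ax.set_xlabel("cm")
    np.atleast_1d(axes)[0].set_ylabel("count")
    np.atleast_1d(axes)[-1].legend(fontsize=7)
    return _save(fig, path)


def regression_plot(table: MeasurementTable, partition: Partition,
                    fit: RegressionFit, path: str | Path) -> Path:
    keep = partition.labels != NOISE
    fj = FEATURE_COLUMNS.index(fit.feature)
    x = partition.labels[keep]
    y = np.log(table.features[keep, fj] * CM_TO_MM)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x + np.random.default_rng(0).uniform(-0.08, 0.08, len(x)),
               y, s=8, alpha=0.5)
    grid = np.linspace(x.min() - 0.3, x.max() + 0.3, 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, "k-",
            label=(f"y = {fit.slope:.3f}x + {fit.intercept:.3f}\n"
                   f"$R^2$ = {fit.r_squared:.3f}, "
                   f"$e^b$ = {fit.growth_rate:.3f}"))
    ax.set_xlabel("instar number")
    ax.set_ylabel(f"ln({fit.feature.replace('_cm', '')}, mm)")
    ax.legend(fontsize=8)
    return _save(fig, path)


def pca_plot(proj: PcaProjection, partition: Partition,
             path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("tab10")
    for label in np.unique(partition.labels):
        mask = partition.labels == label
        color = "0.6" if label == NOISE else cmap((label - 1) % 10)
        name = "noise" if label == NOISE else f"instar {label}"
        ax.scatter(proj.scores[mask, 0], proj.scores[mask, 1], s=10,
                   color=color, label=name)
    evr = proj.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend(fontsize=8)
    return _save(fig, path)
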