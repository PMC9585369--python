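"""Model-based clustering backends: k-means and Gaussian mixtures.

These are the comparative backends against which the density methods
are checked: Lloyd's k-means with multiple random restarts, and
Gaussian mixture models fitted by EM over six covariance families with
BIC model selection.

The covariance families are the orientation-free subset of the usual
model-based-clustering taxonomy (volume/shape axes only):

    =================  =====  =========================================
    family             code   covariance structure
    =================  =====  =========================================
    spherical-equal    EII    sigma^2 I, shared by all components
    spherical-varying  VII    sigma_k^2 I, per component
    diagonal-equal     EEI    diag(v), shared
    diagonal-varying   VVI    diag(v_k), per component
    full-equal         EEE    full Sigma, shared
    full-varying       VVV    full Sigma_k, per component (unconstrained)
    =================  =====  =========================================

BIC follows the maximize-me convention, BIC = 2 logL - m ln n, so the
best model has the *largest* BIC.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .io import MeasurementTable
from .partition import Partition, canonical_partition

COVARIANCE_FAMILIES: tuple[str, ...] = (
    "spherical-equal", "spherical-varying",
    "diagonal-equal", "diagonal-varying",
    "full-equal", "full-varying",
)

FAMILY_CODES = {
    "spherical-equal": "EII", "spherical-varying": "VII",
    "diagonal-equal": "EEI", "diagonal-varying": "VVI",
    "full-equal": "EEE", "full-varying": "VVV",
}

_COV_EIGENVALUE_FLOOR = 1e-10


def _as_features(table) -> np.ndarray:
    if isinstance(table, MeasurementTable):
        return table.features
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


# --------------------------------------------------------------------------
# k-means


@dataclasses.dataclass(frozen=True)
class KmeansFit:
    """Result of Lloyd's algorithm: best of ``n_starts`` restarts."""

    k: int
    centers: np.ndarray
    labels: np.ndarray           # 0-based component labels
    wss: float                   # within-cluster sum of squares
    n_iter: int
    seed: int
    wss_history: tuple[float, ...] = ()   # per-iteration WSS (non-increasing)


def kmeans(table, k: int, seed: int = 0, n_starts: int = 10,
           max_iter: int = 300) -> tuple[KmeansFit, Partition]:
    """Cluster into k groups minimizing within-cluster sum of squares.

    Runs Lloyd iterations to convergence (no label changes, or
    ``max_iter``) from ``n_starts`` random initializations (k distinct
    rows each) and keeps the lowest-WSS solution.  Empty clusters are
    repaired by reseeding the center at the point farthest from its
    current center.  WSS is non-increasing across iterations within a
    run.
    """
    X = _as_features(table)
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (k={k}, n={n})")
    rng = np.random.default_rng(seed)
    best: KmeansFit | None = None
    for _ in range(max(n_starts, 1)):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        history: list[float] = []
        for it in range(1, max_iter + 1):
            d2 = cdist(X, centers, metric="sqeuclidean")
            new_labels = d2.argmin(axis=1)
            reseeded: set[int] = set()
            for j in range(k):  # repair empty clusters
                if not (new_labels == j).any():
                    # farthest point from its center, one per empty cluster
                    gaps = d2[np.arange(n), new_labels].copy()
                    if reseeded:
                        gaps[list(reseeded)] = -np.inf
                    far = int(gaps.argmax())
                    reseeded.add(far)
                    centers[j] = X[far]
                    new_labels[far] = j
            if (new_labels == labels).all():
                break
            labels = new_labels
            history.append(float(((X - centers[labels]) ** 2).sum()))
            for j in range(k):
                centers[j] = X[labels == j].mean(axis=0)
        wss = float(((X - centers[labels]) ** 2).sum())
        history.append(wss)
        if best is None or wss < best.wss:
            best = KmeansFit(k=k, centers=centers.copy(), labels=labels.copy(),
                             wss=wss, n_iter=it, seed=seed,
                             wss_history=tuple(history))
    assert best is not None
    return best, canonical_partition(best.labels + 1, X)


# --------------------------------------------------------------------------
# Gaussian mixtures


@dataclasses.dataclass(frozen=True)
class GmmFit:
    """A fitted Gaussian mixture model.

    ``covariances`` is always stored as a (k, d, d) array regardless of
    family; ``bic = 2 logL - n_params ln(n)`` (larger is better).
    """

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    n_params: int
    bic: float
    n_iter: int
    converged: bool
    responsibilities: np.ndarray
    log_likelihood_history: tuple[float, ...] = ()

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment by maximum responsibility (ties: lower index)."""
        return self.responsibilities.argmax(axis=1)


def gmm_n_params(k: int, d: int, family: str) -> int:
    """Free-parameter count of a k-component mixture in d dimensions."""
    base = (k - 1) + k * d  # weights + means
    cov = {
        "spherical-equal": 1,
        "spherical-varying": k,
        "diagonal-equal": d,
        "diagonal-varying": k * d,
        "full-equal": d * (d + 1) // 2,
        "full-varying": k * d * (d + 1) // 2,
    }[family]
    return base + cov


def _floor_covariance(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, _COV_EIGENVALUE_FLOOR)
    return (vecs * vals) @ vecs.T


def _m_step_covariances(X, resp, means, nk, family) -> np.ndarray:
    n, d = X.shape
    k = means.shape[0]
    scatter = np.empty((k, d, d))
    for j in range(k):
        diff = X - means[j]
        scatter[j] = (resp[:, j, None] * diff).T @ diff / nk[j]
    if family == "full-varying":
        covs = scatter
    elif family == "full-equal":
        pooled = np.tensordot(nk, scatter, axes=1) / n
        covs = np.repeat(pooled[None], k, axis=0)
    else:
        variances = np.einsum("kii->ki", scatter)  # per-component diagonals
        if family == "diagonal-equal":
            variances = np.repeat((nk @ variances / n)[None], k, axis=0)
        elif family == "spherical-varying":
            variances = np.repeat(variances.mean(axis=1, keepdims=True), d,
                                  axis=1)
        elif family == "spherical-equal":
            variances = np.full((k, d), (nk @ variances.mean(axis=1)) / n)
        covs = np.zeros((k, d, d))
        for j in range(k):
            np.fill_diagonal(covs[j], variances[j])
    return np.array([_floor_covariance(c) for c in covs])


def _log_gaussian(X: np.ndarray, mean: np.ndarray,
                  cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    z = solve_triangular(chol, (X - mean).T, lower=True)
    maha = (z ** 2).sum(axis=0)
    log_det = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det + maha)


def gmm_em(table, k: int, family: str = "full-varying", seed: int = 0,
           n_starts: int = 3, max_iter: int = 500,
           tol: float = 1e-8) -> GmmFit:
    """Fit a k-component Gaussian mixture by EM.

    Initialization is the best-of-``n_starts`` k-means solution (hard
    responsibilities followed by an M-step).  Iterates until the
    relative log-likelihood change falls below ``tol`` or ``max_iter``
    is reached; the log-likelihood is non-decreasing across iterations.
    Covariance eigenvalues are floored at 1e-10, which also handles
    degenerate (zero-variance) inputs.
    """
    if family not in COVARIANCE_FAMILIES:
        raise ValueError(
            f"unknown family {family!r}; choose one of {COVARIANCE_FAMILIES}")
    X = _as_features(table)
    n, d = X.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (k={k}, n={n})")
    m = gmm_n_params(k, d, family)

    fit, _ = kmeans(X, k, seed=seed, n_starts=n_starts, max_iter=100)
    resp = np.zeros((n, k))
    resp[np.arange(n), fit.labels] = 1.0

    log_lik = -np.inf
    converged = False
    ll_history: list[float] = []
    for it in range(1, max_iter + 1):
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = _m_step_covariances(X, resp, means, nk, family)
        log_prob = np.empty((n, k))
        for j in range(k):
            log_prob[:, j] = np.log(weights[j]) + _log_gaussian(
                X, means[j], covs[j])
        norm = logsumexp(log_prob, axis=1)
        new_log_lik = float(norm.sum())
        ll_history.append(new_log_lik)
        resp = np.exp(log_prob - norm[:, None])
        if new_log_lik + 1e-9 * max(1.0, abs(new_log_lik)) < log_lik:
            raise AssertionError(
                f"EM log-likelihood decreased: {log_lik} -> {new_log_lik}")
        if np.isfinite(log_lik) and (
                abs(new_log_lik - log_lik)
                <= tol * max(1.0, abs(new_log_lik))):
            log_lik = new_log_lik
            converged = True
            break
        log_lik = new_log_lik

    bic = 2.0 * log_lik - m * np.log(n)
    return GmmFit(
        k=k, family=family, weights=weights, means=means, covariances=covs,
        log_likelihood=log_lik, n_params=m, bic=float(bic), n_iter=it,
        converged=converged, responsibilities=resp,
        log_likelihood_history=tuple(ll_history),
    )


@dataclasses.dataclass(frozen=True)
class BicSelection:
    """BIC model-selection scan over (k, family) pairs."""

    table: pd.DataFrame          # index k, columns family, values BIC
    best: GmmFit
    partition: Partition


def bic_select(table, k_range: Sequence[int] = range(1, 10),
               families: Sequence[str] = COVARIANCE_FAMILIES,
               seed: int = 0) -> BicSelection:
    """Fit every (k, family) pair and keep the largest-BIC model.

    Failed fits (singular covariances, k too large for the family)
    appear as NaN in the BIC table; the scan fails only if every fit
    fails.  The returned partition is the best model's hard assignment.
    """
    k_range = list(k_range)
    families = list(families)
    if not k_range or not families:
        raise ValueError("k_range and families must be non-empty")
    X = _as_features(table)
    bic_table = pd.DataFrame(np.nan, index=k_range, columns=families)
    bic_table.index.name = "k"
    best: GmmFit | None = None
    for k in k_range:
        for family in families:
            try:
                fit = gmm_em(X, k, family=family, seed=seed)
            except (np.linalg.LinAlgError, ValueError, FloatingPointError):
                continue
            bic_table.loc[k, family] = fit.bic
            if best is None or fit.bic > best.bic:
                best = fit
    if best is None:
        raise RuntimeError("all mixture fits failed")
    partition = canonical_partition(best.labels + 1, X)
    return BicSelection(table=bic_table, best=best, partition=partition)
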