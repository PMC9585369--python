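"""Synthetic larval morphometric tables with geometric instar growth.

The generator emulates a measurement campaign on *Tuta absoluta*
(tomato leafminer) larvae: 240 specimens across four instars, each
specimen described by head capsule length, head capsule width and
mandible width in cm.  Per-instar feature means follow Dyar's rule —
roughly geometric growth with ratio 1.44–1.72 between successive
instars — with within-instar coefficients of variation of about 4–10%
and non-overlapping per-instar size ranges.

Each instar's feature vector is drawn from a truncated trivariate
normal distribution: means and SDs come from the reference statistics
below, the three features share a constant pairwise correlation
(default 0.8 — larger larvae have jointly larger heads and mandibles),
and draws falling outside the per-instar per-feature range are
resampled rather than clipped, so no probability mass piles up at the
interval endpoints.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import FEATURE_COLUMNS, MeasurementTable
from .partition import Partition, canonical_partition

# Reference per-instar statistics for T. absoluta larvae reared on tomato.
# Feature order matches FEATURE_COLUMNS: head capsule length, head capsule
# width, mandible width; one row per instar (1..4); units cm, CV in %.
REFERENCE_GROUP_SIZES: tuple[int, ...] = (69, 42, 35, 94)

REFERENCE_MEANS_CM = np.array([
    [0.123, 0.190, 0.089],
    [0.212, 0.304, 0.145],
    [0.339, 0.492, 0.231],
    [0.532, 0.736, 0.332],
])

REFERENCE_CVS_PCT = np.array([
    [9.683, 5.227, 9.300],
    [9.997, 5.739, 6.716],
    [4.741, 5.093, 5.294],
    [7.464, 4.410, 5.724],
])

REFERENCE_RANGES_CM = np.array([
    [[0.098, 0.148], [0.173, 0.216], [0.069, 0.113]],
    [[0.160, 0.254], [0.271, 0.340], [0.128, 0.168]],
    [[0.308, 0.371], [0.448, 0.554], [0.202, 0.254]],
    [[0.448, 0.610], [0.670, 0.811], [0.283, 0.374]],
])


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic instar-table generator.

    Defaults reproduce the reference study conditions: 4 instars,
    group sizes (69, 42, 35, 94), the reference means/CVs/ranges and an
    inter-feature correlation of 0.8.

    Parameters
    ----------
    group_sizes
        Specimens per instar; ``n_instars`` is its length.
    feature_means_cm, feature_cvs_pct
        (n_instars, 3) arrays; SD is derived as ``cv/100 * mean``.
        Within each feature the per-instar means must be strictly
        increasing (instars grow).
    inter_feature_correlation
        Constant pairwise correlation rho in [0, 1) among the three
        features within an instar.
    truncation_cm
        Optional (n_instars, 3, 2) array of (min, max) bounds per instar
        and feature; draws outside are resampled.  ``None`` disables
        truncation.
    """

    group_sizes: tuple[int, ...] = REFERENCE_GROUP_SIZES
    feature_means_cm: np.ndarray = dataclasses.field(
        default_factory=lambda: REFERENCE_MEANS_CM.copy())
    feature_cvs_pct: np.ndarray = dataclasses.field(
        default_factory=lambda: REFERENCE_CVS_PCT.copy())
    inter_feature_correlation: float = 0.8
    truncation_cm: np.ndarray | None = dataclasses.field(
        default_factory=lambda: REFERENCE_RANGES_CM.copy())
    seed: int = 0

    @property
    def n_instars(self) -> int:
        return len(self.group_sizes)

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        self.feature_means_cm = np.asarray(self.feature_means_cm, dtype=float)
        self.feature_cvs_pct = np.asarray(self.feature_cvs_pct, dtype=float)
        k, d = self.n_instars, len(FEATURE_COLUMNS)
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.feature_means_cm.shape != (k, d):
            raise ValueError(
                f"feature_means_cm must have shape {(k, d)}, "
                f"got {self.feature_means_cm.shape}")
        if self.feature_cvs_pct.shape != (k, d):
            raise ValueError(
                f"feature_cvs_pct must have shape {(k, d)}, "
                f"got {self.feature_cvs_pct.shape}")
        if (self.feature_means_cm <= 0).any():
            raise ValueError("feature means must be strictly positive")
        if (self.feature_cvs_pct < 0).any():
            raise ValueError("CVs must be nonnegative")
        if k > 1 and not (np.diff(self.feature_means_cm, axis=0) > 0).all():
            raise ValueError(
                "per-instar means must be strictly increasing within "
                "each feature")
        rho = self.inter_feature_correlation
        if not (0.0 <= rho < 1.0):
            raise ValueError("inter_feature_correlation must be in [0, 1)")
        if self.truncation_cm is not None:
            self.truncation_cm = np.asarray(self.truncation_cm, dtype=float)
            if self.truncation_cm.shape != (k, d, 2):
                raise ValueError(
                    f"truncation_cm must have shape {(k, d, 2)}, "
                    f"got {self.truncation_cm.shape}")
            lo = self.truncation_cm[..., 0]
            hi = self.truncation_cm[..., 1]
            if (hi - lo < 1e-12).any():
                raise ValueError("infeasible truncation: empty interval")
            inside = (lo <= self.feature_means_cm) & (self.feature_means_cm <= hi)
            if not inside.all():
                raise ValueError(
                    "truncation intervals must contain their means")

    @property
    def feature_sds_cm(self) -> np.ndarray:
        return self.feature_cvs_pct / 100.0 * self.feature_means_cm

    def to_dict(self) -> dict:
        return {
            "group_sizes": list(self.group_sizes),
            "feature_means_cm": self.feature_means_cm.tolist(),
            "feature_cvs_pct": self.feature_cvs_pct.tolist(),
            "inter_feature_correlation": self.inter_feature_correlation,
            "truncation_cm": (None if self.truncation_cm is None
                              else self.truncation_cm.tolist()),
            "seed": int(self.seed),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


_MAX_RESAMPLE_ROUNDS = 1000


def generate_instar_dataset(config: GeneratorConfig) -> MeasurementTable:
    """Draw a measurement table from the configured instar mixture.

    Each instar contributes ``group_sizes[i]`` rows drawn i.i.d. from a
    trivariate normal with the instar's mean vector, per-feature SDs of
    ``cv/100 * mean`` and constant pairwise correlation rho; rows with
    any feature outside the truncation interval are redrawn.  The true
    instar label is recorded per row.  Bit-identical output for equal
    config + seed.
    """
    rng = np.random.default_rng(config.seed)
    d = len(FEATURE_COLUMNS)
    rho = config.inter_feature_correlation
    corr = np.full((d, d), rho)
    np.fill_diagonal(corr, 1.0)
    blocks: list[np.ndarray] = []
    labels: list[int] = []
    for i, size in enumerate(config.group_sizes):
        mu = config.feature_means_cm[i]
        sd = config.feature_sds_cm[i]
        cov = corr * np.outer(sd, sd)
        bounds = (None if config.truncation_cm is None
                  else config.truncation_cm[i])
        block = _sample_truncated_mvn(rng, mu, cov, bounds, size)
        blocks.append(block)
        labels.extend([i + 1] * size)
    features = np.vstack(blocks)
    return MeasurementTable.from_arrays(features, instar=labels)


def _sample_truncated_mvn(rng, mu, cov, bounds, size):
    out = np.empty((size, len(mu)))
    need = np.arange(size)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        # "eigh" tolerates positive *semi*-definite covariances, so the
        # CV = 0 (zero-variance) degenerate case yields the mean exactly
        draw = rng.multivariate_normal(mu, cov, size=len(need),
                                       method="eigh")
        out[need] = draw
        if bounds is None:
            return out
        lo, hi = bounds[:, 0], bounds[:, 1]
        bad = ((out[need] < lo) | (out[need] > hi)).any(axis=1)
        need = need[bad]
        if len(need) == 0:
            return out
    raise RuntimeError(
        "truncation rejection sampling did not converge; the truncation "
        "interval carries too little probability mass")


def generated_truth(table: MeasurementTable) -> Partition:
    """The generator's true instar labels as a canonical Partition.

    The labels are data, not row order: a row-shuffled copy of the table
    yields the correspondingly shuffled partition.  Raises ``ValueError``
    if the table carries no instar column.
    """
    if not table.has_instar:
        raise ValueError("table carries no instar (truth) labels")
    return canonical_partition(table.instar, table.features)
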