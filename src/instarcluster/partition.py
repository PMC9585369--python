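"""Cluster partitions and partition-agreement metrics.

A :class:`Partition` is the common currency of all four clustering
backends: one integer label per specimen, where 0 marks noise and
1..K are clusters.  Labels are canonicalized so that cluster 1 has the
smallest mean of the first feature (head capsule length) — instar 1 is
always the smallest larvae, which makes instar numbering deterministic
and biologically ordered regardless of the backend's internal labeling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import comb

NOISE = 0


@dataclasses.dataclass(frozen=True)
class Partition:
    """Per-specimen cluster labels with a noise label of 0."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer array")
        if (labels < 0).any():
            raise ValueError("labels must be >= 0 (0 means noise)")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def is_noise(self) -> np.ndarray:
        return self.labels == NOISE

    def cluster_sizes(self) -> dict[int, int]:
        """Sizes of the non-noise clusters, keyed by label."""
        uniq, counts = np.unique(self.labels[self.labels != NOISE],
                                 return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    def sizes_in_label_order(self) -> tuple[int, ...]:
        sizes = self.cluster_sizes()
        return tuple(sizes[k] for k in sorted(sizes))


def canonical_partition(labels: np.ndarray, features: np.ndarray) -> Partition:
    """Relabel clusters 1..K by ascending cluster mean of the first feature.

    Noise (0) is preserved.  The result is invariant to any permutation
    of the input cluster labels, so every backend produces comparable
    partitions.
    """
    labels = np.asarray(labels, dtype=int)
    features = np.asarray(features, dtype=float)
    if len(labels) != len(features):
        raise ValueError("labels and features length mismatch")
    out = np.zeros_like(labels)
    uniq = [u for u in np.unique(labels) if u != NOISE]
    means = {u: features[labels == u, 0].mean() for u in uniq}
    for new, u in enumerate(sorted(uniq, key=lambda u: means[u]), start=1):
        out[labels == u] = new
    return Partition(out)


def adjusted_rand_index(a: np.ndarray | Partition,
                        b: np.ndarray | Partition) -> float:
    """Chance-corrected agreement between two partitions (ARI).

    Noise is treated as its own class.  Returns 1.0 for identical
    partitions (up to label permutation) and ~0 for independent ones.
    """
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if len(la) != len(lb):
        raise ValueError("partitions must have equal length")
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    contingency = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(contingency, (ia, ib), 1)
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(len(la), 2)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
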