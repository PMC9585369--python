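"""Reading, validating and writing larval morphometric measurement tables.

A measurement table holds one row per larval specimen with three
morphometric features, all in centimetres: head capsule length, head
capsule width and mandible width.  These are the standard sclerotized
structures used for instar classification because they do not grow
between molts.  An optional ``instar`` column carries a known (or
generated) instar label.

On disk a table is a plain comma-separated file with a header, UTF-8
encoded, dot decimal separator.  The canonical column names are

    specimen_id, head_capsule_length_cm, head_capsule_width_cm,
    mandible_width_cm[, instar]

``read_measurements`` accepts a ``column_map`` to adapt other headers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

FEATURE_COLUMNS: tuple[str, str, str] = (
    "head_capsule_length_cm",
    "head_capsule_width_cm",
    "mandible_width_cm",
)
ID_COLUMN = "specimen_id"
INSTAR_COLUMN = "instar"
CLUSTER_COLUMN = "cluster"

#: label used for noise / unclassified specimens in serialized partitions
NOISE_LABEL = 0


class MeasurementValidationError(ValueError):
    """Raised when a measurement table fails validation.

    ``problems`` is a list of human-readable diagnostics, each naming the
    offending row (0-based, excluding the header) and column where that
    makes sense.  Validation is total: every malformed row is reported,
    and no partially loaded table is ever returned.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid measurement table:\n  " + "\n  ".join(self.problems)
        )


@dataclasses.dataclass(frozen=True)
class MeasurementTable:
    """Validated per-specimen morphometric records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns.  All
    three feature values are strictly positive and finite and specimen
    ids are unique; these invariants are enforced at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        problems = _validate_frame(self.data)
        if problems:
            raise MeasurementValidationError(problems)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> np.ndarray:
        """(n, 3) float array of the features in canonical column order."""
        return self.data.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def specimen_ids(self) -> np.ndarray:
        return self.data[ID_COLUMN].to_numpy()

    @property
    def has_instar(self) -> bool:
        return INSTAR_COLUMN in self.data.columns

    @property
    def instar(self) -> np.ndarray:
        """True/assigned instar labels, if the table carries them."""
        if not self.has_instar:
            raise ValueError("table has no instar column")
        return self.data[INSTAR_COLUMN].to_numpy(dtype=int)

    def equals(self, other: "MeasurementTable", rtol: float = 1e-9) -> bool:
        if len(self) != len(other):
            return False
        if not np.array_equal(self.specimen_ids.astype(str),
                              other.specimen_ids.astype(str)):
            return False
        return bool(np.allclose(self.features, other.features, rtol=rtol))

    @classmethod
    def from_arrays(
        cls,
        features: np.ndarray,
        specimen_ids: Sequence | None = None,
        instar: Sequence[int] | None = None,
    ) -> "MeasurementTable":
        """Build a table from an (n, 3) feature array."""
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError(
                f"features must be (n, {len(FEATURE_COLUMNS)}), "
                f"got {features.shape}"
            )
        n = len(features)
        if specimen_ids is None:
            specimen_ids = [f"sp{i + 1:04d}" for i in range(n)]
        frame = pd.DataFrame({ID_COLUMN: list(specimen_ids)})
        for j, col in enumerate(FEATURE_COLUMNS):
            frame[col] = features[:, j]
        if instar is not None:
            frame[INSTAR_COLUMN] = np.asarray(instar, dtype=int)
        return cls(frame.reset_index(drop=True))


def _validate_frame(frame: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    for col in (ID_COLUMN, *FEATURE_COLUMNS):
        if col not in frame.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        return problems
    ids = frame[ID_COLUMN].astype(str)
    dupes = ids[ids.duplicated()].unique()
    for d in dupes:
        problems.append(f"duplicate specimen_id {d!r}")
    for col in FEATURE_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        for row in frame.index[values.isna()]:
            problems.append(f"row {row}: column {col!r} is not numeric")
        ok = values.notna()
        bad = ok & ~(np.isfinite(values.fillna(np.nan)) & (values > 0))
        for row in frame.index[bad]:
            problems.append(
                f"row {row}: column {col!r} must be strictly positive and "
                f"finite, got {frame.loc[row, col]!r}"
            )
    if INSTAR_COLUMN in frame.columns:
        inst = pd.to_numeric(frame[INSTAR_COLUMN], errors="coerce")
        bad = inst.isna() | (inst < 1) | (inst != inst.round())
        for row in frame.index[bad]:
            problems.append(
                f"row {row}: column 'instar' must be a positive integer, "
                f"got {frame.loc[row, INSTAR_COLUMN]!r}"
            )
    return problems


def read_measurements(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> MeasurementTable:
    """Read and validate a measurement CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping from canonical column name to the name used in
        the file, e.g. ``{"head_capsule_width_cm": "HCW"}``.  Unmapped
        canonical names are looked up directly.

    Raises
    ------
    FileNotFoundError
        if the file does not exist.
    MeasurementValidationError
        with row-indexed diagnostics for every malformed value; a
        partially loaded table is never returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={0: str})
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in rename if src not in raw.columns]
        if missing:
            raise MeasurementValidationError(
                [f"mapped column {m!r} not present in file" for m in missing]
            )
        raw = raw.rename(columns=rename)
    keep = [c for c in (ID_COLUMN, *FEATURE_COLUMNS, INSTAR_COLUMN)
            if c in raw.columns]
    if ID_COLUMN not in raw.columns and len(raw.columns) > 0:
        # no id column: synthesize stable row ids
        raw = raw.copy()
        raw[ID_COLUMN] = [f"sp{i + 1:04d}" for i in range(len(raw))]
        keep = [ID_COLUMN] + keep
    frame = raw.loc[:, keep].reset_index(drop=True)
    for col in FEATURE_COLUMNS:
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return MeasurementTable(frame)


def write_measurements(table: MeasurementTable, path: str | Path) -> Path:
    """Write a table to CSV preserving feature values to full precision."""
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.10g")
    return path


def write_partition(table: MeasurementTable, partition, path: str | Path) -> Path:
    """Write the table with an appended cluster-label column.

    Noise points are encoded as 0; cluster labels are 1..K in the
    canonical (smallest-instar-first) order carried by the partition.
    """
    labels = np.asarray(partition.labels, dtype=int)
    if len(labels) != len(table):
        raise ValueError(
            f"partition length {len(labels)} != table length {len(table)}"
        )
    path = Path(path)
    out = table.data.copy()
    out[CLUSTER_COLUMN] = labels
    out.to_csv(path, index=False, float_format="%.10g")
    return path


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one clustering-and-validation run.

    Exactly one clustering method is selected per run; the ``params``
    mapping carries that method's parameters (``eps``/``min_pts`` for the
    density methods, ``eps_cl`` or ``xi`` for OPTICS extraction, ``k``
    for k-means, ``k_range``/``families`` for the mixture models).  The
    seed is recorded in every output so that runs are reproducible.
    """

    method: str = "optics"
    params: dict = dataclasses.field(default_factory=dict)
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    seed: int = 0
    output_dir: str = "instar_run"

    _METHODS = ("optics", "dbscan", "kmeans", "gmm")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(
                f"unknown clustering method {self.method!r}; "
                f"choose one of {self._METHODS}"
            )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": dict(self.params),
            "feature_names": list(self.feature_names),
            "seed": int(self.seed),
            "output_dir": str(self.output_dir),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(
            method=d.get("method", "optics"),
            params=dict(d.get("params", {})),
            feature_names=tuple(d.get("feature_names", FEATURE_COLUMNS)),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "instar_run")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
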