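"""Orchestration: generate -> cluster -> validate -> report.

``run_pipeline`` runs one clustering backend on a measurement table and
then the full validation battery (summary statistics, Brooks-Dyar and
Crosby indices, log-linear regression, frequency analysis, PCA), and
returns a serializable :class:`RunReport`.  ``compare_methods`` runs
several configurations and reports their pairwise adjusted Rand
indices — the operational meaning of "the methods found the same
instars" is ARI = 1.

Derived quantities that a reader would need to reproduce a run (the
k-NN knee, the automatic extraction radius, the BIC argmax) are logged
at info level and echoed in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import density, mixture, stats
from .io import (FEATURE_COLUMNS, MeasurementTable, PipelineConfig,
                 write_partition)
from .partition import Partition, adjusted_rand_index
from .synthetic import generated_truth

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunReport:
    """Everything one clustering-and-validation run produced.

    Serializes to JSON and round-trips; every number is recomputable
    from the inputs named in the manifest plus the recorded seed.
    """

    config: dict
    n_specimens: int
    n_clusters: int
    cluster_sizes: list[int]
    n_noise: int
    derived: dict                       # knee, eps_cl, BIC argmax, ...
    summary: list[dict] | None          # instar x feature records
    regressions: dict[str, dict] | None
    crosby_pass: dict[str, bool] | None
    frequency_overlap: dict[str, list[float]] | None
    any_overlap: bool | None
    ari_vs_truth: float | None
    validation_skipped: str | None
    manifest: list[str] = dataclasses.field(default_factory=list)

    @property
    def validation_passed(self) -> bool:
        if self.validation_skipped is not None:
            return False
        assert self.crosby_pass is not None
        return all(self.crosby_pass.values()) and not self.any_overlap

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunReport":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        return cls(**json.loads(text))


def cluster_table(table: MeasurementTable,
                  config: PipelineConfig) -> tuple[Partition, dict]:
    """Dispatch to the configured clustering backend.

    Returns the canonical partition plus a dict of derived quantities
    (knee estimate, automatic extraction radius, BIC table, ...).
    """
    p = dict(config.params)
    derived: dict = {"method": config.method, "seed": int(config.seed)}
    if config.method == "optics":
        min_pts = int(p.get("min_pts", 5))
        eps = float(p.get("eps", np.inf))
        res = density.optics_order(table,
                                   density.NeighborhoodParams(eps, min_pts))
        if "xi" in p:
            xi = float(p["xi"])
            part = density.extract_clusters_xi(res, xi).partition
            derived["extraction"] = {"kind": "xi", "xi": xi}
        else:
            if "eps_cl" in p:
                eps_cl = float(p["eps_cl"])
            else:
                eps_cl = density.default_extraction_radius(table, min_pts)
            part = density.extract_clusters_reachability(res, eps_cl)
            derived["extraction"] = {"kind": "threshold", "eps_cl": eps_cl}
            logger.info("OPTICS flat extraction at eps_cl=%.5g", eps_cl)
    elif config.method == "dbscan":
        eps = float(p.get("eps", 0.04))
        min_pts = int(p.get("min_pts", 4))
        part = density.dbscan(table,
                              density.NeighborhoodParams(eps, min_pts))
        derived["eps"] = eps
        derived["min_pts"] = min_pts
    elif config.method == "kmeans":
        k = int(p.get("k", 4))
        fit, part = mixture.kmeans(table, k, seed=config.seed,
                                   n_starts=int(p.get("n_starts", 10)))
        derived["wss"] = fit.wss
    elif config.method == "gmm":
        k_range = p.get("k_range", list(range(1, 10)))
        families = p.get("families", list(mixture.COVARIANCE_FAMILIES))
        sel = mixture.bic_select(table, k_range=k_range, families=families,
                                 seed=config.seed)
        part = sel.partition
        derived["bic_best"] = {"k": sel.best.k, "family": sel.best.family,
                               "bic": sel.best.bic}
        logger.info("BIC argmax: k=%d family=%s", sel.best.k,
                    sel.best.family)
    else:  # pragma: no cover - PipelineConfig already validates
        raise ValueError(f"unknown method {config.method!r}")
    return part, derived


def run_pipeline(config: PipelineConfig, table: MeasurementTable,
                 output_dir: str | Path | None = None) -> RunReport:
    """Cluster a table and validate the result.

    With fewer clusters than 1 (everything noise) the validation
    battery is skipped with an explicit notice instead of failing.
    When ``output_dir`` is given, the partition CSV, summary TSV and
    JSON report are written there.
    """
    part, derived = cluster_table(table, config)
    sizes = list(part.sizes_in_label_order())
    report = RunReport(
        config=config.to_dict(),
        n_specimens=len(table),
        n_clusters=part.n_clusters,
        cluster_sizes=sizes,
        n_noise=int(part.is_noise.sum()),
        derived=derived,
        summary=None, regressions=None, crosby_pass=None,
        frequency_overlap=None, any_overlap=None,
        ari_vs_truth=None, validation_skipped=None,
    )
    if table.has_instar:
        report.ari_vs_truth = adjusted_rand_index(part,
                                                  generated_truth(table))
    if part.n_clusters < 1:
        report.validation_skipped = (
            "no clusters found (all points noise); validation skipped")
        logger.warning(report.validation_skipped)
    else:
        summary = stats.summarize_instars(table, part)
        report.summary = (summary.table.reset_index()
                          .to_dict(orient="records"))
        report.crosby_pass = {}
        for feature in FEATURE_COLUMNS:
            dyar = summary.dyar(feature)
            if len(dyar) >= 2:
                _, ok = stats.crosby_indices(dyar)
                report.crosby_pass[feature] = ok
        if part.n_clusters >= 2:
            report.regressions = {
                feature: dataclasses.asdict(
                    stats.dyar_regression(table, part, feature))
                for feature in FEATURE_COLUMNS
            }
        freq = stats.frequency_analysis(table, part)
        report.frequency_overlap = {
            f: list(map(float, v)) for f, v in freq.overlaps_cm.items()
        }
        report.any_overlap = freq.any_overlap

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        part_path = write_partition(table, part, outdir / "partition.csv")
        report.manifest.append(str(part_path))
        if report.summary is not None:
            summary_path = outdir / "instar_summary.tsv"
            pd.DataFrame(report.summary).to_csv(summary_path, sep="\t",
                                                index=False)
            report.manifest.append(str(summary_path))
        report_path = outdir / "report.json"
        report.to_json(report_path)
        report.manifest.append(str(report_path))
    return report


def compare_methods(table: MeasurementTable,
                    configs: Sequence[PipelineConfig]) -> pd.DataFrame:
    """Pairwise adjusted Rand indices between the configured backends.

    Noise is treated as its own class.  Returns a symmetric DataFrame
    indexed by method name (suffixed when a method repeats).
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations to compare")
    names: list[str] = []
    partitions: list[Partition] = []
    for cfg in configs:
        part, _ = cluster_table(table, cfg)
        name = cfg.method
        if name in names:
            name = f"{name}_{sum(n.startswith(cfg.method) for n in names)}"
        names.append(name)
        partitions.append(part)
    k = len(partitions)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = adjusted_rand_index(partitions[i],
                                                        partitions[j])
    return pd.DataFrame(mat, index=names, columns=names)
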