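"""Shared data model and on-disk formats.

Canonical matrix format is TSV (UTF-8, '.' decimal): first column
``sample_id``, header row of feature ids.  Floats are serialized with 10
significant digits so writer/reader pairs round-trip exactly at text level.
Networks travel as GraphML, the reference store as JSON, configuration as a
flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "SampleMetadata",
    "AbundanceTable",
    "LatentVariableMatrix",
    "PipelineConfig",
    "FormatError",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_lv_matrix",
    "write_lv_matrix",
    "write_enrichment_report",
    "read_enrichment_report",
    "write_network",
    "read_network",
    "fmt_float",
    "stage_timer",
]

GROUPS = ("A", "B", "C")
TIMEPOINTS = ("T0", "T1", "T2")

log = logging.getLogger("momix")


class FormatError(ValueError):
    """Structurally malformed on-disk input (duplicates, empty schema, ...)."""


class ValidationError(ValueError):
    """Well-formed input violating a type invariant (e.g. negative abundance)."""


def fmt_float(x: float) -> str:
    return format(float(x), ".10g")


@contextmanager
def stage_timer(stage: str) -> Iterator[None]:
    """Log wall time of a pipeline stage on the shared channel."""
    t0 = time.perf_counter()
    log.info("stage %s: start", stage)
    yield
    log.info("stage %s: done in %.3fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# sample metadata


@dataclass
class SampleMetadata:
    """Per-sample design labels: treatment group and sampling timepoint."""

    sample_ids: list[str]
    group: dict[str, str]
    timepoint: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in metadata")
        for sid in self.sample_ids:
            if self.group.get(sid) not in GROUPS:
                raise ValidationError(f"sample {sid}: group must be one of {GROUPS}")
            if self.timepoint.get(sid) not in TIMEPOINTS:
                raise ValidationError(
                    f"sample {sid}: timepoint must be one of {TIMEPOINTS}"
                )

    def samples_at(self, timepoint: str) -> list[str]:
        return [s for s in self.sample_ids if self.timepoint[s] == timepoint]

    def groups_of(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.group[s] for s in sample_ids]


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "timepoint"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    return SampleMetadata(
        sample_ids=list(df["sample_id"]),
        group=dict(zip(df["sample_id"], df["group"])),
        timepoint=dict(zip(df["sample_id"], df["timepoint"])),
    )


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    lines = ["sample_id\tgroup\ttimepoint"]
    for sid in meta.sample_ids:
        lines.append(f"{sid}\t{meta.group[sid]}\t{meta.timepoint[sid]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# abundance tables


@dataclass
class AbundanceTable:
    """Samples x features non-negative matrix (taxa or pathway block)."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    block: str  # TAXON | PATHWAY
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.block not in ("TAXON", "PATHWAY"):
            raise ValidationError(f"unknown block {self.block!r}")
        if len(self.feature_ids) == 0:
            raise FormatError("abundance table has an empty feature set")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError("values shape does not match id lists")
        if np.any(self.values < 0):
            raise ValidationError("abundance table contains negative entries")
        if self.block == "TAXON":
            rowsums = self.values.sum(axis=1)
            self.normalized = bool(np.all(np.abs(rowsums - 1.0) < 1e-9))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceTable(
            list(sample_ids), list(self.feature_ids), self.values[idx], self.block
        )


def _read_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would mangle duplicates
        raise FormatError(f"{path}: duplicate feature ids")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no feature columns")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    return list(df.index.astype(str)), list(df.columns.astype(str)), values


def _write_matrix(
    sample_ids: Sequence[str],
    feature_ids: Sequence[str],
    values: np.ndarray,
    path: str | Path,
) -> None:
    lines = ["sample_id\t" + "\t".join(feature_ids)]
    for sid, row in zip(sample_ids, values):
        lines.append(sid + "\t" + "\t".join(fmt_float(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_abundance_table(path: str | Path, block: str) -> AbundanceTable:
    sample_ids, feature_ids, values = _read_matrix(path)
    return AbundanceTable(sample_ids, feature_ids, values, block)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    _write_matrix(table.sample_ids, table.feature_ids, table.values, path)


# ---------------------------------------------------------------------------
# NMR latent variables


@dataclass
class LatentVariableMatrix:
    """Samples x NMR latent-variable scores with LV -> metabolite membership."""

    sample_ids: list[str]
    lv_ids: list[str]
    scores: np.ndarray
    lv_metabolites: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.lv_ids)):
            raise ValidationError("scores shape does not match id lists")
        unknown = set(self.lv_metabolites) - set(self.lv_ids)
        if unknown:
            raise ValidationError(f"lv_metabolites keys not in lv_ids: {unknown}")
        for lv in self.lv_ids:
            if not self.lv_metabolites.get(lv):
                raise ValidationError(f"LV {lv} has no metabolite membership")

    def subset_samples(self, sample_ids: Sequence[str]) -> "LatentVariableMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return LatentVariableMatrix(
            list(sample_ids), list(self.lv_ids), self.scores[idx], self.lv_metabolites
        )


def write_lv_matrix(lv: LatentVariableMatrix, path: str | Path) -> None:
    """Write scores TSV plus a sidecar ``<path>.members.tsv`` membership map."""
    _write_matrix(lv.sample_ids, lv.lv_ids, lv.scores, path)
    lines = ["lv_id\tmetabolite"]
    for lv_id in lv.lv_ids:
        for met in sorted(lv.lv_metabolites[lv_id]):
            lines.append(f"{lv_id}\t{met}")
    Path(str(path) + ".members.tsv").write_text("\n".join(lines) + "\n")


def read_lv_matrix(path: str | Path) -> LatentVariableMatrix:
    sample_ids, lv_ids, scores = _read_matrix(path)
    members: dict[str, set[str]] = {}
    mdf = pd.read_csv(str(path) + ".members.tsv", sep="\t", dtype=str)
    for lv_id, met in zip(mdf["lv_id"], mdf["metabolite"]):
        members.setdefault(lv_id, set()).add(met)
    return LatentVariableMatrix(sample_ids, lv_ids, scores, members)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters with their documented defaults."""

    n_trees: int = 500
    random_seed: int = 42
    n_mds_axes: int = 3
    n_feature_clusters: int = 5
    fdr_threshold: float = 0.05
    enrichment_alpha: float = 0.05
    distance_metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_mds_axes < 1 or self.n_feature_clusters < 1:
            raise ValidationError("counts must be positive")
        if not (0 < self.fdr_threshold <= 1) or not (0 < self.enrichment_alpha <= 1):
            raise ValidationError("thresholds must lie in (0, 1]")
        if self.distance_metric not in ("bray_curtis", "euclidean"):
            raise ValidationError(f"unknown distance metric {self.distance_metric!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# enrichment report (Table-1-style) and networks

REPORT_COLUMNS = (
    "Time",
    "Cluster label",
    "Metabolite",
    "Enriched pathway",
    "p-value",
    "overlap-genes",
)


def write_enrichment_report(records: Sequence, path: str | Path) -> None:
    """Write the per-timepoint enrichment report.

    One row per (metabolite, enriched pathway) pair: timepoint, cluster
    label, metabolite name, pathway name, enrichment p-value and the
    overlapping input genes, in stable input order.
    """
    lines = ["\t".join(REPORT_COLUMNS)]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.timepoint,
                    f"Cluster {rec.cluster_label}",
                    rec.metabolite,
                    rec.pathway_name,
                    fmt_float(rec.p_value),
                    ",".join(sorted(rec.overlap_genes)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_enrichment_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"p-value": float})


NODE_TYPES = ("gene", "enzyme", "reaction", "compound")


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Serialize a typed Gene-Compound-Reaction-Enzyme network as GraphML."""
    for node, data in net.nodes(data=True):
        if data.get("type") not in NODE_TYPES:
            raise ValidationError(f"node {node!r} has invalid type {data.get('type')!r}")
    for u, v in net.edges():
        if u not in net.nodes or v not in net.nodes:  # pragma: no cover - nx invariant
            raise ValidationError(f"dangling edge ({u}, {v})")
    nx.write_graphml(net, str(path))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
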