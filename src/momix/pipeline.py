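"""Per-timepoint orchestration and the reproducible full run.

``analyze_timepoint`` chains the stages for one timepoint — beta-diversity
ordination, differential abundance, tri-omic integration, extra-trees
selection, Ward bi-clustering, enrichment and network construction — while
``run_all`` executes every timepoint found in a data directory, writes all
artifacts, and records a manifest of input/output digests so a rerun with
the same config and seed is byte-identical.  The global seed is expanded
into per-stage seeds through a stable stage-name hash, keeping stages
independent yet fully reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import __version__
from .cluster import ClusterMap, bicluster, group_separation_score
from .diversity import (
    DifferentialResult,
    OrdinationResult,
    differential_abundance,
    distance_matrix,
    pcoa,
)
from .enrich import EnrichedPathwayRecord, run_timepoint
from .features import ImportanceReport, IntegratedFeatureMatrix, gini_importance, integrate_features
from .io import (
    AbundanceTable,
    LatentVariableMatrix,
    PipelineConfig,
    SampleMetadata,
    fmt_float,
    read_abundance_table,
    read_lv_matrix,
    read_metadata,
    stage_timer,
    write_enrichment_report,
    write_network,
)
from .kegg import MiniKeggFixture, load_reference

__all__ = [
    "TimepointResult",
    "RunManifest",
    "stage_seed",
    "analyze_timepoint",
    "run_all",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class TimepointResult:
    timepoint: str
    ordination: OrdinationResult
    taxa_tests: list[DifferentialResult]
    pathway_tests: list[DifferentialResult]
    integrated: IntegratedFeatureMatrix
    importance: ImportanceReport
    selected: list[str]
    cluster_map: ClusterMap
    separation_ari: float
    enrichment: list[EnrichedPathwayRecord]
    networks: dict[int, nx.Graph]


def analyze_timepoint(
    meta: SampleMetadata,
    taxa: AbundanceTable,
    pathways: AbundanceTable,
    lv: LatentVariableMatrix,
    timepoint: str,
    ref: MiniKeggFixture,
    cfg: PipelineConfig,
) -> TimepointResult:
    """Run the full analysis chain for one timepoint."""
    samples = meta.samples_at(timepoint)
    groups = meta.groups_of(samples)
    seed = stage_seed(cfg.random_seed, f"select:{timepoint}")

    with stage_timer(f"{timepoint}:ordination"):
        taxa_tp = taxa.subset_samples(samples)
        dmat = distance_matrix(taxa_tp, metric=cfg.distance_metric)
        ordination = pcoa(dmat, cfg.n_mds_axes)
    with stage_timer(f"{timepoint}:differential"):
        taxa_tests = differential_abundance(taxa_tp, groups, cfg.fdr_threshold)
        pw_tp = pathways.subset_samples(samples)
        pathway_tests = differential_abundance(pw_tp, groups, cfg.fdr_threshold)
    with stage_timer(f"{timepoint}:integrate"):
        integrated = integrate_features(
            lv, ordination, pathways, meta, timepoint, n_mds_axes=cfg.n_mds_axes
        )
    with stage_timer(f"{timepoint}:select"):
        report = gini_importance(integrated, groups, n_trees=cfg.n_trees, seed=seed)
        selected = report.selected_ids()
    with stage_timer(f"{timepoint}:cluster"):
        if len(selected) < cfg.n_feature_clusters:
            raise PipelineError(
                "cluster",
                f"{timepoint}: {len(selected)} selected features < "
                f"k={cfg.n_feature_clusters} requested clusters",
            )
        cmap = bicluster(integrated.subset_features(selected), cfg.n_feature_clusters)
        ari = group_separation_score(cmap, meta)
    with stage_timer(f"{timepoint}:enrich"):
        lv_tp = lv.subset_samples(samples)
        enrichment, networks = run_timepoint(cmap, lv_tp, ref, cfg)

    return TimepointResult(
        timepoint=timepoint,
        ordination=ordination,
        taxa_tests=taxa_tests,
        pathway_tests=pathway_tests,
        integrated=integrated,
        importance=report,
        selected=selected,
        cluster_map=cmap,
        separation_ari=ari,
        enrichment=enrichment,
        networks=networks,
    )


# ---------------------------------------------------------------------------
# full run over a data directory


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _expected_inputs(data_dir: Path) -> tuple[list[str], dict[str, Path]]:
    files = {"metadata": data_dir / "metadata.tsv", "reference": data_dir / "reference.json"}
    timepoints = sorted(
        p.stem.split("_", 1)[1] for p in data_dir.glob("taxa_*.tsv")
    )
    for tp in timepoints:
        files[f"taxa_{tp}"] = data_dir / f"taxa_{tp}.tsv"
        files[f"pathways_{tp}"] = data_dir / f"pathways_{tp}.tsv"
        files[f"lv_{tp}"] = data_dir / f"lv_{tp}.tsv"
        files[f"lv_members_{tp}"] = data_dir / f"lv_{tp}.tsv.members.tsv"
    return timepoints, files


def _write_timepoint_outputs(res: TimepointResult, out_dir: Path) -> list[Path]:
    tp = res.timepoint
    written: list[Path] = []

    def emit(name: str, lines: list[str]) -> None:
        p = out_dir / name
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    ord_lines = [
        "sample_id\t" + "\t".join(res.ordination.axis_ids),
        *(
            sid + "\t" + "\t".join(fmt_float(v) for v in row)
            for sid, row in zip(res.ordination.sample_ids, res.ordination.coordinates)
        ),
    ]
    emit(f"ordination_{tp}.tsv", ord_lines)

    for name, tests in [("taxa", res.taxa_tests), ("pathways", res.pathway_tests)]:
        emit(
            f"differential_{name}_{tp}.tsv",
            ["feature_id\tH\tp\tp_adj\tsignificant"]
            + [
                f"{t.feature_id}\t{fmt_float(t.H)}\t{fmt_float(t.p_raw)}\t"
                f"{fmt_float(t.p_adjusted)}\t{str(t.significant).lower()}"
                for t in tests
            ],
        )

    emit(
        f"importance_{tp}.tsv",
        ["feature_id\tblock\timportance\tselected"]
        + [
            f"{f}\t{res.integrated.blocks[f]}\t{fmt_float(imp)}\t{str(bool(sel)).lower()}"
            for f, imp, sel in zip(
                res.importance.feature_ids,
                res.importance.importance,
                res.importance.selected,
            )
        ],
    )

    from .cluster import extract_associations

    eligible = {
        a.cluster_label: a.eligible for a in extract_associations(res.cluster_map)
    }
    emit(
        f"clusters_{tp}.tsv",
        ["feature_id\tblock\tcluster\teligible_cluster"]
        + [
            f"{f}\t{res.cluster_map.blocks[f]}\t{c}\t{str(eligible[c]).lower()}"
            for f, c in sorted(res.cluster_map.feature_clusters.items())
        ],
    )

    report_path = out_dir / f"enrichment_{tp}.tsv"
    write_enrichment_report(res.enrichment, report_path)
    written.append(report_path)

    for label, net in sorted(res.networks.items()):
        p = out_dir / f"{tp}_cluster{label}.graphml"
        write_network(net, p)
        written.append(p)

    return written


def run_all(cfg: PipelineConfig, data_dir: str | Path, out_dir: str | Path) -> RunManifest:
    """Execute every stage for every timepoint present in ``data_dir``.

    Fails fast on the first stage error (stage-tagged); partial outputs are
    retained for debugging.  All inputs and outputs are digested into the
    returned manifest.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    timepoints, files = _expected_inputs(data_dir)
    if not timepoints:
        raise PipelineError("inputs", f"no taxa_<timepoint>.tsv tables in {data_dir}")
    missing = [str(p) for p in files.values() if not p.exists()]
    if missing:
        raise PipelineError("inputs", f"missing input files: {missing}")

    out_dir.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(files["metadata"])
    ref = load_reference(files["reference"])
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.random_seed,
        version=__version__,
        inputs={k: _digest(p) for k, p in sorted(files.items())},
    )
    summary_lines = ["timepoint\tn_samples\tn_selected\tseparation_ari\tn_enriched_records"]
    for tp in timepoints:
        taxa = read_abundance_table(files[f"taxa_{tp}"], "TAXON")
        pathways = read_abundance_table(files[f"pathways_{tp}"], "PATHWAY")
        lv = read_lv_matrix(files[f"lv_{tp}"])
        res = analyze_timepoint(meta, taxa, pathways, lv, tp, ref, cfg)
        for p in _write_timepoint_outputs(res, out_dir):
            manifest.outputs[p.name] = _digest(p)
        summary_lines.append(
            f"{tp}\t{len(res.integrated.sample_ids)}\t{len(res.selected)}\t"
            f"{fmt_float(res.separation_ari)}\t{len(res.enrichment)}"
        )
    summary = out_dir / "summary.tsv"
    summary.write_text("\n".join(summary_lines) + "\n")
    manifest.outputs[summary.name] = _digest(summary)
    manifest.to_json(out_dir / "manifest.json")
    return manifest
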