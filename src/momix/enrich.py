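"""Pathway over-representation and Gene-Compound-Reaction-Enzyme networks.

Each eligible feature cluster (one holding at least one NMR latent variable
together with at least one functional pathway) contributes an input set:
the genes obtained by unpacking its member pathways plus the compounds
resolved from its member LVs' metabolites.  Every reference pathway is then
tested for over-representation with the hypergeometric upper tail on the
combined gene+compound universe (the union of all reference pathway
members).  Enriched pathways are reported one row per (input metabolite,
pathway) pair and expanded into a typed network: genes link to the enzymes
they encode, enzymes to the reactions they catalyze, reactions to their
substrate and product compounds; compounds shared between enriched
pathways appear once, connecting strands of metabolism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom

from .cluster import ClusterMap, extract_associations
from .io import LatentVariableMatrix, PipelineConfig
from .kegg import MiniKeggFixture, resolve_metabolites, unpack_pathway

__all__ = [
    "EnrichmentInput",
    "EnrichedPathwayRecord",
    "hypergeom_tail",
    "enriched_pathways",
    "enrich",
    "build_network",
    "build_cluster_input",
    "run_timepoint",
]

log = logging.getLogger("momix")


@dataclass
class EnrichmentInput:
    """Genes and compounds contributed by one eligible cluster."""

    timepoint: str
    cluster_label: int
    genes: set[str]
    compounds: set[str]  # compound ids
    metabolite_names: dict[str, str] = field(default_factory=dict)  # id -> display name

    def __post_init__(self) -> None:
        if not self.genes and not self.compounds:
            raise ValueError("enrichment input must contain genes or compounds")


@dataclass
class EnrichedPathwayRecord:
    timepoint: str
    cluster_label: int
    metabolite: str
    pathway_id: str
    pathway_name: str
    p_value: float
    overlap_genes: set[str]
    overlap_compounds: set[str]


def hypergeom_tail(k: int, universe: int, pathway_size: int, draw: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, pathway_size, draw)."""
    if universe <= 0:
        raise ValueError("empty universe")
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, universe, pathway_size, draw))


def _universe(ref: MiniKeggFixture) -> set[str]:
    members: set[str] = set()
    for pid in ref.pathways:
        members |= {f"g:{g}" for g in ref.pathway_genes(pid)}
        members |= {f"c:{c}" for c in ref.pathway_compounds(pid)}
    return members


def enriched_pathways(
    inp: EnrichmentInput, ref: MiniKeggFixture, alpha: float = 0.05
) -> dict[str, tuple[float, set[str], set[str]]]:
    """Over-represented pathways: id -> (p, overlap genes, overlap compound ids).

    Genes and compounds are pooled into one membership margin over the
    universe of all reference pathway members; a pathway qualifies when its
    hypergeometric upper-tail p is at most alpha and the overlap is
    non-empty.
    """
    universe = _universe(ref)
    if not universe:
        raise ValueError("reference store has an empty pathway universe")
    draw = ({f"g:{g}" for g in inp.genes} | {f"c:{c}" for c in inp.compounds}) & universe
    out: dict[str, tuple[float, set[str], set[str]]] = {}
    for pid in sorted(ref.pathways):
        genes = {f"g:{g}" for g in ref.pathway_genes(pid)}
        comps = {f"c:{c}" for c in ref.pathway_compounds(pid)}
        members = genes | comps
        overlap = draw & members
        p = hypergeom_tail(len(overlap), len(universe), len(members), len(draw))
        if p > alpha or not overlap:
            continue
        out[pid] = (p, {m[2:] for m in overlap & genes}, {m[2:] for m in overlap & comps})
    return out


def enrich(
    inp: EnrichmentInput, ref: MiniKeggFixture, alpha: float = 0.05
) -> list[EnrichedPathwayRecord]:
    """Hypergeometric over-representation of each reference pathway.

    For every enriched pathway, one record is emitted per input metabolite
    belonging to that pathway, mirroring the repeated-row report layout;
    records are sorted by (cluster, metabolite, p).
    """
    records: list[EnrichedPathwayRecord] = []
    for pid, (p, overlap_genes, overlap_compound_ids) in enriched_pathways(
        inp, ref, alpha
    ).items():
        for cid in sorted(inp.compounds):
            if cid not in ref.pathway_compounds(pid):
                continue
            records.append(
                EnrichedPathwayRecord(
                    timepoint=inp.timepoint,
                    cluster_label=inp.cluster_label,
                    metabolite=inp.metabolite_names.get(cid, ref.compound_name(cid)),
                    pathway_id=pid,
                    pathway_name=ref.pathways[pid].name,
                    p_value=p,
                    overlap_genes=overlap_genes,
                    overlap_compounds=overlap_compound_ids,
                )
            )
    records.sort(key=lambda r: (r.cluster_label, r.metabolite, r.p_value, r.pathway_id))
    return records


def build_network(
    records: list[EnrichedPathwayRecord],
    inp: EnrichmentInput,
    ref: MiniKeggFixture,
    pathway_ids: set[str] | None = None,
) -> nx.Graph:
    """Expand enriched pathways into a Gene-Compound-Reaction-Enzyme graph.

    Nodes are typed gene/enzyme/reaction/compound; edges run gene-enzyme,
    enzyme-reaction and reaction-compound.  Nodes present in the input sets
    are flagged observed (``input_flag``); everything else is
    reference-completed.  Compounds shared by several enriched pathways
    appear as a single node, so connected metabolic strands merge.
    """
    net = nx.Graph()
    if pathway_ids is None:
        pathway_ids = {r.pathway_id for r in records}
    for pid in sorted(pathway_ids):
        pw = ref.pathways[pid]
        for rid in pw.reactions:
            rx = ref.reactions[rid]
            net.add_node(rid, type="reaction", name=rx.name, input_flag=False)
            enzyme = f"EC:{rx.enzyme_ec}"
            net.add_node(enzyme, type="enzyme", name=rx.enzyme_ec, input_flag=False)
            net.add_edge(enzyme, rid, kind="enzyme-reaction")
            for cid in list(rx.substrates) + list(rx.products):
                name = ref.compound_name(cid)
                if cid not in net.nodes:
                    net.add_node(
                        cid,
                        type="compound",
                        name=name,
                        input_flag=cid in inp.compounds,
                    )
                net.add_edge(rid, cid, kind="reaction-compound")
            for ko in rx.kos:
                rec = ref.ko_genes.get(ko)
                if rec is None:
                    continue
                if rec.gene_symbol not in net.nodes:
                    net.add_node(
                        rec.gene_symbol,
                        type="gene",
                        ko=ko,
                        entrez=rec.entrez_id if rec.entrez_id is not None else -1,
                        input_flag=rec.gene_symbol in inp.genes,
                    )
                net.add_edge(rec.gene_symbol, enzyme, kind="gene-enzyme")
    _validate_network(net)
    return net


def _validate_network(net: nx.Graph) -> None:
    for node, data in net.nodes(data=True):
        if data.get("type") == "reaction" and not any(
            net.nodes[nb].get("type") == "compound" for nb in net.neighbors(node)
        ):
            raise ValueError(f"reaction node {node} has no compound neighbor")


def build_cluster_input(
    association,
    cmap: ClusterMap,
    lv: LatentVariableMatrix,
    ref: MiniKeggFixture,
    timepoint: str,
) -> EnrichmentInput | None:
    """Assemble the gene/compound input set of one eligible cluster.

    Member pathways absent from the reference store are skipped (and
    logged): a functional profile covers far more pathways than any offline
    store does.  Metabolite names that fail synonym resolution are likewise
    surfaced in the log rather than silently dropped.
    """
    genes: set[str] = set()
    for pid in sorted(association.pathway_members):
        if pid not in ref.pathways:
            log.debug("cluster %d: pathway %s not in reference, skipped",
                      association.cluster_label, pid)
            continue
        recs, skipped = unpack_pathway(pid, ref)
        if skipped:
            log.debug("pathway %s: %d KOs without gene symbols", pid, len(skipped))
        genes |= {r.gene_symbol for r in recs}
    names: list[str] = []
    for lv_id in sorted(association.lv_members):
        names.extend(sorted(lv.lv_metabolites.get(lv_id, set())))
    compounds: set[str] = set()
    display: dict[str, str] = {}
    for res in resolve_metabolites(names, ref):
        if res.status == "resolved":
            compounds.add(res.compound_id)
            display.setdefault(res.compound_id, res.query_name)
        else:
            log.debug("metabolite %r: %s", res.query_name, res.status)
    if not genes and not compounds:
        return None
    return EnrichmentInput(
        timepoint=timepoint,
        cluster_label=association.cluster_label,
        genes=genes,
        compounds=compounds,
        metabolite_names=display,
    )


def run_timepoint(
    cmap: ClusterMap,
    lv: LatentVariableMatrix,
    ref: MiniKeggFixture,
    cfg: PipelineConfig,
) -> tuple[list[EnrichedPathwayRecord], dict[int, nx.Graph]]:
    """Enrichment + network construction over all eligible clusters of a map."""
    report: list[EnrichedPathwayRecord] = []
    networks: dict[int, nx.Graph] = {}
    eligible = [a for a in extract_associations(cmap) if a.eligible]
    if not eligible:
        log.warning("timepoint %s: no eligible clusters", cmap.timepoint)
        return [], {}
    for assoc in eligible:
        inp = build_cluster_input(assoc, cmap, lv, ref, cmap.timepoint)
        if inp is None:
            continue
        hits = enriched_pathways(inp, ref, alpha=cfg.enrichment_alpha)
        records = enrich(inp, ref, alpha=cfg.enrichment_alpha)
        report.extend(records)
        if hits:
            networks[assoc.cluster_label] = build_network(
                records, inp, ref, pathway_ids=set(hits)
            )
    return report, networks
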