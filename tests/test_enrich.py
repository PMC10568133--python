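"""Hypergeometric enrichment against an exact combinatorial oracle; networks."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from momix.enrich import (
    EnrichmentInput,
    build_cluster_input,
    build_network,
    enrich,
    enriched_pathways,
    hypergeom_tail,
    run_timepoint,
)
from momix.kegg import Compound, GeneRecord, MiniKeggFixture, Pathway


def tail_oracle(k, M, n, N) -> Fraction:
    """Exact P(X >= k) by enumerating the hypergeometric pmf."""
    total = Fraction(0)
    for j in range(k, min(n, N) + 1):
        total += Fraction(comb(n, j) * comb(M - n, N - j), comb(M, N))
    return total


def test_hypergeom_tail_matches_exact_oracle_small_universes():
    for M in range(2, 26, 4):
        for n in range(1, M + 1, 3):
            for N in range(1, M + 1, 3):
                for k in range(0, min(n, N) + 1):
                    assert hypergeom_tail(k, M, n, N) == pytest.approx(
                        float(tail_oracle(k, M, n, N)), abs=1e-12
                    )


def test_hypergeom_closed_form_full_overlap():
    # universe of 20, pathway of 5, input exactly those 5
    assert hypergeom_tail(5, 20, 5, 5) == pytest.approx(1 / comb(20, 5), rel=1e-12)


def test_hypergeom_empty_universe_rejected():
    with pytest.raises(ValueError):
        hypergeom_tail(1, 0, 0, 0)


# ---------------------------------------------------------------------------
# enrichment over the fixture


def _histidine_input(mini_kegg, cluster=1):
    genes = mini_kegg.pathway_genes("ko00340")
    return EnrichmentInput(
        timepoint="T0",
        cluster_label=cluster,
        genes=set(genes),
        compounds={"C00785"},
        metabolite_names={"C00785": "Urocanate"},
    )


def test_histidine_pathway_enriched_with_urocanate_pair(mini_kegg):
    records = enrich(_histidine_input(mini_kegg), mini_kegg, alpha=0.05)
    assert any(
        r.metabolite == "Urocanate" and r.pathway_name == "Histidine metabolism"
        for r in records
    )
    rec = [r for r in records if r.pathway_name == "Histidine metabolism"][0]
    assert rec.p_value <= 0.05
    assert rec.overlap_genes <= mini_kegg.pathway_genes("ko00340")
    assert "C00785" in rec.overlap_compounds


def test_disjoint_input_yields_no_records(mini_kegg):
    inp = EnrichmentInput("T0", 1, genes={"NOPE1", "NOPE2"}, compounds=set())
    assert enrich(inp, mini_kegg, alpha=0.05) == []


def test_enrichment_false_positive_rate_under_random_inputs(mini_kegg, rng):
    """Random same-size draws from the universe reach p <= alpha at rate <= alpha."""
    from momix.enrich import _universe

    universe = sorted(_universe(mini_kegg))
    alpha = 0.05
    n_trials = 400
    false = 0
    pid = "ko00340"
    for _ in range(n_trials):
        draw = rng.choice(universe, size=8, replace=False)
        genes = {d[2:] for d in draw if d.startswith("g:")}
        comps = {d[2:] for d in draw if d.startswith("c:")}
        inp = EnrichmentInput("T0", 1, genes=genes, compounds=comps)
        hits = enriched_pathways(inp, mini_kegg, alpha=alpha)
        if pid in hits:
            false += 1
    rate = false / n_trials
    se = np.sqrt(alpha * (1 - alpha) / n_trials)
    assert rate <= alpha + 3 * se


# ---------------------------------------------------------------------------
# network construction


def test_network_alanine_reaction_links_four_compounds(mini_kegg):
    inp = EnrichmentInput(
        "T1", 2, genes=mini_kegg.pathway_genes("ko00250"), compounds={"C00041"},
        metabolite_names={"C00041": "L-Alanine"},
    )
    records = enrich(inp, mini_kegg, alpha=0.05)
    net = build_network(records, inp, mini_kegg)
    assert "R00258" in net.nodes
    for cid in ("C00041", "C00026", "C00022", "C00025"):
        assert net.has_edge("R00258", cid)
    assert net.nodes["C00041"]["input_flag"]
    assert not net.nodes["C00026"]["input_flag"]


def test_network_inositol_dual_phosphohydrolases(mini_kegg):
    inp = EnrichmentInput(
        "T1", 3, genes=mini_kegg.pathway_genes("ko00562"), compounds={"C00137"},
    )
    records = enrich(inp, mini_kegg, alpha=0.05)
    net = build_network(records, inp, mini_kegg)
    assert net.has_edge("R01185", "C00137")
    assert net.has_edge("R01186", "C00137")


def test_network_urocanate_dual_provenance(mini_kegg):
    records = enrich(_histidine_input(mini_kegg), mini_kegg, alpha=0.05)
    net = build_network(records, _histidine_input(mini_kegg), mini_kegg)
    neighbors = {
        nb for nb in net.neighbors("C00785")
        if net.nodes[nb]["type"] == "reaction"
    }
    assert {"R01168", "R02914"} <= neighbors


def test_network_node_and_edge_typing(mini_kegg):
    inp = _histidine_input(mini_kegg)
    net = build_network(enrich(inp, mini_kegg, alpha=0.05), inp, mini_kegg)
    for _, data in net.nodes(data=True):
        assert data["type"] in {"gene", "enzyme", "reaction", "compound"}
    kinds = {d["kind"] for _, _, d in net.edges(data=True)}
    assert kinds <= {"gene-enzyme", "enzyme-reaction", "reaction-compound"}
    # every reaction node touches a compound
    for node, data in net.nodes(data=True):
        if data["type"] == "reaction":
            assert any(
                net.nodes[nb]["type"] == "compound" for nb in net.neighbors(node)
            )


def test_network_inputs_close_to_enriched_reactions(mini_kegg):
    """Observed nodes sit within three edges of an enriched pathway reaction."""
    import networkx as nx

    inp = _histidine_input(mini_kegg)
    net = build_network(enrich(inp, mini_kegg, alpha=0.05), inp, mini_kegg)
    reactions = [n for n, d in net.nodes(data=True) if d["type"] == "reaction"]
    for node, data in net.nodes(data=True):
        if data.get("input_flag"):
            dist = min(
                nx.shortest_path_length(net, node, r) for r in reactions
            )
            assert dist <= 3


def test_empty_enrichment_input_rejected():
    with pytest.raises(ValueError):
        EnrichmentInput("T0", 1, genes=set(), compounds=set())


def test_build_network_rejects_inconsistent_reference():
    ref = MiniKeggFixture(
        pathways={"p1": Pathway("p1", "broken", ["K00001"], ["R1"])},
        ko_genes={"K00001": GeneRecord("K00001", "g1")},
        reactions={},
        compounds={"C1": Compound("C1", "thing")},
    )
    with pytest.raises(ValueError):
        ref.validate()


# ---------------------------------------------------------------------------
# per-timepoint orchestration


def test_run_timepoint_only_eligible_clusters_produce_networks(mini_kegg, rng, config):
    from momix.cluster import bicluster
    from momix.features import IntegratedFeatureMatrix
    from momix.io import LatentVariableMatrix

    samples = [f"s{i}" for i in range(8)]
    blocks = {"LV1": "LV", "ko00340": "PATHWAY", "axis1": "MDS_AXIS", "axis2": "MDS_AXIS"}
    base = rng.normal(size=8)
    values = np.column_stack([
        base + 0.05 * rng.normal(size=8),          # LV1
        base + 0.05 * rng.normal(size=8),          # ko00340, tied to LV1
        rng.normal(size=8) + 40,                    # axis1 far away
        rng.normal(size=8) + 40,                    # axis2
    ])
    values = (values - values.mean(0)) / values.std(0)
    X = IntegratedFeatureMatrix(samples, list(blocks), values, blocks, "T1")
    cmap = bicluster(X, k=2)
    lv = LatentVariableMatrix(
        samples, ["LV1"], rng.normal(size=(8, 1)), {"LV1": {"Urocanate"}}
    )
    report, networks = run_timepoint(cmap, lv, mini_kegg, config)
    # exactly one eligible cluster (LV1 + ko00340); axes-only cluster excluded
    assert len(networks) == 1
    assert any(r.metabolite == "Urocanate" for r in report)


def test_run_timepoint_no_eligible_clusters_warns_not_errors(mini_kegg, rng, config):
    from momix.cluster import bicluster
    from momix.features import IntegratedFeatureMatrix
    from momix.io import LatentVariableMatrix

    samples = [f"s{i}" for i in range(6)]
    blocks = {"axis1": "MDS_AXIS", "axis2": "MDS_AXIS"}
    X = IntegratedFeatureMatrix(
        samples, list(blocks), rng.normal(size=(6, 2)), blocks, "T0"
    )
    cmap = bicluster(X, k=2)
    lv = LatentVariableMatrix(
        samples, ["LV1"], rng.normal(size=(6, 1)), {"LV1": {"Acetate"}}
    )
    report, networks = run_timepoint(cmap, lv, mini_kegg, config)
    assert report == [] and networks == {}


def test_cluster_input_skips_pathways_absent_from_reference(mini_kegg, rng):
    from momix.cluster import ClusterAssociation
    from momix.io import LatentVariableMatrix

    assoc = ClusterAssociation(
        cluster_label=1,
        lv_members={"LV1"},
        pathway_members={"ko00340", "ko99999"},
        mds_members=set(),
        eligible=True,
    )
    lv = LatentVariableMatrix(
        ["s1"], ["LV1"], np.zeros((1, 1)), {"LV1": {"Urocanate", "mystery-compound"}}
    )
    inp = build_cluster_input(assoc, None, lv, mini_kegg, "T1")
    assert inp.genes == mini_kegg.pathway_genes("ko00340")
    assert inp.compounds == {"C00785"}  # unresolved name skipped, not fatal
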