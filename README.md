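# momix

Multi-omic feature integration, selection, bi-clustering and
pathway-enrichment networks for microbiome nutrition studies.

`momix` reimplements, as a tested and reusable pipeline, an analysis
framework for dietary-intervention studies of the broiler caeca microbiome:
three omic layers — NMR metabolomics summarized as latent variables (LVs),
species-level shotgun taxonomy, and functional-pathway abundances — are
integrated per timepoint, reduced to a minimal set of discriminative
features, bi-clustered, and translated into Gene-Compound-Reaction-Enzyme
networks that describe which biochemical mechanisms a treatment modulates.
It targets the setting of a vitamin B2 (riboflavin) supplementation trial:
three treatment groups (control 5 mg/kg, +50 mg/kg, +100 mg/kg) sampled at
three timepoints (day 14/28/42), 21 metagenomes per group and timepoint.

## The method

Per timepoint, with samples *i* and treatment groups *y*:

1. **Diversity & differential abundance.** Alpha diversity is the
   Gini–Simpson index 1 − Σ *p*ᵢ²; beta diversity is Bray–Curtis
   dissimilarity Σ|*a*−*b*| / Σ(*a*+*b*), ordinated by classical PCoA
   (eigendecomposition of the double-centered −½D² matrix). Each feature is
   tested across groups with the tie-corrected Kruskal–Wallis H and
   corrected by Benjamini–Hochberg at FDR ≤ 0.05.
2. **Integration.** Three feature blocks — LV scores, the leading PCoA
   axes, pathway abundances — are concatenated and standard scaled.
3. **Selection.** An extremely-randomized-trees classifier discriminating
   the groups assigns every feature its Gini importance (total impurity
   decrease, weighted by the fraction of samples reaching the node,
   averaged over the ensemble, normalized to sum 1). A feature is kept iff
   its importance is *strictly* greater than the mean importance, i.e.
   > 1/p.
4. **Bi-clustering.** Samples and selected features are clustered
   independently with Ward linkage on the scaled matrix; the feature
   dendrogram is cut into k = 5 flat clusters. A cluster is *eligible* when
   it associates at least one LV with at least one functional pathway.
5. **Enrichment networks.** Each eligible cluster's pathways are unpacked
   to genes (KO → symbol, ENTREZ when available) and its LV metabolites
   resolved against compound synonyms; every reference pathway is tested by
   the hypergeometric upper tail on the pooled gene+compound universe, and
   enriched pathways (p ≤ 0.05) are expanded into typed
   gene–enzyme–reaction–compound graphs with observed inputs flagged.

Because the original sequencing data live in an external repository, the
package ships a synthetic-data generator that emulates the study design —
planted signature species (*Alistipes* dominance in controls at 72.38%
end-of-cycle relative abundance, *Lactobacillus crispatus* at 12.40% and
*Subdoligranulum* at 20.19% in the high-dose group, ...), planted
differential pathways, and group-shifted LVs, at half effect strength on
day 14 and full strength after — plus a deterministic offline mini
KEGG-like reference with the key urocanate, inositol and
alanine/aspartate/glutamate reactions.

## Worked example

```bash
python analysis/01_simulate.py --seed 1        # writes results/synthetic_data/
python analysis/04_biclustering.py --seed 1
python analysis/05_enrichment_networks.py --seed 1
```

prints (abridged):

```
T0: separation ARI 0.6515806488; 5 feature clusters, 5 eligible for enrichment
T1: separation ARI 0.902880006; 5 feature clusters, 2 eligible for enrichment
T2: separation ARI 1; 5 feature clusters, 2 eligible for enrichment
T1: 2 report rows, 2 networks
   cluster 1: myo-Inositol -> Inositol phosphate metabolism (p=4.48e-04)
   cluster 2: Urocanate -> Histidine metabolism (p=6.42e-07)
```

Treatment separation (adjusted Rand index of the k = 3 sample-dendrogram
cut against the true groups) is partial at the first sampling and complete
later, and the bi-clustering correctly ties the urocanate-bearing LV to the
histidine-metabolism pathway block and the myo-inositol LV to the inositol
block; the exported GraphML networks contain both urocanate-producing
reactions (R01168 histidine ammonia-lyase and R02914, the
imidazolepropanoate hydro-lyase route), the dual provenance that explains a
metabolite staying level while one of its source pathways is suppressed.

The same stages are scriptable via the CLI:

```bash
momix simulate --seed 1 --outdir data/
momix run-all --data-dir data/ --seed 1 --outdir out/
```

`run-all` writes every per-timepoint artifact (ordination, differential
tables, importances, clusters, enrichment report, networks) and a manifest
of input/output digests; reruns with the same config and seed are
byte-identical.

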