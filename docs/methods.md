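# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of the `momix` pipeline. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Statistical components

**Alpha diversity.** `simpson_index` returns the Gini–Simpson form
1 − Σ pᵢ² after internally renormalizing the input, so it is invariant to
the overall scale of counts. The complementary (1/D) and classic (Σ pᵢ²)
forms are not used; the Gini–Simpson convention matches the common
"simpson" diversity of ecology toolkits and is stated explicitly because
naming conventions differ across packages.

**Beta diversity and ordination.** Bray–Curtis dissimilarity on species
relative abundances is the default sample distance (Euclidean is available
via `distance_metric` for non-compositional blocks). Ordination is
classical scaling: eigendecomposition of −½ J D² J with J the centering
matrix; axes are eigenvectors scaled by √λ, kept in descending-λ order.
Bray–Curtis matrices need not be Euclidean-embeddable, so negative
eigenvalues can occur; those axes are discarded, and requesting more axes
than have positive eigenvalues returns fewer with a warning rather than
fabricating coordinates. On Euclidean-embeddable inputs the retained axes
reproduce all pairwise distances to 1e-8 (tested).

**Differential abundance.** Per-feature Kruskal–Wallis with midranks for
ties and the standard tie correction 1 − Σ(t³−t)/(N³−N); H = 0, p = 1 is
returned when all values are identical. p-values use the chi-square
approximation with k−1 df at every sample size, matching standard
implementations; exact small-sample p-values are out of scope. Family-wise
correction is Benjamini–Hochberg step-up at FDR ≤ 0.05 (the procedure tied
to the stated FDR threshold); Bonferroni is available as a conservative
alternative flag. Note that the BH *adjusted values* are not a fixed point
of the procedure (re-adjusting adjusted p-values can increase them), so the
suite checks exact agreement with a step-up oracle and monotonicity, not
idempotence.

**Feature selection.** `ExtraTreesClassifier` with Gini impurity,
√p candidate features per split, randomized thresholds, no bootstrap,
unlimited depth, 500 trees, fixed seed — standard extra-trees defaults,
all recorded in the `ImportanceReport` for reproducibility. Importance is
mean decrease in impurity (node-weighted, ensemble-averaged, normalized to
sum 1), verified node-by-node against a traversal oracle on shallow trees.
Selection keeps features with importance strictly greater than the mean;
after normalization the threshold is exactly 1/p, so an exactly uniform
importance vector (and the degenerate single-feature case) selects
nothing. Zero-variance columns are excluded from the fit, flagged, and
assigned importance zero. Selection runs once per timepoint; it is not
iterated to convergence, since nothing in the selection rule changes on a
second pass over the same matrix.

**Scaling.** Features are standard scaled (population SD) within each
timepoint, because every downstream analysis is per-timepoint. Constant
columns scale to all-zero and are flagged instead of producing NaN.

**Bi-clustering.** Independent Ward trees over rows (samples) and columns
(features) of the scaled selected matrix — the cluster-map convention, not
spectral co-clustering. Ward presumes squared-Euclidean geometry, hence
Euclidean distances on the scaled matrix for both axes. Flat feature
clusters come from a maxclust cut at k = 5 (the default
`n_feature_clusters`; the study's cluster maps show five numbered
clusters), relabeled 1..k in dendrogram leaf order so labels read
left-to-right on a heatmap. Merge heights are monotone and the merge
sequence agrees with an exhaustive greedy Lance–Williams oracle for n ≤ 7
(tested); ties break toward the smallest original index for determinism.
Treatment separation is quantified as the adjusted Rand index between the
k = 3 cut of the sample tree and the true groups.

**Eligibility and enrichment.** A feature cluster is eligible for
enrichment iff it contains at least one LV and at least one functional
pathway. Its input set is the union of the genes of its member pathways
(unpacked KO → gene symbol; KOs without symbols are reported in a skipped
list, never silently dropped) and the compounds resolved from its member
LVs' metabolite names (exact match after case-folding and
whitespace/hyphen normalization — no fuzzy matching, and synonym
collisions are reported as ambiguous rather than guessed). Enrichment is
the hypergeometric upper tail with genes and compounds pooled into a
single margin; the universe is the union of all pathway members in the
loaded reference store, not all of KEGG — an offline-determinism choice
and a fidelity limitation, since a small universe makes the test
conservative for large inputs. No multiple-testing correction is applied
across pathways by default (the report format is per-pathway); BH across
pathways is available behind a flag. One report row is emitted per (input
metabolite, enriched pathway) pair, replicating the repeated-row report
style; networks are built from *all* enriched pathways of a cluster, so an
enriched pathway whose compounds were not observed still contributes its
reactions.

**Networks.** Typed graphs: gene—enzyme—reaction—compound, one edge kind
per level. Nodes present in the cluster's input sets carry
`input_flag=true` (observed); everything else is reference-completed.
Compounds shared between enriched pathways appear once, which is what lets
separate enriched pathways join into connected strands. Serialization is
GraphML; absent ENTREZ ids are encoded as −1 (GraphML has no null).

## Synthetic study design

The generator emulates the structure of the supplementation trial the
pipeline targets; its defaults are the study conditions the tests run
under.

* **Layout.** Groups A (control), B (+50 mg/kg), C (+100 mg/kg); 21
  samples per group per timepoint; timepoints T0/T1/T2 with effect
  multiplier 0.5 at T0 and 1.0 afterwards, so treatment separation is
  partial at the first sampling and complete later — the qualitative
  pattern the study reports.
* **Taxa.** 60 species. Each sample is one Dirichlet draw whose mean puts
  the group's signature species exactly at their target abundances and
  spreads the remaining mass over a sparse background (concentration 0.5
  per species, long-tailed like real species profiles). Signature targets
  reuse the study's printed values where available: *Alistipes*
  72.38/5.34/25.87% across A/B/C at T2, *L. crispatus* 12.40% and
  *Subdoligranulum* 20.19% in C from T1, *R. torques* ≈17% in C; remaining
  cells are interpolations at roughly half strength at T0. Group means
  converge to the targets (within Monte-Carlo error, tested) and every row
  sums to one.
* **Pathways.** 190 pathways, log-normal(0, 1) background. Eight planted
  pathways (four per treated group, including the fixture pathways
  histidine / inositol-phosphate / purine metabolism) are shifted by +2.5
  log-fold in their group.
* **Latent variables.** Six LVs, standard-normal scores; LV1 (carrying
  Urocanate and Xanthine) is shifted +2.5 SD in group B, LV2
  (myo-Inositol) +2.5 SD in group C. Every LV carries a non-empty
  metabolite list drawn from the reference compound names.
* **Response coupling.** Planted LV and pathway effects are scaled by a
  shared per-sample factor 1 + N(0, 0.25): a strongly responding bird
  shifts in both its metabolome and its functional profile. This
  within-group inter-omic correlation is what real dose-response data
  exhibit and what the bi-clustering stage exists to exploit; without it,
  LV and pathway features co-vary only through group membership and the
  LV–pathway co-clustering is fragile. The effect sizes (2.5) and coupling
  spread (0.25) were fixed once, as the weakest setting at which the
  planted structure is reliably recoverable at the study's sample sizes
  (median planted-feature recall ≥ 0.9; full-strength separation
  ARI ≥ 0.9 with half-strength clearly lower; ≥ 90% end-to-end recovery of
  the urocanate/histidine association), and are not tuned per test.
* **Determinism.** All draws flow from `numpy` generators seeded by
  (design seed, timepoint index, stream id); identical designs produce
  byte-identical datasets.

What the generator does *not* emulate: compositional zero-inflation and
sequencing depth noise, phylogenetic correlation between species,
covariance among background pathways, non-Gaussian LV score distributions,
and any real relationship between taxa and the pathways they encode.
Passing tests therefore demonstrate that the pipeline recovers planted
multi-omic structure of realistic magnitude at the study's sample sizes —
not that it would behave identically on profiler output from real
sequencing runs.

## Reference store

The bundled mini KEGG-like store is a deterministic synthetic stand-in for
a licensed KEGG mirror: six pathways, nine reactions, 38 KO → gene
mappings, 31 compounds with synonyms. The chemistry of the key reactions
is real — R01168 (histidine ammonia-lyase: L-Histidine → Urocanate +
Ammonia), R02914 (4,5-dihydro-4-oxo-5-imidazolepropanoate hydro-lyase:
4-Imidazolone-5-propanoate → Urocanate + Water), R01185/R01186 (the two
myo-inositol phosphate phosphohydrolases), R00526 (N-formyl-L-aspartate
amidohydrolase → Aspartate + Formate), R00258 (alanine aminotransferase:
L-Alanine + 2-Oxoglutarate → Pyruvate + L-Glutamate) — while filler KO ids,
most gene symbols and some ENTREZ ids are synthetic placeholders in a
single generic namespace (no organism resolution). Live KEGG REST access
exists behind an explicit `online=True` flag with byte-stable caching;
offline mode never opens a socket, and all tests run offline.

## Orchestration and reproducibility

`run_all` discovers the timepoints present in a data directory, validates
that every expected input exists before any stage runs, executes the
stages per timepoint (fail-fast, errors tagged with the stage name,
partial outputs retained), and writes a manifest of the config snapshot,
seed, and SHA-256 digests of every input and output. Floats are serialized
with 10 significant digits and all iteration orders are deterministic, so
a rerun with the same config and seed is byte-identical (tested). The
global seed expands into per-stage seeds via a CRC-32 hash of the stage
name, keeping stages independent but reproducible; derived seeds stay
below 2³¹. Timepoints share no state.

## Problem sizes

Unit tests run on reduced designs (8–12 samples per group, 30–40 features)
where the planted structure is still present but individual timepoints may
miss weak associations; the seed-grid experiments (selection recovery,
separation ordering, end-to-end enrichment recovery) run the full default
design — 63 samples, 199 integrated features, 500 trees — over 20 seeds,
which is where the recovery guarantees above are measured.

## Known limitations

* The Kruskal–Wallis chi-square p is anti-conservative for very small
  groups; with 21 per group it is adequate.
* The enrichment universe is the reference store, not the organism's full
  gene/compound complement; p-values are comparable within a run, not
  across reference versions.
* Cluster numbering follows dendrogram leaf order; a different but
  equally valid convention (e.g. cluster size) would permute labels.
* The eligibility rule is binary (LV and pathway co-membership); it does
  not weigh how strongly the cluster's members correlate.
* Bray–Curtis does not satisfy the triangle inequality; no test asserts
  it, and PCoA handles the resulting negative eigenvalues by discarding
  those axes.
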