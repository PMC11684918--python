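# Methods

`tknet` implements a transkingdom network analysis for two-experiment
microbiome / host studies: it takes ASV count tables, host phenotype and
gene-expression measurements and group metadata for a three-arm design
(normal diet ND, Western diet WD, WD plus cholestyramine WD_Ch; two
independent experiments of five mice per group), and nominates microbes that
may mediate the host's response to the treatment. This note describes the
model and procedure, the tunable parameters, the synthetic-data generator,
the numerical conventions, and the known limitations.

## Analysis procedure

**Normalization.** ASV counts are relativized per million within each
sample, filtered per experiment to the minimal set of most-abundant features
covering 99.95% of cumulative abundance, intersected across experiments, and
quantile normalized (Bolstad-style: each sample is mapped onto the
cross-sample mean of order statistics; tied values receive the mean of the
reference values at the tied positions). The 99.95% rule is read as "keep
the high-abundance prefix": features are ranked by total abundance across
all samples and the shortest prefix whose cumulative share reaches the
threshold is kept, so only the bottom 0.05% tail of abundance is discarded.
Host parameters are divided by their within-experiment median, which puts
the two experiments on a common scale while preserving fold-change
semantics; this requires strictly positive measurements. A second path used
only for response-group classification takes raw counts to per-sample
relative proportions and divides each feature by its mean across all
samples.

**Diversity.** Shannon index (natural log by default), observed-feature
counts, Bray-Curtis dissimilarities, classical PCoA (double-centering,
eigendecomposition, positive eigenvalues only; each axis's sign is fixed so
its largest-magnitude coordinate is positive), and Clarke's ANOSIM
(R = difference of mean between- and within-group dissimilarity ranks over
M/2, p from seeded label permutations with the add-one estimator,
999 permutations by default).

**Differential testing with cross-experiment consistency.** A feature is
only eligible for significance if its fold-change direction (sign of the
group-mean difference) agrees across both experiments; ties (exactly equal
means) count as inconsistent. Eligible features are tested by Mann-Whitney U
on the pooled samples — exact p by full enumeration when the combined sample
size is at most 20 with no ties, otherwise the normal approximation with tie
and continuity corrections — followed by Benjamini-Hochberg control over the
tested set. Host parameters use a one-tailed test in the shared fold-change
direction at FDR 0.05 (the direction is data-driven: improvements can be
decreases, e.g. glucose, or increases, e.g. Gcg); ASVs use a two-tailed test
at FDR 0.1. Family-level analysis tests each experiment separately
(two-tailed, p < 0.05), requires fold-change consistency, and combines the
per-experiment p-values with Fisher's method (X² = −2Σln pᵢ against
chi-square with 2k df).

**Response-group classification.** Over the three comparisons WD vs ND,
WD_Ch vs WD and WD_Ch vs ND (on mean-normalized relative abundances, pooled
two-tailed p-values plus per-experiment sign consistency), each ASV is
labeled `reversed` (shifted by the diet, shifted back by the treatment),
`treatment_only` (shifted only under treatment) or `diet_only` (shifted by
diet regardless of treatment). The rules are mutually exclusive. The default
significance threshold is p < 0.05, the convention of the original study's
heatmap figure; the looser p < 0.1 stated in its methods text is available
via `AnalysisConfig(heatmap_p_threshold=0.1)`. We default to 0.05 because,
at this design's sample sizes, the 0.1 variant admits roughly one false
`reversed` call for every two true ones (the WD arm is shared by two of the
three comparisons, so a chance fluctuation of the WD group mean produces
spuriously "reversed" patterns), whereas 0.05 keeps the empirical false
discovery rate of the `reversed` set near 0.15–0.2 at ~0.9 sensitivity.

**Network construction.** Nodes are the significant ASVs plus significant
host parameters for the WD_Ch vs WD comparison. Within the treated group
only, Spearman correlations are computed per experiment and on the pooled
(concatenated after per-experiment normalization) samples; Spearman p-values
use the t-distribution approximation with n−2 df (exact permutation p
available for small n). An edge is kept iff (1) the per-experiment
correlation signs agree and are nonzero, (2) the pooled p is below 0.05, and
(3) the causality filter passes: the pooled correlation sign equals the
product of the endpoints' fold-change signs. The causality filter is the
standard "correlation inequality" screen — an edge whose sign contradicts
how its endpoints moved between conditions cannot reflect a consistent
causal chain and is removed; it is the only such rule expressible from the
quantities this pipeline computes. Missing host values are deleted pairwise.
The network is a simple undirected graph; the main component is the largest
connected component (ties broken by node count, then by lexicographically
smallest member).

**Key-node ranking.** For every node, degree and bipartite betweenness
centrality (BiBC) between the microbial and host node groups:
BiBC(v) = Σ over pairs (s ∈ microbes, t ∈ host parameters), s ≠ v ≠ t, of
σ_st(v)/σ_st, where σ_st counts shortest s–t paths and σ_st(v) those through
v; disconnected pairs contribute nothing. BiBC is computed by a Brandes-type
dependency accumulation restricted to cross-group pairs (sources taken from
the smaller group) and is left unnormalized — it "counts paths" — with a
pair-count-normalized variant available by config. ASVs are ranked by BiBC
descending, ties by degree then id, and the (degree, BiBC) Pareto frontier
is reported alongside.

**Random-network validation.** The null model draws uniform random simple
graphs G(n, m) with exactly the real network's node and edge counts (no
self- or multi-edges; sampled as m distinct index pairs), reassigns the two
group labels uniformly at random with the real group sizes, and records each
network's maximum-BiBC node's (degree, BiBC) pair (BiBC ties broken toward
higher degree; the maximum-degree node is recorded alongside, since "largest
BiBC and degree" does not define a unique composite). Over 10,000 such
networks this yields an empirical density of random extremes, and the upper
tail probability P(degree ≥ d AND BiBC ≥ b) measures how likely a hub at
least as prominent as an observed node would be by chance. The 2D histogram
bins raw frequencies on an integer degree grid with 50 BiBC bins by default
(configurable). A log–log least-squares fit of the degree histogram (k ≥ 1,
nonzero counts) provides the usual power-law diagnostic of biological
networks.

## Configuration defaults

| parameter | default | meaning |
|---|---|---|
| `cumulative_abundance_threshold` | 0.9995 | abundance-prefix filter per experiment |
| `heatmap_p_threshold` | 0.05 | response-group significance (0.1 variant available) |
| `host_fdr` | 0.05 | BH level, one-tailed host tests |
| `asv_fdr` | 0.1 | BH level, two-tailed ASV tests |
| `edge_p_threshold` | 0.05 | pooled Spearman p for edges |
| `n_null_networks` | 10,000 | random-graph ensemble size |
| `anosim_permutations` | 999 | label permutations |
| `shannon_base` | natural log | alpha-diversity base |

## Synthetic-data generator

`generate_study` emulates the two-experiment design so that every stage can
run and be validated without any external data: 2 experiments × 3 groups ×
5 mice, 200 ASVs.

*Counts.* ASV counts are negative binomial (Gamma–Poisson) with
per-ASV baseline log-means N(5.5, 1.5²) — about 51,000 reads per sample over
200 features, matching a typical MiSeq depth — dispersion (NB size) k = 3,
and per-sample lognormal depth factors with σ = 0.25 (depth CV ≈ 0.25; the
relativization step removes depth again, which is exactly what the tests
should exercise). Group structure enters through log-mean shifts of
magnitude ln 4: 14 `reversed` ASVs shift under WD and revert under WD_Ch,
31 `treatment_only` ASVs shift only under WD_Ch, 17 `diet_only` ASVs shift
under both; 138 null ASVs are identical across groups. Shift directions
alternate down the abundance ranking within each category so the heaviest
shifted taxa roughly cancel and group totals stay comparable — otherwise the
compositional denominator itself becomes a group effect and inflates false
`reversed` calls among null taxa.

*The bridge.* One reversed ASV is the planted regulator. In the treated
group, one gene and one phenotype are lognormal functions of its latent
log-abundance with measured rank correlation ≈ `bridge_strength` (0.8); the
latent loading is inflated by 1.16 to compensate rank attenuation from
sequencing depth, Poisson noise and finite samples, a factor calibrated by
Monte-Carlo so the realized treated-group Spearman correlation averages the
configured value. The other reversed ASVs form a co-responding module around
the bridge (rank correlation `module_coupling` = 0.7), the way co-varying
guilds appear in real communities; module members draw a lognormal latent
with the NB's log-scale variance, re-allocating a share of it to the bridge
axis so that coupling changes neither their marginal means nor variances
(and therefore does not degrade differential power). All coupling
coefficients are signed by the endpoints' fold-change directions, so genuine
associations are exactly the ones the causality filter admits.

*Host parameters.* Six phenotypes (diet-induced, restored by treatment) and
five genes (treatment-only response) with lognormal noise (σ = 0.3) around
group offsets of 0.8 on the log scale — large enough that all host
parameters are detectably shifted at n = 10 pooled, mirroring a study in
which all measured host parameters entered the network. Non-bridge
parameters share a "metabolic state" factor (variance share 0.55) that makes
host readouts co-vary as metabolic panels do; in the treated group that
factor carries a mild bridge-axis component (loading 0.625 ·
`bridge_strength`).

*What is not emulated.* Richness and evenness differences between groups
(all ASVs are present everywhere, so Shannon and observed-ASV shifts are
absent); taxonomy (no lineage simulation); chimeras and raw reads;
phylogenetic structure; batch effects beyond the per-experiment independent
draws. Passing recovery tests therefore demonstrate the statistical
machinery on data with the assumed correlation and effect structure, not
performance on real sequencing artifacts.

## Numerical conventions and edge cases

- All randomness flows from one seed through a fixed `SeedSequence`
  derivation to per-stage seeds (all < 2³¹), so single stages can be re-run
  in isolation and whole runs are byte-identical per seed.
- Scale tags on count tables enforce the normalization order; operations
  refuse inputs on the wrong scale.
- Ties: quantile normalization averages reference values over tied runs;
  Mann-Whitney switches to the tie-corrected normal approximation; ANOSIM
  uses mid-ranks; BiBC ties in the null-ensemble summary resolve toward
  higher degree; ranking ties resolve by degree, then node id; equal-sized
  components resolve by smallest member.
- Degenerate inputs: all-zero samples, zero medians, constant vectors in
  correlations, p = 0 in Fisher's method, and infeasible planted-set sizes
  all raise informative errors; zero-mean features in mean normalization are
  zeroed with a warning; an edgeless network's "main component" is the
  lexicographically smallest single node.
- Spearman correlations that are undefined (constant node within the treated
  samples) exclude the pair rather than the node.

## Known limitations

- With five mice per group, the pooled treated-group sample is n = 10; the
  edge filter then requires |ρ| ≥ 0.65, and about 2–3% of all null node
  pairs pass the full filter chain by chance (sign consistency is nearly
  free once the pooled correlation is large, and the causality screen
  removes only half of chance edges). A typical run therefore carries tens
  of chance edges, whose random-graph structure contains high-BiBC
  articulation nodes. Competing hubs of this origin often outrank the
  planted bridge: the bridge reliably reaches the top handful of ASVs (and
  its edges are the strongest genuine ones), but its exact top-1 BiBC rank
  is not stable across simulations at this sample size.
- Relatedly, any ASV correlated with the bridge is almost equally correlated
  with the bridge's strongly-coupled host targets, so module members form
  direct ASV–host "shortcut" edges that bypass the bridge on shortest paths.
  This caps the bridge's own BiBC; it is an intrinsic property of
  threshold-based correlation networks around a strong hub, not an artifact
  of this implementation.
- Pooling two experiments of five samples also means each variable's
  treated-group mean carries a between-experiment sampling offset; aligned
  offsets inflate pooled correlations, which is part of why the chance-edge
  rate exceeds the nominal 5% × ½ × ½. The per-experiment sign-consistency
  requirement mitigates but does not remove this.
- ANOSIM permutation p-values are estimated, not exact; with 999
  permutations the smallest attainable p is 0.001.
- The exact tie and permutation conventions of external web tools differ;
  printed third-party ANOSIM/PCoA values are not expected to replicate to
  the last digit on identical data.
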