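# tknet — transkingdom network analysis of microbiome–host studies

`tknet` is a Python library (with a thin CLI) for the network-based analysis
of paired microbiome and host-physiology data from multi-experiment designs.
The motivating setting is a mouse study of the bile-acid sequestrant
cholestyramine: three diet groups (normal diet ND, Western diet WD, and WD
with 2% cholestyramine, WD+Ch), five mice per group, repeated in two
independent experiments, with 16S ASV tables, metabolic phenotypes and
gene-expression measurements per animal. The scientific question is which
gut microbes are candidate *mediators* of the host's response to treatment —
not merely which ones change in abundance.

The pipeline reproduces the full analysis chain:

1. **Normalization** — per-million relativization, a 99.95%
   cumulative-abundance filter per experiment, cross-experiment feature
   intersection, quantile normalization; per-experiment median
   normalization of host parameters.
2. **Diversity** — Shannon index, observed features, Bray-Curtis distances,
   PCoA, and Clarke's ANOSIM with seeded permutations.
3. **Differential analysis** — features must share their fold-change
   direction across both experiments, then pooled Mann-Whitney U tests with
   Benjamini-Hochberg control (ASVs: two-tailed, FDR 0.1; host parameters:
   one-tailed in the shared direction, FDR 0.05); family-level tests
   combined across experiments with Fisher's method; and a three-way
   response-group classifier (diet-reversed / treatment-only / diet-only).
4. **Network reconstruction** — Spearman correlations within the treated
   group, keeping an edge only if the per-experiment correlation signs
   agree, the pooled p < 0.05, and the correlation sign equals the product
   of the endpoints' fold-change signs (the "correlation inequality" /
   causality filter).
5. **Key-node ranking** — degree and *bipartite betweenness centrality*
   (BiBC): for node v and the microbe/host bipartition,
   `BiBC(v) = Σ_{s∈microbes, t∈host} σ_st(v)/σ_st`, the summed fraction of
   shortest cross-kingdom paths through v.
6. **Random-network validation** — 10,000 Erdős–Rényi G(n, m) graphs with
   the real network's size and group proportions; the empirical density of
   each random network's best (degree, BiBC) node gives a tail probability
   for observing a hub as prominent as a candidate by chance.

A first-class synthetic-data module generates the full two-experiment study
with planted ground truth — response-category ASV sets and one "bridge" ASV
whose latent abundance drives a gene and a phenotype in the treated group —
so every stage is testable end-to-end with no external data. See
[docs/methods.md](docs/methods.md) for the model, parameter defaults and
known limitations.

## Worked example

```python
from tknet import AnalysisConfig, SimulationConfig, generate_study, truth_report
from tknet.pipeline import run_pipeline

study = generate_study(SimulationConfig(seed=42))
res = run_pipeline(study, AnalysisConfig(rng_seed=42), null_count=10_000)

print(res.response_labels.value_counts().to_dict())
print(truth_report(study.truth, res.response_labels.to_dict())[["tp", "fp", "sensitivity", "fdr"]])
```

prints (seed 42):

```
{'none': 129, 'treatment_only': 29, 'diet_only': 18, 'reversed': 16}
                tp  fp  sensitivity       fdr
category
reversed        13   3     0.928571  0.187500
treatment_only  27   2     0.870968  0.068966
diet_only       16   2     0.941176  0.111111
```

Of the 14 planted diet-reversed ASVs, 13 are recovered (3 false calls among
16), with similar recovery for the other planted categories. The network
stage then surfaces the planted bridge microbe:

```
network: 62 nodes, 93 edges, main component 48 nodes
planted bridge ASV47: degree=8, BiBC=91.9, rank 3/51 among ASVs
probability a random network's best node matches it: 0.2224
```

The bridge sits in the top handful of ASVs by bottleneck centrality with the
strongest genuine host correlations; its tail probability under the matched
random ensemble quantifies how unusual that position is (near zero in runs
where it dominates; see the methods note for why its exact top-1 rank is
unstable at five mice per group).

The same stages are scriptable from a shell:

```bash
tknet simulate --outdir study/ --seed 42
tknet run-all --config run.yaml --outdir results/ --seed 42
tknet null --n 84 --m 154 --group1 73 --group2 11 --count 10000 --seed 1 --out null.tsv
```

and `examples/` contains one short narrative script per capability.

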