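"""Generate a synthetic two-experiment mouse study with planted structure.

Two experiments x three diet groups (ND, WD, WD+cholestyramine) x five mice,
with negative-binomial ASV counts, three planted ASV response categories, and
one "bridge" ASV whose latent abundance drives a gene and a phenotype in the
treated group.
"""

from tknet import SimulationConfig, generate_study

cfg = SimulationConfig(seed=42)
study = generate_study(cfg)

print(f"experiments: {sorted(study.counts)}")
print(f"ASV count table per experiment: {study.counts[1].shape} (features x samples)")
print(f"host parameters: {study.host.data.shape[0]} "
      f"({(study.host.info['kind'] == 'phenotype').sum()} phenotypes, "
      f"{(study.host.info['kind'] == 'gene').sum()} genes)")
print("planted categories:", study.truth.membership.value_counts().to_dict())
print(f"bridge ASV: {study.truth.bridge_asv_id} -> "
      f"{study.truth.bridge_gene_id}, {study.truth.bridge_phenotype_id}")

# The planted categories define which ASVs a correct analysis should call
# diet-reversed (14), treatment-only (31) and diet-only (17); the bridge ASV
# is the ground-truth microbial regulator the network stage should surface.
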