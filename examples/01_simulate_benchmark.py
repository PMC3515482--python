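"""Generate a synthetic multi-study GWAS benchmark with planted signal.

Builds a small genome, block-LD SNP map, and a category database in which
two planted categories carry genes with stochastically small p-values,
then prints what was planted — the ground truth later examples recover.
"""

from pathgwas.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    n_genes=200,
    n_categories=50,
    n_planted=2,
    n_studies=2,
    signal_gene_fraction=0.4,
    signal_beta_a=0.15,
    seed=11,
)
ds = simulate_dataset(cfg)

print(f"genes: {len(ds.genes)}  SNPs: {len(ds.snps)}  LD pairs: {len(ds.ld)}")
print(f"categories: {len(ds.gene_sets)}  studies: {sorted(ds.studies)}")
print(f"planted categories: {sorted(ds.truth.planted_category_ids)}")
for sid, genes in sorted(ds.truth.signal_genes_by_study.items()):
    print(f"  {sid}: {len(genes)} signal genes (one causal SNP each)")
# Null SNPs draw p ~ Uniform(0,1); each signal gene's causal SNP draws
# p ~ Beta(0.15, 1), so Pr(p < t) = t^0.15 — e.g. 64% below 0.05.
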