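"""Map associated SNPs to genes and test gene sets for over-representation.

Uses the toy annotation shipped with the simulator; categories with 10 or
fewer (or 1000 or more) genes are excluded before testing, and q-values
are BH-adjusted over the retained categories.
"""

import milknet as mk

cfg = mk.demo_config("scratch_example", seed=3).simulate
cohort = mk.simulate_cohort(cfg)
toy = mk.make_toy_annotation(cohort.genotypes, cfg)

table, _, _ = mk.gwas_scan(cohort.genotypes, cohort.phenotypes, "kappa_cn")
assignment = mk.map_snps_to_genes(cohort.genotypes.snp_map, toy.annotation, flank_bp=15_000)
sig = mk.significant_genes(table, assignment, alpha=0.05)["kappa_cn"]
print(f"{len(assignment.universe())} genes with >=1 SNP; {len(sig)} significant for kappa_cn")

res = mk.fisher_enrichment(sig, assignment.universe(), toy.gene_sets)
print(res.head(5).to_string(index=False))
# p_fisher is the exact hypergeometric upper tail for the category overlap;
# a small q_value means more significant genes fall in the set than chance.
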