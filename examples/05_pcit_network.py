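"""PCIT co-association network, topology metrics and the best TF trio.

Edges survive when no node trio explains them away (PCIT) and |r| >= 0.8;
negative edge weights mark putative repression.
"""

import pandas as pd

import milknet as mk

cfg = mk.demo_config("scratch_example", seed=5).simulate
cohort = mk.simulate_cohort(cfg)
toy = mk.make_toy_annotation(cohort.genotypes, cfg)
grm = mk.build_grm(cohort.genotypes)

assoc = pd.concat(
    [
        mk.gwas_scan(cohort.genotypes, cohort.phenotypes, t, grm=grm)[0]
        for t in cohort.phenotypes.trait_names
    ],
    ignore_index=True,
)
awm = mk.build_awm(assoc, toy.annotation, key_trait="kappa_cn", min_other_traits=2)

corr = mk.pairwise_correlation(awm)
flags = mk.pcit(corr)
net = mk.filter_edges(corr, flags, min_abs_r=0.80, tf_genes=set(toy.tf_genes))
print(f"PCIT kept {flags.sum() // 2} pairs; |r|>=0.8 leaves {net.n_nodes} nodes, {net.n_edges} edges")

topo = mk.topology(net)
print("highest-degree genes:")
print(topo.head(3).to_string(index=False))

if len(net.tfs_in_network()) >= 3:
    trio = mk.best_tf_trio(net)
    print(f"best TF trio {trio.tf_ids} covers {len(trio.covered_targets)} targets "
          f"({trio.coverage_fraction:.0%} of non-TF genes)")
    print(trio.per_tf.to_string(index=False))
# frac_repressed is the share of a TF's targets connected by negative edges.
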