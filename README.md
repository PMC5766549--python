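# milknet

Mixed-model GWAS, gene-set enrichment and AWM–PCIT co-association
networks for milk protein genetics.

Milk protein composition — the casein fractions (β-CN, κ-CN, α_S1-CN,
α_S2-CN) and whey proteins (β-LG, α-LA) expressed as shares of total milk
nitrogen — drives cheese-making quality and is under strong genetic
control, with a major casein-cluster locus on BTA6 and the β-LG (*PAEP*)
region on BTA11.  `milknet` is a library for the integrated analysis
that dissects such traits on SNP-chip data:

1. **GRAMMAR-GC association scans.**  Per trait, fit the polygenic model
   `y = Xb + a + e` with `a ~ N(0, G σ²_g)` where `G` is built from the
   identity-by-state estimator
   `f_ij = (1/N) Σ_k (x_ik − p_k)(x_jk − p_k) / (p_k(1 − p_k))`
   (genotypes coded 0, ½, 1), regress the BLUP-adjusted residuals on each
   SNP, and correct with genomic control `λ = median(χ²)/0.4549`.
   Genomic heritability is `h² = σ²_g/(σ²_g + σ²_e)`; per-SNP variance is
   `2pqa²`.  Conditional scans fix top SNPs as covariates to expose
   secondary signals and quantify how much additive variance they absorb.
2. **Gene-set enrichment.**  SNPs with nominal P < 0.05 are assigned to
   genes within 15 kb, and GO/KEGG-style categories (>10 and <1000 genes)
   are tested one-sided with the exact hypergeometric tail, BH-adjusted.
3. **Association Weight Matrix (AWM).**  A genes × traits matrix of
   standardized SNP effects (z = β/SE) anchored to a key phenotype
   (κ-casein by default): SNPs associated with the key trait (P ≤ 0.05)
   or with ≥3 other traits (P < 0.05), within 10 kb of a gene, one SNP
   per gene.  A permutation test compares the phenotypic variance the
   AWM SNPs capture against random SNP sets of equal size.
4. **PCIT network and TF trios.**  Pairwise correlations of AWM rows are
   filtered by the partial-correlation-and-information-theory (PCIT)
   trio test and an |r| ≥ 0.80 cut; the network gets degree/closeness/
   betweenness metrics and an exhaustive search for the transcription-
   factor trio whose direct neighborhoods cover the most genes, with
   targets labelled induced (positive edge) or repressed (negative edge).

A synthetic-cohort generator reproduces the study design (herd-date,
parity and days-in-milk fixed effects, clustered trait correlations, a
~70%-variance key-trait QTL, per-trait h² from 0.09 to 0.83) so the
entire pipeline is testable without access to animal data.

## Worked example

```python
import milknet as mk

# simulate a demo cohort and run the whole analysis
cfg = mk.demo_config("demo_out", seed=0)       # 300 cows, 3,000 SNPs, 6 traits
manifest = mk.run_pipeline(cfg)
print(manifest["n_significant_snps"])           # 5
print(manifest["conditional"]["sigma_g2_change"])  # -0.496
print(manifest["observed_variance_fraction"])   # 0.567
print(manifest["null_mean_variance_fraction"])  # 0.011
print(manifest["permutation_p"])                # 0.002
print(manifest["network_nodes"], manifest["network_edges"])  # 85 2525
```

With seed 0 this prints the numbers shown: 5 SNPs pass the genome-wide
threshold P < 5×10⁻⁵ (the simulated κ-CN QTL and its neighbours);
conditioning on the top κ-CN SNP removes ~50% of the estimated additive
variance, mirroring how a casein-cluster peak dominates the trait; the
AWM SNPs capture 57% of the key trait's phenotypic variance versus ~1%
for random SNP sets (permutation P = 0.002, the floor at R = 500); and
the PCIT-filtered co-association network retains 85 genes and 2,525
edges from which the best TF trio is selected.  All stage outputs (QC
report, per-trait association tables, variance components, enrichment,
AWM, network SIF/GraphML, node metrics, TF trio) are written under
`demo_out/` together with a checksummed manifest; re-running with the
same seed reproduces every file byte-identically.

The same stages are exposed individually (`simulate_cohort`, `apply_qc`,
`build_grm`, `fit_polygenic`, `gwas_scan`, `conditional_scan`,
`map_snps_to_genes`, `fisher_enrichment`, `build_awm`,
`variance_explained_permutation`, `pcit`, `filter_edges`, `topology`,
`best_tf_trio`) — see `examples/` for one short script per capability —
and as a thin CLI:

```sh
milknet run --demo --outdir demo_out --seed 0
milknet gwas --bfile cohort --pheno cohort.pheno.tsv --trait kappa_cn --out assoc.tsv
```

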