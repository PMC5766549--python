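# Methods

`milknet` implements an integrated genetic analysis of correlated milk
nitrogen-fraction phenotypes: a mixed-model association scan per trait,
genomic heritability, conditional scans, gene-set over-representation,
an Association Weight Matrix (AWM) anchored to a key phenotype, and a
partial-correlation (PCIT) gene co-association network with
transcription-factor (TF) trio selection.  This note records the models,
the defaults and why, the numerical choices, and what the synthetic data
do and do not emulate.

## Polygenic model and GRM

Each trait is analysed under

    y = X b + a + e,    a ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)

with fixed effects for herd-date contemporary group, parity class
(1, 2, 3, >=4) and 30-day days-in-milk class.  The marker-based kinship is
the identity-by-state estimator

    f_ij = (1/N) sum_k (x_ik - p_k)(x_jk - p_k) / (p_k (1 - p_k)),

with genotypes coded 0, 1/2, 1 and `p_k` the "+" allele frequency.  Under
Hardy-Weinberg equilibrium `E[f_ii] = 1/2`, so `f` is a kinship matrix; the
relationship matrix entering the model is `G = 2 f` (standard quantitative
genetics), which puts `sigma_g^2` on the observed scale and makes the
genomic heritability `h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)`
comparable to the simulated variance ratio.  Missing genotypes are
mean-imputed for the GRM and excluded pairwise in per-SNP regressions.

REML uses the spectral decomposition of `G`: after rotating the data by
its eigenvectors the covariance is diagonal in the variance ratio, so the
restricted likelihood is maximised by a 1-D bounded Brent search over
`h^2 in [0, 0.999]` (tolerance 1e-8) with the fixed effects and the total
variance profiled out.  Negative eigenvalues (numerical) are floored at
zero.  Samples missing a trait are dropped for that trait only.

## GRAMMAR-GC association scan

Three steps: (1) fit the polygenic model; (2) regress its BLUP-adjusted
residuals `e_hat = sigma_e^2 V^-1 (y - X b_hat)` on each SNP dosage and
form the score statistic; (3) genomic control, `lambda = median(chi2) /
0.4549`, with P-values from `chi2 / max(lambda, 1)`.  `lambda` is
reported unfloored; the floor applies only to the P correction, since the
residual-scale deflation is handled separately by the gamma factor.

Residual-scale effect estimates are deflated relative to the mixed-model
estimates by a per-SNP factor

    gamma_k = sigma_e^2 (g_c' V^-1 g_c) / (g_c' g_c),

cheap to evaluate exactly once the GRM is eigendecomposed.  The scan
divides `beta` by the mean gamma and SE by its square root, so the
standardized effects `z = beta / SE` (the AWM entries) are recalibrated,
while the chi2/P columns remain the raw score test plus genomic control.
This choice keeps the null calibration of lambda independent of the
(noisy) h^2 estimate; effect-size recovery is verified on simulation.

Per-SNP variance is `2 p q a^2` with `a` the (recalibrated) additive
effect, and its share of additive variance uses the unconditional
`sigma_g^2` by default.  Conditional scans append the fixed SNP dosages
to `X` (dropping collinear columns with a warning), refit, rescan, and
report the change in `sigma_g^2` and `h^2`.  LD is the squared Pearson
correlation of dosages (composite, genotype-based).

## Marker QC

Retained SNPs need call rate > 0.95, MAF > 0.005 (non-missing calls
only), and an exact Hardy-Weinberg test P > 0.001 Bonferroni-corrected.
The exact test sums genotype-configuration probabilities no larger than
the observed one (mid-P off — the conservative standard).  The Bonferroni
divisor is the pre-filter SNP count (the stated rule does not say which;
this is the choice, exposed in `QcThresholds`).  QC is order-independent
and idempotent by construction.

## Gene-set enrichment

SNPs map to every gene whose interval extended by 15 kb on both ends
contains them (inclusive boundaries; multi-assignment allowed).  A gene
is significant for a trait if any assigned SNP has GC-corrected P < 0.05.
Categories are tested one-sided for over-representation with the exact
hypergeometric tail; only categories with more than 10 and fewer than
1000 genes (after intersecting with the universe) are tested.  The gene
universe is all genes with at least one assigned SNP, computed globally.
"q-values" are Benjamini-Hochberg adjusted P-values over exactly the
filtered category list; significance is q < 0.05.  No gene-length bias
correction is applied — the test is a plain Fisher/hypergeometric test.

## AWM

A SNP enters the AWM if it is associated with the key trait (P <= 0.05)
OR with at least 3 other traits (P < 0.05) — the asymmetric inequalities
are deliberate — and lies strictly closer than 10 kb to its nearest
annotated gene.  The OR combination follows the source selection logic
(key-associated or multi-trait-associated); a stricter AND reading is
available via `combine="and"`.  One SNP per gene: smallest key-trait P,
ties by larger |z| on the key trait, then lowest genomic position — a
total order, so construction is deterministic and independent of input
order, and the row count equals the distinct-gene count.  `Ap` is the
mean number of other phenotypes associated (P <= 0.05) with the
key-associated SNPs; it is reported, not fed back into the >=3 rule.
Cells hold `z = beta/SE` from the gamma-recalibrated scan; a missing fit
sets the cell to 0 under a recorded mask rather than dropping the row.

Trait clustering uses distance `1 - r` on AWM columns with average
linkage (the linkage criterion is not dictated by the procedure; average
is the default here, toggleable).

The variance-explained permutation builds a GRM from the AWM SNPs,
records `h^2` from the polygenic fit, and compares it with the same
statistic for equally sized random SNP sets (without replacement,
excluding the AWM SNPs by default for a cleaner null; inclusion is a
flag).  `empirical_p = (1 + #{null >= observed}) / (R + 1)`.

## PCIT network

Gene-gene correlations are Pearson correlations of AWM rows.  For every
node trio PCIT computes the three first-order partial correlations and a
tolerance `eps` equal to the mean of the |partial/direct| ratios (terms
with |direct| < 1e-12 are skipped; denominators are clamped at 1e-12).
An edge is locally non-significant in a trio if its |r| is below
`eps`-scaled magnitudes of *both* other legs, and globally significant
iff no trio kills it.  The implementation vectorizes over the
conditioning node (O(n^3) time, O(n^2) memory) and is verified against a
naive triple loop.  Two boundary behaviours worth knowing: with equal
positive off-diagonal correlations every edge survives (no trio can
discriminate), while with equal negative correlations the ratio
|partial/direct| = 1/(1+v) exceeds 1 and the rule removes every edge.

Edges are retained when PCIT-significant AND |r| >= 0.80 (inclusive),
keeping the sign as the edge weight; filtering after PCIT is the default
order.  Topology uses unweighted shortest paths: degree, per-component
(Wasserman-Faust) closeness with harmonic centrality reported as the
disconnected-graph fallback, and normalized betweenness.

The best TF trio is found by exhaustive enumeration over all TF triples:
score = number of distinct direct neighbors of the trio (the trio itself
excluded), ties by larger summed |edge weight| to the covered targets,
then lexicographic ids.  Direct neighbors only — "regulated" means
connected at path length 1; longer-range spanning is out of scope.
Greedy selection provably differs on constructed fixtures, hence the
exhaustive search.  A target counts as repressed/induced by a TF when
their edge weight is negative/positive; zero-weight edges are excluded
with a warning.

## Synthetic cohorts

The generator emulates the study design: ~1,011 cows in 85 herd-date
groups with 4 parity and ten 30-day days-in-milk classes; ~37,568
biallelic SNPs on 29 autosomes drawn per SNP as Binomial(2, p) under HWE
with p ~ U(0.05, 0.5); 15 traits with the study's genomic heritabilities
(0.094-0.833) in three correlation clusters; a major casein-cluster-like
QTL on chromosome 6 at 70% of the key trait's additive variance plus
secondary loci (beta-/alpha-S1-casein 0.48/0.38 nearby, a chromosome-11
beta-lactoglobulin locus at 0.25).  Per trait, phenotypes are
`herd + parity + DIM + QTL + polygenic + residual` on a unit
genetic-plus-residual scale (`sigma_g^2 = h^2`); the polygenic term is
drawn from `N(0, 2f h^2 (1 - qtl_fraction))` using the *same* kinship
estimator as the analysis, so simulation and inference share one genetic
model.  Residuals are equicorrelated within phenotype clusters
(within-cluster correlation 0.6 by default — the study reports no
phenotypic correlations, so the magnitude is a free parameter).  Fixed
effect class SDs default to 0.30 (herd), 0.15 (parity), 0.15 (DIM):
herd-date contemporary groups dominate environmental structure in field
data; magnitudes are otherwise unreported.  Traits the published
three-group clustering leaves unplaced (milk yield, true protein N,
other N) are assigned by composition: the minor/other N compounds with
cluster 1, true protein N with cluster 2.

Optional adjacent-SNP LD is induced by copying the previous dosage
column per individual with a configured probability (default 0 —
independent markers).  This is *not* coalescent-realistic LD: there are
no haplotype blocks, no allele-frequency drift, no pedigree.  Passing
tests therefore demonstrate the statistical machinery under the assumed
model, not robustness to real-genome LD structure, ascertainment or
population stratification.  RNG substreams come from
`SeedSequence([seed, k])`, so a fixed seed gives byte-identical PLINK,
phenotype and annotation files and nearby seeds give independent
replicates.

The toy annotation tiles ~0.5 genes per SNP (20 kb bodies centred on SNP
positions, 10% duplicated with a half-length shift to create deliberate
overlaps), emits gene sets whose sizes straddle the >10/<1000 filter
(including one of exactly 10), and flags ~8% of genes as TFs.

## Problem sizes and checks

The acceptance checks run at the sizes their contracts state: GRM
moments at n=200 with 5,000 SNPs; heritability recovery at n=500 with
2,000 SNPs, 20 replicates per h^2 level in {0.2, 0.5, 0.8} (the
20-replicate mean is compared with truth — the single-fit REML sampling
SD at this design is ~0.12 by the eigen-spectrum Fisher information, so
per-fit agreement tighter than that is not a meaningful target); null
calibration at n=500 with 10,000 SNPs; QTL power at n=1,000 with 3,000
SNPs and 20 replicates; permutation calibration at n=200 with a 240-SNP
panel, 120-SNP sets, R=200 and 50 repeats (sizes chosen so subset GRMs
capture clearly positive variance, keeping the empirical P off the
h^2 = 0 boundary where ties would distort uniformity).  The packaged
demo is n=300, 3,000 SNPs, 6 traits, R=500, chosen to exercise every
stage end-to-end on one CPU while leaving a nonempty network and >=3
network TFs.  The demo's AWM rule uses `min_other_traits=2` because only
5 non-key traits exist (the >=3-of-14 rule scaled to the demo's trait
count).

## Known limitations

- Single-GRM, single-record model: no repeated measures, dominance,
  multi-GRM partitioning or X-dosage handling.
- The gamma recalibration is a scalar; SNPs in strong LD with large-h^2
  polygenic background have SNP-specific deflation that a scalar cannot
  fully undo.
- Percent-Va uses the residual-scale recalibrated effect; for a very
  large QTL the polygenic fit absorbs part of the QTL variance, so %Va
  is conservative.
- PCIT's published contract is reproduced from its algorithmic
  definition and checked against a naive oracle, not against any legacy
  binary.
- The enrichment stage tests over-representation only; gene-length and
  LD-clumping biases of SNP-to-gene significance are not modelled.
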