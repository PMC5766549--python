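"""Synthetic dairy-cohort generator.

Emulates the statistical design the analysis assumes: ~1,000 cows in
herd-date contemporary groups with parity and 30-day days-in-milk classes,
a medium-density SNP panel on 29 autosomes, 15 correlated milk
nitrogen-fraction phenotypes organised in three correlation clusters, a
casein-cluster-like major QTL contributing up to ~70% of the additive
variance of the key trait (kappa-casein proportion), and a polygenic
background with per-trait heritabilities spanning ~0.1-0.8.

The defaults of :class:`SimConfig` are the study-scale conditions; tests
and the packaged demo pass smaller sizes explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations as ann_io
from .errors import ConfigurationError
from .genotypes import GenotypeMatrix, PhenotypeTable, write_phenotypes, write_plink
from .gwas import build_grm

# The 15 traits: milk yield plus the milk nitrogen fractions
# (caseins, whey proteins and non-protein N), as shares of total milk N.
TRAIT_NAMES = [
    "milk_yield",
    "protein_n",
    "casein_total",
    "beta_cn",
    "kappa_cn",
    "alpha_s1_cn",
    "alpha_s1p_cn",
    "alpha_s1p_ratio",
    "alpha_s2_cn",
    "whey_total",
    "beta_lg",
    "alpha_la",
    "other_n",
    "minor_n",
    "mun",
]

# Genomic heritabilities of the 15 traits (same order as TRAIT_NAMES).
DEFAULT_H2 = {
    "milk_yield": 0.094,
    "protein_n": 0.402,
    "casein_total": 0.133,
    "beta_cn": 0.833,
    "kappa_cn": 0.681,
    "alpha_s1_cn": 0.661,
    "alpha_s1p_cn": 0.171,
    "alpha_s1p_ratio": 0.183,
    "alpha_s2_cn": 0.365,
    "whey_total": 0.523,
    "beta_lg": 0.558,
    "alpha_la": 0.194,
    "other_n": 0.402,
    "minor_n": 0.363,
    "mun": 0.248,
}

# Three phenotype correlation clusters: non-protein/minor N compounds;
# whey proteins, total casein and the alpha-S fractions; the casein /
# urea / phosphorylation group.  Milk yield and protein N, which the
# clustering leaves unplaced, are assigned by composition.
DEFAULT_CLUSTERS = {
    "milk_yield": 1,
    "minor_n": 1,
    "other_n": 1,
    "mun": 3,
    "whey_total": 2,
    "casein_total": 2,
    "alpha_s2_cn": 2,
    "alpha_la": 2,
    "protein_n": 2,
    "beta_cn": 3,
    "kappa_cn": 3,
    "beta_lg": 2,
    "alpha_s1_cn": 2,
    "alpha_s1p_cn": 3,
    "alpha_s1p_ratio": 3,
}


@dataclasses.dataclass
class QtlSpec:
    """A simulated QTL: chromosome, base-pair position, and the fraction
    of each target trait's additive variance it explains."""

    chrom: int
    pos: int
    effects: dict[str, float]

    def __post_init__(self) -> None:
        for trait, frac in self.effects.items():
            if not 0.0 < frac < 1.0:
                raise ConfigurationError(
                    f"QTL variance fraction {frac} for {trait!r} outside (0, 1)"
                )


def default_qtls() -> list[QtlSpec]:
    """A casein-cluster-like locus on chromosome 6 (major kappa-casein QTL
    at ~70% of additive variance, with beta-/alpha-S1-casein effects at a
    nearby position) and a beta-lactoglobulin locus on chromosome 11."""
    return [
        QtlSpec(chrom=6, pos=87_400_000, effects={"kappa_cn": 0.70}),
        QtlSpec(
            chrom=6,
            pos=87_200_000,
            effects={"beta_cn": 0.48, "alpha_s1_cn": 0.38},
        ),
        QtlSpec(chrom=11, pos=104_300_000, effects={"beta_lg": 0.25, "whey_total": 0.20}),
    ]


@dataclasses.dataclass
class SimConfig:
    """Configuration of one synthetic cohort.  Defaults are study-scale."""

    n_individuals: int = 1011
    n_snps: int = 37568
    n_chromosomes: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    trait_names: list[str] = dataclasses.field(default_factory=lambda: list(TRAIT_NAMES))
    trait_clusters: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLUSTERS)
    )
    within_cluster_corr: float = 0.6
    h2: dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_H2))
    qtls: list[QtlSpec] = dataclasses.field(default_factory=default_qtls)
    n_herds: int = 85
    parity_classes: int = 4
    dim_classes: int = 10
    herd_sd: float = 0.30
    parity_sd: float = 0.15
    dim_sd: float = 0.15
    ld_copy_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ConfigurationError("need n_individuals >= 2 and n_snps >= 1")
        if not 0.0 <= self.ld_copy_prob < 1.0:
            raise ConfigurationError("ld_copy_prob outside [0, 1)")
        if not 0.0 <= self.within_cluster_corr < 1.0:
            raise ConfigurationError("within_cluster_corr outside [0, 1)")
        missing = [t for t in self.trait_names if t not in self.h2]
        if missing:
            raise ConfigurationError(f"traits without h2: {missing}")
        for t in self.trait_names:
            if not 0.0 <= self.h2[t] <= 0.99:
                raise ConfigurationError(f"h2[{t!r}]={self.h2[t]} outside [0, 0.99]")
        uncovered = [t for t in self.trait_names if t not in self.trait_clusters]
        if uncovered:
            raise ConfigurationError(f"traits without cluster: {uncovered}")
        for q in self.qtls:
            unknown = [t for t in q.effects if t not in self.trait_names]
            if unknown:
                raise ConfigurationError(f"QTL targets unknown traits: {unknown}")
            if q.chrom > self.n_chromosomes:
                raise ConfigurationError(
                    f"QTL on chromosome {q.chrom} > n_chromosomes={self.n_chromosomes}"
                )


@dataclasses.dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """HWE genotypes: per SNP ``p ~ U(maf_range)``, dosage ~ Binomial(2, p).

    Adjacent-SNP LD is optionally induced by copying the previous SNP's
    dosage column with probability ``ld_copy_prob`` per individual.  Map
    positions are strictly increasing within chromosome; each configured
    QTL position is guaranteed to exist in the map (the nearest simulated
    position on that chromosome is moved onto it).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    m, n = config.n_snps, config.n_individuals

    # chromosome sizes as even split, remainder on the first chromosomes
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)

    positions = np.empty(m, dtype=np.int64)
    start = 0
    for c in range(1, config.n_chromosomes + 1):
        size = per_chrom[c - 1]
        gaps = rng.integers(20_000, 120_000, size=size)
        pos = np.cumsum(gaps) + 10_000
        used: set[int] = set()
        for q in config.qtls:
            if q.chrom == c and size > 0:
                order = np.argsort(np.abs(pos - q.pos))
                j = next(int(i) for i in order if int(i) not in used)
                pos[j] = q.pos
                used.add(j)
        if size > 1 and np.any(np.diff(pos) <= 0):
            pos = np.sort(pos)
        positions[start : start + size] = pos
        start += size

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosage = rng.binomial(2, p[None, :].repeat(n, axis=0)).astype(np.int8)
    if config.ld_copy_prob > 0:
        copy = rng.random((n, m)) < config.ld_copy_prob
        new_chrom = np.concatenate([[True], chroms[1:] != chroms[:-1]])
        copy[:, new_chrom] = False
        for k in range(1, m):
            mask = copy[:, k]
            if mask.any():
                dosage[mask, k] = dosage[mask, k - 1]

    snp_map = pd.DataFrame(
        {
            "snp": [f"snp_{c}_{pos}" for c, pos in zip(chroms, positions)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "B",
        }
    )
    sample_ids = [f"cow_{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimConfig) -> SyntheticCohort:
    """Simulate trait values on top of the given genotypes.

    Per trait ``y = herd + parity + DIM + QTL + polygenic + residual`` on a
    unit genetic-plus-residual variance scale: ``sigma_g^2 = h^2`` and
    ``sigma_e^2 = 1 - h^2``.  The polygenic term is drawn from
    ``N(0, 2f h^2 (1 - qtl_fraction))`` using the same kinship estimator
    as the analysis; residuals are correlated within phenotype clusters at
    ``within_cluster_corr``.  Ground truth (true h^2, QTL effects and
    realized variance fractions) is recorded in ``truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = genotypes.n_individuals
    traits = config.trait_names

    # fixed-effect classes
    herd = rng.integers(0, config.n_herds, size=n)
    parity = rng.integers(0, config.parity_classes, size=n)
    dim = rng.integers(0, config.dim_classes, size=n)
    herd_eff = rng.normal(0.0, config.herd_sd, size=config.n_herds)
    parity_eff = rng.normal(0.0, config.parity_sd, size=config.parity_classes)
    dim_eff = rng.normal(0.0, config.dim_sd, size=config.dim_classes)
    fixed_part = herd_eff[herd] + parity_eff[parity] + dim_eff[dim]

    # QTL lookup: every configured locus must exist in the map
    qtl_cols: dict[tuple[int, int], np.ndarray] = {}
    snp_by_locus = {
        (int(c), int(pos)): k
        for k, (c, pos) in enumerate(
            zip(genotypes.snp_map["chrom"], genotypes.snp_map["pos"])
        )
    }
    if config.qtls:
        dosage_f = genotypes.dosage_float(impute=True)
        for q in config.qtls:
            key = (q.chrom, q.pos)
            if key not in snp_by_locus:
                raise ConfigurationError(
                    f"QTL position chr{q.chrom}:{q.pos} absent from the SNP map"
                )
            qtl_cols[key] = dosage_f[:, snp_by_locus[key]]
        del dosage_f

    # polygenic covariance via the analysis-time kinship estimator;
    # monomorphic SNPs (possible at small n) are excluded for the GRM only
    p = genotypes.allele_freq()
    poly = np.flatnonzero((p > 0) & (p < 1))
    grm = build_grm(genotypes.select_snps(poly))
    a_rel = grm.relationship
    chol = np.linalg.cholesky(a_rel + 1e-8 * np.eye(n))

    qtl_frac_per_trait = {t: 0.0 for t in traits}
    for q in config.qtls:
        for t, frac in q.effects.items():
            qtl_frac_per_trait[t] += frac
    for t, f in qtl_frac_per_trait.items():
        if f >= 1.0:
            raise ConfigurationError(f"QTL fractions for {t!r} sum to {f} >= 1")

    # cluster-correlated residuals: equicorrelation within cluster
    cluster_of = [config.trait_clusters[t] for t in traits]
    shared: dict[int, np.ndarray] = {
        c: rng.standard_normal(n) for c in sorted(set(cluster_of))
    }
    rho = config.within_cluster_corr

    y = np.zeros((n, len(traits)))
    truth_qtl = []
    truth_traits = {}
    genetic_values = np.zeros((n, len(traits)))
    for j, t in enumerate(traits):
        h2 = config.h2[t]
        sigma_g2 = h2
        sigma_e2 = 1.0 - h2
        g_val = np.zeros(n)
        for q in config.qtls:
            if t not in q.effects:
                continue
            col = qtl_cols[(q.chrom, q.pos)]
            pk = col.mean() / 2.0
            var_needed = q.effects[t] * sigma_g2
            a = np.sqrt(var_needed / (2.0 * pk * (1.0 - pk)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            g_val += sign * a * (col - col.mean())
            truth_qtl.append(
                {
                    "trait": t,
                    "chrom": q.chrom,
                    "pos": q.pos,
                    "snp": genotypes.snp_map["snp"].iloc[snp_by_locus[(q.chrom, q.pos)]],
                    "effect": sign * a,
                    "va_fraction": q.effects[t],
                }
            )
        poly_var = (1.0 - qtl_frac_per_trait[t]) * sigma_g2
        g_val += chol @ rng.standard_normal(n) * np.sqrt(poly_var)
        resid = (
            np.sqrt(rho) * shared[cluster_of[j]] + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        ) * np.sqrt(sigma_e2)
        genetic_values[:, j] = g_val
        y[:, j] = fixed_part + g_val + resid
        realized = float(np.var(g_val) / (np.var(g_val) + np.var(resid)))
        truth_traits[t] = {
            "h2": h2,
            "sigma_g2": sigma_g2,
            "sigma_e2": sigma_e2,
            "realized_h2": realized,
            "cluster": cluster_of[j],
        }

    table = pd.DataFrame(
        {
            "id": genotypes.sample_ids,
            "herd_date": [f"hd_{h:03d}" for h in herd],
            "parity_class": [f"p{min(v + 1, 4)}" for v in parity],
            "dim_class": [f"d{v:02d}" for v in dim],
        }
    )
    for j, t in enumerate(traits):
        table[t] = y[:, j]
    phen = PhenotypeTable(table=table, trait_names=list(traits))
    truth = {
        "traits": truth_traits,
        "qtls": truth_qtl,
        "seed": config.seed,
        "n_individuals": n,
        "n_snps": genotypes.n_snps,
    }
    return SyntheticCohort(genotypes=genotypes, phenotypes=phen, truth=truth)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Genotypes + phenotypes in one call."""
    return simulate_phenotypes(simulate_genotypes(config), config)


# ---------------------------------------------------------------------------
# Toy annotation, gene sets and TF catalog
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ToyAnnotation:
    annotation: pd.DataFrame
    gene_sets: dict[str, list[str]]
    tf_genes: list[str]


def make_toy_annotation(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    genes_per_chrom: int | None = None,
    gene_length: int = 20_000,
    overlap_fraction: float = 0.1,
    n_gene_sets: int = 12,
    tf_fraction: float = 0.08,
) -> ToyAnnotation:
    """Tile gene intervals over the simulated map and emit gene sets / TFs.

    Genes are centred on SNP positions so that roughly half the markers
    fall inside or near a gene; a fraction of genes is duplicated with a
    shifted interval to create deliberate overlaps.  Gene-set sizes are
    spread across the enrichment size filter's boundaries (including sets
    of exactly 10 genes, which the strict ``>10`` filter must drop).  A
    configured fraction of genes is flagged as transcription factors.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    for c, sub in genotypes.snp_map.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        k = genes_per_chrom if genes_per_chrom is not None else max(2, len(pos) // 2)
        anchor_idx = np.unique(
            rng.choice(len(pos), size=min(k, len(pos)), replace=False)
        )
        for i, ai in enumerate(sorted(anchor_idx)):
            centre = int(pos[ai])
            start = max(1, centre - gene_length // 2)
            rows.append((f"gene_{c}_{i:04d}", int(c), start, start + gene_length - 1))
    ann = pd.DataFrame(rows, columns=ann_io.ANNOTATION_COLUMNS)
    # deliberate overlaps: shift a copy of some genes by half a length
    n_overlap = int(len(ann) * overlap_fraction)
    if n_overlap:
        pick = rng.choice(len(ann), size=n_overlap, replace=False)
        extra = ann.iloc[pick].copy()
        extra["gene_id"] = [f"{g}_ov" for g in extra["gene_id"]]
        extra["start"] = extra["start"] + gene_length // 2
        extra["end"] = extra["end"] + gene_length // 2
        ann = pd.concat([ann, extra], ignore_index=True)
    ann = ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    genes = ann["gene_id"].tolist()
    sizes = []
    for i in range(n_gene_sets):
        if i == 0:
            sizes.append(10)  # boundary: excluded by the strict >10 filter
        elif i == 1:
            sizes.append(11)  # boundary: smallest retained size
        else:
            sizes.append(int(rng.integers(12, max(13, min(60, len(genes))))))
    gene_sets = {
        f"SET_{i:03d}": sorted(
            rng.choice(genes, size=min(s, len(genes)), replace=False).tolist()
        )
        for i, s in enumerate(sizes)
    }
    n_tf = max(3, int(len(genes) * tf_fraction))
    tf_genes = sorted(rng.choice(genes, size=min(n_tf, len(genes)), replace=False).tolist())
    return ToyAnnotation(annotation=ann, gene_sets=gene_sets, tf_genes=tf_genes)


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: SyntheticCohort,
    outdir: str | Path,
    annotation: ToyAnnotation | None = None,
    prefix: str = "cohort",
) -> dict[str, str]:
    """Write PLINK genotypes, phenotype TSV, truth JSON and (optionally)
    BED annotation, GMT gene sets and the TF list.  Returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_plink(cohort.genotypes, outdir / prefix)
    paths["bed"] = str(outdir / f"{prefix}.bed")
    write_phenotypes(cohort.phenotypes, outdir / f"{prefix}.pheno.tsv")
    paths["phenotypes"] = str(outdir / f"{prefix}.pheno.tsv")
    (outdir / f"{prefix}.truth.json").write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True)
    )
    paths["truth"] = str(outdir / f"{prefix}.truth.json")
    if annotation is not None:
        ann_io.write_bed(annotation.annotation, outdir / f"{prefix}.genes.bed")
        ann_io.write_gmt(annotation.gene_sets, outdir / f"{prefix}.sets.gmt")
        ann_io.write_tf_list(annotation.tf_genes, outdir / f"{prefix}.tfs.txt")
        paths["annotation"] = str(outdir / f"{prefix}.genes.bed")
        paths["gene_sets"] = str(outdir / f"{prefix}.sets.gmt")
        paths["tf_list"] = str(outdir / f"{prefix}.tfs.txt")
    return paths
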