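"""Association Weight Matrix construction, trait clustering and the
variance-explained permutation test.

The AWM is a genes x traits matrix of standardized SNP effects
(``z = beta / SE``) anchored to a key phenotype (kappa-casein proportion
in the motivating study).  A SNP enters if it is associated with the key
trait (``P <= p_key``) or with at least ``min_other_traits`` other traits
(``P < p_other``) — the asymmetric inequalities mirror the published
selection rule — and lies strictly closer than ``gene_dist_bp`` to its
nearest annotated gene.  One SNP is kept per gene (smallest key-trait P;
ties by larger ``|z|`` on the key trait, then lowest genomic position), so
the row count equals the distinct-gene count.  ``Ap`` is the average
number of other phenotypes associated (``P <= p_key``) with the
key-associated SNPs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import EmptyResultError
from .genotypes import GenotypeMatrix
from .gwas import Grm, build_grm, fit_polygenic


@dataclasses.dataclass
class AWMatrix:
    """Genes x traits matrix of standardized SNP effects."""

    z: pd.DataFrame  # index: gene ids; columns: trait labels
    key_trait: str
    ap: float
    snp_of_gene: pd.Series  # gene id -> chosen SNP id
    mask: pd.DataFrame  # True where the underlying fit was missing (z set to 0)
    selection: pd.DataFrame  # per-SNP audit trail of the selection rule

    def __post_init__(self) -> None:
        if self.key_trait not in self.z.columns:
            raise ValueError(f"key trait {self.key_trait!r} not among AWM columns")
        if self.z.index.duplicated().any():
            raise ValueError("duplicate gene rows in AWM")
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("non-finite z values in AWM")

    @property
    def snps(self) -> list[str]:
        return self.snp_of_gene.tolist()


def nearest_gene_distance(snp_map: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Distance (bp) from each SNP to its nearest gene; 0 inside a gene.

    Returns a frame with columns ``snp, gene_id, distance``; SNPs on
    chromosomes without genes get distance ``inf`` and a null gene.
    """
    rows = []
    by_chrom = {c: sub for c, sub in annotation.groupby("chrom")}
    for c, snps in snp_map.groupby("chrom"):
        genes = by_chrom.get(c)
        for snp, pos in zip(snps["snp"], snps["pos"]):
            if genes is None or not len(genes):
                rows.append((snp, None, np.inf))
                continue
            start = genes["start"].to_numpy()
            end = genes["end"].to_numpy()
            dist = np.where(
                pos < start, start - pos, np.where(pos > end, pos - end, 0)
            ).astype(float)
            order = np.lexsort((genes["gene_id"].to_numpy(), dist))
            best = order[0]
            rows.append((snp, genes["gene_id"].iloc[best], float(dist[best])))
    return pd.DataFrame(rows, columns=["snp", "gene_id", "distance"])


def build_awm(
    assoc: pd.DataFrame,
    annotation: pd.DataFrame,
    key_trait: str,
    p_key: float = 0.05,
    p_other: float = 0.05,
    min_other_traits: int = 3,
    gene_dist_bp: int = 10_000,
    p_column: str = "p_gc",
    combine: str = "or",
) -> AWMatrix:
    """Build the AWM from a long-format association table.

    ``assoc`` must cover every trait for the candidate SNPs with columns
    ``snp, chrom, pos, trait, beta, se`` and the chosen P column.
    ``combine`` joins the two selection clauses (``"or"`` reproduces the
    source method's admission rule; ``"and"`` is the stricter sequential
    reading), both gated by gene proximity.
    """
    traits = sorted(assoc["trait"].unique())
    if key_trait not in traits:
        raise KeyError(f"key trait {key_trait!r} not present in association table")
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")

    pmat = assoc.pivot_table(index="snp", columns="trait", values=p_column)
    z_raw = assoc.assign(z=assoc["beta"] / assoc["se"]).pivot_table(
        index="snp", columns="trait", values="z"
    )
    pos_info = assoc.drop_duplicates("snp").set_index("snp")[["chrom", "pos"]]

    key_p = pmat[key_trait]
    other_cols = [t for t in traits if t != key_trait]
    n_other = (pmat[other_cols] < p_other).sum(axis=1)
    key_pass = key_p <= p_key
    other_pass = n_other >= min_other_traits
    assoc_pass = (key_pass | other_pass) if combine == "or" else (key_pass & other_pass)

    near = nearest_gene_distance(
        pos_info.reset_index().rename(columns={"index": "snp"}), annotation
    ).set_index("snp")
    proximal = near["distance"] < gene_dist_bp
    selected = assoc_pass & proximal.reindex(assoc_pass.index, fill_value=False)

    selection = pd.DataFrame(
        {
            "snp": pmat.index,
            "p_key": key_p,
            "n_other_traits": n_other,
            "key_pass": key_pass,
            "other_pass": other_pass,
            "nearest_gene": near["gene_id"].reindex(pmat.index),
            "gene_distance": near["distance"].reindex(pmat.index),
            "selected": selected,
        }
    ).reset_index(drop=True)

    chosen = selection[selection["selected"]].copy()
    if not len(chosen):
        raise EmptyResultError("no SNP passed the AWM selection rule")

    # one SNP per gene: smallest key P, then largest |z_key|, then position
    chosen["abs_z_key"] = z_raw[key_trait].reindex(chosen["snp"]).abs().to_numpy()
    chosen["chrom"] = pos_info["chrom"].reindex(chosen["snp"]).to_numpy()
    chosen["pos"] = pos_info["pos"].reindex(chosen["snp"]).to_numpy()
    chosen = chosen.sort_values(
        by=["p_key", "abs_z_key", "chrom", "pos"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    per_gene = chosen.drop_duplicates("nearest_gene", keep="first")

    genes = per_gene["nearest_gene"].tolist()
    snps = per_gene["snp"].tolist()
    z = z_raw.reindex(snps).copy()
    mask = ~np.isfinite(z)
    z = z.where(np.isfinite(z), 0.0)
    z.index = pd.Index(genes, name="gene_id")
    mask.index = z.index
    z = z[traits]
    mask = mask[traits]

    # Ap over the key-associated SNP set, same P threshold as the key rule
    key_snps = key_pass[key_pass].index
    ap = float((pmat.loc[key_snps, other_cols] <= p_key).sum(axis=1).mean()) if len(key_snps) else 0.0

    return AWMatrix(
        z=z,
        key_trait=key_trait,
        ap=ap,
        snp_of_gene=pd.Series(snps, index=z.index, name="snp"),
        mask=mask,
        selection=selection,
    )


# ---------------------------------------------------------------------------
# Trait clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TraitClustering:
    linkage: np.ndarray
    labels: dict[str, int]
    correlation: pd.DataFrame


def cluster_traits(
    awm: AWMatrix, n_clusters: int = 3, method: str = "average"
) -> TraitClustering:
    """Agglomerative clustering of traits on ``1 - r`` of AWM columns."""
    z = awm.z.to_numpy()
    if z.shape[1] < 2:
        raise ValueError("need at least 2 traits to cluster")
    stds = z.std(axis=0)
    if np.any(stds == 0):
        trait = awm.z.columns[int(np.argmax(stds == 0))]
        raise ValueError(f"constant AWM column for trait {trait!r}")
    corr = np.corrcoef(z.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method=method)
    cut = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    labels = {t: int(c) for t, c in zip(awm.z.columns, cut)}
    return TraitClustering(
        linkage=link,
        labels=labels,
        correlation=pd.DataFrame(corr, index=awm.z.columns, columns=awm.z.columns),
    )


# ---------------------------------------------------------------------------
# Variance-explained permutation test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermutationReport:
    observed: float
    null_mean: float
    null_quantiles: dict[str, float]
    empirical_p: float
    n_replicates: int

    def summary(self) -> str:
        p_txt = (
            f"< {1.0 / self.n_replicates:.3g}"
            if self.empirical_p <= 1.0 / (self.n_replicates + 1)
            else f"= {self.empirical_p:.4g}"
        )
        return (
            f"observed variance fraction {self.observed:.3f} vs null mean "
            f"{self.null_mean:.3f} (P {p_txt}, {self.n_replicates} replicates)"
        )


def variance_explained_permutation(
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str,
    awm_snps: list[str],
    n_replicates: int = 10_000,
    seed: int = 0,
    exclude_observed: bool = True,
) -> PermutationReport:
    """Phenotypic variance captured by the AWM SNPs versus random SNP sets.

    The observed statistic is ``sigma_g^2 / (sigma_g^2 + sigma_e^2)`` from
    the polygenic model with the relationship matrix restricted to the AWM
    SNPs; the null distribution repeats this with equally sized random SNP
    sets (sampled without replacement, excluding the AWM SNPs themselves
    by default).  ``empirical_p = (1 + #{null >= observed}) / (R + 1)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    idx = genotypes.snp_index(awm_snps)
    if idx.size > genotypes.n_snps:
        raise ValueError("more AWM SNPs than panel SNPs")
    pool = (
        np.setdiff1d(np.arange(genotypes.n_snps), idx)
        if exclude_observed
        else np.arange(genotypes.n_snps)
    )
    if pool.size < idx.size:
        raise ValueError("SNP pool smaller than the AWM set")

    y = phenotypes.trait(trait)
    cov = phenotypes.covariates()

    def h2_for(snp_idx: np.ndarray) -> float:
        grm = build_grm(genotypes.select_snps(snp_idx))
        return fit_polygenic(y, cov, grm).vc.h2

    observed = h2_for(idx)
    rng = np.random.default_rng(seed)
    null = np.empty(n_replicates)
    for r in range(n_replicates):
        null[r] = h2_for(rng.choice(pool, size=idx.size, replace=False))
    empirical_p = (1.0 + float((null >= observed).sum())) / (n_replicates + 1.0)
    qs = np.quantile(null, [0.05, 0.25, 0.5, 0.75, 0.95])
    return PermutationReport(
        observed=float(observed),
        null_mean=float(null.mean()),
        null_quantiles={f"q{q:02d}": float(v) for q, v in zip((5, 25, 50, 75, 95), qs)},
        empirical_p=float(empirical_p),
        n_replicates=n_replicates,
    )
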