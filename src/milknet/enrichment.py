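"""SNP-to-gene mapping and gene-set over-representation testing.

SNPs are assigned to every gene whose interval, extended by a flanking
window (15 kb by default) on both the 5' and 3' ends, contains the SNP
position; multi-assignment to overlapping genes is allowed.  A gene is
called significant for a trait if any of its assigned SNPs passes a
nominal GC-corrected P threshold.  Functional categories are tested for
over-representation of significant genes with a one-sided Fisher exact
(hypergeometric) test; only categories with more than ``min_size`` and
fewer than ``max_size`` genes (after intersection with the universe) are
inspected, and Benjamini-Hochberg adjusted P-values ("q-values") are
reported over exactly that filtered list.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError


@dataclasses.dataclass
class GeneAssignment:
    """SNP -> genes mapping at a given flank distance."""

    snp_to_genes: dict[str, list[str]]
    flank_bp: int
    unassigned: list[str]

    def universe(self) -> set[str]:
        """All genes with at least one assigned SNP."""
        out: set[str] = set()
        for genes in self.snp_to_genes.values():
            out.update(genes)
        return out

    def genes_for(self, snp: str) -> list[str]:
        return self.snp_to_genes.get(snp, [])


def map_snps_to_genes(
    snp_map: pd.DataFrame, annotation: pd.DataFrame, flank_bp: int = 15_000
) -> GeneAssignment:
    """Assign each SNP to all genes within ``flank_bp`` of the gene body.

    ``annotation`` uses 1-based inclusive intervals; the flanked interval
    ``[start - flank, end + flank]`` is inclusive on both ends, so a SNP
    exactly ``flank_bp`` past a gene end is still assigned.  SNPs on
    chromosomes absent from the annotation stay unassigned and are listed
    in the report.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    assignment: dict[str, list[str]] = {}
    unassigned: list[str] = []
    by_chrom = {c: sub for c, sub in annotation.groupby("chrom")}
    for c, snps in snp_map.groupby("chrom"):
        genes = by_chrom.get(c)
        if genes is None:
            unassigned.extend(snps["snp"].tolist())
            continue
        starts = genes["start"].to_numpy() - flank_bp
        ends = genes["end"].to_numpy() + flank_bp
        names = genes["gene_id"].to_numpy()
        pos = snps["pos"].to_numpy()
        hit = (pos[:, None] >= starts[None, :]) & (pos[:, None] <= ends[None, :])
        for i, snp in enumerate(snps["snp"]):
            found = names[hit[i]]
            if found.size:
                assignment[snp] = sorted(found.tolist())
            else:
                unassigned.append(snp)
    return GeneAssignment(
        snp_to_genes=assignment, flank_bp=flank_bp, unassigned=unassigned
    )


def significant_genes(
    assoc: pd.DataFrame, assignment: GeneAssignment, alpha: float = 0.05
) -> dict[str, set[str]]:
    """Per trait, the set of genes with any assigned SNP at ``p_gc < alpha``."""
    out: dict[str, set[str]] = {}
    sig = assoc[assoc["p_gc"] < alpha]
    for trait, sub in sig.groupby("trait"):
        genes: set[str] = set()
        for snp in sub["snp"]:
            genes.update(assignment.genes_for(snp))
        out[str(trait)] = genes
    for trait in assoc["trait"].unique():
        out.setdefault(str(trait), set())
    return out


def fisher_enrichment(
    sig_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, list[str]],
    min_size: int = 10,
    max_size: int = 1000,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test per functional category.

    ``P = P(X >= k)`` under the hypergeometric null with the category
    intersected with the universe.  Categories of size ``<= min_size`` or
    ``>= max_size`` are excluded before testing; BH-adjusted q-values are
    computed over the retained categories only.
    """
    if not universe:
        raise EmptyResultError("empty gene universe")
    if not sig_genes <= universe:
        raise ValueError("sig_genes must be a subset of the universe")
    m_total = len(universe)
    n_sig = len(sig_genes)
    rows = []
    for name, genes in gene_sets.items():
        cat = set(genes) & universe
        size = len(cat)
        if size <= min_size or size >= max_size:
            continue
        overlap = len(cat & sig_genes)
        p = float(stats.hypergeom.sf(overlap - 1, m_total, n_sig, size))
        rows.append((name, size, overlap, p))
    result = pd.DataFrame(rows, columns=["category", "size", "overlap", "p_fisher"])
    if len(result):
        _, q, _, _ = multipletests(result["p_fisher"].to_numpy(), method="fdr_bh")
        result["q_value"] = q
        result["significant"] = result["q_value"] < q_cutoff
        result = result.sort_values("p_fisher", kind="stable").reset_index(drop=True)
    else:
        result["q_value"] = np.array([], dtype=float)
        result["significant"] = np.array([], dtype=bool)
    return result
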