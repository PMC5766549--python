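"""End-to-end orchestration: simulate/load -> QC -> GWAS -> enrichment ->
AWM -> permutation -> PCIT network -> topology -> TF trio.

Every stage writes plain-text artifacts (TSV tables, JSON reports) into
the output directory, and the run finishes with a manifest recording the
parameter echo, seed and a SHA-256 checksum per artifact so that re-runs
under the same seed can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann_io
from . import awm as awm_mod
from . import enrichment as enr
from . import network as net_mod
from . import simulate as sim
from .errors import ConfigurationError
from .genotypes import (
    PhenotypeTable,
    QcThresholds,
    apply_qc,
    read_phenotypes,
    read_plink,
)
from .gwas import GWAS_SIGNIFICANCE, build_grm, conditional_scan, gwas_scan


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs.  Either ``simulate`` is set (the cohort
    is generated in-run) or the four input paths must exist."""

    outdir: str
    seed: int = 0
    # inputs: simulate or load
    simulate: sim.SimConfig | None = None
    genotype_prefix: str | None = None
    phenotype_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    tf_list_path: str | None = None
    # stage parameters
    qc: QcThresholds = dataclasses.field(default_factory=QcThresholds)
    gwas_threshold: float = GWAS_SIGNIFICANCE
    key_trait: str = "kappa_cn"
    run_conditional: bool = True
    sig_alpha: float = 0.05
    flank_bp: int = 15_000
    min_set_size: int = 10
    max_set_size: int = 1000
    p_key: float = 0.05
    p_other: float = 0.05
    min_other_traits: int = 3
    gene_dist_bp: int = 10_000
    n_trait_clusters: int = 3
    permutation_replicates: int = 10_000
    min_abs_r: float = 0.80

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                p
                for p in (
                    self.phenotype_path,
                    self.annotation_path,
                    self.gene_sets_path,
                    self.tf_list_path,
                )
                if p is None or not Path(p).exists()
            ]
            if self.genotype_prefix is None or not Path(
                self.genotype_prefix + ".bed"
            ).exists():
                missing.append((self.genotype_prefix or "<unset>") + ".bed")
            if missing:
                raise ConfigurationError(f"missing input files: {missing}")
        if not 0 < self.gwas_threshold < 1:
            raise ConfigurationError("gwas_threshold outside (0, 1)")
        if not 0 < self.min_abs_r <= 1:
            raise ConfigurationError("min_abs_r outside (0, 1]")
        if self.permutation_replicates < 1:
            raise ConfigurationError("permutation_replicates must be >= 1")


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """The packaged small-scale demonstration run: 300 cows, 3,000 SNPs on
    6 chromosomes, 6 traits in two correlation clusters, a major key-trait
    QTL, and 500 permutation replicates."""
    traits = ["kappa_cn", "beta_cn", "alpha_s1_cn", "beta_lg", "whey_total", "minor_n"]
    cfg = sim.SimConfig(
        n_individuals=300,
        n_snps=3000,
        n_chromosomes=6,
        maf_range=(0.1, 0.5),
        trait_names=traits,
        trait_clusters={
            "kappa_cn": 1,
            "beta_cn": 1,
            "alpha_s1_cn": 1,
            "beta_lg": 2,
            "whey_total": 2,
            "minor_n": 2,
        },
        h2={t: sim.DEFAULT_H2[t] for t in traits},
        qtls=[
            sim.QtlSpec(chrom=6, pos=87_400_000, effects={"kappa_cn": 0.70}),
            sim.QtlSpec(
                chrom=6, pos=87_200_000, effects={"beta_cn": 0.48, "alpha_s1_cn": 0.38}
            ),
            sim.QtlSpec(chrom=1, pos=104_300_000, effects={"beta_lg": 0.25, "whey_total": 0.20}),
        ],
        n_herds=20,
        parity_classes=4,
        dim_classes=6,
        seed=seed,
    )
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        simulate=cfg,
        min_other_traits=2,
        permutation_replicates=500,
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    if "simulate" in raw and raw["simulate"] is not None:
        simcfg = raw.pop("simulate")
        qtls = [sim.QtlSpec(**q) for q in simcfg.pop("qtls", [])]
        if "maf_range" in simcfg:
            simcfg["maf_range"] = tuple(simcfg["maf_range"])
        raw["simulate"] = sim.SimConfig(**simcfg, qtls=qtls)
    if "qc" in raw and raw["qc"] is not None:
        raw["qc"] = QcThresholds(**raw["qc"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to
    ``manifest.json``).  Any stage error aborts with partial artifacts
    preserved on disk."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        artifacts[name] = str(path)

    def save_json(obj, name: str) -> None:
        path = outdir / name
        _write_json(obj, path)
        artifacts[name] = str(path)

    # -- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        cohort = sim.simulate_cohort(config.simulate)
        toy = sim.make_toy_annotation(cohort.genotypes, config.simulate)
        sim.write_cohort(cohort, outdir / "inputs", annotation=toy)
        genotypes, phenotypes = cohort.genotypes, cohort.phenotypes
        annotation = toy.annotation
        gene_sets = toy.gene_sets
        tf_genes = set(toy.tf_genes)
        for p in sorted((outdir / "inputs").iterdir()):
            artifacts[f"inputs/{p.name}"] = str(p)
    else:
        genotypes = read_plink(config.genotype_prefix)
        phenotypes = read_phenotypes(config.phenotype_path)
        annotation = ann_io.read_bed(config.annotation_path)
        gene_sets = ann_io.read_gmt(config.gene_sets_path)
        tf_genes = ann_io.read_tf_list(config.tf_list_path)
        phenotypes, genotypes = phenotypes.intersect(genotypes)

    # -- stage: QC ---------------------------------------------------------
    genotypes, qc_report = apply_qc(genotypes, config.qc)
    save_tsv(qc_report, "qc_report.tsv")

    # -- stage: GWAS (per-trait REML + GRAMMAR-GC) -------------------------
    grm = build_grm(genotypes)
    traits = phenotypes.trait_names
    assoc_tables, vc_report, gc_report = [], {}, {}
    for trait in traits:
        table, gc, fit = gwas_scan(genotypes, phenotypes, trait, grm=grm)
        assoc_tables.append(table)
        vc_report[trait] = dataclasses.asdict(fit.vc)
        gc_report[trait] = gc.lam
    assoc = pd.concat(assoc_tables, ignore_index=True)
    save_tsv(assoc, "assoc.tsv")
    save_json(vc_report, "variance_components.json")
    save_json(gc_report, "genomic_control.json")
    n_significant = int((assoc["p_gc"] < config.gwas_threshold).sum())

    # -- stage: conditional scan on the key trait's top SNP ----------------
    conditional_report = None
    if config.run_conditional:
        key_assoc = assoc[assoc["trait"] == config.key_trait]
        top = key_assoc.loc[key_assoc["p_gc"].idxmin()]
        cond = conditional_scan(
            genotypes, phenotypes, config.key_trait, [str(top["snp"])], grm=grm
        )
        conditional_report = {
            "fixed_snps": [str(top["snp"])],
            "sigma_g2_before": cond.base_vc.sigma_g2,
            "sigma_g2_after": cond.vc.sigma_g2,
            "sigma_g2_change": cond.sigma_g2_change,
            "h2_before": cond.base_vc.h2,
            "h2_after": cond.vc.h2,
            "dropped_snps": cond.dropped_snps,
        }
        save_tsv(cond.assoc, "assoc_conditional.tsv")
        save_json(conditional_report, "conditional.json")

    # -- stage: enrichment -------------------------------------------------
    assignment = enr.map_snps_to_genes(
        genotypes.snp_map, annotation, flank_bp=config.flank_bp
    )
    sig = enr.significant_genes(assoc, assignment, alpha=config.sig_alpha)
    universe = assignment.universe()
    enrich_tables = []
    for trait in traits:
        table = enr.fisher_enrichment(
            sig[trait],
            universe,
            gene_sets,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
        )
        table.insert(0, "trait", trait)
        enrich_tables.append(table)
    enrichment_table = pd.concat(enrich_tables, ignore_index=True)
    save_tsv(enrichment_table, "enrichment.tsv")

    # -- stage: AWM --------------------------------------------------------
    awm = awm_mod.build_awm(
        assoc,
        annotation,
        key_trait=config.key_trait,
        p_key=config.p_key,
        p_other=config.p_other,
        min_other_traits=config.min_other_traits,
        gene_dist_bp=config.gene_dist_bp,
    )
    awm.z.reset_index().to_csv(outdir / "awm.tsv", sep="\t", index=False, float_format="%.10g")
    artifacts["awm.tsv"] = str(outdir / "awm.tsv")
    clustering = awm_mod.cluster_traits(awm, n_clusters=config.n_trait_clusters)
    save_json(
        {
            "key_trait": awm.key_trait,
            "ap": awm.ap,
            "n_genes": int(len(awm.z)),
            "snp_of_gene": awm.snp_of_gene.to_dict(),
            "trait_clusters": clustering.labels,
        },
        "awm_meta.json",
    )

    # -- stage: variance-explained permutation -----------------------------
    perm = awm_mod.variance_explained_permutation(
        genotypes,
        phenotypes,
        config.key_trait,
        awm.snps,
        n_replicates=config.permutation_replicates,
        seed=config.seed + 1000,
    )
    save_json(dataclasses.asdict(perm), "permutation.json")

    # -- stage: PCIT network -----------------------------------------------
    corr = net_mod.pairwise_correlation(awm)
    flags = net_mod.pcit(corr)
    network = net_mod.filter_edges(corr, flags, min_abs_r=config.min_abs_r, tf_genes=tf_genes)
    net_mod.write_sif(network, outdir / "network.sif")
    artifacts["network.sif"] = str(outdir / "network.sif")
    net_mod.write_graphml(network, outdir / "network.graphml")
    artifacts["network.graphml"] = str(outdir / "network.graphml")
    topo = net_mod.topology(network)
    save_tsv(topo, "node_metrics.tsv")

    trio_report = None
    if len(network.tfs_in_network()) >= 3:
        trio = net_mod.best_tf_trio(network)
        trio_report = {
            "tf_ids": list(trio.tf_ids),
            "n_covered_targets": len(trio.covered_targets),
            "coverage_fraction": trio.coverage_fraction,
            "per_tf": trio.per_tf.to_dict(orient="records"),
        }
        save_json(trio_report, "tf_trio.json")

    # -- manifest ----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("outdir",)
        },
        "n_snps_post_qc": genotypes.n_snps,
        "n_individuals": genotypes.n_individuals,
        "n_significant_snps": n_significant,
        "pcit_significant_pairs": int(flags.sum() // 2),
        "network_nodes": network.n_nodes,
        "network_edges": network.n_edges,
        "awm_genes": int(len(awm.z)),
        "permutation_p": perm.empirical_p,
        "observed_variance_fraction": perm.observed,
        "null_mean_variance_fraction": perm.null_mean,
        "conditional": conditional_report,
        "tf_trio": trio_report,
        "checksums": {name: _sha256(Path(path)) for name, path in sorted(artifacts.items())},
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
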