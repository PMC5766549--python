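"""Genotype and phenotype containers, PLINK binary I/O and marker QC.

Genotypes are stored as the dosage of the first (``a1``, "+") allele in
``{0, 1, 2}`` with ``-1`` marking a missing call.  The kinship estimator
used downstream expects the half-dosage coding ``{0, 1/2, 1}``; that view
is exposed by :meth:`GenotypeMatrix.half_dosage` so there is exactly one
canonical storage.

Marker quality control follows the standard chip-data recipe: per-SNP call
rate, minor-allele frequency computed from non-missing calls only, and an
exact Hardy-Weinberg test with optional Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError

MISSING = -1

_BED_MAGIC = b"\x6c\x1b\x01"
# two-bit PLINK codes -> a1 dosage (00=hom a1, 10=het, 11=hom a2, 01=missing)
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with marker map metadata.

    Parameters
    ----------
    dosage
        ``(n_individuals, n_snps)`` int8 array of a1-allele counts,
        ``-1`` for missing.
    snp_map
        DataFrame with columns ``snp, chrom, pos, a1, a2`` (one row per
        marker, same order as the columns of ``dosage``).
    sample_ids
        Unique individual identifiers, same order as the rows of ``dosage``.
    """

    dosage: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise FormatError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_map) != m:
            raise FormatError(f"{len(self.snp_map)} map rows for {m} SNP columns")
        if len(set(self.sample_ids)) != n:
            raise FormatError("sample ids are not unique")
        if self.snp_map["snp"].duplicated().any():
            raise FormatError("SNP ids are not unique")
        if (self.snp_map["pos"].to_numpy() < 0).any():
            raise FormatError("negative map positions")
        self.snp_map = self.snp_map.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the a1 ("+") allele among non-missing calls."""
        d = np.where(self.missing_mask(), np.nan, self.dosage.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def half_dosage(self, impute: bool = True) -> np.ndarray:
        """Genotypes on the ``{0, 1/2, 1}`` scale used by the kinship
        estimator; missing calls are mean-imputed per SNP when ``impute``."""
        x = np.where(self.missing_mask(), np.nan, self.dosage.astype(float)) / 2.0
        if impute:
            col_mean = np.nanmean(x, axis=0)
            idx = np.where(np.isnan(x))
            x[idx] = np.take(col_mean, idx[1])
        return x

    def dosage_float(self, impute: bool = True) -> np.ndarray:
        """Dosage on the ``{0,1,2}`` scale as float, optionally mean-imputed."""
        return self.half_dosage(impute=impute) * 2.0

    # -- selection --------------------------------------------------------
    def select_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            snp_map=self.snp_map.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def select_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [order[s] for s in ids]
        return GenotypeMatrix(
            dosage=self.dosage[rows, :],
            snp_map=self.snp_map.copy(),
            sample_ids=list(ids),
        )

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_map["snp"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)


# ---------------------------------------------------------------------------
# PLINK binary I/O
# ---------------------------------------------------------------------------

def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam (variant-major .bed)."""
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": g.snp_map["chrom"],
            "snp": g.snp_map["snp"],
            "cm": 0,
            "pos": g.snp_map["pos"],
            "a1": g.snp_map["a1"],
            "a2": g.snp_map["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.sample_ids,
            "iid": g.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = g.n_individuals
    n_bytes = (n + 3) // 4
    # map dosage -> 2-bit code, pack 4 samples per byte (low bits first)
    code = np.empty_like(g.dosage, dtype=np.uint8)
    for dosage_value, bed_code in _DOSAGE_TO_BED_CODE.items():
        code[g.dosage == dosage_value] = bed_code
    padded = np.zeros((n_bytes * 4, g.n_snps), dtype=np.uint8)
    padded[:n, :] = code
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    blocks = padded.reshape(n_bytes, 4, g.n_snps)
    packed = (blocks << shifts[None, :, None]).sum(axis=1).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # variant-major


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a variant-major PLINK ``.bed/.bim/.fam`` fileset."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes "
            f"{raw[:3]!r}, expected {_BED_MAGIC!r}"
        )
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_bytes * m:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: {body.size} payload bytes, "
            f"expected {n_bytes * m} for {n} samples x {m} variants"
        )
    blocks = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for i, shift in enumerate((0, 2, 4, 6)):
        codes[:, i::4] = (blocks >> shift) & 0b11
    dosage = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    snp_map = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map, sample_ids=list(fam["iid"]))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = ("herd_date", "parity_class", "dim_class")


@dataclasses.dataclass
class PhenotypeTable:
    """Per-individual trait values plus fixed-effect class covariates.

    ``table`` holds one row per individual with columns ``id``, the three
    class covariates (herd-date contemporary group, parity class, 30-day
    days-in-milk class) and one real-valued column per trait (NaN allowed).
    """

    table: pd.DataFrame
    trait_names: list[str]

    def __post_init__(self) -> None:
        for col in ("id", *COVARIATE_COLUMNS):
            if col not in self.table.columns:
                raise FormatError(f"phenotype table missing column {col!r}")
        for t in self.trait_names:
            if t not in self.table.columns:
                raise FormatError(f"phenotype table missing trait column {t!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["id"].astype(str))

    def covariates(self) -> pd.DataFrame:
        return self.table[list(COVARIATE_COLUMNS)].astype(str)

    def trait(self, name: str) -> np.ndarray:
        if name not in self.trait_names:
            raise KeyError(f"unknown trait {name!r}")
        return self.table[name].to_numpy(dtype=float)

    def intersect(self, genotypes: GenotypeMatrix) -> tuple["PhenotypeTable", GenotypeMatrix]:
        """Restrict both tables to the shared individuals, genotype order."""
        shared = [s for s in genotypes.sample_ids if s in set(self.sample_ids)]
        if not shared:
            raise EmptyResultError("no shared individuals between genotypes and phenotypes")
        sub = self.table.set_index(self.table["id"].astype(str)).loc[shared].reset_index(drop=True)
        return (
            PhenotypeTable(table=sub, trait_names=list(self.trait_names)),
            genotypes.select_samples(shared),
        )


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    cols = ["id", *COVARIATE_COLUMNS, *p.trait_names]
    p.table[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    # round_trip parsing so that write -> read is bit-exact on trait values
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    trait_names = [c for c in df.columns if c not in ("id", *COVARIATE_COLUMNS)]
    return PhenotypeTable(table=df, trait_names=trait_names)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test P-value (Wigginton-style, mid-P off).

    Sums the probabilities of all heterozygote counts compatible with the
    observed allele counts that are no more probable than the observed one.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het

    # probabilities over all possible het counts with the same parity as rare
    het_values = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(het_values.size)
    # start from mid het count and recur both ways for numerical stability
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    start = np.searchsorted(het_values, mid)
    probs[start] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r+2)(d+2)) with
    # r = (rare-h)/2 rare homs, d = n - (h+r) common homs
    for i in range(start, 0, -1):
        h = het_values[i]
        r = (rare - h) // 2
        d = n - h - r
        probs[i - 1] = probs[i] * h * (h - 1) / ((r + 1.0) * (d + 1.0)) / 4.0
    for i in range(start, het_values.size - 1):
        h = het_values[i]
        r = (rare - h) // 2
        d = n - h - r
        probs[i + 1] = probs[i] * 4.0 * r * d / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE P-value per SNP from non-missing genotype counts."""
    out = np.ones(g.n_snps)
    d = g.dosage
    for k in range(g.n_snps):
        col = d[:, k]
        col = col[col != MISSING]
        n_hom_a1 = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_hom_a2 = int((col == 0).sum())
        out[k] = hwe_exact_test(n_het, n_hom_a1, n_hom_a2)
    return out


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QcThresholds:
    """Marker-level filters: call rate > ``min_call_rate``, MAF >
    ``min_maf`` and exact HWE P > ``hwe_alpha`` (divided by the number of
    tested SNPs when ``hwe_bonferroni``)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.005
    hwe_alpha: float = 0.001
    hwe_bonferroni: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")


def apply_qc(
    g: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply marker QC; returns the filtered matrix and a per-SNP report.

    The report has one row per input SNP with the computed call rate, MAF
    and HWE P-value, a ``retained`` flag and a comma-separated ``reasons``
    field for removed markers.  The Bonferroni divisor is the pre-filter
    SNP count.
    """
    if g.n_snps == 0:
        raise EmptyResultError("apply_qc on an empty genotype matrix")
    t = thresholds or QcThresholds()
    call = g.call_rate()
    maf = g.maf()
    hwe_p = hwe_pvalues(g)
    hwe_cut = t.hwe_alpha / g.n_snps if t.hwe_bonferroni else t.hwe_alpha

    reasons = []
    for k in range(g.n_snps):
        r = []
        if not call[k] > t.min_call_rate:
            r.append("call_rate")
        if not maf[k] > t.min_maf:
            r.append("maf")
        if not hwe_p[k] > hwe_cut:
            r.append("hwe")
        reasons.append(",".join(r))
    report = pd.DataFrame(
        {
            "snp": g.snp_map["snp"],
            "call_rate": call,
            "maf": maf,
            "hwe_p": hwe_p,
            "retained": [r == "" for r in reasons],
            "reasons": reasons,
        }
    )
    keep = np.flatnonzero(report["retained"].to_numpy())
    if keep.size == 0:
        raise EmptyResultError("QC removed every SNP; thresholds too strict?")
    return g.select_snps(keep), report
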