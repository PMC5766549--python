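"""Mixed-model association machinery: GRM, REML, GRAMMAR-GC, LD.

The association procedure is the three-step GRAMMAR-GC scheme:

1. fit the additive polygenic model ``y = X b + a + e`` with
   ``a ~ N(0, G sigma_g^2)`` and ``e ~ N(0, I sigma_e^2)`` by REML, where
   ``G`` is the marker-based relationship matrix;
2. regress the BLUP-adjusted residuals on each SNP dosage (score test);
3. recalibrate the statistics — a scalar "gamma" factor undoes the known
   deflation of residual-based effect estimates, and genomic control
   (lambda = median chi2 / 0.4549) corrects any remaining miscalibration.

The identity-by-state coefficient between individuals i and j is

    f_ij = (1/N) sum_k (x_ik - p_k)(x_jk - p_k) / (p_k (1 - p_k))

with genotypes ``x`` coded 0, 1/2, 1 and ``p_k`` the "+" allele frequency.
Under Hardy-Weinberg equilibrium ``E[f_ii] = 1/2``, i.e. ``f`` is a kinship
coefficient; the relationship matrix entering the model is ``G = 2 f`` so
that ``sigma_g^2`` is the additive genetic variance on the observed scale
and the genomic heritability ``h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``
matches the simulated variance ratio.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import MonomorphicSNPError
from .genotypes import GenotypeMatrix

# median of the chi-square(1 df) distribution
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

GWAS_SIGNIFICANCE = 5e-5


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Grm:
    """Identity-by-state kinship matrix ``f`` (diagonal ~ 1/2 under HWE)."""

    matrix: np.ndarray
    sample_ids: list[str]
    _eig: tuple[np.ndarray, np.ndarray] | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(m).all():
            raise ValueError("GRM has non-finite entries")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        self.matrix = (m + m.T) / 2.0

    @property
    def relationship(self) -> np.ndarray:
        """The relationship matrix ``2 f`` used by the polygenic model."""
        return 2.0 * self.matrix

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of the relationship matrix, eigen-floored at 0."""
        if self._eig is None:
            d, u = np.linalg.eigh(self.relationship)
            d = np.clip(d, 0.0, None)
            self._eig = (d, u)
        return self._eig


def build_grm(g: GenotypeMatrix) -> Grm:
    """Marker-based IBS kinship from the ``{0, 1/2, 1}`` genotype coding.

    Missing dosages are mean-imputed per SNP.  Raises
    :class:`MonomorphicSNPError` naming the first offending marker if any
    SNP is fixed.
    """
    p = g.allele_freq()
    mono = np.flatnonzero(~((p > 0.0) & (p < 1.0)))
    if mono.size:
        names = g.snp_map["snp"].iloc[mono[:5]].tolist()
        raise MonomorphicSNPError(
            f"{mono.size} monomorphic SNP(s) in GRM input, e.g. {names}"
        )
    x = g.half_dosage(impute=True)
    z = (x - p) / np.sqrt(p * (1.0 - p))
    f = (z @ z.T) / g.n_snps
    return Grm(matrix=f, sample_ids=list(g.sample_ids))


# ---------------------------------------------------------------------------
# Polygenic REML fit
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("negative variance component")


@dataclasses.dataclass
class PolygenicFit:
    """REML fit of the single-GRM polygenic model for one trait.

    ``residuals`` are the BLUP-adjusted residuals ``y - X beta - a_hat``
    used by the association scan; ``sample_index`` maps them back to rows
    of the genotype matrix (individuals with missing phenotype are dropped
    per-trait).
    """

    vc: VarianceComponents
    beta: np.ndarray
    residuals: np.ndarray
    sample_index: np.ndarray
    _rot: dict = dataclasses.field(default_factory=dict, repr=False)

    def gamma_factor(self, g: GenotypeMatrix) -> float:
        """Mean per-SNP deflation of residual-scale effect estimates.

        For a centred dosage vector ``g_c`` the residual regression
        estimate equals the mixed-model one times
        ``gamma_k = sigma_e^2 (g_c' V^-1 g_c) / (g_c' g_c)``; the scalar
        returned is the mean of ``gamma_k`` over all polymorphic SNPs.
        """
        u = self._rot["u"]
        delta = self._rot["delta"]
        sigma_p2 = self.vc.sigma_g2 + self.vc.sigma_e2
        x = g.dosage_float(impute=True)[self.sample_index, :]
        xc = x - x.mean(axis=0)
        ss = (xc**2).sum(axis=0)
        ok = ss > 0
        xr = u.T @ xc[:, ok]
        quad = ((xr**2) / delta[:, None]).sum(axis=0) / sigma_p2
        gammas = self.vc.sigma_e2 * quad / ss[ok]
        return float(gammas.mean())


def design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design: intercept + dummy columns for object/categorical
    covariates, numeric columns passed through."""
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
        else:
            cols.append(col.to_numpy(dtype=float))
    x = np.column_stack(cols)
    # drop collinear columns (keep first occurrences) via rank-revealing QR
    q, r, piv = _qr_pivot(x)
    rank = int((np.abs(np.diag(r)) > 1e-8 * max(1.0, abs(r[0, 0]))).sum())
    if rank < x.shape[1]:
        keep = np.sort(piv[:rank])
        x = x[:, keep]
    return x


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def fit_polygenic(
    y: np.ndarray,
    covariates: pd.DataFrame,
    grm: Grm,
    h2_bounds: tuple[float, float] = (0.0, 0.999),
) -> PolygenicFit:
    """REML fit of ``y = X b + a + e`` with ``a ~ N(0, 2f sigma_g^2)``.

    Uses the spectral decomposition of the relationship matrix: after
    rotating data by the eigenvectors the covariance is diagonal in the
    variance ratio, so REML reduces to a 1-D bounded optimization of
    ``h^2`` (Brent) with ``beta`` and the total variance profiled out.
    Individuals with missing phenotype are dropped for this trait only.
    """
    y = np.asarray(y, dtype=float)
    keep = np.flatnonzero(np.isfinite(y))
    if keep.size < len(y):
        covariates = covariates.iloc[keep]
        y = y[keep]
        sub = Grm(
            matrix=grm.matrix[np.ix_(keep, keep)],
            sample_ids=[grm.sample_ids[i] for i in keep],
        )
    else:
        sub = grm
    x = design_matrix(covariates)
    n, p = x.shape
    if n - p < 2:
        raise ValueError(f"only {n} observations for {p} fixed effects")
    if len(np.unique(np.round(y - x @ np.linalg.lstsq(x, y, rcond=None)[0], 12))) < 2:
        raise ValueError("phenotype constant after covariate adjustment")

    d, u = sub.eig()
    ystar = u.T @ y
    xstar = u.T @ x

    def neg_reml(h2: float) -> float:
        return -_reml_loglik(h2, d, ystar, xstar, n, p)[0]

    res = optimize.minimize_scalar(
        neg_reml, bounds=h2_bounds, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(
            f"REML optimizer failed in h2 bounds {h2_bounds}: {res.message}"
        )
    h2 = float(res.x)
    loglik, beta, sigma_p2, delta = _reml_loglik(h2, d, ystar, xstar, n, p, full=True)
    sigma_g2 = h2 * sigma_p2
    sigma_e2 = (1.0 - h2) * sigma_p2
    # BLUP-adjusted residuals: e_hat = sigma_e^2 V^-1 (y - X beta)
    r_rot = ystar - xstar @ beta
    e_rot = (1.0 - h2) / delta * r_rot
    residuals = u @ e_rot
    vc = VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=sigma_g2 / (sigma_g2 + sigma_e2),
        loglik=loglik,
    )
    return PolygenicFit(
        vc=vc,
        beta=beta,
        residuals=residuals,
        sample_index=keep,
        _rot={"u": u, "delta": delta},
    )


def _reml_loglik(h2, d, ystar, xstar, n, p, full=False):
    delta = h2 * d + (1.0 - h2)
    w = 1.0 / delta
    xtwx = (xstar * w[:, None]).T @ xstar
    xtwy = (xstar * w[:, None]).T @ ystar
    beta = np.linalg.solve(xtwx, xtwy)
    r = ystar - xstar @ beta
    rss = float(r @ (w * r))
    sigma_p2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        (n - p) * np.log(sigma_p2)
        + np.log(delta).sum()
        + logdet_xtwx
        + (n - p)
    )
    if full:
        return float(ll), beta, sigma_p2, delta
    return float(ll), beta, sigma_p2


# ---------------------------------------------------------------------------
# GRAMMAR scan with genomic control
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GcFactor:
    lam: float
    method: str = "median"

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lambda={self.lam} must be positive")


def grammar_scan(
    fit: PolygenicFit,
    g: GenotypeMatrix,
    trait: str = "trait",
    gamma_correct: bool = True,
) -> tuple[pd.DataFrame, GcFactor]:
    """Regress BLUP-adjusted residuals on each SNP dosage.

    Returns the per-SNP association table (beta, SE, chi2, raw and
    GC-corrected P, MAF, SNP variance ``2 p q a^2`` and its share of the
    additive variance) and the genomic-control factor.  Zero-variance SNPs
    are kept in the table flagged with NaN statistics.  Missing genotypes
    are excluded pairwise; the gamma recalibration divides ``beta`` by the
    estimated shrinkage ``gamma`` and SE by ``sqrt(gamma)``.  The
    genomic-control factor and the reported chi2/P columns use the raw
    residual score test; gamma touches only the effect scale (and hence
    the standardized effects ``beta/se`` that feed the AWM).
    """
    e = fit.residuals
    d = g.dosage[fit.sample_index, :].astype(float)
    miss = d < 0
    d[miss] = np.nan

    n_obs = (~miss).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        g_mean = np.nanmean(d, axis=0)
    dc = d - g_mean
    dc[miss] = 0.0
    e_col = e[:, None] * (~miss)
    e_mean = e_col.sum(axis=0) / n_obs
    ec = (e[:, None] - e_mean) * (~miss)

    sxx = (dc**2).sum(axis=0)
    sxy = (dc * ec).sum(axis=0)
    syy = (ec**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sigma2 = syy / n_obs
        chi2 = np.where(sxx > 0, beta**2 * sxx / sigma2, np.nan)
        se = np.sqrt(sigma2 / sxx)

    gamma = fit.gamma_factor(g) if gamma_correct else 1.0
    beta = beta / gamma
    se = se / np.sqrt(gamma)

    valid = np.isfinite(chi2)
    lam = float(np.median(chi2[valid]) / CHI2_1_MEDIAN) if valid.any() else 1.0
    lam_floor = max(lam, 1.0)
    p_raw = stats.chi2.sf(chi2, 1)
    p_gc = stats.chi2.sf(chi2 / lam_floor, 1)

    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    snp_var = snp_variance(p, beta)
    pct_va = 100.0 * snp_var / fit.vc.sigma_g2 if fit.vc.sigma_g2 > 0 else np.full_like(snp_var, np.nan)

    table = pd.DataFrame(
        {
            "snp": g.snp_map["snp"],
            "chrom": g.snp_map["chrom"],
            "pos": g.snp_map["pos"],
            "trait": trait,
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p_raw": p_raw,
            "p_gc": p_gc,
            "maf": maf,
            "snp_var": snp_var,
            "pct_va": pct_va,
        }
    )
    return table, GcFactor(lam=lam)


def snp_variance(p: float | np.ndarray, a: float | np.ndarray) -> float | np.ndarray:
    """Additive variance contributed by a SNP: ``2 p q a^2``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p) * np.asarray(a, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def gwas_scan(
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str,
    grm: Grm | None = None,
    extra_covariates: pd.DataFrame | None = None,
    gamma_correct: bool = True,
) -> tuple[pd.DataFrame, GcFactor, PolygenicFit]:
    """Convenience wrapper: REML fit + GRAMMAR-GC scan for one trait."""
    if grm is None:
        grm = build_grm(genotypes)
    cov = phenotypes.covariates()
    if extra_covariates is not None:
        cov = pd.concat(
            [cov.reset_index(drop=True), extra_covariates.reset_index(drop=True)],
            axis=1,
        )
    fit = fit_polygenic(phenotypes.trait(trait), cov, grm)
    sub = (
        genotypes
        if fit.sample_index.size == genotypes.n_individuals
        else GenotypeMatrix(
            dosage=genotypes.dosage[fit.sample_index, :],
            snp_map=genotypes.snp_map.copy(),
            sample_ids=[genotypes.sample_ids[i] for i in fit.sample_index],
        )
    )
    # residual scan uses all rows of `sub`; sample_index already applied
    fit_for_scan = dataclasses.replace(fit, sample_index=np.arange(fit.sample_index.size))
    table, gc = grammar_scan(fit_for_scan, sub, trait=trait, gamma_correct=gamma_correct)
    return table, gc, fit


# ---------------------------------------------------------------------------
# Conditional scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConditionalResult:
    assoc: pd.DataFrame
    gc: GcFactor
    vc: VarianceComponents
    base_vc: VarianceComponents
    dropped_snps: list[str]

    @property
    def sigma_g2_change(self) -> float:
        """Relative change in additive variance after conditioning."""
        return (self.vc.sigma_g2 - self.base_vc.sigma_g2) / self.base_vc.sigma_g2

    @property
    def h2_change(self) -> float:
        return self.vc.h2 - self.base_vc.h2


def conditional_scan(
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str,
    fixed_snps: list[str],
    grm: Grm | None = None,
    gamma_correct: bool = True,
) -> ConditionalResult:
    """Rescan with the given SNP dosages added to the fixed effects.

    Mirrors the secondary-signal analysis: the most significant markers
    are fixed in the model to obtain effect estimates adjusted for them,
    and the drop in ``sigma_g^2``/``h^2`` versus the unconditional fit is
    reported.  Collinear fixed SNPs are dropped with a warning.
    """
    if grm is None:
        grm = build_grm(genotypes)
    base_table, base_gc, base_fit = gwas_scan(
        genotypes, phenotypes, trait, grm=grm, gamma_correct=gamma_correct
    )
    if not fixed_snps:
        return ConditionalResult(
            assoc=base_table,
            gc=base_gc,
            vc=base_fit.vc,
            base_vc=base_fit.vc,
            dropped_snps=[],
        )
    idx = genotypes.snp_index(fixed_snps)
    dos = genotypes.dosage_float(impute=True)[:, idx]
    keep_cols, dropped = [], []
    seen = np.ones((genotypes.n_individuals, 0))
    for j, name in enumerate(fixed_snps):
        candidate = np.column_stack([seen, dos[:, j]])
        if np.linalg.matrix_rank(candidate - candidate.mean(axis=0)) > seen.shape[1]:
            seen = candidate
            keep_cols.append(j)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropping collinear fixed SNPs: {dropped}", stacklevel=2)
    extra = pd.DataFrame(
        dos[:, keep_cols], columns=[f"snp_{fixed_snps[j]}" for j in keep_cols]
    )
    table, gc, fit = gwas_scan(
        genotypes,
        phenotypes,
        trait,
        grm=grm,
        extra_covariates=extra,
        gamma_correct=gamma_correct,
    )
    return ConditionalResult(
        assoc=table, gc=gc, vc=fit.vc, base_vc=base_fit.vc, dropped_snps=dropped
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages."""
    ia, ib = g.snp_index([snp_a, snp_b])
    da = g.dosage[:, ia].astype(float)
    db = g.dosage[:, ib].astype(float)
    ok = (da >= 0) & (db >= 0)
    da, db = da[ok], db[ok]
    if da.std() == 0 or db.std() == 0:
        raise MonomorphicSNPError(
            f"ld_r2 requires polymorphic SNPs ({snp_a}, {snp_b})"
        )
    r = np.corrcoef(da, db)[0, 1]
    return float(r**2)
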