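"""GRM arithmetic, REML variance components, GRAMMAR-GC scan, SNP
variance, conditional scans and LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import milknet as mk
from milknet.gwas import CHI2_1_MEDIAN, _reml_loglik

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_forced_arithmetic_single_snp():
    """One SNP with p=0.5: f = (x_i - 1/2)(x_j - 1/2) / (1/4)."""
    g = make_genotypes(np.array([[2], [0], [1], [1]]))  # x = 1, 0, 1/2, 1/2; p = 0.5
    f = mk.build_grm(g).matrix
    assert f[0, 0] == pytest.approx(1.0)   # (1/2)(1/2)/(1/4)
    assert f[0, 1] == pytest.approx(-1.0)  # (1/2)(-1/2)/(1/4)
    assert f[2, 3] == pytest.approx(0.0)


def test_grm_monomorphic_raises_with_name():
    g = make_genotypes(np.array([[2, 1], [2, 0], [2, 2]]))
    with pytest.raises(mk.MonomorphicSNPError, match="s0"):
        mk.build_grm(g)


def test_grm_hwe_expectation():
    """Under HWE the mean diagonal is ~1/2 and off-diagonal ~0."""
    cfg = mk.SimConfig(
        n_individuals=200, n_snps=5000, n_chromosomes=5, maf_range=(0.05, 0.5),
        trait_names=["t"], trait_clusters={"t": 1}, h2={"t": 0.3}, qtls=[], seed=9,
    )
    f = mk.build_grm(mk.simulate_genotypes(cfg)).matrix
    n = f.shape[0]
    diag = np.diag(f).mean()
    off = (f.sum() - np.trace(f)) / (n * (n - 1))
    assert abs(diag - 0.5) < 0.02
    assert abs(off) < 0.01


def test_grm_coding_invariance():
    """Building from {0,1,2} dosages with the compensating 1/2 scaling
    equals the canonical {0,1/2,1} computation."""
    rng = np.random.default_rng(3)
    g = make_genotypes(rng.binomial(2, 0.3, size=(50, 200)).astype(np.int8))
    f = mk.build_grm(g).matrix
    d = g.dosage.astype(float)
    p2 = d.mean(axis=0)  # allele count scale: 2p
    # (x - p)/sqrt(pq) with x = d/2, p = p2/2  =>  (d - p2)/sqrt(p2 (2 - p2))
    z = (d - p2) / np.sqrt(p2 * (2 - p2))
    f_alt = z @ z.T / g.n_snps
    np.testing.assert_allclose(f, f_alt, atol=1e-12)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def test_reml_null_trait(small_cohort):
    rng = np.random.default_rng(0)
    y = rng.standard_normal(small_cohort.genotypes.n_individuals)
    fit = mk.fit_polygenic(
        y, small_cohort.phenotypes.covariates(), mk.build_grm(small_cohort.genotypes)
    )
    assert fit.vc.h2 <= 0.05
    assert fit.vc.h2 == fit.vc.sigma_g2 / (fit.vc.sigma_g2 + fit.vc.sigma_e2)


def test_reml_identity_grm_reduces_to_ols(small_cohort):
    """With G = I the variance split is unidentifiable but the total equals
    the OLS residual variance."""
    n = small_cohort.genotypes.n_individuals
    y = small_cohort.phenotypes.trait("kappa_cn")
    cov = small_cohort.phenotypes.covariates()
    grm = mk.Grm(matrix=0.5 * np.eye(n), sample_ids=small_cohort.genotypes.sample_ids)
    fit = mk.fit_polygenic(y, cov, grm)
    from milknet.gwas import design_matrix

    x = design_matrix(cov)
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    resid = y - x @ beta
    ols_var = resid @ resid / (n - x.shape[1])
    assert fit.vc.sigma_g2 + fit.vc.sigma_e2 == pytest.approx(ols_var, abs=1e-6)


def test_reml_loglik_is_maximal_at_optimum(small_cohort):
    y = small_cohort.phenotypes.trait("kappa_cn")
    grm = mk.build_grm(small_cohort.genotypes)
    fit = mk.fit_polygenic(y, small_cohort.phenotypes.covariates(), grm)
    d, u = grm.eig()
    from milknet.gwas import design_matrix

    x = design_matrix(small_cohort.phenotypes.covariates())
    n, p = x.shape
    ll_opt = _reml_loglik(fit.vc.h2, d, u.T @ y, u.T @ x, n, p)[0]
    for h2 in (0.05, 0.25, 0.45, 0.65, 0.85):
        ll = _reml_loglik(h2, d, u.T @ y, u.T @ x, n, p)[0]
        assert ll <= ll_opt + 1e-6


def test_reml_recovers_simulated_h2_on_average():
    est = []
    for rep in range(8):
        cfg = mk.SimConfig(
            n_individuals=400, n_snps=800, n_chromosomes=4, maf_range=(0.1, 0.5),
            trait_names=["t"], trait_clusters={"t": 1}, h2={"t": 0.5},
            qtls=[], n_herds=10, seed=400 + rep,
        )
        cohort = mk.simulate_cohort(cfg)
        fit = mk.fit_polygenic(
            cohort.phenotypes.trait("t"),
            cohort.phenotypes.covariates(),
            mk.build_grm(cohort.genotypes),
        )
        est.append(fit.vc.h2)
    assert abs(np.mean(est) - 0.5) < 0.12


# ---------------------------------------------------------------------------
# GRAMMAR scan
# ---------------------------------------------------------------------------

def test_gc_lambda_identity_when_chi2_at_median():
    """If every chi2 equals the chi2(1) median, lambda = 1 and p_gc = p_raw."""
    assert CHI2_1_MEDIAN == pytest.approx(0.4549, abs=1e-4)
    chi2 = np.full(100, CHI2_1_MEDIAN)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    assert lam == 1.0


def test_grammar_scan_null_calibration(small_cohort):
    """Permuted (null) residual-scale trait: uniform p_raw, lambda near 1."""
    g = small_cohort.genotypes
    rng = np.random.default_rng(1)
    y = rng.standard_normal(g.n_individuals)
    fit = mk.fit_polygenic(y, small_cohort.phenotypes.covariates(), mk.build_grm(g))
    table, gc = mk.grammar_scan(fit, g)
    assert 0.5 < gc.lam < 1.6
    assert stats.kstest(table["p_raw"].dropna(), "uniform").pvalue > 0.01


def test_grammar_scan_zero_variance_snp_flagged_nan(small_cohort):
    g = small_cohort.genotypes
    dosage = g.dosage.copy()
    dosage[:, 0] = 1  # constant column
    g2 = make_genotypes(dosage)
    rng = np.random.default_rng(2)
    y = rng.standard_normal(g2.n_individuals)
    fit = mk.fit_polygenic(
        y, small_cohort.phenotypes.covariates(), mk.Grm(0.5 * np.eye(g2.n_individuals), g2.sample_ids)
    )
    table, _ = mk.grammar_scan(fit, g2)
    assert len(table) == g2.n_snps
    assert np.isnan(table["chi2"].iloc[0])


def test_grammar_effect_size_recovery(small_cohort):
    """Gamma recalibration restores the QTL effect magnitude: the scan's
    beta for the simulated QTL matches the true allele substitution effect
    within 35% (residual-scale estimates without the correction are
    noticeably more deflated)."""
    truth = small_cohort.truth["qtls"][0]
    g = small_cohort.genotypes
    table, _, _ = mk.gwas_scan(g, small_cohort.phenotypes, "kappa_cn")
    got = float(table.set_index("snp").loc[truth["snp"], "beta"])
    # truth["effect"] is on the dosage scale used by the simulation
    assert np.sign(got) == np.sign(truth["effect"])
    assert abs(got) == pytest.approx(abs(truth["effect"]), rel=0.35)
    table_nc, _, _ = mk.gwas_scan(
        g, small_cohort.phenotypes, "kappa_cn", gamma_correct=False
    )
    got_nc = float(table_nc.set_index("snp").loc[truth["snp"], "beta"])
    assert abs(got_nc) < abs(got)  # uncorrected estimate is deflated


def test_scan_results_independent_of_trait_order(small_cohort):
    g = small_cohort.genotypes
    grm = mk.build_grm(g)
    first = {}
    for order in (["kappa_cn", "beta_lg"], ["beta_lg", "kappa_cn"]):
        for t in order:
            table, _, _ = mk.gwas_scan(g, small_cohort.phenotypes, t, grm=grm)
            if t not in first:
                first[t] = table
            else:
                pd.testing.assert_frame_equal(first[t], table)


# ---------------------------------------------------------------------------
# SNP variance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p,a,expected",
    [(0.5, 1.0, 0.5), (0.0, 3.0, 0.0), (1.0, 3.0, 0.0), (0.24, 2.0, 1.4592)],
)
def test_snp_variance(p, a, expected):
    assert mk.snp_variance(p, a) == pytest.approx(expected, abs=1e-12)


def test_snp_variance_rejects_bad_frequency():
    with pytest.raises(ValueError):
        mk.snp_variance(1.2, 1.0)


# ---------------------------------------------------------------------------
# Conditional scan
# ---------------------------------------------------------------------------

def test_conditional_empty_equals_base(small_cohort):
    g = small_cohort.genotypes
    grm = mk.build_grm(g)
    base, _, _ = mk.gwas_scan(g, small_cohort.phenotypes, "kappa_cn", grm=grm)
    cond = mk.conditional_scan(g, small_cohort.phenotypes, "kappa_cn", [], grm=grm)
    pd.testing.assert_frame_equal(base, cond.assoc)
    assert cond.sigma_g2_change == 0.0


def test_conditional_on_qtl_reduces_genetic_variance():
    """Averaged over replicates, fixing a 50%-Va QTL in the model removes a
    large share of the estimated additive variance."""
    changes = []
    for rep in range(4):
        cfg = mk.SimConfig(
            n_individuals=400, n_snps=800, n_chromosomes=4, maf_range=(0.1, 0.5),
            trait_names=["t"], trait_clusters={"t": 1}, h2={"t": 0.5},
            qtls=[mk.QtlSpec(chrom=2, pos=5_000_000, effects={"t": 0.5})],
            n_herds=10, seed=500 + rep,
        )
        cohort = mk.simulate_cohort(cfg)
        cond = mk.conditional_scan(
            cohort.genotypes, cohort.phenotypes, "t", [cohort.truth["qtls"][0]["snp"]]
        )
        changes.append(cond.sigma_g2_change)
    assert np.mean(changes) < -0.25


def test_conditional_collinear_snp_dropped(small_cohort):
    g = small_cohort.genotypes
    dosage = np.column_stack([g.dosage, g.dosage[:, :1]])
    g2 = make_genotypes(dosage)
    phen = small_cohort.phenotypes
    with pytest.warns(UserWarning, match="collinear"):
        cond = mk.conditional_scan(g2, phen, "kappa_cn", ["s0", f"s{g.n_snps}"])
    assert cond.dropped_snps == [f"s{g.n_snps}"]


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_identical_columns_full_ld():
    rng = np.random.default_rng(4)
    col = rng.binomial(2, 0.4, size=200).astype(np.int8)
    g = make_genotypes(np.column_stack([col, col]))
    assert mk.ld_r2(g, "s0", "s1") == pytest.approx(1.0)


def test_ld_hand_computed_pearson():
    g = make_genotypes(np.array([[0, 0], [1, 1], [2, 2], [2, 0]]))
    r = np.corrcoef([0, 1, 2, 2], [0, 1, 2, 0])[0, 1]
    assert mk.ld_r2(g, "s0", "s1") == pytest.approx(r**2, abs=1e-12)


def test_ld_independent_snps_near_zero():
    rng = np.random.default_rng(5)
    g = make_genotypes(rng.binomial(2, 0.3, size=(1000, 200)).astype(np.int8))
    vals = [mk.ld_r2(g, f"s{2*k}", f"s{2*k+1}") for k in range(100)]
    assert np.mean(vals) < 0.01


def test_ld_monomorphic_raises():
    g = make_genotypes(np.array([[2, 1], [2, 0], [2, 1]]))
    with pytest.raises(mk.MonomorphicSNPError):
        mk.ld_r2(g, "s0", "s1")
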