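"""Canonical correlation engine: closed forms, oracles, the Wilks/Rao
test and the Fisher-z power approximation."""

import numpy as np
import pytest
from scipy import stats

from snpcca.cca import (
    SnpCcaScan,
    canonical_correlations,
    covariance_blocks,
    min_detectable_r,
    wilks_lambda_test,
    CovarianceBlocks,
)
from snpcca.containers import DomainError
from snpcca.simulate import CohortSpec, simulate_genotypes, simulate_phenotypes


class TestCovarianceBlocks:
    def test_identity_when_y_equals_x(self, rng):
        x = rng.standard_normal((50, 3))
        b = covariance_blocks(x, x)
        np.testing.assert_allclose(b.s_xy, b.s_xx, atol=1e-12)
        np.testing.assert_allclose(np.cov(x, rowvar=False), b.s_xx, atol=1e-12)

    def test_orthogonal_columns_zero_cross(self):
        x = np.array([[1.0], [-1], [1], [-1], [1], [-1]])
        y = np.array([[1.0], [1], [-1], [-1], [1], [1]])
        y -= y.mean()
        assert abs(covariance_blocks(x, y).s_xy[0, 0]) < 1e-12

    def test_hand_computed_1x2(self):
        x = np.array([[1.0], [2], [3], [4], [10]])
        y = np.column_stack([np.array([2.0, 4, 6, 8, 20]), np.array([1.0, 0, 1, 0, 1])])
        b = covariance_blocks(x, y)
        assert b.s_xx[0, 0] == pytest.approx(np.var(x, ddof=1))
        assert b.s_xy[0, 0] == pytest.approx(2 * np.var(x, ddof=1))

    def test_constant_column_named(self, rng):
        x = rng.standard_normal((20, 2))
        x[:, 1] = 3.0
        with pytest.raises(DomainError, match="column 1"):
            covariance_blocks(x, rng.standard_normal((20, 2)))


class TestCanonicalCorrelations:
    def test_closed_form_identity_blocks(self):
        b = CovarianceBlocks(np.array([[1.0]]), np.array([[0.3, 0.4]]), np.eye(2), 100)
        r, a, w = canonical_correlations(b)
        assert r[0] == pytest.approx(0.5)

    def test_zero_cross_covariance(self):
        b = CovarianceBlocks(np.eye(2), np.zeros((2, 2)), np.eye(2), 100)
        r, _, _ = canonical_correlations(b)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_matches_eigenvalue_oracle(self, rng):
        """r must equal sqrt(eigvals(Sxx^-1 Sxy Syy^-1 Syx)) from an
        independent eigen-solver."""
        for _ in range(10):
            z = rng.standard_normal((60, 6))
            x, y = z[:, :3], z[:, 3:] + 0.5 * z[:, :3]
            b = covariance_blocks(x, y)
            r, _, _ = canonical_correlations(b)
            m = np.linalg.inv(b.s_xx) @ b.s_xy @ np.linalg.inv(b.s_yy) @ b.s_xy.T
            expected = np.sqrt(np.sort(np.linalg.eigvals(m).real)[::-1])
            np.testing.assert_allclose(r, expected, atol=1e-8)

    def test_weights_achieve_r(self, rng):
        x = rng.standard_normal((200, 2))
        y = x @ rng.standard_normal((2, 3)) + rng.standard_normal((200, 3))
        b = covariance_blocks(x, y)
        r, a, w = canonical_correlations(b)
        u = (x - x.mean(0)) @ a[:, 0]
        v = (y - y.mean(0)) @ w[:, 0]
        assert np.corrcoef(u, v)[0, 1] == pytest.approx(r[0], abs=1e-10)

    def test_affine_invariance_of_y(self, rng):
        """Canonical correlations are unchanged by invertible affine maps of Y."""
        x = rng.standard_normal((80, 2))
        y = rng.standard_normal((80, 3)) + 0.4 * x @ rng.standard_normal((2, 3))
        r0, _, _ = canonical_correlations(covariance_blocks(x, y))
        t = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        r1, _, _ = canonical_correlations(covariance_blocks(x, y @ t + 5.0))
        np.testing.assert_allclose(r0, r1, atol=1e-9)

    def test_singular_block_errors(self, rng):
        x = rng.standard_normal((30, 2))
        x = np.column_stack([x, x[:, 0] + 1e-14 * rng.standard_normal(30)])
        with pytest.raises(DomainError, match="singular"):
            canonical_correlations(covariance_blocks(x, rng.standard_normal((30, 2))))


class TestWilksLambdaTest:
    def test_null_gives_unit_lambda(self):
        lam, f, df1, df2, p = wilks_lambda_test(np.zeros(2), 100, 2, 2)
        assert lam == 1.0 and f == 0.0 and p == 1.0

    def test_g1_p2_hand_value(self):
        lam, f, df1, df2, p = wilks_lambda_test(np.array([0.3]), 100, 1, 2)
        assert f == pytest.approx((0.09 / 0.91) * (97 / 2), rel=1e-12)
        assert (df1, df2) == (2.0, 97.0)
        assert p == pytest.approx(stats.f.sf(f, 2, 97), rel=1e-12)

    def test_g1_p1_equals_pearson_t_test(self, rng):
        x = rng.standard_normal(40)
        y = 0.3 * x + rng.standard_normal(40)
        r = abs(np.corrcoef(x, y)[0, 1])
        _, _, _, _, p = wilks_lambda_test(np.array([r]), 40, 1, 1)
        assert p == pytest.approx(stats.pearsonr(x, y).pvalue, rel=1e-9)

    def test_lambda_product_identity(self, rng):
        r = rng.uniform(0, 0.9, 3)
        lam, *_ = wilks_lambda_test(r, 500, 3, 3)
        assert lam == pytest.approx(np.prod(1 - r**2), abs=1e-12)

    def test_small_n_errors(self):
        with pytest.raises(DomainError):
            wilks_lambda_test(np.array([0.1]), 4, 1, 2)


class TestMinDetectableR:
    def test_published_cohort_sizes(self):
        assert round(min_detectable_r(2494), 2) == 0.12
        assert round(min_detectable_r(1917), 2) == 0.14

    def test_two_sided_is_larger(self):
        assert min_detectable_r(2494, sided="two") > min_detectable_r(2494, sided="one")

    def test_monotone_decreasing_in_n(self):
        rs = [min_detectable_r(n) for n in (500, 2000, 10000, 10**8)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.001

    def test_invalid_bounds(self):
        with pytest.raises(DomainError):
            min_detectable_r(100, alpha=0.9, power=0.5)


class TestSnpCcaScan:
    def test_perfect_proxy_snp(self, small_cohort):
        _, g, sim = small_cohort
        pheno = sim.phenotypes
        g2 = g.subset_variants(np.arange(g.n_variants) < 5)
        # overwrite one dosage column with a monotone proxy of eGFR
        g2.dosage[:, 0] = (pheno.egfr_std > np.quantile(pheno.egfr_std, 0.5)).astype(float) + (
            pheno.egfr_std > np.quantile(pheno.egfr_std, 0.8)
        ).astype(float)
        res = SnpCcaScan(g2, pheno).fit()
        assert res.table.loc[0, "r1"] > 0.7
        assert res.table.loc[0, "p"] < 5e-8

    def test_scan_identical_to_naive_cca(self, small_cohort):
        """The vectorised scan must reproduce per-SNP canonical_correlations."""
        _, g, sim = small_cohort
        res = SnpCcaScan(g, sim.phenotypes).fit()
        y = sim.phenotypes.y_block()
        for j in [0, 17, 123, 299]:
            b = covariance_blocks(g.dosage[:, [j]], y)
            r, _, _ = canonical_correlations(b)
            assert res.table.loc[j, "r1"] == pytest.approx(r[0], abs=1e-10)
            lam, f, df1, df2, p = wilks_lambda_test(r, b.n, 1, y.shape[1])
            assert res.table.loc[j, "p"] == pytest.approx(p, rel=1e-9)

    def test_bonferroni_mode(self, small_cohort):
        _, g, sim = small_cohort
        res = SnpCcaScan(g, sim.phenotypes).fit(adjust="bonferroni_by_count")
        np.testing.assert_allclose(
            res.table["p_adj"], np.minimum(1.0, res.table["p"] * g.n_variants)
        )

    def test_bonferroni_with_external_m(self, small_cohort):
        _, g, sim = small_cohort
        m = 8_346_783  # genome-scale SNP count: cut-off becomes 0.05/m
        res = SnpCcaScan(g, sim.phenotypes).fit(adjust="bonferroni_by_count", m_tests=m)
        sig = res.significant(alpha=0.05)
        assert set(sig.index) == set(res.table.index[res.table["p"] < 0.05 / m])

    def test_sample_mismatch_errors(self, small_cohort):
        _, g, sim = small_cohort
        pheno = sim.phenotypes
        shuffled = g.subset_samples(list(reversed(g.samples)))
        with pytest.raises(DomainError):
            SnpCcaScan(shuffled, pheno)

    def test_summary_mentions_counts(self, small_cohort):
        _, g, sim = small_cohort
        s = SnpCcaScan(g, sim.phenotypes).fit().summary()
        assert "SNPs tested" in s and str(g.n_variants) in s


def test_parameter_recovery_planted_r1(rng):
    """Mean estimated r1 over replicates is close to the planted value."""
    from snpcca.simulate import effect_for_target_r1

    target, c = 0.3, -0.4
    rho = effect_for_target_r1(target, c)
    n, reps = 2000, 60
    est = np.empty(reps)
    for k in range(reps):
        x = rng.binomial(2, 0.3, n).astype(float)
        xs = (x - x.mean()) / x.std()
        e = rng.multivariate_normal([0, 0], [[1, c], [c, 1]], size=n)
        y1 = rho * xs + np.sqrt(1 - rho**2) * e[:, 0]
        y2 = -rho * xs + np.sqrt(1 - rho**2) * e[:, 1]
        r, _, _ = canonical_correlations(covariance_blocks(x[:, None], np.column_stack([y1, y2])))
        est[k] = r[0]
    assert abs(est.mean() - target) < 0.02
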