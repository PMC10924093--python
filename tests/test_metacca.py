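"""Summary-statistic canonical correlation: standardisation, S_YY
estimation, PSD shrinkage, input validation and the per-SNP solve."""

import numpy as np
import pandas as pd
import pytest

from snpcca.containers import DomainError
from snpcca.metacca import (
    MetaCcaScan,
    estimate_pheno_corr,
    metacca_per_snp,
    shrink_to_psd,
    standardize_betas,
    validate_summary_input,
)
from snpcca.simulate import CohortSpec, simulate_genotypes, simulate_phenotypes, simulate_summary_stats


class TestStandardizeBetas:
    def test_zero_beta(self):
        assert standardize_betas(0.0, 0.1, 100) == 0.0

    def test_formula_value(self):
        assert standardize_betas(0.1, 0.02, 1000) == pytest.approx(5 / np.sqrt(1023))

    def test_sign_preserved(self, rng):
        beta = rng.standard_normal(100)
        out = standardize_betas(beta, np.full(100, 0.05), np.full(100, 500))
        np.testing.assert_array_equal(np.sign(out), np.sign(beta))
        assert (np.abs(out) < 1).all()

    def test_matches_ols_correlation(self, rng):
        """t-based standardisation recovers the sample correlation from
        an actual OLS fit on standardised variables."""
        x = rng.standard_normal(400)
        y = 0.3 * x + rng.standard_normal(400)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        sxx = float(((x - x.mean()) ** 2).sum())
        beta = float(((x - x.mean()) * (y - y.mean())).sum()) / sxx
        rss = float(((y - beta * x) ** 2).sum())
        se = np.sqrt(rss / (398 * sxx))
        assert standardize_betas(beta, se, 400) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_se_zero_errors(self):
        with pytest.raises(DomainError):
            standardize_betas(0.1, 0.0, 100)


class TestShrinkToPsd:
    def test_psd_input_unchanged(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        out, k = shrink_to_psd(m)
        assert k == 0
        np.testing.assert_array_equal(out, m)

    def test_known_iteration_count(self):
        out, k = shrink_to_psd(np.array([[1.0, 1.2], [1.2, 1.0]]))
        assert k == 183
        assert out[0, 1] == pytest.approx(1.2 * 0.999**183)
        assert np.linalg.eigvalsh(out).min() >= 1e-12

    def test_diagonal_never_touched(self, rng):
        m = rng.standard_normal((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        out, _ = shrink_to_psd(m)
        np.testing.assert_array_equal(np.diag(out), np.diag(m))
        assert (np.abs(out) <= np.abs(m) + 1e-15).all()

    def test_always_terminates_unit_diagonal(self, rng):
        for _ in range(20):
            m = np.clip(rng.uniform(-1.5, 1.5, (3, 3)), -1.5, 1.5)
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            out, _ = shrink_to_psd(m)
            assert np.linalg.eigvalsh(out).min() >= 1e-12


class TestEstimatePhenoCorr:
    def test_recovers_known_correlation(self):
        """Null genetics, phenotypic correlation 0.6, 5000 SNPs: the
        effect-column estimate recovers both the population value and
        (more tightly) the realised cohort correlation."""
        spec = CohortSpec(n_samples=3000, n_snps=5000, n_causal=0, pheno_corr=0.6,
                          ld_rho=0.0, seed=11)
        g = simulate_genotypes(spec)
        sim = simulate_phenotypes(g, spec)
        ss = simulate_summary_stats(g, sim.phenotypes)
        eff = pd.DataFrame(
            {
                "r_egfr": standardize_betas(ss["beta_egfr"], ss["se_egfr"], ss["n_egfr"]),
                "r_bun": standardize_betas(ss["beta_bun"], ss["se_bun"], ss["n_bun"]),
            }
        )
        pheno = estimate_pheno_corr(eff, ["egfr", "bun"])
        assert pheno.s_yy[0, 1] == pytest.approx(0.6, abs=0.05)
        realised = np.corrcoef(sim.phenotypes.egfr_std, sim.phenotypes.bun_std)[0, 1]
        assert pheno.s_yy[0, 1] == pytest.approx(realised, abs=0.02)
        assert pheno.s_yy[0, 0] == 1.0

    def test_independent_traits_near_zero(self, rng):
        m = 4000
        estimates = []
        for _ in range(5):
            eff = pd.DataFrame({"r_egfr": rng.standard_normal(m) * 0.02,
                                "r_bun": rng.standard_normal(m) * 0.02})
            estimates.append(abs(estimate_pheno_corr(eff, ["egfr", "bun"]).s_yy[0, 1]))
        assert np.median(estimates) < 3 / np.sqrt(m)
        assert max(estimates) < 5 / np.sqrt(m)

    def test_duplicate_traits_flagged_near_one(self, rng, caplog):
        r = rng.standard_normal(2000) * 0.03
        eff = pd.DataFrame({"r_a": r, "r_b": r + 1e-12 * rng.standard_normal(2000)})
        with caplog.at_level("WARNING"):
            pheno = estimate_pheno_corr(eff, ["a", "b"])
        # PSD shrinkage backs the degenerate off-diagonal off 1 slightly
        assert pheno.s_yy[0, 1] == pytest.approx(1.0, abs=0.01)
        assert "near-duplicate" in caplog.text

    def test_too_few_snps(self):
        with pytest.raises(DomainError):
            estimate_pheno_corr(pd.DataFrame({"r_a": [0.1], "r_b": [0.2]}), ["a", "b"])


class TestValidateSummaryInput:
    def _table(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2", "2", "3", "3"],
                "pos": [100, 200, 300, 300, 500, 600],
                "rsid": [f"rs{i}" for i in range(6)],
                "ref": ["A", "C", "G", "G", "T", "AT"],
                "ea": ["G", "T", "A", "A", "C", "A"],
                "af": [0.2, 0.005, 0.3, 0.3, 0.4, 0.25],
                "beta_egfr": [0.1] * 6,
                "se_egfr": [0.01] * 6,
                "n_egfr": [1000] * 6,
                "beta_bun": [-0.1] * 6,
                "se_bun": [0.01, 0.01, 0.01, 0.01, 0.0, 0.01],
                "n_bun": [900] * 6,
            }
        )

    def test_all_filters_counted(self):
        out, rep = validate_summary_input(self._table(), ["egfr", "bun"])
        assert rep["removed_se_zero"] == 1        # row 4 (se_bun = 0)
        assert rep["removed_non_acgt"] == 1       # row 5 ("AT")
        assert rep["removed_duplicate"] == 2      # both copies of 2:300
        assert rep["removed_af"] == 1             # af 0.005
        assert rep["retained"] == 1 and len(out) == 1
        assert out.loc[0, "pos"] == 100

    def test_empty_output_warns_not_errors(self):
        t = self._table()
        t["se_egfr"] = 0.0
        with pytest.warns(UserWarning):
            out, _ = validate_summary_input(t, ["egfr", "bun"])
        assert len(out) == 0


class TestMetaccaPerSnp:
    def test_closed_form_2x2(self):
        r1, *_ = metacca_per_snp(np.array([0.1, -0.1]), np.array([[1, 0.5], [0.5, 1.0]]), 1000)
        assert r1 == pytest.approx(0.2)

    def test_null_effects(self):
        r1, lam, f, df1, df2, p = metacca_per_snp(
            np.zeros(2), np.array([[1, 0.5], [0.5, 1.0]]), 1000
        )
        assert r1 == 0.0 and p == 1.0

    def test_opposite_sign_synergy(self):
        """With positively correlated traits, opposite-direction effects
        carry more multivariate signal than same-direction ones."""
        s_yy = np.array([[1, 0.6], [0.6, 1.0]])
        for c in np.linspace(0.01, 0.49, 12):
            r_opp, *_ = metacca_per_snp(np.array([c, -c]), s_yy, 5000)
            r_same, *_ = metacca_per_snp(np.array([c, c]), s_yy, 5000)
            assert r_opp > r_same


def test_engines_agree_on_simulated_cohort():
    """Individual-level CCA and the summary-statistic reconstruction give
    near-identical per-SNP r1 and p on the same cohort."""
    from snpcca.cca import SnpCcaScan

    spec = CohortSpec(n_samples=1500, n_snps=600, n_causal=8, effect_size=0.12, seed=3)
    g = simulate_genotypes(spec)
    sim = simulate_phenotypes(g, spec)
    cca = SnpCcaScan(g, sim.phenotypes).fit()
    ss = simulate_summary_stats(g, sim.phenotypes)
    meta = MetaCcaScan(ss).fit()
    merged = cca.table.merge(meta.table, on=["chrom", "pos"], suffixes=("_cca", "_meta"))
    assert len(merged) == 600
    dr = (merged["r1_cca"] - merged["r1_meta"]).abs()
    assert dr.median() < 0.01
    lp = -np.log10(np.maximum(merged[["p_cca", "p_meta"]], 1e-300))
    rank_corr = pd.Series(lp["p_cca"]).corr(pd.Series(lp["p_meta"]), method="spearman")
    assert rank_corr > 0.99
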