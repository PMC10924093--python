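"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: Hardy-Weinberg
genotypes with a uniform MAF spectrum and block LD (Gaussian-copula
thresholding, so block correlation is analytically controlled and the
marginals are exactly HWE); bivariate kidney-function latents driven by
sparse causal SNPs with opposite-sign effects on the two traits plus
correlated residual noise; per-SNP ordinary-least-squares summary
statistics; paired GWAS/eQTL regions with shared or distinct causal
variants; and log2 expression matrices with a planted differentially
expressed fraction.

Every generator is a pure function of its spec and seed; per-stage
random streams are derived from the one cohort seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .containers import DomainError, GenotypeMatrix, PhenotypeMatrix
from .coloc import RegionStats

__all__ = [
    "CohortSpec",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_summary_stats",
    "simulate_eqtl_pair",
    "simulate_expression",
    "effect_for_target_r1",
]

# Observed raw-scale ranges the back-transforms target (CKD cohort scales):
# eGFR 3.3-139 ml/min/1.73m2; serum urea about 1.7-63.7 mmol/L.
_EGFR_RANGE = (3.3, 139.0)
_LOG10_BUN_MEAN = 0.8
_LOG10_BUN_SD = 0.25
_UREA_TO_BUN = 2.14

_STREAM = {"genotypes": 11, "phenotypes": 23, "summary": 37, "eqtl": 53, "expression": 71}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference cohort used throughout testing:
    2,000 samples x 2,000 SNPs in LD blocks of 10 (within-block latent
    correlation 0.4), 20 causal SNPs with opposite-direction effects of
    correlation-scale size 0.15 on the two traits, residual eGFR-BUN
    correlation -0.5 (the traits are physiologically anti-correlated),
    and half the cohort labelled CKD cases (the lowest-eGFR half).
    """

    n_samples: int = 2000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_block_size: int = 10
    ld_rho: float = 0.4
    n_causal: int = 20
    effect_size: float = 0.15
    direction_mode: str = "opposite"
    pheno_corr: float = -0.5
    case_fraction: float = 0.5
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise DomainError("n_causal cannot exceed n_snps")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise DomainError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise DomainError("ld_rho must lie in [0, 1)")
        if not (-1 < self.pheno_corr < 1):
            raise DomainError("pheno_corr must lie in (-1, 1)")
        if self.direction_mode not in ("opposite", "same", "mixed"):
            raise DomainError(f"unknown direction_mode {self.direction_mode!r}")
        if not (0 <= self.case_fraction <= 1):
            raise DomainError("case_fraction must lie in [0, 1]")


def _rng(spec_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed) % (2**31), _STREAM[stage]])


def simulate_genotypes(spec: CohortSpec) -> GenotypeMatrix:
    """HWE genotypes with exchangeable within-block latent correlation.

    Per block, latent vectors z = sqrt(rho)*shared + sqrt(1-rho)*own
    are thresholded at each SNP's HWE genotype quantiles, so marginal
    genotype frequencies are exactly Hardy-Weinberg at the drawn MAF.
    SNPs are laid out on chromosome 1 at 5 kb spacing.
    """
    rng = _rng(spec.seed, "genotypes")
    n, m = spec.n_samples, spec.n_snps
    maf = rng.uniform(*spec.maf_range, size=m)
    z = np.empty((n, m))
    for start in range(0, m, spec.ld_block_size):
        width = min(spec.ld_block_size, m - start)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        z[:, start : start + width] = np.sqrt(spec.ld_rho) * shared + np.sqrt(1 - spec.ld_rho) * own
    # HWE thresholds for dosage of the effect (minor) allele
    p0 = (1 - maf) ** 2
    p1 = 2 * maf * (1 - maf)
    t0 = stats.norm.ppf(p0)
    t1 = stats.norm.ppf(p0 + p1)
    dosage = (z > t0).astype(float) + (z > t1).astype(float)
    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        dosage[mask] = np.nan
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(4, size=m)
    ea = (ref + 1 + rng.choice(3, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 10_000 + 5_000 * np.arange(m),
            "rsid": [f"rs{spec.seed % 1000}{j:06d}" for j in range(m)],
            "ref": bases[ref],
            "ea": bases[ea],
        }
    )
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


@dataclass
class SimulatedPhenotypes:
    """Phenotype block plus the raw scales and generative truth."""

    phenotypes: PhenotypeMatrix
    egfr_raw: np.ndarray
    urea_raw: np.ndarray
    causal_idx: np.ndarray
    beta_egfr: np.ndarray
    beta_bun: np.ndarray


def simulate_phenotypes(g: GenotypeMatrix, spec: CohortSpec) -> SimulatedPhenotypes:
    """Bivariate kidney-function latents from sparse causal SNPs.

    Causal dosage columns are standardised and weighted by
    ``effect_size`` (correlation scale); the BUN-side signs follow
    ``direction_mode``. Residual noise is bivariate normal with
    correlation ``pheno_corr``. Latents are mapped monotonically onto
    plausible raw scales (eGFR ml/min/1.73m2 and serum urea mmol/L) so
    the standardisation code paths run on realistic magnitudes; cases
    are the lowest-eGFR ``case_fraction`` of the cohort.
    """
    rng = _rng(spec.seed, "phenotypes")
    n = g.n_samples
    dose = g.dosage
    if np.isnan(dose).any():
        raise DomainError("phenotype simulation needs complete genotypes")
    causal = np.sort(rng.choice(g.n_variants, size=spec.n_causal, replace=False))
    beta_e = np.full(spec.n_causal, spec.effect_size)
    if spec.direction_mode == "opposite":
        beta_b = -beta_e
    elif spec.direction_mode == "same":
        beta_b = beta_e.copy()
    else:
        beta_b = beta_e * rng.choice([-1.0, 1.0], size=spec.n_causal)

    if spec.n_causal:
        xc = dose[:, causal]
        sd = xc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xs = (xc - xc.mean(axis=0)) / sd
        gen_e = xs @ beta_e
        gen_b = xs @ beta_b
    else:
        gen_e = gen_b = np.zeros(n)

    # residual variance tops each trait's latent up to (approximately)
    # unit total variance, so effect_size is on the correlation scale
    resid_sd_e = np.sqrt(max(1.0 - float(beta_e @ beta_e), 0.05))
    resid_sd_b = np.sqrt(max(1.0 - float(beta_b @ beta_b), 0.05))
    cov = np.array([[1.0, spec.pheno_corr], [spec.pheno_corr, 1.0]])
    noise = rng.multivariate_normal([0, 0], cov, size=n)
    latent_e = gen_e + resid_sd_e * noise[:, 0]
    latent_b = gen_b + resid_sd_b * noise[:, 1]

    # monotone maps to raw scales (rank-INT and log-Z undo them)
    ze = (latent_e - latent_e.mean()) / latent_e.std(ddof=1)
    zb = (latent_b - latent_b.mean()) / latent_b.std(ddof=1)
    lo, hi = _EGFR_RANGE
    egfr_raw = lo + (hi - lo) * stats.norm.cdf(ze)
    urea_raw = _UREA_TO_BUN * 10 ** (_LOG10_BUN_MEAN + _LOG10_BUN_SD * zb)

    n_cases = int(round(spec.case_fraction * n))
    order = np.argsort(egfr_raw)
    case = np.zeros(n)
    case[order[:n_cases]] = 1.0

    from .qc import build_phenotype_matrix

    pheno = build_phenotype_matrix(egfr_raw, urea_raw, case, samples=g.samples)
    return SimulatedPhenotypes(
        phenotypes=pheno, egfr_raw=egfr_raw, urea_raw=urea_raw,
        causal_idx=causal, beta_egfr=beta_e, beta_bun=beta_b,
    )


def simulate_summary_stats(g: GenotypeMatrix, y: PhenotypeMatrix) -> pd.DataFrame:
    """Per-SNP, per-trait simple OLS summary statistics.

    Regressions of each standardised phenotype on each dosage column
    give beta, SE (residual-variance based, n-2 df), p (t test), n and
    the effect-allele frequency, in the wide merged-trait layout the
    summary-statistic engine consumes. Monomorphic SNPs are dropped.
    """
    if g.samples != y.samples:
        raise DomainError("sample sets differ between genotypes and phenotypes")
    dose = g.dosage
    n = dose.shape[0]
    xc = dose - dose.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    poly = sxx > 0
    if not poly.all():
        import warnings

        warnings.warn(f"dropping {int((~poly).sum())} monomorphic SNP(s)", stacklevel=2)
    out = g.variants.loc[poly, ["chrom", "pos", "rsid", "ref", "ea"]].reset_index(drop=True)
    out["af"] = dose[:, poly].mean(axis=0) / 2.0
    xc = xc[:, poly]
    sxx = sxx[poly]
    for trait, vals in (("egfr", y.egfr_std), ("bun", y.bun_std)):
        yc = vals - vals.mean()
        syy = float((yc**2).sum())
        sxy = xc.T @ yc
        beta = sxy / sxx
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0) / ((n - 2) * sxx))
        tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        out[f"beta_{trait}"] = beta
        out[f"se_{trait}"] = se
        out[f"p_{trait}"] = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        out[f"n_{trait}"] = n
    return out


def simulate_eqtl_pair(
    shared: bool, n_snps: int = 100, causal_z: float = 12.0, seed: int = 0, n: int = 10_000
) -> tuple[RegionStats, RegionStats]:
    """A GWAS region and an eQTL region with shared or distinct causals.

    Null SNPs have z ~ N(0,1); the causal SNP in each region has
    expected |z| = ``causal_z``. With ``shared`` both causal signals
    sit at the same variant, otherwise at distinct variants.
    """
    if n_snps < 10:
        raise DomainError("need at least 10 SNPs per region")
    rng = _rng(seed, "eqtl")
    idx1 = int(rng.integers(n_snps))
    if shared:
        idx2 = idx1
    else:
        idx2 = int(rng.integers(n_snps - 1))
        if idx2 >= idx1:
            idx2 += 1
    se = 1.0 / np.sqrt(n)
    bases = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1_000_000 + 2_000 * np.arange(n_snps),
            "ref": "A",
            "ea": "G",
            "n": n,
        }
    )
    tables = []
    for idx in (idx1, idx2):
        z = rng.standard_normal(n_snps)
        if causal_z:
            z[idx] = causal_z + rng.standard_normal()
        t = bases.copy()
        t["beta"] = z * se
        t["varbeta"] = se**2
        tables.append(RegionStats(table=t))
    return tables[0], tables[1]


def simulate_expression(
    n_genes: int = 2000,
    n_case: int = 10,
    n_control: int = 10,
    de_fraction: float = 0.05,
    true_lfc: float = 1.2,
    sigma: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Log2 expression with a planted differentially expressed fraction.

    Returns (gene x sample DataFrame, group labels, truth mask of DE
    genes). DE genes are shifted by ``true_lfc`` in cases.
    """
    if min(n_case, n_control) < 2:
        raise DomainError("need at least two samples per group")
    rng = _rng(seed, "expression")
    base = rng.uniform(4, 12, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    truth = np.zeros(n_genes, dtype=bool)
    truth[rng.choice(n_genes, size=n_de, replace=False)] = True
    shift = np.where(truth, true_lfc * rng.choice([-1.0, 1.0], size=n_genes), 0.0)
    n_tot = n_case + n_control
    mat = base[:, None] + sigma * rng.standard_normal((n_genes, n_tot))
    mat[:, :n_case] += shift[:, None]
    cols = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_control)]
    groups = ["case"] * n_case + ["control"] * n_control
    df = pd.DataFrame(mat, index=[f"GENE{i:05d}" for i in range(n_genes)], columns=cols)
    return df, groups, truth


def effect_for_target_r1(r1: float, pheno_corr: float) -> float:
    """Per-SNP correlation-scale effect giving population canonical r1.

    For a single causal SNP with opposite-direction effects (rho, -rho)
    on two unit-variance traits whose residuals correlate at
    ``pheno_corr`` = c, the trait covariance is d = -rho^2 + c(1-rho^2)
    and r1^2 = 2 rho^2 / (1 - d); this inverts that relation.
    """
    if not (0 < r1 < 1):
        raise DomainError("target r1 must lie in (0, 1)")

    def gap(rho: float) -> float:
        d = -rho**2 + pheno_corr * (1 - rho**2)
        return 2 * rho**2 / (1 - d) - r1**2

    return brentq(gap, 1e-9, 0.999999)
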