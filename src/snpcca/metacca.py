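r"""Canonical correlation reconstructed from GWAS summary statistics.

When only per-trait univariate GWAS results (beta, SE, N) are
available, the per-SNP canonical correlation against P phenotypes can
still be recovered: each beta is converted to a genotype-phenotype
correlation

.. math:: r_{xy} = \frac{t}{\sqrt{t^2 + n - 2}}, \qquad t = \beta / \mathrm{SE},

the phenotypic correlation matrix :math:`S_{YY}` is estimated as the
correlation of those standardised-effect columns across the genome
(genetic effects on any single SNP are tiny, so genome-wide the column
correlation is dominated by the phenotypic correlation), and the
single-SNP canonical correlation is

.. math:: r_1^2 = s^T S_{YY}^{-1} s

with ``s`` the per-SNP vector of standardised effects. The full joint
covariance ``[[1, s^T], [s, S_YY]]`` is shrunk towards positive
semidefiniteness before solving, by repeatedly damping off-diagonals.

A key behaviour for paired kidney-function traits: with a positive
phenotypic correlation, opposite-sign effect pairs (eGFR up, BUN down)
yield a larger canonical correlation than same-sign pairs of equal
magnitude, which is exactly the direction structure the discovery
filter keeps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DomainError, variant_ids
from .cca import wilks_lambda_test

logger = logging.getLogger(__name__)

__all__ = [
    "PhenoCorrMatrix",
    "standardize_betas",
    "estimate_pheno_corr",
    "shrink_to_psd",
    "validate_summary_input",
    "metacca_per_snp",
    "MetaCcaScan",
    "MetaCcaResults",
]

_VALID_BASES = frozenset("ACGT")


@dataclass
class PhenoCorrMatrix:
    """Estimated phenotypic correlation matrix S_YY (unit diagonal, PSD)."""

    s_yy: np.ndarray
    n_snps_used: int
    traits: tuple[str, ...]


def standardize_betas(beta, se, n):
    """Convert (beta, SE, N) to the genotype-phenotype correlation r_xy.

    r_xy = t / sqrt(t^2 + n - 2) with t = beta/SE; the sign of beta is
    preserved and |r_xy| < 1 always.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if (se <= 0).any():
        raise DomainError("standard errors must be positive")
    if (n <= 2).any():
        raise DomainError("need n > 2 per SNP")
    t = beta / se
    out = t / np.sqrt(t**2 + n - 2)
    return out if out.ndim else float(out)


def estimate_pheno_corr(
    effects: pd.DataFrame, traits: list[str], z_exclude: float = 3.0
) -> PhenoCorrMatrix:
    """Estimate S_YY from standardised-effect columns across the genome.

    ``effects`` must carry one ``r_<trait>`` column per trait; the
    off-diagonals are the Pearson correlations of those columns over
    the retained SNPs, the diagonal is forced to exactly 1, and the
    result is shrunk to PSD.

    The estimator assumes the columns are dominated by null SNPs, whose
    effect estimates correlate only through the phenotypic correlation.
    When per-trait ``n_<trait>`` columns are present, SNPs carrying a
    strong association signal (any trait |z| >= ``z_exclude``) are
    therefore excluded first; genuinely associated SNPs are extreme
    outliers on the effect scale and otherwise bias the estimate away
    from the phenotypic correlation.
    """
    cols = [f"r_{t}" for t in traits]
    mat = effects[cols].to_numpy(dtype=float)
    n_cols = [f"n_{t}" for t in traits]
    if z_exclude and all(c in effects.columns for c in n_cols):
        ns = effects[n_cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            z = np.abs(mat) * np.sqrt((ns - 2) / np.maximum(1 - mat**2, 1e-12))
        keep = (z < z_exclude).all(axis=1)
        if keep.sum() >= max(3, 0.1 * len(mat)):
            mat = mat[keep]
    m = mat.shape[0]
    if m < 3:
        raise DomainError(f"need at least 3 SNPs to estimate S_YY, got {m}")
    if m < 1000:
        warnings.warn(
            f"estimating the phenotypic correlation from only {m} SNPs; "
            "1000+ recommended", stacklevel=2,
        )
    s_yy = np.corrcoef(mat, rowvar=False)
    np.fill_diagonal(s_yy, 1.0)
    off = s_yy[np.triu_indices_from(s_yy, 1)]
    if (np.abs(off) > 1 - 1e-9).any():
        logger.warning("near-duplicate trait columns detected (|corr| ~ 1)")
    s_yy, _ = shrink_to_psd(s_yy)
    return PhenoCorrMatrix(s_yy=s_yy, n_snps_used=m, traits=tuple(traits))


def shrink_to_psd(
    sigma: np.ndarray,
    factor: float = 0.999,
    min_eig: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, int]:
    """Damp off-diagonals until the matrix is positive semidefinite.

    Off-diagonal entries are multiplied by ``factor`` repeatedly until
    the minimum eigenvalue reaches ``min_eig``; the diagonal is never
    touched. Returns the shrunk matrix and the iteration count.
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.allclose(sigma, sigma.T, atol=1e-12):
        raise DomainError("shrink_to_psd requires a symmetric matrix")
    out = sigma.copy()
    diag = np.diag(out).copy()
    for it in range(max_iter + 1):
        if np.linalg.eigvalsh(out).min() >= min_eig:
            return out, it
        out *= factor
        np.fill_diagonal(out, diag)
    raise DomainError(f"shrink_to_psd failed to converge in {max_iter} iterations")


def validate_summary_input(
    stats: pd.DataFrame, traits: list[str], af_min: float = 0.01
) -> tuple[pd.DataFrame, dict]:
    """Apply the summary-statistics input filters, with a count report.

    Rows are dropped when any trait SE is exactly 0, an allele is not a
    single A/C/G/T base, the variant key (chrom:pos:ref:ea) is
    duplicated (all copies dropped), or the effect-allele frequency is
    outside [af_min, 1 - af_min]. Rows lacking an AF skip the AF gate
    with a logged warning.
    """
    df = stats.reset_index(drop=True)
    report = {"input": len(df)}

    se_cols = [f"se_{t}" for t in traits]
    bad_se = (df[se_cols] == 0).any(axis=1)
    report["removed_se_zero"] = int(bad_se.sum())
    df = df[~bad_se]

    ok_alleles = df["ref"].isin(_VALID_BASES) & df["ea"].isin(_VALID_BASES)
    report["removed_non_acgt"] = int((~ok_alleles).sum())
    df = df[ok_alleles]

    key = variant_ids(df)
    dup = key.duplicated(keep=False)
    report["removed_duplicate"] = int(dup.sum())
    df = df[~dup]

    if "af" in df.columns:
        af = df["af"]
        no_af = af.isna()
        if no_af.any():
            logger.warning("%d row(s) lack AF; AF filter skipped for them", int(no_af.sum()))
        bad_af = (~no_af) & ((af < af_min) | (af > 1 - af_min))
        report["removed_af"] = int(bad_af.sum())
        df = df[~bad_af]
    else:
        logger.warning("no AF column; AF filter skipped")
        report["removed_af"] = 0

    report["retained"] = len(df)
    if len(df) == 0:
        warnings.warn("no SNPs survived summary-statistics validation", stacklevel=2)
    return df.reset_index(drop=True), report


def metacca_per_snp(
    effects: np.ndarray,
    s_yy: np.ndarray,
    n: int,
) -> tuple[float, float, float, float, float, float]:
    """Single-SNP canonical correlation from standardised effects.

    Builds the joint covariance [[1, s^T], [s, S_YY]], shrinks it to
    PSD, and solves r1^2 = s'^T S_YY'^-1 s' on the shrunk entries; the
    p-value comes from the Wilks/Rao F test with G=1, P=len(s).

    Returns (r1, wilks_lambda, f_stat, df1, df2, p).
    """
    s = np.asarray(effects, dtype=float)
    p_dim = s.size
    if (np.abs(s) >= 1).any():
        raise DomainError("standardised effects must have |r_xy| < 1")
    joint = np.empty((p_dim + 1, p_dim + 1))
    joint[0, 0] = 1.0
    joint[0, 1:] = s
    joint[1:, 0] = s
    joint[1:, 1:] = s_yy
    joint, _ = shrink_to_psd(joint)
    s_shr = joint[0, 1:]
    syy_shr = joint[1:, 1:]
    r2 = float(s_shr @ np.linalg.solve(syy_shr, s_shr))
    if r2 > 1 + 1e-9:
        raise DomainError(f"canonical correlation^2 = {r2:.4g} > 1 after shrinkage")
    r2 = min(max(r2, 0.0), 1.0)
    r1 = np.sqrt(r2)
    lam, f, df1, df2, p = wilks_lambda_test(np.array([r1]), n=n, g=1, p=p_dim)
    return float(r1), lam, f, df1, df2, p


class MetaCcaResults:
    """Results of a summary-statistic canonical correlation scan."""

    def __init__(self, table: pd.DataFrame, s_yy: PhenoCorrMatrix, adjust: str, m_tests: int, report: dict):
        self.table = table
        self.s_yy = s_yy
        self.adjust = adjust
        self.m_tests = m_tests
        self.validation_report = report

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.adjust == "fixed_genomewide":
            return self.table[self.table["p"] < 5e-8]
        return self.table[self.table["p_adj"] < alpha]

    def summary(self, top: int = 10) -> str:
        t = self.table.nsmallest(top, "p")
        off = self.s_yy.s_yy[np.triu_indices_from(self.s_yy.s_yy, 1)]
        lines = [
            "Summary-statistic canonical correlation scan",
            f"  SNPs tested:        {len(self.table)}",
            f"  S_YY off-diagonal:  {np.array2string(off, precision=3)}"
            f" (from {self.s_yy.n_snps_used} SNPs)",
            f"  adjustment:         {self.adjust} (m = {self.m_tests})",
            f"  significant (0.05): {len(self.significant())}",
            "",
            t[["chrom", "pos", "rsid", "r1", "f_stat", "p", "p_adj"]].to_string(index=False),
        ]
        return "\n".join(lines)


class MetaCcaScan:
    """Per-SNP canonical correlation model over GWAS summary statistics.

    Parameters
    ----------
    stats
        Wide summary-statistics table (one row per variant) carrying
        per-trait ``beta_<t>``, ``se_<t>``, ``n_<t>`` columns, as built
        by :func:`snpcca.io.merge_trait_tables`.
    traits
        Trait names, default ``("egfr", "bun")``.
    n_convention
        Per-SNP sample size for the Wilks test: ``"min"`` (default,
        conservative) or ``"mean"`` over the traits.
    """

    def __init__(
        self,
        stats: pd.DataFrame,
        traits: tuple[str, ...] = ("egfr", "bun"),
        af_min: float = 0.01,
        n_convention: str = "min",
    ):
        if n_convention not in ("min", "mean"):
            raise DomainError(f"unknown n convention {n_convention!r}")
        self.traits = list(traits)
        self.af_min = af_min
        self.n_convention = n_convention
        self.stats, self.validation_report = validate_summary_input(stats, self.traits, af_min=af_min)

    def fit(self, adjust: str = "fixed_genomewide", m_tests: int | None = None) -> MetaCcaResults:
        if adjust not in ("bonferroni_by_count", "fixed_genomewide"):
            raise DomainError(f"unknown adjustment mode {adjust!r}")
        df = self.stats.copy()
        if df.empty:
            raise DomainError("no SNPs to analyse after validation")
        for t in self.traits:
            df[f"r_{t}"] = standardize_betas(df[f"beta_{t}"], df[f"se_{t}"], df[f"n_{t}"])
        pheno = estimate_pheno_corr(df, self.traits)  # n_<t> columns enable signal trimming

        n_cols = df[[f"n_{t}" for t in self.traits]].to_numpy(dtype=float)
        n_snp = n_cols.min(axis=1) if self.n_convention == "min" else n_cols.mean(axis=1)
        eff = df[[f"r_{t}" for t in self.traits]].to_numpy(dtype=float)

        out = np.empty((len(df), 6))
        for i in range(len(df)):
            out[i] = metacca_per_snp(eff[i], pheno.s_yy, int(round(n_snp[i])))
        m_eff = m_tests if m_tests is not None else len(df)
        pvals = out[:, 5]
        p_adj = np.minimum(1.0, pvals * m_eff) if adjust == "bonferroni_by_count" else pvals.copy()

        table = df[["chrom", "pos", "rsid", "ref", "ea"]].copy()
        table["r1"] = out[:, 0]
        table["wilks_lambda"] = out[:, 1]
        table["f_stat"] = out[:, 2]
        table["df1"] = out[:, 3]
        table["df2"] = out[:, 4]
        table["p"] = pvals
        table["p_adj"] = p_adj
        for t in self.traits:
            table[f"r_{t}"] = df[f"r_{t}"]
            table[f"beta_{t}"] = df[f"beta_{t}"]
        return MetaCcaResults(table=table, s_yy=pheno, adjust=adjust, m_tests=m_eff, report=self.validation_report)
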