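r"""Canonical correlation analysis of genotype against paired phenotypes.

The first canonical correlation between an X block (SNP dosages) and a
Y block (standardised phenotypes) is

.. math::

    r_1 = \max_{a, b} \; \mathrm{corr}(X a, \; Y b)
        = \frac{a^T \Sigma_{XY} b}
               {\sqrt{a^T \Sigma_{XX} a}\,\sqrt{b^T \Sigma_{YY} b}},

computed as the singular values of the whitened cross-covariance
:math:`K = \Sigma_{XX}^{-1/2}\,\Sigma_{XY}\,\Sigma_{YY}^{-1/2}`.
Significance of the joint null (all canonical correlations zero) is
tested through Wilks' Lambda :math:`\Lambda = \prod_i (1 - r_i^2)` with
Rao's F approximation.

The genome scan model :class:`SnpCcaScan` fits one CCA per SNP (X is a
single dosage column, Y the two kidney-function traits), matching the
univariate-SNP multivariate-phenotype design; for that G=1 case the
Wilks F coincides exactly with the overall F of regressing the dosage
on the Y block, which the tests exploit as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DomainError, GenotypeMatrix, PhenotypeMatrix

__all__ = [
    "CovarianceBlocks",
    "covariance_blocks",
    "canonical_correlations",
    "wilks_lambda_test",
    "min_detectable_r",
    "SnpCcaScan",
    "SnpCcaResults",
]

_EIG_FLOOR = 1e-10


@dataclass
class CovarianceBlocks:
    """Sample covariance blocks of a joint (X, Y) observation matrix."""

    s_xx: np.ndarray
    s_xy: np.ndarray
    s_yy: np.ndarray
    n: int


def covariance_blocks(x: np.ndarray, y: np.ndarray) -> CovarianceBlocks:
    """Sample (n-1 denominator) covariance blocks of two data matrices."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.ndim == 2 and x.shape[0] == 1:
        x = x.T
    if y.ndim == 2 and y.shape[0] == 1:
        y = y.T
    n, g = x.shape
    ny, p = y.shape
    if n != ny:
        raise DomainError(f"sample counts differ: {n} vs {ny}")
    if n <= max(g, p) + 2:
        raise DomainError(f"need n > max(G,P)+2 samples, got n={n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values in input")
    for name, mat in (("x", x), ("y", y)):
        const = mat.std(axis=0) == 0
        if const.any():
            raise DomainError(f"constant column {int(np.flatnonzero(const)[0])} in {name}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    denom = n - 1
    return CovarianceBlocks(
        s_xx=(xc.T @ xc) / denom,
        s_xy=(xc.T @ yc) / denom,
        s_yy=(yc.T @ yc) / denom,
        n=n,
    )


def _inv_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition with a floor."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < _EIG_FLOOR:
        raise DomainError(
            f"{name} is numerically singular (min eigenvalue {vals.min():.3g}); "
            "remove collinear columns or add a ridge"
        )
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def canonical_correlations(blocks: CovarianceBlocks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlations and weight vectors from covariance blocks.

    Returns ``(r, a, b)`` with r descending in [0, 1] and weight columns
    ``a[:, i]``, ``b[:, i]`` normalised so the canonical variates have
    unit variance; the sign convention makes the first nonzero entry of
    each X-side weight vector positive.
    """
    wx = _inv_sqrt(np.atleast_2d(blocks.s_xx), "s_xx")
    wy = _inv_sqrt(np.atleast_2d(blocks.s_yy), "s_yy")
    k = wx @ np.atleast_2d(blocks.s_xy) @ wy
    u, s, vt = np.linalg.svd(k)
    r = np.clip(s, 0.0, 1.0)
    ncomp = r.size
    a = wx @ u[:, :ncomp]
    b = wy @ vt.T[:, :ncomp]
    for i in range(ncomp):
        nz = np.flatnonzero(np.abs(a[:, i]) > 1e-12)
        if nz.size and a[nz[0], i] < 0:
            a[:, i] *= -1
            b[:, i] *= -1
    return r, a, b


def wilks_lambda_test(
    r: np.ndarray, n: int, g: int, p: int
) -> tuple[float, float, float, float, float]:
    """Wilks' Lambda with Rao's F approximation.

    Lambda = prod(1 - r_i^2); with gp = g*p,
    t = sqrt((g^2 p^2 - 4)/(g^2 + p^2 - 5)) when gp > 2 else 1,
    w = n - (g + p + 3)/2, df1 = gp, df2 = w*t - gp/2 + 1,
    F = ((1 - Lambda^(1/t)) / Lambda^(1/t)) * (df2/df1),
    with the p-value from the upper tail of F(df1, df2).
    """
    if n <= g + p + 1:
        raise DomainError(f"need n > G + P + 1, got n={n}, G={g}, P={p}")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    lam = float(np.prod(1.0 - r**2))
    gp = g * p
    t = np.sqrt((g**2 * p**2 - 4) / (g**2 + p**2 - 5)) if gp > 2 else 1.0
    w = n - (g + p + 3) / 2.0
    df1 = float(gp)
    df2 = w * t - gp / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    f = ((1.0 - lam_t) / lam_t) * (df2 / df1) if lam_t > 0 else np.inf
    pval = float(stats.f.sf(f, df1, df2))
    return lam, float(f), df1, df2, pval


def min_detectable_r(
    n: int, alpha: float = 5e-8, power: float = 0.80, sided: str = "one"
) -> float:
    """Minimum detectable correlation at given sample size, alpha and power.

    Fisher-z approximation: r = tanh((z_{1-alpha} + z_{power}) / sqrt(n-3)),
    with alpha halved for the two-sided variant. Monotone decreasing in n.
    """
    if n <= 3:
        raise DomainError("need n > 3 for the Fisher-z approximation")
    if not (0 < alpha < power < 1):
        raise DomainError("require 0 < alpha < power < 1")
    if sided not in ("one", "two"):
        raise DomainError(f"sided must be 'one' or 'two', got {sided!r}")
    a = alpha / 2 if sided == "two" else alpha
    z = stats.norm.ppf(1 - a) + stats.norm.ppf(power)
    return float(np.tanh(z / np.sqrt(n - 3)))


class SnpCcaResults:
    """Results of a per-SNP canonical correlation scan.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per SNP with columns chrom, pos, rsid, ref, ea, r1,
        wilks_lambda, f_stat, df1, df2, p, p_adj plus per-trait weights.
    """

    def __init__(self, table: pd.DataFrame, n: int, adjust: str, m_tests: int):
        self.table = table
        self.n = n
        self.adjust = adjust
        self.m_tests = m_tests

    @property
    def p_adjusted(self) -> np.ndarray:
        return self.table["p_adj"].to_numpy()

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Rows passing the scan's multiple-testing rule."""
        if self.adjust == "fixed_genomewide":
            return self.table[self.table["p"] < 5e-8]
        return self.table[self.table["p_adj"] < alpha]

    def summary(self, top: int = 10) -> str:
        t = self.table.nsmallest(top, "p")
        lines = [
            "Per-SNP canonical correlation scan",
            f"  SNPs tested:        {len(self.table)}",
            f"  samples:            {self.n}",
            f"  adjustment:         {self.adjust} (m = {self.m_tests})",
            f"  min p:              {self.table['p'].min():.3g}",
            f"  significant (0.05): {len(self.significant())}",
            "",
            t[["chrom", "pos", "rsid", "r1", "f_stat", "p", "p_adj"]].to_string(index=False),
        ]
        return "\n".join(lines)

    def manhattan(self, ax=None):
        """Manhattan plot of -log10 p by genomic position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = self.table.sort_values(["chrom", "pos"], key=lambda s: s.astype(int) if s.name == "chrom" else s)
        x = np.arange(len(t))
        for i, (_, grp) in enumerate(t.groupby("chrom", sort=False)):
            idx = t.index.get_indexer(grp.index)
            ax.scatter(x[idx], -np.log10(grp["p"]), s=4, color=f"C{i % 2}")
        ax.axhline(-np.log10(5e-8), color="red", lw=0.8, ls="--")
        ax.set_xlabel("genomic order")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax


class SnpCcaScan:
    """Per-SNP canonical correlation model for an individual-level cohort.

    X is a single SNP dosage column (G = 1) and Y the standardised
    phenotype block (P = 2, or 3 with the case-status indicator). The
    scan is vectorised over SNPs but contractually identical to the
    naive per-SNP :func:`canonical_correlations` computation.

    Parameters
    ----------
    genotypes
        Post-QC dosage matrix (no missing cells).
    phenotypes
        Standardised phenotype block aligned on the same samples.
    """

    def __init__(self, genotypes: GenotypeMatrix, phenotypes: PhenotypeMatrix):
        if genotypes.samples != phenotypes.samples:
            raise DomainError("genotype and phenotype sample sets differ or are misordered")
        if genotypes.has_missing():
            raise DomainError("CCA cannot handle missing dosages; run QC first")
        self.genotypes = genotypes
        self.phenotypes = phenotypes

    @classmethod
    def from_files(cls, vcf_path, pheno_path, include_status_in_y: bool = False) -> "SnpCcaScan":
        """Build the model from a VCF and a phenotype TSV.

        The phenotype TSV needs columns sample_id, egfr, urea, status;
        samples are intersected and aligned on the VCF order.
        """
        from .io import read_genotypes_vcf
        from .qc import build_phenotype_matrix

        g = read_genotypes_vcf(vcf_path)
        ph = pd.read_csv(pheno_path, sep="\t", dtype={"sample_id": str})
        ph = ph.set_index("sample_id")
        keep = [s for s in g.samples if s in ph.index]
        g = g.subset_samples(keep)
        ph = ph.loc[keep]
        y = build_phenotype_matrix(
            ph["egfr"].to_numpy(), ph["urea"].to_numpy(), ph["status"].to_numpy(),
            samples=keep, include_status_in_y=include_status_in_y,
        )
        return cls(g, y)

    def fit(self, adjust: str = "fixed_genomewide", m_tests: int | None = None) -> SnpCcaResults:
        """Run the scan and attach multiple-testing-adjusted p-values.

        ``adjust``: ``bonferroni_by_count`` sets p_adj = min(1, p*m)
        judged at 0.05; ``fixed_genomewide`` keeps raw p judged at 5e-8
        (p_adj is then the raw p).
        """
        if adjust not in ("bonferroni_by_count", "fixed_genomewide"):
            raise DomainError(f"unknown adjustment mode {adjust!r}")
        x = self.genotypes.dosage
        y = self.phenotypes.y_block()
        n, m = x.shape
        p_dim = y.shape[1]
        if n <= 1 + p_dim + 1:
            raise DomainError("too few samples for the Wilks test")

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        denom = n - 1
        s_yy = (yc.T @ yc) / denom
        s_yy_inv = np.linalg.inv(s_yy)
        c = (xc.T @ yc) / denom                      # m x P cross-covariances
        s_xx = (xc**2).sum(axis=0) / denom           # per-SNP variance
        if (s_xx == 0).any():
            raise DomainError(
                f"monomorphic SNP at column {int(np.flatnonzero(s_xx == 0)[0])}"
            )
        r2 = np.einsum("ij,jk,ik->i", c, s_yy_inv, c) / s_xx
        r2 = np.clip(r2, 0.0, 1.0)
        r1 = np.sqrt(r2)

        # Rao F for G=1: t=1 (gp = P <= 3 handled below), Lambda = 1 - r1^2
        g_dim = 1
        gp = g_dim * p_dim
        t = np.sqrt((g_dim**2 * p_dim**2 - 4) / (g_dim**2 + p_dim**2 - 5)) if gp > 2 else 1.0
        w = n - (g_dim + p_dim + 3) / 2.0
        df1 = float(gp)
        df2 = w * t - gp / 2.0 + 1.0
        lam = 1.0 - r2
        lam_t = lam ** (1.0 / t)
        with np.errstate(divide="ignore"):
            f = ((1.0 - lam_t) / lam_t) * (df2 / df1)
        pvals = stats.f.sf(f, df1, df2)

        m_eff = m_tests if m_tests is not None else m
        if adjust == "bonferroni_by_count":
            p_adj = np.minimum(1.0, pvals * m_eff)
        else:
            p_adj = pvals.copy()

        # Y-side weights: b proportional to s_yy^-1 c, unit canonical variance
        b_raw = c @ s_yy_inv.T
        table = self.genotypes.variants.copy()
        table["r1"] = r1
        table["wilks_lambda"] = lam
        table["f_stat"] = f
        table["df1"] = df1
        table["df2"] = df2
        table["p"] = pvals
        table["p_adj"] = p_adj
        for j, trait in enumerate(self.phenotypes.trait_names):
            table[f"b_{trait}"] = b_raw[:, j]
        return SnpCcaResults(table=table, n=n, adjust=adjust, m_tests=m_eff)
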