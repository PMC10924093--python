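"""Differential-expression filtering and allele-frequency follow-up.

Differential expression between CKD cases and controls is assessed on
log2 expression with a Welch two-sample test per gene and
Benjamini-Hochberg adjustment; a gene passes only when both gates hold:
|log2 fold change| >= 1 and BH-adjusted p < 0.05.

Allele-frequency follow-up compares a cohort's effect-allele frequency
at a SNP with a general-population reference (gnomAD-style af + allele
number): candidates are shortlisted at a |difference| >= 10%, tested
with a Yates-corrected chi-square on the 2x2 allele-count table, and
flagged significant when the difference exceeds 15% with p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DomainError, GenotypeMatrix

__all__ = [
    "bh_adjust",
    "differential_expression",
    "allele_freq",
    "yates_chi_square",
    "af_comparison",
    "AfComparison",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_expression(
    expr: pd.DataFrame,
    groups,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch test of case vs control log2 expression.

    ``expr`` is gene x sample (already log2); ``groups`` is a
    case/control label per sample column, with 1/"case" marking cases.
    Returns a table with log2fc (case mean - control mean), p, p_adj
    and the ``passes`` flag (both gates).
    """
    labels = np.asarray([1 if g in (1, "1", "case") else 0 for g in groups])
    if labels.size != expr.shape[1]:
        raise DomainError("one group label required per sample column")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise DomainError("need at least two samples per group")
    case = expr.loc[:, labels == 1].to_numpy(dtype=float)
    ctrl = expr.loc[:, labels == 0].to_numpy(dtype=float)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": expr.index,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
        }
    )
    out["passes"] = (np.abs(out["log2fc"]) >= lfc_threshold) & (out["p_adj"] < alpha)
    return out


def allele_freq(
    g: GenotypeMatrix, snp_index: int, subgroup: list[str] | None = None
) -> tuple[float, int]:
    """Effect-allele frequency and allele number at one variant.

    ``subgroup`` restricts to a sample subset (e.g. CKD cases).
    Returns (af, allele_number = 2 * n_samples).
    """
    if not 0 <= snp_index < g.n_variants:
        raise DomainError(f"variant index {snp_index} out of range")
    work = g if subgroup is None else g.subset_samples(list(subgroup))
    if work.n_samples == 0:
        raise DomainError("empty sample subgroup")
    col = work.dosage[:, snp_index]
    if np.isnan(col).any():
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise DomainError("no called genotypes at this variant")
    an = 2 * col.size
    return float(col.sum() / an), an


def yates_chi_square(table2x2) -> tuple[float, float]:
    """Chi-square test with Yates' continuity correction on a 2x2 table.

    chi2 = sum((|O - E| - 0.5)^2 / E), with each term floored at zero
    when |O - E| < 0.5; p from the chi-square distribution with 1 df.
    """
    obs = np.asarray(table2x2, dtype=float)
    if obs.shape != (2, 2):
        raise DomainError("a 2x2 table is required")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise DomainError("all table marginals must be positive")
    expected = np.outer(row, col) / obs.sum()
    diff = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class AfComparison:
    cohort_af: float
    cohort_an: int
    reference_af: float
    reference_an: int
    af_diff: float
    shortlisted: bool
    chi2_yates: float | None
    p: float | None
    significant: bool


def af_comparison(
    cohort: tuple[float, int],
    reference: tuple[float, int],
    shortlist_diff: float = 0.10,
    report_diff: float = 0.15,
) -> AfComparison:
    """Compare a cohort allele frequency against a population reference.

    Shortlisting (|diff| >= ``shortlist_diff``) gates the chi-square
    test; significance additionally requires |diff| > ``report_diff``
    and p < 0.05. The contingency unit is allele counts (2n).
    """
    caf, can = float(cohort[0]), int(cohort[1])
    raf, ran = float(reference[0]), int(reference[1])
    if can <= 0 or ran <= 0:
        raise DomainError("allele numbers must be positive")
    diff = caf - raf
    shortlisted = abs(diff) >= shortlist_diff
    chi2 = p = None
    significant = False
    if shortlisted:
        table = [
            [round(caf * can), round((1 - caf) * can)],
            [round(raf * ran), round((1 - raf) * ran)],
        ]
        chi2, p = yates_chi_square(table)
        significant = abs(diff) > report_diff and p < 0.05
    return AfComparison(
        cohort_af=caf, cohort_an=can, reference_af=raf, reference_an=ran,
        af_diff=diff, shortlisted=shortlisted, chi2_yates=chi2, p=p,
        significant=significant,
    )
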