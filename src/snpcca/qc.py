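"""Genotype QC, ancestry filtering and phenotype standardisation.

The variant filters mirror standard array-QC practice for a canonical
correlation analysis that cannot tolerate missing cells: minor-allele
frequency, per-variant missingness, an exact Hardy-Weinberg test, and a
final removal of any variant still carrying a missing genotype. Sample
filtering is a Euclidean-radius test in PC1-PC2 space around a
reference ancestry panel. Phenotypes are standardised the way the
kidney-function literature does: eGFR by rank-based inverse-normal
transformation, serum urea converted to blood urea nitrogen (BUN) then
log10 Z-scored.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .containers import AUTOSOMES, DomainError, GenotypeMatrix, PhenotypeMatrix, QcReport

__all__ = [
    "hwe_exact_test",
    "filter_variants_qc",
    "ancestry_filter",
    "transform_bun",
    "rank_inverse_normal",
    "build_phenotype_matrix",
]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, heterozygote counts with
    the same parity are enumerated and the p-value is the summed
    probability of all outcomes no more likely than the observed one
    (the two-sided convention used by standard genotype-QC tools).

    Returns 1.0 for monomorphic sites.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise DomainError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise DomainError("at least one genotyped sample required")
    n_ref = 2 * counts[0] + counts[1]
    n_alt = 2 * counts[2] + counts[1]
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        # P(het | allele counts) under HWE, conditional distribution
        return (
            het * np.log(2)
            + gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(het + 1)
            - gammaln(hom_common + 1)
            - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([log_prob(h) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs = probs[hets == counts[1]][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def filter_variants_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.015,
    hwe_alpha: float = 1e-5,
    drop_any_missing: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the variant QC filters in their fixed order.

    Order: non-autosome, MAF < ``maf_min``, missingness >=
    ``max_missing`` (note the inclusive threshold), exact HWE p <
    ``hwe_alpha``, then (optionally) any remaining missing cell.
    """
    report = QcReport(variants_in=g.n_variants, samples_in=0)
    work = g

    autosomal = work.variants["chrom"].astype(str).isin(AUTOSOMES).to_numpy()
    report.removed_non_autosome = int((~autosomal).sum())
    work = work.subset_variants(autosomal)

    af = work.effect_allele_freq()
    maf = np.minimum(af, 1 - af)
    keep = maf >= maf_min
    report.removed_maf = int((~keep).sum())
    work = work.subset_variants(keep)

    miss_rate = np.isnan(work.dosage).mean(axis=0)
    keep = miss_rate < max_missing
    report.removed_missingness = int((~keep).sum())
    work = work.subset_variants(keep)

    hwe_p = np.empty(work.n_variants)
    for j in range(work.n_variants):
        col = work.dosage[:, j]
        col = col[~np.isnan(col)]
        hwe_p[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    keep = hwe_p >= hwe_alpha
    report.removed_hwe = int((~keep).sum())
    work = work.subset_variants(keep)

    if drop_any_missing:
        keep = ~np.isnan(work.dosage).any(axis=0)
        report.removed_any_missing = int((~keep).sum())
        work = work.subset_variants(keep)

    report.variants_retained = work.n_variants
    report.check_accounting()
    if work.n_variants == 0:
        report.notes.append("no variants survived QC")
    return work, report


def ancestry_filter(
    sample_pcs: np.ndarray,
    reference_pcs: np.ndarray,
    scale: float = 2.0,
    sample_ids: list[str] | None = None,
) -> list:
    """Retain samples within a scaled radius of the reference-panel centre.

    The centre is the mean of the reference PC1-PC2 coordinates and the
    radius is ``scale`` times the maximum reference distance from that
    centre; samples at distance <= radius are retained. Any
    ``scale >= 1`` therefore retains every reference point itself.
    """
    if scale <= 0:
        raise DomainError("ancestry scale factor must be positive")
    ref = np.atleast_2d(np.asarray(reference_pcs, dtype=float))
    pts = np.atleast_2d(np.asarray(sample_pcs, dtype=float))
    if ref.shape[0] < 1 or ref.shape[1] != 2 or pts.shape[1] != 2:
        raise DomainError("PC coordinates must be 2-D with at least one reference point")
    center = ref.mean(axis=0)
    radius = scale * np.linalg.norm(ref - center, axis=1).max()
    dist = np.linalg.norm(pts - center, axis=1)
    keep = dist <= radius
    ids = sample_ids if sample_ids is not None else list(range(len(pts)))
    return [s for s, k in zip(ids, keep) if k]


def transform_bun(urea: np.ndarray, urea_to_bun_divisor: float = 2.14) -> np.ndarray:
    """Serum urea (mmol/L) -> BUN -> log10 -> Z-score (n-1 SD).

    The conversion divisor reflects the molecular-weight ratio between
    urea and its nitrogen content; it is configurable because reported
    conventions vary slightly.
    """
    urea = np.asarray(urea, dtype=float)
    if urea.size < 2:
        raise DomainError("need at least two urea values")
    if (urea <= 0).any():
        raise DomainError("urea values must be positive")
    logbun = np.log10(urea / urea_to_bun_divisor)
    sd = logbun.std(ddof=1)
    if sd == 0:
        raise DomainError("urea values are constant; Z-score undefined")
    return (logbun - logbun.mean()) / sd


def rank_inverse_normal(values: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal transformation (Blom offset).

    Ties receive average ranks r; the output is the standard-normal
    quantile of (r - offset) / (n + 1 - 2*offset). Strictly monotone in
    the input for untied values.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise DomainError("need at least two values for rank transformation")
    if np.ptp(values) == 0:
        raise DomainError("values are constant; rank transformation undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def build_phenotype_matrix(
    egfr: np.ndarray,
    urea: np.ndarray,
    case_flags: np.ndarray,
    samples: list[str] | None = None,
    include_status_in_y: bool = False,
    urea_to_bun_divisor: float = 2.14,
) -> PhenotypeMatrix:
    """Assemble the standardised phenotype block for the CCA Y side.

    Both phenotype measurements are assumed to have been taken on the
    same date per sample; enforcing that is the caller's responsibility.
    """
    egfr = np.asarray(egfr, dtype=float)
    urea = np.asarray(urea, dtype=float)
    case_flags = np.asarray(case_flags, dtype=float)
    if not (len(egfr) == len(urea) == len(case_flags)):
        raise DomainError("egfr, urea and case_flags must have equal lengths")
    if samples is None:
        samples = [f"S{i}" for i in range(len(egfr))]
    return PhenotypeMatrix(
        samples=list(samples),
        egfr_std=rank_inverse_normal(egfr),
        bun_std=transform_bun(urea, urea_to_bun_divisor),
        case_indicator=case_flags,
        include_status_in_y=include_status_in_y,
    )
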