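"""Core in-memory containers shared across the pipeline.

Variant tables are plain :class:`pandas.DataFrame` objects with a fixed
column contract (see :data:`VARIANT_COLUMNS`); genotype and phenotype
blocks are thin dataclasses wrapping numpy arrays so the numerical code
can stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AUTOSOMES",
    "VARIANT_COLUMNS",
    "DomainError",
    "FormatError",
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "QcReport",
    "variant_ids",
]

#: Chromosome labels accepted anywhere in the pipeline (autosomes only).
AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Identity columns every variant-keyed table carries, in order.
VARIANT_COLUMNS = ["chrom", "pos", "rsid", "ref", "ea"]

_VALID_BASES = frozenset("ACGT")


class DomainError(ValueError):
    """An input violates a documented precondition."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def variant_ids(df: pd.DataFrame) -> pd.Series:
    """``chrom:pos:ref:ea`` key strings for a variant-keyed frame."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"]
        + ":"
        + df["ea"]
    )


def validate_variant_frame(df: pd.DataFrame) -> None:
    """Check the variant identity-column contract.

    Raises :class:`DomainError` on non-autosomal chromosomes, non-ACGT
    single-base alleles, or ref == effect allele.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table lacks columns: {missing}")
    bad_chrom = set(df["chrom"].astype(str)) - AUTOSOMES
    if bad_chrom:
        raise DomainError(f"non-autosomal chromosomes present: {sorted(bad_chrom)}")
    for col in ("ref", "ea"):
        bad = ~df[col].isin(_VALID_BASES)
        if bad.any():
            raise DomainError(f"non-ACGT {col} allele at row {int(np.flatnonzero(bad)[0])}")
    same = df["ref"] == df["ea"]
    if same.any():
        raise DomainError(f"ref == effect allele at row {int(np.flatnonzero(same)[0])}")


@dataclass
class GenotypeMatrix:
    """Sample-by-variant effect-allele dosage matrix.

    Parameters
    ----------
    samples
        Ordered sample identifiers, length ``n``.
    variants
        Variant metadata frame with :data:`VARIANT_COLUMNS`, one row per
        variant, aligned with the columns of ``dosage``.
    dosage
        ``n x m`` float array of effect-allele counts; entries are
        0/1/2, with ``nan`` marking missing genotypes (only permitted
        before QC).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise DomainError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosage).any())

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(samples=list(keep), variants=self.variants.copy(), dosage=self.dosage[rows])


@dataclass
class PhenotypeMatrix:
    """Standardised kidney-function phenotype block.

    ``egfr_std`` is the rank-based inverse-normal transform of eGFR,
    ``bun_std`` the log10 Z-score of BUN, and ``case_indicator`` a 0/1
    chronic-kidney-disease status flag that may optionally be appended
    to the Y block of the canonical correlation.
    """

    samples: list[str]
    egfr_std: np.ndarray
    bun_std: np.ndarray
    case_indicator: np.ndarray
    include_status_in_y: bool = False

    def __post_init__(self) -> None:
        n = len(self.samples)
        for name in ("egfr_std", "bun_std", "case_indicator"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise DomainError(f"{name} length {arr.shape} != {n} samples")
            setattr(self, name, arr)

    def y_block(self) -> np.ndarray:
        """Phenotype matrix fed to the CCA Y side (n x 2, or n x 3 with status)."""
        cols = [self.egfr_std, self.bun_std]
        if self.include_status_in_y:
            cols.append(self.case_indicator)
        return np.column_stack(cols)

    @property
    def trait_names(self) -> list[str]:
        names = ["egfr", "bun"]
        if self.include_status_in_y:
            names.append("status")
        return names


@dataclass
class QcReport:
    """Per-filter removal counts for one QC pass.

    Satisfies the accounting identity removed + retained == input on
    each axis.
    """

    variants_in: int = 0
    removed_non_autosome: int = 0
    removed_maf: int = 0
    removed_missingness: int = 0
    removed_hwe: int = 0
    removed_any_missing: int = 0
    variants_retained: int = 0
    samples_in: int = 0
    removed_ancestry: int = 0
    removed_manual: int = 0
    samples_retained: int = 0
    notes: list[str] = field(default_factory=list)

    def variant_removals(self) -> int:
        return (
            self.removed_non_autosome
            + self.removed_maf
            + self.removed_missingness
            + self.removed_hwe
            + self.removed_any_missing
        )

    def check_accounting(self) -> None:
        if self.variants_in != self.variant_removals() + self.variants_retained:
            raise DomainError("variant QC accounting identity violated")
        if self.samples_in and self.samples_in != (
            self.removed_ancestry + self.removed_manual + self.samples_retained
        ):
            raise DomainError("sample QC accounting identity violated")

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "variants_in",
                "removed_non_autosome",
                "removed_maf",
                "removed_missingness",
                "removed_hwe",
                "removed_any_missing",
                "variants_retained",
                "samples_in",
                "removed_ancestry",
                "removed_manual",
                "samples_retained",
            )
        }
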