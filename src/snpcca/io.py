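"""Readers and writers for the file formats the pipeline touches.

Summary-statistics tables arrive in consortium-specific TSV dialects
(CKDGen-style, OpenGWAS-style, or the package's own generic header);
all are normalised into one internal per-trait schema::

    chrom  pos  rsid  ref  ea  af  beta  se  p  n

Genotypes come from VCF (GT fields only), gene intervals from BED, and
every tabular result is written back as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AUTOSOMES,
    FormatError,
    GenotypeMatrix,
    variant_ids,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DIALECTS",
    "read_summary_stats",
    "merge_trait_tables",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_gene_intervals_bed",
    "write_results_table",
    "read_results_table",
]

#: Column maps from each supported dialect onto the internal schema.
DIALECTS: dict[str, dict[str, str]] = {
    "ckdgen": {
        "Chr": "chrom",
        "Pos_b37": "pos",
        "RSID": "rsid",
        "Allele1": "ea",
        "Allele2": "ref",
        "Freq1": "af",
        "Effect": "beta",
        "StdErr": "se",
        "P-value": "p",
        "n": "n",
    },
    "opengwas": {
        "chr": "chrom",
        "pos": "pos",
        "rsid": "rsid",
        "ea": "ea",
        "nea": "ref",
        "eaf": "af",
        "beta": "beta",
        "se": "se",
        "p": "p",
        "n": "n",
    },
    "generic": {
        "chr": "chrom",
        "pos": "pos",
        "rsid": "rsid",
        "ref": "ref",
        "alt": "ea",
        "beta": "beta",
        "se": "se",
        "n": "n",
        "af": "af",
        "p": "p",
    },
}

#: Columns a dialect may omit; everything else is mandatory.
_OPTIONAL = {"generic": {"p"}, "ckdgen": set(), "opengwas": set()}

INTERNAL_COLUMNS = ["chrom", "pos", "rsid", "ref", "ea", "af", "beta", "se", "p", "n"]


def read_summary_stats(path: str | Path, dialect: str = "generic") -> pd.DataFrame:
    """Load a per-SNP, single-trait GWAS summary-statistics TSV.

    Chromosome labels are normalised (a leading ``chr`` is stripped) and
    rows on non-autosomal chromosomes are dropped with a logged count.
    When the dialect carries no p-value column, a two-sided normal
    p-value is derived from beta/se.

    Raises
    ------
    FormatError
        If a mandatory column is missing or a numeric cell fails to
        parse (the error names the offending 1-based data row).
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown summary-stats dialect: {dialect!r}")
    colmap = DIALECTS[dialect]
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap if c not in raw.columns and colmap[c] not in _OPTIONAL[dialect]]
    if missing:
        raise FormatError(f"{path}: dialect {dialect!r} requires missing column(s) {missing}")
    df = raw.rename(columns=colmap)[[c for c in INTERNAL_COLUMNS if c in raw.rename(columns=colmap).columns]]

    for col in ("pos", "af", "beta", "se", "p", "n"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: unparseable numeric value in column {col!r} at data row {row}")
        df[col] = parsed
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(float).round().astype(int)
    for col in ("ref", "ea"):
        df[col] = df[col].str.upper()

    df["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    autosomal = df["chrom"].isin(AUTOSOMES)
    n_dropped = int((~autosomal).sum())
    if n_dropped:
        logger.info("read_summary_stats: dropped %d non-autosomal row(s)", n_dropped)
    df = df.loc[autosomal].reset_index(drop=True)

    if "p" not in df.columns:
        from scipy import stats

        z = df["beta"] / df["se"]
        df["p"] = 2.0 * stats.norm.sf(np.abs(z))
    return df[INTERNAL_COLUMNS]


def merge_trait_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join single-trait tables on the variant key into one wide table.

    The result has the identity columns plus ``af`` (from the first
    trait) and per-trait ``beta_<t>``, ``se_<t>``, ``p_<t>``, ``n_<t>``
    columns. Only variants present in every trait (exact chrom, pos,
    ref, effect-allele match) are retained.
    """
    if not tables:
        raise FormatError("no trait tables supplied")
    keys = ["chrom", "pos", "ref", "ea"]
    wide = None
    for trait, df in tables.items():
        part = df.rename(
            columns={"beta": f"beta_{trait}", "se": f"se_{trait}", "p": f"p_{trait}", "n": f"n_{trait}"}
        )
        if wide is None:
            wide = part
        else:
            part = part.drop(columns=["rsid", "af"])
            wide = wide.merge(part, on=keys, how="inner")
    return wide.reset_index(drop=True)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix.

    Dosage is the per-sample ALT-allele count (0/1/2); missing GTs are
    stored as ``nan``. Multi-allelic and non-SNP records are skipped
    with a logged count, as are non-autosomal records.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[dict] = []
    dosages: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        chrom = rec.CHROM.removeprefix("chr")
        if (
            chrom not in AUTOSOMES
            or len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.REF not in "ACGT"
            or rec.ALT[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        gts = np.array(rec.genotypes, dtype=object)
        dose = np.empty(len(samples), dtype=float)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            dose[i] = np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0))
        rows.append(
            {"chrom": chrom, "pos": rec.POS, "rsid": rec.ID or ".", "ref": rec.REF, "ea": rec.ALT[0]}
        )
        dosages.append(dose)
    if n_skipped:
        logger.info("read_genotypes_vcf: skipped %d non-biallelic-SNP/non-autosomal record(s)", n_skipped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "ref", "ea"])
    dosage = np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    g = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage matrix as a minimal GT-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted({str(c) for c in g.variants["chrom"]}, key=int):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in g.variants.iterrows():
            gts = "\t".join(
                "./." if np.isnan(d) else code[d] for d in g.dosage[:, j]
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.ea}\t.\tPASS\t.\tGT\t{gts}\n")


def read_gene_intervals_bed(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) into 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "symbol"], usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True)
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV (12 significant digits for floats).

    Round-trips bit-exactly for string columns and to 12 significant
    digits for numerics via :func:`read_results_table`.
    """
    if results.columns.empty:
        raise FormatError("refusing to write a table with no columns")
    parent = Path(path).parent
    if not parent.exists():
        raise IOError(f"directory does not exist: {parent}")
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def summary_stats_ids(df: pd.DataFrame) -> pd.Series:
    """Variant key strings for any variant-keyed table (convenience re-export)."""
    return variant_ids(df)
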