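"""Significance thresholding, direction filtering, cross-dataset
harmonisation/replication, and lead-SNP clumping with nearest-gene
annotation.

The clumping procedure follows the FUMA SNP2GENE convention: greedy by
ascending p-value, significant SNPs with pairwise LD r-squared below
0.6 to every previously chosen SNP become *independent significant*
SNPs; among those, r-squared below 0.1 defines *lead* SNPs; loci are
the intervals spanned by each lead's dependents, merged when closer
than 250 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DomainError, GenotypeMatrix, variant_ids

__all__ = [
    "significance_filter",
    "opposite_direction_filter",
    "harmonize_across_datasets",
    "replicate_nominal",
    "ld_r2_from_panel",
    "clump_lead_snps",
    "nearest_gene",
    "Locus",
    "LocusSet",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def significance_filter(
    results: pd.DataFrame, mode: str = "fixed_genomewide", alpha: float = 0.05
) -> pd.DataFrame:
    """Keep rows passing the scan-wide significance rule.

    ``bonferroni_by_count`` keeps p < alpha / m (m = table length);
    ``fixed_genomewide`` keeps p < 5e-8.
    """
    if results.empty:
        raise DomainError("significance_filter requires a non-empty results table")
    if mode == "bonferroni_by_count":
        thr = alpha / len(results)
    elif mode == "fixed_genomewide":
        thr = 5e-8
    else:
        raise DomainError(f"unknown significance mode {mode!r}")
    return results[results["p"] < thr].reset_index(drop=True)


def opposite_direction_filter(
    stats: pd.DataFrame, beta_cols: tuple[str, str] = ("beta_egfr", "beta_bun")
) -> pd.DataFrame:
    """Retain SNPs whose two trait effects point in opposite directions.

    For kidney function, a variant raising eGFR should lower BUN (and
    vice versa) with respect to the same effect allele; rows with
    same-sign or zero effects are excluded.
    """
    a, b = (stats[c].to_numpy(dtype=float) for c in beta_cols)
    return stats[(a * b) < 0].reset_index(drop=True)


def harmonize_across_datasets(
    a: pd.DataFrame, b: pd.DataFrame, allow_swap: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Join two variant tables on (chrom, pos, ref, ea), resolving flips.

    Exact allele matches join unchanged; with ``allow_swap``, sites
    where b's ref/effect alleles are swapped relative to a join with
    b's beta columns sign-flipped and AF complemented. Strand-ambiguous
    A/T and C/G sites never join via swap. Column names from b are
    suffixed ``_b``. Returns (matched table, report).
    """
    keys = ["chrom", "pos", "ref", "ea"]
    exact = a.merge(b, on=keys, how="inner", suffixes=("", "_b"))
    report = {"exact": len(exact)}
    pieces = [exact]
    if allow_swap:
        matched_a = set(variant_ids(exact))
        rest_a = a[~variant_ids(a).isin(matched_a)]
        b_sw = b.rename(columns={"ref": "ea", "ea": "ref"})
        ambiguous = [tuple(x) for x in b_sw[["ref", "ea"]].itertuples(index=False)]
        b_sw = b_sw[[t not in _AMBIGUOUS for t in ambiguous]]
        swap = rest_a.merge(b_sw, on=keys, how="inner", suffixes=("", "_b"))
        for col in swap.columns:
            if col.startswith("beta") and col.endswith("_b"):
                swap[col] = -swap[col]
            if col in ("af_b",):
                swap[col] = 1 - swap[col]
        report["swapped"] = len(swap)
        pieces.append(swap)
    out = pd.concat(pieces, ignore_index=True)
    report["unmatched_a"] = len(a) - len(out)
    report["unmatched_b"] = len(b) - len(out)
    return out, report


def replicate_nominal(
    candidates: pd.DataFrame,
    cohort_results: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep candidates with p < alpha in every cohort's results.

    A candidate absent from any cohort table cannot replicate; it is
    dropped and listed in the second return value (untestable ids).
    """
    ids = variant_ids(candidates)
    keep = np.ones(len(candidates), dtype=bool)
    untestable: list[str] = []
    for name, table in cohort_results.items():
        lookup = dict(zip(variant_ids(table), table["p"]))
        for i, vid in enumerate(ids):
            p = lookup.get(vid)
            if p is None:
                if keep[i]:
                    untestable.append(vid)
                keep[i] = False
            elif p >= alpha:
                keep[i] = False
    return candidates[keep].reset_index(drop=True), untestable


def ld_r2_from_panel(panel: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise dosage r-squared from a genotype panel (dense, small panels)."""
    x = panel.dosage
    if np.isnan(x).any():
        raise DomainError("LD panel must not contain missing dosages")
    r = np.corrcoef(x, rowvar=False)
    ids = variant_ids(panel.variants)
    return pd.DataFrame(r**2, index=ids, columns=ids)


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    lead: str
    lead_p: float
    independent: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)
    nearest_gene: str = ""


@dataclass
class LocusSet:
    loci: list[Locus]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": l.chrom, "start": l.start, "end": l.end,
                    "lead": l.lead, "lead_p": l.lead_p,
                    "n_independent": len(l.independent), "n_members": len(l.members),
                    "nearest_gene": l.nearest_gene,
                }
                for l in self.loci
            ]
        )


def _pair_r2(ld: pd.DataFrame, pos: dict[str, int], chrom: dict[str, str],
             a: str, b: str, window_bp: int) -> float:
    # Cross-chromosome or beyond-window pairs are taken as unlinked.
    if chrom[a] != chrom[b] or abs(pos[a] - pos[b]) > window_bp:
        return 0.0
    try:
        return float(ld.loc[a, b])
    except KeyError:
        raise DomainError(f"LD r2 missing for pair ({a}, {b})") from None


def clump_lead_snps(
    sig: pd.DataFrame,
    ld: pd.DataFrame | GenotypeMatrix,
    r2_indep: float = 0.6,
    r2_lead: float = 0.1,
    merge_kb: float = 250,
    window_bp: int = 1_000_000,
) -> LocusSet:
    """Greedy lead-SNP clumping of a significant-SNP table.

    ``sig`` needs chrom, pos, ref, ea, p columns; ``ld`` is either a
    dense r-squared DataFrame indexed by variant id or a genotype panel
    to compute it from. Every significant SNP ends up in exactly one
    locus; ties on p break by (chrom, pos).
    """
    if isinstance(ld, GenotypeMatrix):
        ld = ld_r2_from_panel(ld)
    sig = sig.copy().reset_index(drop=True)
    sig["_vid"] = variant_ids(sig)
    pos = dict(zip(sig["_vid"], sig["pos"].astype(int)))
    chrom = dict(zip(sig["_vid"], sig["chrom"].astype(str)))
    order = sig.sort_values(["p", "chrom", "pos"], kind="mergesort")

    independent: list[str] = []
    assigned_to_indep: dict[str, str] = {}
    for _, row in order.iterrows():
        vid = row["_vid"]
        linked = [
            i for i in independent
            if _pair_r2(ld, pos, chrom, vid, i, window_bp) >= r2_indep
        ]
        if linked:
            assigned_to_indep[vid] = linked[0]  # best-p independent SNP
        else:
            independent.append(vid)
            assigned_to_indep[vid] = vid

    pmap = dict(zip(sig["_vid"], sig["p"]))
    leads: list[str] = []
    indep_to_lead: dict[str, str] = {}
    for vid in independent:  # already in ascending-p order
        linked = [l for l in leads if _pair_r2(ld, pos, chrom, vid, l, window_bp) >= r2_lead]
        if linked:
            indep_to_lead[vid] = linked[0]
        else:
            leads.append(vid)
            indep_to_lead[vid] = vid

    loci: list[Locus] = []
    for lead in leads:
        members = [v for v in sig["_vid"] if indep_to_lead[assigned_to_indep[v]] == lead]
        indeps = [v for v in independent if indep_to_lead[v] == lead]
        positions = [pos[v] for v in members]
        loci.append(
            Locus(
                chrom=chrom[lead], start=min(positions), end=max(positions),
                lead=lead, lead_p=float(pmap[lead]),
                independent=indeps, members=members,
            )
        )
    loci.sort(key=lambda l: (int(l.chrom), l.start))

    merged: list[Locus] = []
    for loc in loci:
        if merged and merged[-1].chrom == loc.chrom and loc.start - merged[-1].end <= merge_kb * 1000:
            prev = merged[-1]
            best = prev if prev.lead_p <= loc.lead_p else loc
            merged[-1] = Locus(
                chrom=prev.chrom, start=min(prev.start, loc.start), end=max(prev.end, loc.end),
                lead=best.lead, lead_p=best.lead_p,
                independent=prev.independent + loc.independent,
                members=prev.members + loc.members,
            )
        else:
            merged.append(loc)
    return LocusSet(loci=merged)


def nearest_gene(leads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each lead SNP with the closest gene on its chromosome.

    ``genes`` uses 1-based inclusive intervals (chrom, start, end,
    symbol). Distance is 0 inside a gene body; ties break by the
    smaller interval, then the lexicographically smaller symbol. A
    chromosome with no genes annotates as ``"none"``.
    """
    out = leads.copy()
    symbols, distances = [], []
    for _, row in leads.iterrows():
        cands = genes[genes["chrom"].astype(str) == str(row["chrom"])]
        if cands.empty:
            symbols.append("none")
            distances.append(np.nan)
            continue
        p = int(row["pos"])
        dist = np.where(
            (cands["start"] <= p) & (p <= cands["end"]), 0,
            np.minimum(np.abs(cands["start"] - p), np.abs(cands["end"] - p)),
        )
        width = (cands["end"] - cands["start"]).to_numpy()
        ranked = sorted(zip(dist, width, cands["symbol"]))
        symbols.append(ranked[0][2])
        distances.append(int(ranked[0][0]))
    out["nearest_gene"] = symbols
    out["gene_distance"] = distances
    return out
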