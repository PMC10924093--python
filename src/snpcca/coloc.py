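r"""Bayesian colocalisation of a GWAS region with an eQTL region.

For each SNP, the evidence for association is summarised by a
Wakefield approximate Bayes factor

.. math::

    \log \mathrm{ABF} = \tfrac12 \log(1 - r) + \tfrac12 z^2 r,
    \qquad r = \frac{W}{W + V},

with z = beta / sqrt(varbeta), V = varbeta and W the prior effect
variance (prior SD 0.15 for quantitative traits). Five hypotheses are
weighed for a region: H0 no association with either trait; H1/H2
association with one trait only; H3 both traits, distinct causal
variants; H4 both traits, one shared causal variant. Prior
probabilities per SNP: p1 = p2 = 1e-4 (single-trait causal), p12 =
1e-6 (shared causal). Posterior probabilities PP0-PP4 normalise to 1;
a region is declared colocalised when PP4 exceeds 0.8. All Bayes
factor accumulation happens in log space (regions with |z| > 30 would
overflow otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "RegionStats",
    "ColocResult",
    "extract_region",
    "wakefield_log_abf",
    "coloc_abf",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class RegionStats:
    """Per-SNP association statistics for one genomic window.

    ``table`` columns: chrom, pos, ref, ea (plus optional rsid), beta,
    varbeta (= se^2, > 0), n; optional af.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["varbeta"] <= 0).any():
            raise DomainError("varbeta must be positive for every SNP")
        if t["chrom"].astype(str).nunique() > 1:
            raise DomainError("a region must lie on a single chromosome")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def snp_ids(self) -> pd.Series:
        t = self.table
        return t["chrom"].astype(str) + ":" + t["pos"].astype(str) + ":" + t["ref"] + ":" + t["ea"]


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one region pair."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps_tested: int
    pp4_threshold: float = 0.8

    @property
    def colocalised(self) -> bool:
        return self.pp4 > self.pp4_threshold

    def as_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4,
            "n_snps_tested": self.n_snps_tested, "colocalised": self.colocalised,
        }


def extract_region(
    lead: dict | pd.Series, stats: pd.DataFrame, window_bp: int = 200_000
) -> RegionStats:
    """SNPs within ``window_bp`` (inclusive) of the lead position.

    ``stats`` needs chrom, pos, ref, ea, beta, se, n columns; varbeta
    is derived as se^2.
    """
    chrom = str(lead["chrom"])
    pos = int(lead["pos"])
    sub = stats[
        (stats["chrom"].astype(str) == chrom)
        & ((stats["pos"] - pos).abs() <= window_bp)
    ].copy()
    key = (
        (stats["chrom"].astype(str) == chrom) & (stats["pos"] == pos)
        & (stats["ref"] == lead["ref"]) & (stats["ea"] == lead["ea"])
    )
    if not key.any():
        raise DomainError(f"lead SNP {chrom}:{pos} not present in the statistics table")
    if len(sub) == 1:
        logger.warning("region around %s:%d contains only the lead SNP; colocalisation is under-powered", chrom, pos)
    if "varbeta" not in sub.columns:
        sub["varbeta"] = sub["se"] ** 2
    return RegionStats(table=sub)


def wakefield_log_abf(beta, varbeta, prior_sd: float = 0.15):
    """Wakefield log approximate Bayes factor for one association."""
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if (varbeta <= 0).any():
        raise DomainError("varbeta must be positive")
    w = prior_sd**2
    r = w / (w + varbeta)
    z2 = beta**2 / varbeta
    out = 0.5 * np.log1p(-r) + 0.5 * z2 * r
    return out if out.ndim else float(out)


def coloc_abf(
    region1: RegionStats,
    region2: RegionStats,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-6,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    pp4_threshold: float = 0.8,
) -> ColocResult:
    """Approximate-Bayes-factor colocalisation of two regions.

    Regions are intersected on the variant key; allele-swapped matches
    are accepted (beta sign is irrelevant, only z^2 enters the ABF)
    except at strand-ambiguous A/T / C/G sites, which are dropped.
    """
    t1 = region1.table.copy()
    t2 = region2.table.copy()
    t1["_vid"] = region1.snp_ids()
    t2["_vid"] = region2.snp_ids()
    sw = t2.copy()
    sw["ref"], sw["ea"] = t2["ea"], t2["ref"]
    ambiguous = [(r, e) in _AMBIGUOUS for r, e in zip(sw["ref"], sw["ea"])]
    sw = sw[~np.asarray(ambiguous)]
    sw["_vid"] = sw["chrom"].astype(str) + ":" + sw["pos"].astype(str) + ":" + sw["ref"] + ":" + sw["ea"]
    t2_all = pd.concat([t2, sw]).drop_duplicates("_vid")
    merged = t1.merge(t2_all[["_vid", "beta", "varbeta"]], on="_vid", suffixes=("_1", "_2"))
    if merged.empty:
        raise DomainError("no shared SNPs between the two regions")

    l1 = wakefield_log_abf(merged["beta_1"].to_numpy(), merged["varbeta_1"].to_numpy(), prior_sd1)
    l2 = wakefield_log_abf(merged["beta_2"].to_numpy(), merged["varbeta_2"].to_numpy(), prior_sd2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # H3 sums over distinct SNP pairs: sum_i sum_{j != i} BF1_i BF2_j,
    # computed as log(exp(lsum1+lsum2) - exp(lsum12)) without leaving
    # log space; the difference underflows to "no distinct pairs" when
    # one shared SNP utterly dominates both regions
    gap = lsum12 - (lsum1 + lsum2)
    if gap >= -1e-15:
        lh3_pairs = -np.inf
    else:
        lh3_pairs = lsum1 + lsum2 + np.log1p(-np.exp(gap))

    lw = np.array([
        0.0,
        np.log(p1) + lsum1,
        np.log(p2) + lsum2,
        np.log(p1) + np.log(p2) + lh3_pairs,
        np.log(p12) + lsum12,
    ])
    pps = np.exp(lw - logsumexp(lw))
    pps /= pps.sum()
    return ColocResult(
        pp0=float(pps[0]), pp1=float(pps[1]), pp2=float(pps[2]),
        pp3=float(pps[3]), pp4=float(pps[4]),
        n_snps_tested=len(merged), pp4_threshold=pp4_threshold,
    )
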