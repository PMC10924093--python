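"""Overlap enrichment between SNP discovery sets.

Under independence, the expected overlap of sets of sizes n1, n2 drawn
from a universe of N SNPs is n1*n2/N (and n1*n2*n3/N^2 for a triple);
fold enrichment is observed/expected. Significance for a pairwise
overlap is the hypergeometric upper tail P(X >= observed); the triple
case uses a Poisson upper tail at the independence mean, a declared
approximation since the exact triple-intersection null has no standard
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import DomainError

__all__ = ["OverlapResult", "expected_overlap", "overlap_test"]


@dataclass
class OverlapResult:
    universe_n: int
    set_sizes: tuple[int, ...]
    degree: int
    observed: int
    expected: float
    fold: float
    p: float
    method: str

    def as_dict(self) -> dict:
        return {
            "universe_n": self.universe_n, "set_sizes": list(self.set_sizes),
            "degree": self.degree, "observed": self.observed,
            "expected": self.expected, "fold": self.fold, "p": self.p,
            "method": self.method,
        }


def expected_overlap(set_sizes, universe_n: int) -> float:
    """Expected intersection size of independent sets in a finite universe."""
    sizes = [int(s) for s in set_sizes]
    if universe_n <= 0:
        raise DomainError("universe size must be positive")
    if any(s > universe_n for s in sizes):
        raise DomainError("a set cannot exceed the universe")
    if len(sizes) == 2:
        return sizes[0] * sizes[1] / universe_n
    if len(sizes) == 3:
        return sizes[0] * sizes[1] * sizes[2] / universe_n**2
    raise DomainError(f"only degree 2 or 3 supported, got {len(sizes)} sets")


def overlap_test(observed: int, set_sizes, universe_n: int) -> OverlapResult:
    """Overlap enrichment with expected count, fold, and an upper-tail p.

    Degree 2: exact hypergeometric P(X >= observed). Degree 3: Poisson
    upper tail at the independence mean (approximate, recorded in
    ``method``).
    """
    sizes = tuple(int(s) for s in set_sizes)
    observed = int(observed)
    if observed < 0 or observed > min(sizes):
        raise DomainError("observed overlap must lie in [0, min(set sizes)]")
    expected = expected_overlap(sizes, universe_n)
    if len(sizes) == 2:
        n1, n2 = sizes
        p = float(stats.hypergeom.sf(observed - 1, universe_n, n1, n2))
        method = "hypergeometric"
    else:
        p = float(stats.poisson.sf(observed - 1, expected))
        method = "poisson_approximation"
    fold = observed / expected if expected > 0 else np.nan
    return OverlapResult(
        universe_n=int(universe_n), set_sizes=sizes, degree=len(sizes),
        observed=observed, expected=float(expected), fold=float(fold),
        p=min(1.0, p), method=method,
    )
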