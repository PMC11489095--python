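"""Set-overlap arithmetic and one-sided hypergeometric overlap testing.

Given two hit lists drawn from a common universe of N items, the overlap
k between a list of size K and a list of size n is tested against the
hypergeometric null P[X >= k], X ~ Hypergeom(N, K, n). The tail is summed
in log space so large universes do not underflow. The universe is always an
explicit caller-supplied parameter: overlap p-values are meaningless
without it, so there is no default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Set

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

_TINY = np.nextafter(0.0, 1.0)  # smallest positive float; keeps p in (0, 1]


@dataclass(frozen=True)
class OverlapQuery:
    """Universe size N, set sizes K and n, observed overlap k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        for name in ("N", "K", "n", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.K > self.N:
            raise ValueError(f"K={self.K} exceeds universe N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds universe N={self.N}")
        if self.k > min(self.K, self.n):
            raise ValueError(f"k={self.k} exceeds min(K, n)={min(self.K, self.n)}")


def hypergeom_overlap_logp(query: OverlapQuery) -> float:
    """log P[X >= k] for X ~ Hypergeom(N, K, n); always finite."""
    N, K, n, k = query.N, query.K, query.n, query.k
    if k == 0:
        return 0.0
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:  # pragma: no cover - excluded by invariants
        return -np.inf
    return float(logsumexp(hypergeom.logpmf(support, N, K, n)))


def hypergeom_overlap_p(query: OverlapQuery) -> float:
    """Exact upper-tail overlap probability P[X >= k], in (0, 1].

    Computed via a log-space tail sum; results smaller than the smallest
    positive float are clamped to it (use :func:`hypergeom_overlap_logp`
    when the magnitude matters at that scale).
    """
    p = float(np.exp(hypergeom_overlap_logp(query)))
    return min(1.0, max(p, _TINY))


def venn_decompose(total_a: int, total_b: int, overlap: int) -> tuple:
    """Specific (non-shared) counts for two sets from totals and overlap."""
    if overlap > min(total_a, total_b):
        raise ValueError(
            f"overlap {overlap} exceeds a set total ({total_a}, {total_b})"
        )
    if min(total_a, total_b, overlap) < 0:
        raise ValueError("counts must be non-negative")
    return total_a - overlap, total_b - overlap


def overlap_report(
    list_a: Iterable[str],
    list_b: Iterable[str],
    universe: Iterable[str],
) -> Dict:
    """Deduplicate, test and report the overlap of two id lists.

    Returns the query counts, the one-sided hypergeometric p, the specific
    counts and the sorted shared ids. Ids outside the universe are an error
    (named in the message), as is an empty universe.
    """
    uni: Set[str] = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    a = set(list_a)
    b = set(list_b)
    stray = sorted((a | b) - uni)
    if stray:
        raise ValueError(f"ids outside universe: {stray}")
    shared = a & b
    query = OverlapQuery(N=len(uni), K=len(a), n=len(b), k=len(shared))
    a_specific, b_specific = venn_decompose(len(a), len(b), len(shared))
    return {
        "universe_size": query.N,
        "set_a_size": query.K,
        "set_b_size": query.n,
        "overlap": query.k,
        "a_specific": a_specific,
        "b_specific": b_specific,
        "p_value": hypergeom_overlap_p(query),
        "log_p": hypergeom_overlap_logp(query),
        "shared_ids": sorted(shared),
    }
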