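"""Over-representation analysis (ORA) with exact hypergeometric p-values
and Benjamini–Hochberg FDR control.

For a query gene set of size n drawn from a universe of size N, the
over-representation p-value of a gene set with K members in the universe
and k members in the query is the upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

i.e. the one-sided Fisher's exact test.  The tail is summed exactly in
log space (log-binomials via lgamma, log-sum-exp accumulation), so tiny
p-values do not underflow prematurely.

q-values come from the Benjamini–Hochberg step-up procedure over all
tested sets (those overlapping the query at all); retained results have
q strictly below the configured cut (default 0.01).  The default
enrichment universe is the union of all genes in the loaded collection —
an explicit, reproducible background in the spirit of annotation-based
enrichment tools; the plain overlap count k is used, not the EASE-style
k − 1 deflation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import GeneSetCollection, ValidationError

log = logging.getLogger("netpharm")

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_fdr",
    "enrich",
]


@dataclass
class EnrichmentResult:
    """Per-set ORA outcome (universe-restricted counts)."""

    set_id: str
    set_name: str
    k: int  # |query ∩ set|
    K: int  # |set ∩ universe|
    n: int  # |query ∩ universe|
    N: int  # |universe|
    p_value: float
    fdr: float = math.nan
    retained: bool = False


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    ``K`` successes in a universe of ``N``; ``n`` draws; ``k`` observed
    successes.  Computed by exact summation of the pmf in log space.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if value != int(value) or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {value}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValidationError(f"require K <= N and n <= N, got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValidationError(f"impossible configuration: k={k} > min(K={K}, n={n})")
    if k == 0:
        return 1.0
    # pmf support starts at max(0, n - (N - K)); below that terms vanish.
    lo = max(k, n - (N - K))
    hi = min(K, n)
    if lo > hi:
        return 0.0
    log_denominator = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denominator
        for i in range(lo, hi + 1)
    ]
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return min(1.0, math.exp(total))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving on return.

    q(i) = min over j >= i (in p-sorted order) of m * p(j) / j, clipped to
    [0, 1].  Permutation-equivariant and monotone in the p ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    fdr_max: float | None = 0.01,
) -> list:
    """Rank gene sets by over-representation of ``query``.

    ``universe`` defaults to the union of all genes in ``collection``.
    Query genes outside the universe are dropped (with a logged count).
    One result is produced per set overlapping the query; q-values are BH
    over all tested sets; ``retained`` marks q strictly below ``fdr_max``.
    Results are sorted by ascending p, ties broken by set_id.
    """
    universe_set = frozenset(universe) if universe is not None else collection.all_genes()
    if not universe_set:
        raise ValidationError("enrichment universe is empty")
    query_set = frozenset(query)
    query_in = query_set & universe_set
    n_dropped = len(query_set) - len(query_in)
    if n_dropped:
        log.info("dropped %d query genes outside the universe", n_dropped)
    if not query_in:
        log.warning("empty query after universe restriction; no enrichment computed")
        return []
    n = len(query_in)
    N = len(universe_set)
    results = []
    for gs in collection.sets:
        members = gs.genes & universe_set
        k = len(members & query_in)
        if k == 0:
            continue
        K = len(members)
        p = hypergeometric_tail(k, K, n, N)
        results.append(
            EnrichmentResult(set_id=gs.set_id, set_name=gs.set_name, k=k, K=K, n=n, N=N, p_value=p)
        )
    if not results:
        return []
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.fdr = float(qv)
        r.retained = bool(fdr_max is not None and qv < fdr_max)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results
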