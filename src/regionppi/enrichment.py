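"""Hypergeometric over-representation testing with a custom universe.

The query set (e.g. a region-specific interactome), each gene set (e.g. a
disease-associated gene list) and the universe (e.g. the background brain
interactome's node set) are intersected with the universe before counting,
then the overlap k is tested against Hypergeometric(N, K, m):

    raw_p = P(X ≥ k)   (upper tail, survival function at k − 1)

Raw P-values are Benjamini–Hochberg adjusted across the collection;
adjusted P < 0.05 is flagged significant.

R note: ``phyper(k - 1, m, N - m, K)`` returns the LOWER tail P(X ≤ k − 1)
unless ``lower.tail=FALSE`` is passed; :func:`hypergeom_lower_tail` exposes
that default-tail value for auditing published numbers computed with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_LEVEL = 0.05


def _validate(k: int, m: int, K: int, N: int) -> None:
    if not (0 <= m <= N and 0 <= K <= N):
        raise ValueError(f"require 0 <= m={m}, K={K} <= N={N}")
    if not (0 <= k <= min(m, K)):
        raise ValueError(f"require 0 <= k={k} <= min(m={m}, K={K})")


def hypergeom_upper_tail(k: int, m: int, K: int, N: int) -> float:
    """Exact upper-tail probability P(X ≥ k), X ~ Hypergeometric(N, K, m).

    ``m`` is the query size, ``K`` the gene-set size, ``N`` the universe
    size; equals 1 when k = 0.
    """
    _validate(k, m, K, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, m))


def hypergeom_lower_tail(k: int, m: int, K: int, N: int) -> float:
    """Lower-tail probability P(X ≤ k − 1) = 1 − P(X ≥ k).

    This is what R's ``phyper(k - 1, m, N - m, K)`` returns with its default
    ``lower.tail=TRUE``; kept for reproducing published values computed
    without ``lower.tail=FALSE``.
    """
    _validate(k, m, K, N)
    return float(hypergeom.cdf(k - 1, N, K, m))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted P-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap: query ∩ gene set ∩ universe
    m: int  # query size within universe
    K: int  # gene-set size within universe
    N: int  # universe size
    raw_p: float
    adj_p: float

    @property
    def significant(self) -> bool:
        return self.adj_p < SIGNIFICANCE_LEVEL


def run_enrichment(
    query: set[str],
    collection: Mapping[str, dict] | Mapping[str, set],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Test a query set against every gene set of a collection.

    ``collection`` maps set names either to member sets or to
    ``{"members": set, ...}`` payloads (the GMT reader's shape). All sets
    are intersected with the universe before counting; BH adjustment is
    applied across the whole collection and results are sorted by adjusted
    P, ties broken by set name.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    q = query & universe
    if query and not q:
        import logging

        logging.getLogger(__name__).warning("query does not intersect universe: all tests null")
    names, raw = [], []
    ks, Ks = [], []
    for name, payload in collection.items():
        members = payload["members"] if isinstance(payload, dict) else payload
        gs = set(members) & universe
        k = len(q & gs)
        names.append(name)
        ks.append(k)
        Ks.append(len(gs))
        raw.append(hypergeom_upper_tail(k, len(q), len(gs), len(universe)))
    adj = bh_adjust(raw)
    results = [
        EnrichmentResult(name, k, len(q), K, len(universe), p, ap)
        for name, k, K, p, ap in zip(names, ks, Ks, raw, adj)
    ]
    return sorted(results, key=lambda r: (r.adj_p, r.set_name))
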