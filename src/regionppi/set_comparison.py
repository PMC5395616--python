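"""Interactome set comparison and region-enriched proteome derivation.

Three operations:

- :func:`partition_sets` — split two interactomes into common and
  set-specific parts, with common shares as percentages rounded half-up to
  one decimal (the convention of the published figures);
- :func:`multi_overlap` — exhaustive Venn-region counts for ≥ 2 sets;
- :func:`region_enriched_proteins` — proteins whose abundance in one region
  strictly exceeds ``fold_threshold`` × their median abundance across the
  other regions (default fold 4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal."""
    raw = Decimal(100 * numerator) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SetPartition:
    label_a: str
    label_b: str
    common: frozenset[str]
    specific_a: frozenset[str]
    specific_b: frozenset[str]
    pct_common_a: float
    pct_common_b: float
    pct_specific_a: float
    pct_specific_b: float


def partition_sets(a: set[str], b: set[str], label_a: str = "A", label_b: str = "B") -> SetPartition:
    """Partition two protein sets into common and specific components.

    ``common ∪ specific_a = a`` and ``common ∪ specific_b = b``; the three
    parts are pairwise disjoint. Raises on an empty input (its common share
    would be undefined).
    """
    if not a or not b:
        raise ValueError("partition_sets requires two non-empty sets")
    common = a & b
    return SetPartition(
        label_a=label_a,
        label_b=label_b,
        common=frozenset(common),
        specific_a=frozenset(a - b),
        specific_b=frozenset(b - a),
        pct_common_a=_pct(len(common), len(a)),
        pct_common_b=_pct(len(common), len(b)),
        pct_specific_a=_pct(len(a) - len(common), len(a)),
        pct_specific_b=_pct(len(b) - len(common), len(b)),
    )


def multi_overlap(sets: Mapping[str, set[str]] | Sequence[set[str]]) -> dict[tuple[bool, ...], int]:
    """Count every Venn membership pattern across ≥ 2 sets.

    Keys are boolean membership tuples in the order of the input sets (the
    all-False pattern is omitted); values sum to the size of the union.
    """
    if isinstance(sets, Mapping):
        collection = list(sets.values())
    else:
        collection = list(sets)
    if len(collection) < 2:
        raise ValueError("multi_overlap requires at least two sets")
    counts: dict[tuple[bool, ...], int] = {
        pattern: 0
        for pattern in itertools.product([False, True], repeat=len(collection))
        if any(pattern)
    }
    for protein in set().union(*collection):
        pattern = tuple(protein in s for s in collection)
        counts[pattern] += 1
    return counts


@dataclass(frozen=True)
class RegionEnrichmentRule:
    """Strict fold-over-other-region-median enrichment rule."""

    fold_threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")


def region_enriched_proteins(
    matrix: pd.DataFrame, rule: RegionEnrichmentRule = RegionEnrichmentRule()
) -> dict[str, set[str]]:
    """Derive one region-enriched protein set per abundance-matrix column.

    Protein p is enriched in region r iff
    ``abundance(p, r) > fold_threshold × median(abundance(p, regions ≠ r))``
    — a strict inequality, so a value at exactly the fold boundary does not
    qualify, and a protein may be enriched in more than one region. With an
    all-zero other-region median any positive abundance qualifies; 0 vs 0
    does not. Requires ≥ 3 regions so the other-region median is a real
    summary (with exactly two other regions it is their mean, the standard
    midpoint median).
    """
    if matrix.shape[1] < 3:
        raise ValueError("region enrichment needs at least 3 regions")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    enriched: dict[str, set[str]] = {}
    n_regions = matrix.shape[1]
    for j, region in enumerate(matrix.columns):
        others = np.delete(values, j, axis=1)
        other_median = np.median(others, axis=1)
        mask = values[:, j] > rule.fold_threshold * other_median
        enriched[str(region)] = set(matrix.index[mask])
    assert len(enriched) == n_regions
    return enriched
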