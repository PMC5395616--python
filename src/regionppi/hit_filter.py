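"""Call interactome hits from a paired WT/TG IP-MS detection table.

The bait pulldown is run once in a tagged transgenic (TG) sample and once in
a wild-type (WT) control that captures nonspecific binding. A protein is a
hit if it is detected only in the TG sample, or if it is detected in both
samples and shows clear TG excess on BOTH semi-quantitative readouts:

- count criterion (default ``ratio``): TG sequence count ≥ 2 × WT sequence
  count; the alternative ``difference`` reading (TG ≥ WT + 2) is available
  because the phrasing "two or more sequence counts in the TG sample
  compared to the WT sample" admits either;
- intensity criterion: TG total intensity ≥ 2 × WT total intensity. When
  the WT protein was detected with zero summed intensity, the criterion
  requires a strictly positive TG intensity (any positive value is ≥ 2·0,
  but a 0-vs-0 comparison is no evidence of excess).

Both criteria are inclusive at the boundary ("two or more", "at least
twice").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal

import pandas as pd

CountRule = Literal["ratio", "difference"]

#: branch labels, forming a partition of every valid record
BRANCHES = ("tg_only", "shared_pass", "shared_fail", "wt_only")


@dataclass(frozen=True)
class FilterDecision:
    protein_id: str
    branch: str
    criterion_count_ok: bool
    criterion_intensity_ok: bool

    @property
    def included(self) -> bool:
        return self.branch in ("tg_only", "shared_pass")


@dataclass(frozen=True)
class FilterResult:
    """Hit set plus the per-branch summary used in reports."""

    hits: set[str]
    branch_counts: dict[str, int]
    decisions: list[FilterDecision]


def _count_ok(wt: int, tg: int, rule: CountRule) -> bool:
    if rule == "ratio":
        return tg >= 2 * wt
    if rule == "difference":
        return tg >= wt + 2
    raise ValueError(f"unknown count_rule {rule!r}; expected 'ratio' or 'difference'")


def _intensity_ok(wt_int: float, tg_int: float) -> bool:
    if wt_int == 0:
        return tg_int > 0
    return tg_int >= 2 * wt_int


def classify_detection(
    protein_id: str,
    wt_seq_count: int,
    tg_seq_count: int,
    wt_intensity: float,
    tg_intensity: float,
    count_rule: CountRule = "ratio",
) -> FilterDecision:
    """Assign one detection record to its filter branch.

    Raises ``ValueError`` for a record detected in neither genotype
    (sequence count 0 in both samples).
    """
    if min(wt_seq_count, tg_seq_count, wt_intensity, tg_intensity) < 0:
        raise ValueError(f"{protein_id}: negative count or intensity")
    count_ok = _count_ok(wt_seq_count, tg_seq_count, count_rule)
    intensity_ok = _intensity_ok(wt_intensity, tg_intensity)
    if wt_seq_count == 0 and tg_seq_count == 0:
        raise ValueError(f"{protein_id}: detected in neither genotype")
    if wt_seq_count == 0:
        branch = "tg_only"
    elif tg_seq_count == 0:
        branch = "wt_only"
    elif count_ok and intensity_ok:
        branch = "shared_pass"
    else:
        branch = "shared_fail"
    return FilterDecision(protein_id, branch, count_ok, intensity_ok)


def filter_hits(table: pd.DataFrame, count_rule: CountRule = "ratio") -> FilterResult:
    """Apply the two-branch rule to every record of a detection table.

    Returns the hit set (TG-only ∪ shared-pass) together with branch counts;
    the counts always sum to the table size.
    """
    decisions = [
        classify_detection(
            row.protein_id,
            int(row.wt_seq_count),
            int(row.tg_seq_count),
            float(row.wt_intensity),
            float(row.tg_intensity),
            count_rule=count_rule,
        )
        for row in table.itertuples(index=False)
    ]
    counts = Counter(d.branch for d in decisions)
    hits = {d.protein_id for d in decisions if d.included}
    if not decisions:
        import logging

        logging.getLogger(__name__).warning("empty detection table: no hits called")
    return FilterResult(
        hits=hits,
        branch_counts={b: counts.get(b, 0) for b in BRANCHES},
        decisions=decisions,
    )
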