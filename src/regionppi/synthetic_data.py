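"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a brain-region-specific
bait-interactome experiment:

- a paired WT/TG IP-MS detection table whose composition mirrors the
  published experiment (137 TG-only detections; 259 shared detections of
  which 74 pass both filter criteria, i.e. 185 fail at least one);
- a scale-free background PPI graph by preferential attachment, a 1/10-scale
  stand-in for the published brain interactome (7,880 nodes, 319,756 edges);
- a proteins × brain-regions abundance matrix with planted region-enriched
  proteins (strictly >4-fold over the median of the other regions), at the
  published proteome's proportions (10 regions, roughly a third of proteins
  region-enriched somewhere);
- gene-set collections with planted excess overlap against a query set,
  plus uniform null sets.

Every generator is driven by ``SyntheticSpec.seed`` alone, so identical
specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

PLANTED_CLASS_COLUMN = "planted_class"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_tg_only: int = 137
    n_shared_pass: int = 74
    n_shared_fail: int = 185
    graph_nodes: int = 788
    graph_attach: int = 40
    planted_alpha: float = 2.5
    n_proteins: int = 1000
    n_regions: int = 10
    n_enriched_per_region: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_tg_only",
            "n_shared_pass",
            "n_shared_fail",
            "n_proteins",
            "n_regions",
            "n_enriched_per_region",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.graph_nodes < self.graph_attach + 1:
            raise ValueError(
                f"graph_nodes ({self.graph_nodes}) must be at least graph_attach + 1 "
                f"({self.graph_attach + 1})"
            )
        if self.graph_attach < 1:
            raise ValueError(f"graph_attach must be positive, got {self.graph_attach}")
        if self.planted_alpha <= 1:
            raise ValueError(f"planted_alpha must exceed 1, got {self.planted_alpha}")


def gen_detection_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Paired WT/TG detection table with a hidden planted-class column.

    - ``tg_only`` rows: WT count and intensity 0, TG count ≥ 1;
    - ``shared_pass`` rows: WT count ≥ 1, TG count = 2·WT + jitter (jitter
      ≥ 0, forced ≥ 1 when WT = 1 so the row passes under both the ratio
      and the difference count reading), TG intensity ≥ 2 × WT intensity;
    - ``shared_fail`` rows: both detected, violating exactly one randomly
      chosen criterion (labels defined w.r.t. the default ratio rule).

    Applying the hit filter therefore recovers exactly
    ``n_tg_only + n_shared_pass`` proteins.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []

    def intensity() -> float:
        return float(np.round(rng.lognormal(mean=12.0, sigma=1.0), 2))

    for _ in range(spec.n_tg_only):
        rows.append(
            dict(
                wt_seq_count=0,
                tg_seq_count=int(rng.integers(2, 40)),
                wt_intensity=0.0,
                tg_intensity=intensity(),
                planted_class="tg_only",
            )
        )
    for _ in range(spec.n_shared_pass):
        wt = int(rng.integers(1, 10))
        jitter = int(rng.integers(0, 8))
        if wt == 1 and jitter == 0:
            jitter = 1
        wt_int = intensity()
        rows.append(
            dict(
                wt_seq_count=wt,
                tg_seq_count=2 * wt + jitter,
                wt_intensity=wt_int,
                tg_intensity=float(np.round(wt_int * 2 * rng.uniform(1.0, 3.0), 2)),
                planted_class="shared_pass",
            )
        )
    for _ in range(spec.n_shared_fail):
        wt = int(rng.integers(1, 10))
        wt_int = intensity()
        if rng.random() < 0.5:  # violate the count criterion only
            tg = int(rng.integers(1, 2 * wt))
            tg_int = float(np.round(wt_int * 2 * rng.uniform(1.0, 3.0), 2))
        else:  # violate the intensity criterion only
            tg = 2 * wt + int(rng.integers(0, 8))
            tg_int = float(np.round(wt_int * rng.uniform(0.1, 1.9), 2))
        rows.append(
            dict(
                wt_seq_count=wt,
                tg_seq_count=tg,
                wt_intensity=wt_int,
                tg_intensity=tg_int,
                planted_class="shared_fail",
            )
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "wt_seq_count",
            "tg_seq_count",
            "wt_intensity",
            "tg_intensity",
            PLANTED_CLASS_COLUMN,
        ],
    )
    table.insert(0, "protein_id", [f"P{i:05d}" for i in range(len(table))])
    return table


def gen_background_graph(spec: SyntheticSpec, node_names: list[str] | None = None) -> nx.Graph:
    """Connected scale-free background PPI graph by preferential attachment.

    Uses the Barabási–Albert process: starting from ``graph_attach``
    unconnected seed nodes, each new node attaches ``graph_attach`` edges
    preferentially, giving exactly ``graph_attach · (graph_nodes −
    graph_attach)`` edges, no self-loops or duplicates, and degree exponent
    → 3 for large graphs. ``node_names`` (length ``graph_nodes``) relabels
    the integer nodes, e.g. to overlap with an interactome's proteins.
    """
    g = nx.barabasi_albert_graph(spec.graph_nodes, spec.graph_attach, seed=spec.seed)
    if node_names is not None:
        if len(node_names) != spec.graph_nodes:
            raise ValueError(
                f"node_names has {len(node_names)} entries, expected {spec.graph_nodes}"
            )
        g = nx.relabel_nodes(g, dict(enumerate(node_names)))
    else:
        g = nx.relabel_nodes(g, {i: f"N{i:05d}" for i in g.nodes})
    return g


def ba_edge_count(spec: SyntheticSpec) -> int:
    """Closed-form edge count of the preferential-attachment generator."""
    return spec.graph_attach * (spec.graph_nodes - spec.graph_attach)


def gen_abundance_matrix(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Abundance matrix with exactly planted region-enriched proteins.

    Baseline: a log-normal(0, 1) per-protein abundance level shared across
    regions, with mild per-cell log-normal(0, 0.15) region jitter — wide
    between-protein spread but between-region ratios far below the 4-fold
    rule, so no baseline protein is enriched anywhere. Then, per region,
    ``n_enriched_per_region`` disjoint proteins have that region's value
    raised strictly above 4 × their other-region median (uplift factor
    uniform in [1.25, 2.5] beyond the fold). Returns the matrix and the
    planted region → protein-set labels, which the >4-fold rule recovers
    exactly.
    """
    if spec.n_regions < 3:
        raise ValueError("n_regions must be at least 3")
    if spec.n_enriched_per_region * spec.n_regions > spec.n_proteins:
        raise ValueError("not enough proteins to plant disjoint enriched sets")
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:05d}" for i in range(spec.n_proteins)]
    regions = [f"REGION_{j + 1}" for j in range(spec.n_regions)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_proteins)
    jitter = rng.lognormal(mean=0.0, sigma=0.15, size=(spec.n_proteins, spec.n_regions))
    values = base[:, None] * jitter

    order = rng.permutation(spec.n_proteins)
    planted: dict[str, set[str]] = {}
    pos = 0
    for j, region in enumerate(regions):
        idx = order[pos : pos + spec.n_enriched_per_region]
        pos += spec.n_enriched_per_region
        others = np.delete(values[idx], j, axis=1)
        uplift = rng.uniform(1.25, 2.5, size=len(idx))
        values[idx, j] = 4.0 * np.median(others, axis=1) * uplift
        planted[region] = {proteins[i] for i in idx}
    matrix = pd.DataFrame(values, index=proteins, columns=regions)
    return matrix, planted


def gen_gene_sets(
    spec: SyntheticSpec,
    query: set[str],
    universe: set[str],
    n_null: int = 20,
    n_planted: int = 1,
    set_size: int = 50,
    overlap_factor: float = 3.0,
) -> dict[str, dict]:
    """GMT-writable gene-set collection with planted over-representation.

    ``n_null`` sets are uniform draws of ``set_size`` members from the
    universe; ``n_planted`` sets force their overlap with the query to
    ``overlap_factor`` times the null expectation ``set_size·|query|/|universe|``
    (rounded up, capped at min(set_size, |query|)). Requires query ⊆ universe.
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rng = np.random.default_rng(spec.seed)
    uni = sorted(universe)
    qry = sorted(query)
    non_query = sorted(universe - query)
    sets: dict[str, dict] = {}
    for i in range(n_null):
        members = set(rng.choice(uni, size=min(set_size, len(uni)), replace=False).tolist())
        sets[f"NULL_{i + 1:02d}"] = {"description": "uniform null set", "members": members}
    for i in range(n_planted):
        expectation = set_size * len(qry) / len(uni)
        k = min(int(np.ceil(overlap_factor * expectation)), set_size, len(qry))
        members = set(rng.choice(qry, size=k, replace=False).tolist())
        members |= set(rng.choice(non_query, size=set_size - k, replace=False).tolist())
        sets[f"PLANTED_{i + 1:02d}"] = {
            "description": f"planted overlap {k}",
            "members": members,
        }
    return sets


def sample_power_law(alpha: float, size: int, seed: int, x_max: int = 10**6) -> np.ndarray:
    """Draw integers from the discrete power law P(x) ∝ x^(−α), x ≥ 1.

    Inverse-transform sampling on the support truncated at ``x_max`` (the
    truncated tail mass is negligible for α well above 1 and the default
    cap). Used for parameter-recovery checks of the power-law estimator.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = np.random.default_rng(seed)
    x = np.arange(1, x_max + 1, dtype=float)
    pmf = x ** (-alpha)
    cdf = np.cumsum(pmf / pmf.sum())
    return np.searchsorted(cdf, rng.random(size)) + 1
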