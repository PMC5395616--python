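"""Induced PPI subnetworks and their topology.

Given a background protein–protein interaction graph and a query protein
set (an interactome), this module builds the induced subnetwork — query
proteins plus every background edge between them; query proteins without
any such edge are *orphan nodes* — and quantifies its topology:

- node/edge/orphan counts;
- average path length: the mean number of edges along shortest paths over
  all unordered pairs of distinct nodes that lie in the same connected
  component of the orphan-free subgraph (disconnected pairs are excluded
  from the mean, and orphans from all path/degree statistics);
- degree histogram and a discrete maximum-likelihood power-law exponent α
  (x_min = 1), the scale-free summary of the degree distribution;
- a resampling null for the average path length: draw the same number of
  proteins uniformly from the background, recompute the statistic, repeat;
  the empirical P-value is the fraction of resamples whose statistic is
  strictly smaller than the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path
from scipy.special import zeta

logger = logging.getLogger(__name__)


def induce_subgraph(proteins: set[str], background: nx.Graph) -> nx.Graph:
    """Induce the subnetwork of ``proteins`` on the background graph.

    Query proteins absent from the background are kept as isolated nodes
    (they become orphans), so the node set always equals the query set.
    """
    if not proteins:
        logger.warning("empty protein set: returning empty graph")
        return nx.Graph()
    g = nx.Graph()
    g.add_nodes_from(proteins)
    present = proteins & set(background.nodes)
    g.add_edges_from(background.subgraph(present).edges)
    return g


def find_orphans(g: nx.Graph) -> set[str]:
    """Nodes with no interaction to any other node of the network."""
    return {n for n, d in g.degree if d == 0}


def _apl_from_adjacency(adj: csr_array) -> float | None:
    """Connected-pairs mean shortest-path length from a CSR adjacency."""
    n = adj.shape[0]
    if n < 2 or adj.nnz == 0:
        return None
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    upper = dist[np.triu_indices(n, k=1)]
    finite = upper[np.isfinite(upper)]
    if finite.size == 0:
        return None
    return float(finite.mean())


def avg_path_length(g: nx.Graph) -> float | None:
    """Connected-pairs mean shortest-path length.

    Averages over all unordered pairs of distinct nodes within each
    connected component of the orphan-free subgraph; pairs in different
    components (and pairs involving orphans) contribute nothing. Returns
    ``None`` when no connected pair exists.
    """
    if g.number_of_nodes() < 2 or g.number_of_edges() == 0:
        logger.warning("no connected node pair: average path length undefined")
        return None
    result = _apl_from_adjacency(csr_array(nx.to_scipy_sparse_array(g, format="csr")))
    if result is None:
        logger.warning("no connected node pair: average path length undefined")
    return result


def degree_histogram(g: nx.Graph) -> dict[int, int]:
    """Degree → node count over the orphan-free subgraph."""
    hist: dict[int, int] = {}
    for _, d in g.degree:
        if d > 0:
            hist[d] = hist.get(d, 0) + 1
    return hist


def fit_power_law(
    degrees: Iterable[int] | dict[int, int], x_min: int = 1, min_points: int = 10
) -> float | None:
    """Discrete maximum-likelihood power-law exponent.

    Fits P(x) ∝ x^(−α) for x ≥ ``x_min`` over the degrees at or above
    ``x_min`` by maximizing the Hurwitz-zeta-normalized log-likelihood.
    The default ``x_min = 1`` fits the whole positive-degree range (the
    convention for induced interactome networks here); for generators with
    a built-in minimum degree (e.g. preferential attachment with m edges
    per new node) pass ``x_min = m``, otherwise the flat head of the
    distribution drags α down. Returns ``None`` (with a warning) for fewer
    than ``min_points`` usable degrees, or for a degenerate sample in which
    every degree equals ``x_min`` (the likelihood then increases without
    bound in α).
    """
    if isinstance(degrees, dict):
        xs = np.repeat(list(degrees.keys()), list(degrees.values())).astype(float)
    else:
        xs = np.asarray(list(degrees), dtype=float)
    xs = xs[xs >= x_min]
    if xs.size < min_points:
        logger.warning("power-law fit skipped: only %d degrees >= x_min", xs.size)
        return None
    if np.all(xs == xs[0]):
        logger.warning("power-law fit skipped: degenerate degree sample")
        return None
    mean_log = float(np.mean(np.log(xs)))

    def neg_loglik(alpha: float) -> float:
        return np.log(zeta(alpha, x_min)) + alpha * mean_log

    res = minimize_scalar(neg_loglik, bounds=(1.0001, 25.0), method="bounded")
    return float(res.x)


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_orphans: int
    avg_path_length: float | None
    degree_histogram: dict[int, int]
    alpha: float | None
    #: empirical degree distribution points (degree, fraction of non-orphan nodes)
    degree_density: list[tuple[int, float]]


def topology_report(g: nx.Graph) -> TopologyReport:
    """Full topology summary of an induced interactome network."""
    hist = degree_histogram(g)
    n_nonorphan = sum(hist.values())
    density = [(k, hist[k] / n_nonorphan) for k in sorted(hist)] if n_nonorphan else []
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_orphans=len(find_orphans(g)),
        avg_path_length=avg_path_length(g),
        degree_histogram=hist,
        alpha=fit_power_law(hist),
        degree_density=density,
    )


@dataclass(frozen=True)
class NullDistribution:
    """Resampling null for the average path length of a query network."""

    observed_stat: float | None
    samples: list[float | None]
    n_resamples: int
    n_smaller: int
    empirical_p: float
    seed: int

    @property
    def n_absent(self) -> int:
        return sum(1 for s in self.samples if s is None)


def resample_null(
    query: set[str],
    background: nx.Graph,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Empirical significance of a query network's average path length.

    Each resample draws ``len(query)`` nodes uniformly without replacement
    from the background node list, induces the subgraph and computes the
    average path length with identical conventions. The empirical P-value
    is ``N_i / n_resamples`` with ``N_i`` the number of resamples whose
    statistic is strictly smaller than the observed one; resamples with an
    undefined statistic (no connected pair) count as not-smaller. An
    undefined observed statistic behaves as +infinity: every defined
    resample statistic counts as smaller.
    """
    nodes = sorted(background.nodes)
    if len(query) > len(nodes):
        raise ValueError(f"query size {len(query)} exceeds background size {len(nodes)}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    observed = avg_path_length(induce_subgraph(query, background))
    # one CSR adjacency up front; per resample, slicing rows/columns is the
    # induced subgraph, so sample statistics use identical conventions
    adj = csr_array(nx.to_scipy_sparse_array(background, nodelist=nodes, format="csr"))
    rng = np.random.default_rng(seed)
    samples: list[float | None] = []
    n_smaller = 0
    for _ in range(n_resamples):
        idx = rng.choice(len(nodes), size=len(query), replace=False)
        stat = _apl_from_adjacency(adj[idx][:, idx])
        samples.append(stat)
        if stat is not None and (observed is None or stat < observed):
            n_smaller += 1
    return NullDistribution(
        observed_stat=observed,
        samples=samples,
        n_resamples=n_resamples,
        n_smaller=n_smaller,
        empirical_p=n_smaller / n_resamples,
        seed=seed,
    )
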