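"""Topology of the induced interactome networks.

Induces the common, A-specific and B-specific subnetworks on the background
PPI graph and reports node/edge/orphan counts, connected-pairs average path
length, and the maximum-likelihood power-law degree exponent.
"""

import argparse
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from regionppi import io_formats as io
from regionppi.network_topology import induce_subgraph, topology_report

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

edges = io.read_edge_table(args.data / "background_edges.tsv")
background = nx.from_pandas_edgelist(edges, "protein_a", "protein_b")
print(f"background: {background.number_of_nodes()} nodes, {background.number_of_edges()} edges")

rows = []
for name in ("common", "specific_A", "specific_B"):
    proteins = io.read_protein_set(args.out / f"{name}.tsv")
    sub = induce_subgraph(proteins, background)
    top = topology_report(sub)
    alpha = f"{top.alpha:.2f}" if top.alpha is not None else "n/a"
    apl = f"{top.avg_path_length:.2f}" if top.avg_path_length is not None else "n/a"
    print(f"{name:12s} {top.n_nodes:4d} nodes, {top.n_edges:5d} edges, "
          f"{top.n_orphans:3d} orphans, avg path length {apl}, alpha {alpha}")
    rows.append(
        {
            "network": name,
            "n_nodes": top.n_nodes,
            "n_edges": top.n_edges,
            "n_orphans": top.n_orphans,
            "avg_path_length": top.avg_path_length,
            "alpha": top.alpha,
        }
    )
    edge_rows = sorted((min(u, v), max(u, v)) for u, v in sub.edges)
    io.write_edge_table(
        pd.DataFrame(edge_rows, columns=["protein_a", "protein_b"]),
        args.out / f"network_{name}_edges.tsv",
    )

pd.DataFrame(rows).to_csv(args.out / "topology.tsv", sep="\t", index=False, lineterminator="\n")
print(f"wrote {args.out / 'topology.tsv'}")
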