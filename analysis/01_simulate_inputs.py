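"""Generate the synthetic study inputs with planted ground truth.

Emulates the full input bundle of a two-region bait-interactome study:

- a paired WT/TG IP-MS detection table at the published composition
  (137 TG-only detections; 259 shared, 74 of which pass both filter
  criteria) → the mPFC-side interactome after filtering;
- a second, already-filtered interactome (HP+STR side) sharing 47 proteins
  with the first;
- a dense scale-free background PPI graph (1/10-scale stand-in for the
  7,880-node brain interactome) covering every interactome protein;
- a proteins × 10-region abundance matrix with planted >4-fold
  region-enriched proteins;
- a gene-set collection (GMT) with one planted over-represented set among
  uniform nulls.

Everything is written under results/data/ for the downstream scripts.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from regionppi import io_formats as io
from regionppi.hit_filter import filter_hits
from regionppi.synthetic_data import (
    SyntheticSpec,
    gen_abundance_matrix,
    gen_background_graph,
    gen_detection_table,
    gen_gene_sets,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

out = args.out
out.mkdir(parents=True, exist_ok=True)
spec = SyntheticSpec(seed=args.seed)

table = gen_detection_table(spec)
io.write_detection_table(table, out / "detections.tsv")
print(f"detection table: {len(table)} records "
      f"({(table.wt_seq_count == 0).sum()} TG-only, {(table.wt_seq_count > 0).sum()} shared)")

# second interactome: 47 proteins common with the filtered hits, 208 specific
hits = filter_hits(table).hits
common = sorted(hits)[: 47]
interactome_b = set(common) | {f"HPSTR{i:04d}" for i in range(208)}
io.write_protein_set(interactome_b, out / "interactome_b.tsv")
print(f"second interactome: {len(interactome_b)} proteins, 47 shared with the filtered hits")

# background graph over all interactome proteins plus filler nodes
names = sorted(hits | interactome_b)
names += [f"BG{i:05d}" for i in range(spec.graph_nodes - len(names))]
graph = gen_background_graph(spec, node_names=names)

# plant a dense community on the A-specific interactome: a biologically
# coherent complex should sit closer together than random same-size sets,
# and the resampling null downstream is expected to recover exactly that
community_rng = np.random.default_rng(spec.seed + 1000)
specific_a = sorted(hits - interactome_b)
n_before = graph.number_of_edges()
for i, u in enumerate(specific_a):
    for v in specific_a[i + 1 :]:
        if community_rng.random() < 0.08:
            graph.add_edge(u, v)
print(f"planted community: {graph.number_of_edges() - n_before} extra edges "
      f"among the {len(specific_a)} A-specific proteins")

edges = pd.DataFrame(
    sorted((min(u, v), max(u, v)) for u, v in graph.edges),
    columns=["protein_a", "protein_b"],
)
io.write_edge_table(edges, out / "background_edges.tsv")
print(f"background graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")

matrix, planted = gen_abundance_matrix(spec)
io.write_abundance_matrix(matrix, out / "abundance.tsv")
io.write_gmt(
    {r: {"description": "planted region-enriched", "members": s} for r, s in planted.items()},
    out / "planted_regions.gmt",
)
print(f"abundance matrix: {matrix.shape[0]} proteins x {matrix.shape[1]} regions, "
      f"{sum(len(s) for s in planted.values())} planted region-enriched")

universe = set(graph.nodes)
query = (hits - interactome_b) & universe  # the A-specific interactome, tested downstream
collection = gen_gene_sets(spec, query, universe, n_null=20, n_planted=1, set_size=60)
io.write_gmt(collection, out / "gene_sets.gmt")
print(f"gene sets: {len(collection)} (1 planted, 20 null)")

(out / "meta.json").write_text(json.dumps({"seed": args.seed}, indent=2) + "\n")
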