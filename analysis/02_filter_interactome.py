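"""Call the interactome from the WT/TG detection table.

A protein enters the interactome if it was detected only in the TG
pulldown, or detected in both pulldowns with TG sequence count >= 2x WT and
TG total intensity >= 2x WT. Writes the hit list and a branch-count summary.
"""

import argparse
import json
from pathlib import Path

from regionppi import io_formats as io
from regionppi.hit_filter import filter_hits

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

table = io.read_detection_table(args.data / "detections.tsv")
result = filter_hits(table)

io.write_protein_set(result.hits, args.out / "interactome_a.tsv")
summary = {"n_hits": len(result.hits), "branch_counts": result.branch_counts}
(args.out / "filter_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

print(f"records: {len(table)}")
for branch, n in result.branch_counts.items():
    print(f"  {branch:12s} {n}")
print(f"interactome: {len(result.hits)} proteins "
      f"(TG-only {result.branch_counts['tg_only']} + shared-pass {result.branch_counts['shared_pass']})")
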