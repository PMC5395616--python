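"""Readers and writers for the on-disk artifacts of the pipeline.

Dialects (all plain text, UTF-8, ``\\n`` newlines, stable column order so
outputs diff bit-exactly):

- detection table: TSV, header ``protein_id  wt_seq_count  tg_seq_count
  wt_intensity  tg_intensity`` (extra columns are carried through);
- edge table: TSV, header with two required columns ``protein_a``,
  ``protein_b`` and an optional ``source``;
- protein set: single-column TSV with header ``protein_id``;
- gene sets: standard GMT (name, description, members, tab-separated);
- mapping table: TSV, header ``source_id  target_id``, many-to-one.

All identifiers are normalized on load (uppercased, whitespace-stripped);
normalization is idempotent. Every parse rejection names the offending
row/column.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = [
    "protein_id",
    "wt_seq_count",
    "tg_seq_count",
    "wt_intensity",
    "tg_intensity",
]
COUNT_COLUMNS = ["wt_seq_count", "tg_seq_count"]
INTENSITY_COLUMNS = ["wt_intensity", "tg_intensity"]


def normalize_id(identifier: str) -> str:
    """Normalize a protein/gene identifier: strip whitespace, uppercase."""
    return str(identifier).strip().upper()


def read_detection_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a paired WT/TG IP-MS detection table.

    Counts must be non-negative integers, intensities finite non-negative
    reals, protein ids unique. Raises ``ValueError`` naming the first bad
    row (1-based, excluding the header) and column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["protein_id"] = df["protein_id"].map(normalize_id)

    for col in COUNT_COLUMNS + INTENSITY_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: row {row}, column {col!r}: non-numeric or non-finite value")
        if (numeric < 0).any():
            row = int((numeric < 0).idxmax()) + 1
            raise ValueError(f"{path}: row {row}, column {col!r}: negative value")
        if col in COUNT_COLUMNS:
            if ((numeric % 1) != 0).any():
                row = int(((numeric % 1) != 0).idxmax()) + 1
                raise ValueError(f"{path}: row {row}, column {col!r}: count is not an integer")
            df[col] = numeric.astype(int)
        else:
            df[col] = numeric.astype(float)

    dup = df["protein_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValueError(f"{path}: row {row}: duplicate protein_id {df['protein_id'][dup.idxmax()]!r}")
    return df


def write_detection_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = DETECTION_COLUMNS + [c for c in table.columns if c not in DETECTION_COLUMNS]
    table.loc[:, cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read an undirected PPI edge list.

    Self-loops are dropped and duplicate pairs (A,B ≡ B,A) collapsed; the
    number of dropped rows is logged. Returns columns ``protein_a``,
    ``protein_b`` (lexicographically ordered within each row) and, if
    present in the file, ``source``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_a", "protein_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        logger.warning("%s: empty edge table", path)
    bad = df["protein_a"].isna() | df["protein_b"].isna()
    if bad.any():
        raise ValueError(f"{path}: row {int(bad.idxmax()) + 1}: unparseable edge (missing endpoint)")
    a = df["protein_a"].map(normalize_id)
    b = df["protein_b"].map(normalize_id)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = pd.DataFrame({"protein_a": lo, "protein_b": hi})
    if "source" in df.columns:
        out["source"] = df["source"]
    self_loops = out["protein_a"] == out["protein_b"]
    n_loops = int(self_loops.sum())
    out = out[~self_loops]
    n_dups = int(out.duplicated(subset=["protein_a", "protein_b"]).sum())
    out = out.drop_duplicates(subset=["protein_a", "protein_b"]).reset_index(drop=True)
    if n_loops or n_dups:
        logger.info("%s: dropped %d self-loop(s), %d duplicate edge(s)", path, n_loops, n_dups)
    return out


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    cols = ["protein_a", "protein_b"] + (["source"] if "source" in edges.columns else [])
    edges.loc[:, cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_protein_set(path: str | Path) -> set[str]:
    """Read a single-column protein list (header ``protein_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "protein_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'protein_id'")
    return {normalize_id(p) for p in df["protein_id"].dropna()}


def write_protein_set(proteins: set[str], path: str | Path) -> None:
    pd.DataFrame({"protein_id": sorted(proteins)}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT gene-set file into ``{name: {"description", "members"}}``.

    Member identifiers are normalized; duplicate set names are an error.
    """
    sets: dict[str, dict] = {}
    text = Path(path).read_text()
    if not text.strip():
        logger.warning("%s: empty GMT file", path)
        return sets
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected at least name and description")
        name = fields[0].strip()
        if name in sets:
            raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
        members = {normalize_id(m) for m in fields[2:] if m.strip()}
        sets[name] = {"description": fields[1], "members": members}
    return sets


def write_gmt(sets: Mapping[str, dict], path: str | Path) -> None:
    lines = []
    for name, payload in sets.items():
        members = sorted(payload["members"])
        lines.append("\t".join([name, payload.get("description", "")] + members))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a many-to-one identifier mapping (e.g. mouse → human symbols).

    Duplicate source rows resolve last-wins; the number of overridden rows
    is logged so the tie-break is auditable.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df["source_id"].isna() | df["target_id"].isna()
    if bad.any():
        raise ValueError(f"{path}: row {int(bad.idxmax()) + 1}: incomplete mapping row")
    mapping: dict[str, str] = {}
    n_dup = 0
    for src, tgt in zip(df["source_id"], df["target_id"]):
        key = normalize_id(src)
        if key in mapping:
            n_dup += 1
        mapping[key] = normalize_id(tgt)
    if n_dup:
        logger.warning("%s: %d duplicate source row(s); last occurrence wins", path, n_dup)
    return mapping


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a proteins × regions abundance matrix (TSV, first column ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_id(p) for p in df.index]
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance value")
    return df


def write_abundance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id", lineterminator="\n")
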