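"""Readers and writers for the pipeline's plain-text formats.

Counts are TSV with taxon rows and sample columns (first column taxon ids,
header row of sample ids); metadata/env tables are TSV; trees are newick.
Validation errors name the offending line where possible.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd


class ParseError(ValueError):
    pass


def read_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ParseError(f"{path}: missing or empty counts file")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header must contain at least one sample column")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dup = {s for s in sample_ids if sample_ids.count(s) > 1}
            raise ParseError(f"{path}:1: duplicated sample id(s): {sorted(dup)}")
        taxa, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            taxa.append(parts[0])
            try:
                rows.append([int(float(x)) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count: {exc}") from None
    if len(set(taxa)) != len(taxa):
        dup = {t for t in taxa if taxa.count(t) > 1}
        raise ParseError(f"{path}: duplicated taxon id(s): {sorted(dup)}")
    if not taxa:
        raise ParseError(f"{path}: no taxon rows")
    counts = pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id"),
                          columns=sample_ids, dtype=np.int64)
    if (counts < 0).any().any():
        raise ParseError(f"{path}: negative counts present")
    return counts


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "pond", "day", "stage", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata column(s): {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicated sample_id in metadata")
    return meta.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_env(path: str | Path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t")
    if "day" not in env.columns:
        raise ParseError(f"{path}: env table must have a 'day' column")
    if env["day"].duplicated().any():
        raise ParseError(f"{path}: duplicated day in env table")
    return env.set_index("day")


def write_env(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index_label="day")


def read_tree(path: str | Path, taxa: list[str] | None = None) -> dendropy.Tree:
    """Read a newick tree; optionally check that it covers a taxon set.

    Taxa without a matching tip are a hard error (the assembly stage cannot
    place them); tips absent from the taxon set are merely reported.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise ParseError(f"{path}: malformed newick: {exc}") from None
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if taxa is not None:
        missing = sorted(set(taxa) - tips)
        if missing:
            raise ParseError(
                f"{path}: {len(missing)} taxa have no tree tip, e.g. {missing[:5]}"
            )
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
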