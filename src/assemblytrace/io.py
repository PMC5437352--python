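"""Readers and writers for the external formats the pipeline touches.

Tables are TSV (taxa as rows, samples as columns, first column the taxon
id) or dense-JSON BIOM; trees are newick; metadata and taxonomy are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .containers import (
    RANKS,
    CommunityTable,
    SampleFrame,
    SchemaError,
    TaxonomyTable,
    validate_tree,
)


def read_community_table(path, format: str = "tsv") -> CommunityTable:
    """Read a sample x taxon count table.

    ``format='tsv'``: tab-separated, taxa as rows, samples as columns.
    ``format='biom_json'``: the dense JSON BIOM flavor (rows = taxa).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        if path.stat().st_size == 0:
            raise SchemaError(f"empty table file: {path}")
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if len(set(header[1:])) != len(header[1:]):
            raise SchemaError("duplicate sample ids in table header")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise SchemaError(f"table has no sample columns: {path}")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise SchemaError("duplicate taxon or sample ids in table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric cells in count table")
        return CommunityTable.from_dataframe(df)
    if format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise SchemaError("only dense-JSON BIOM tables are supported")
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        data = np.asarray(doc["data"], dtype=float)  # rows = taxa
        return CommunityTable(data.T, sample_ids, taxon_ids)
    raise ValueError(f"unknown table format: {format!r}")


def write_community_table(table: CommunityTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


def read_tree(path, *, root_at_midpoint: bool = False) -> skbio.TreeNode:
    """Read a rooted newick phylogeny and validate its invariants."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    return validate_tree(tree, root_at_midpoint=root_at_midpoint)


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path) -> SampleFrame:
    """Read per-sample metadata TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleFrame(df)


def write_metadata(frame: SampleFrame, path) -> None:
    frame.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyTable:
    """Read a per-taxon taxonomy TSV.

    Accepts either one column per rank or a single semicolon-delimited
    ``taxonomy`` column with up to seven ranks.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "taxonomy" in df.columns and not set(RANKS) <= set(df.columns):
        parts = df["taxonomy"].fillna("").str.split(";")
        ranks = pd.DataFrame(
            [
                [p.strip() if i < len(row) and (p := row[i]).strip() else "unassigned"
                 for i in range(len(RANKS))]
                for row in parts
            ],
            index=df.index,
            columns=list(RANKS),
        )
        df = pd.concat([ranks, df.drop(columns=["taxonomy"])], axis=1)
    df = df.fillna("unassigned")
    is_dn = None
    if "is_de_novo" in df.columns:
        is_dn = df["is_de_novo"].astype(str).str.lower().isin(("true", "1", "yes"))
        df = df.drop(columns=["is_de_novo"])
    return TaxonomyTable(df, is_de_novo=is_dn)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.data.copy()
    df["is_de_novo"] = tax.is_de_novo
    df.to_csv(path, sep="\t", index_label="taxon_id")
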