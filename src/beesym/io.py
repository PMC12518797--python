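"""Readers and writers for the plain-text interchange formats.

Trees travel as Newick (dendropy), tables as TSV (pandas), distance
matrices as square TSV with a header row/column.
"""

from __future__ import annotations

import dendropy
import pandas as pd

from ._distance import DistanceMatrix
from .cophylo import SymbiontTreeSet

__all__ = [
    "read_tree",
    "write_tree",
    "read_tip_map",
    "read_tree_set",
    "read_table",
    "write_table",
    "read_distance_matrix",
    "write_distance_matrix",
]


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_tip_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tip_id": str})
    if "tip_id" not in df.columns:
        raise ValueError("tip map needs a tip_id column")
    if "is_outgroup" in df.columns:
        df["is_outgroup"] = df["is_outgroup"].astype(bool)
    return df.set_index("tip_id")


def read_tree_set(tree_path, tip_map_path) -> SymbiontTreeSet:
    return SymbiontTreeSet(read_tree(tree_path), read_tip_map(tip_map_path))


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read_tsv(path)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.write_tsv(path)
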