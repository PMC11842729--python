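"""Readers/writers for the plain-text interchange formats.

Feature tables are TSV with a ``#FeatureID`` header column (QIIME-style,
features as rows); sample metadata is TSV with a ``#SampleID`` first
column; taxonomy is TSV with ``Feature ID`` / ``Taxon`` / ``Confidence``
columns (plus hit-flag columns); trees are newick with branch lengths.
Round-tripping any of them is the identity.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    FeatureTable,
    ValidationError,
    validate_annotations,
    validate_metadata,
)

TABLE_HEADER = "#FeatureID"
METADATA_HEADER = "#SampleID"


class ParseError(ValueError):
    """Raised when a file cannot be parsed into a valid object."""


# ---------------------------------------------------------------------------
# feature table


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != TABLE_HEADER:
        raise ParseError(
            f"{path}: first column must be {TABLE_HEADER!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(TABLE_HEADER)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric % 1 != 0) | (numeric < 0)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: cell at feature {df.index[i]!r}, sample {df.columns[j]!r} "
            f"is not a non-negative integer: {df.iat[i, j]!r}"
        )
    try:
        return FeatureTable(numeric.to_numpy(dtype=np.int64), list(df.index), list(df.columns))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = TABLE_HEADER
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != METADATA_HEADER:
        raise ParseError(
            f"{path}: first column must be {METADATA_HEADER!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(METADATA_HEADER)
    df.index.name = METADATA_HEADER
    try:
        return validate_metadata(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = METADATA_HEADER
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy / feature annotations


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["Feature ID", "Taxon", "Confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: taxonomy missing columns {missing}")
    out = pd.DataFrame(index=pd.Index(df["Feature ID"], name="feature_id"))
    out["taxon"] = df["Taxon"].to_numpy()
    out["confidence"] = pd.to_numeric(df["Confidence"]).to_numpy()
    for col, src in (("host_hit", "HostHit"), ("has_16s_hit", "Has16SHit")):
        if src in df.columns:
            out[col] = df[src].map({"True": True, "False": False, "1": True, "0": False}).to_numpy()
        else:
            # flags absent: assume a plain 16S taxonomy export
            out[col] = col == "has_16s_hit"
    try:
        return validate_annotations(out)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_taxonomy(annotations: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {
            "Feature ID": annotations.index,
            "Taxon": annotations["taxon"].to_numpy(),
            "Confidence": annotations["confidence"].to_numpy(),
            "HostHit": annotations["host_hit"].astype(bool).astype(str).to_numpy(),
            "Has16SHit": annotations["has_16s_hit"].astype(bool).astype(str).to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# newick trees


def read_tree(path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"{path}: negative branch length {edge.length}")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate leaf labels")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )
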