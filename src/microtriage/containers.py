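"""Shared domain containers for low-biomass 16S analyses.

The package works on four in-memory objects: an integer feature-by-sample
count table (:class:`FeatureTable`), a sample-metadata frame, a
feature-annotation frame (taxonomy lineage, classifier confidence,
host-genome / 16S reference hit flags), and a phylogeny held as a
:class:`dendropy.Tree`.  Metadata and annotations are plain pandas
DataFrames validated by the functions below, following the convention of
table-centric toolkits rather than per-row record classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SOURCES = frozenset({"brain", "fecal", "blank"})
IMPLANT_STATUSES = frozenset({"unimplanted", "acute", "chronic", "not_applicable"})
TREATMENTS = frozenset({"control", "antibiotic", "not_applicable"})

#: canonical rank order for rank-prefixed lineages (SILVA/Greengenes dialect)
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class ValidationError(ValueError):
    """Raised when an input object violates a structural contract."""


@dataclass
class FeatureTable:
    """Integer count matrix, features as rows (QIIME orientation).

    Parameters
    ----------
    counts : ndarray of shape (n_features, n_samples)
        Non-negative integer read counts.
    feature_ids, sample_ids : sequences of unique str
        Row / column labels.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64, copy=False)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> pd.Series:
        """Library depth (column sum) per sample."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="depth")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    # -- subsetting ------------------------------------------------------
    def select_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing}")
        rows = [index[f] for f in ids]
        return FeatureTable(self.counts[rows, :], ids, list(self.sample_ids))

    def select_samples(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in ids]
        return FeatureTable(self.counts[:, cols], list(self.feature_ids), ids)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample proportions; all-zero samples yield zero columns."""
        d = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / np.where(d > 0, d, np.nan)
        return np.nan_to_num(p)


def validate_metadata(metadata: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample id).

    Required columns: ``source``, ``implant_status``, ``treatment``,
    ``batch``, ``subject_id``.  Blanks must carry ``not_applicable``
    implant status.  If *table* is given the sample sets must coincide.
    """
    required = ["source", "implant_status", "treatment", "batch", "subject_id"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if metadata.index.duplicated().any():
        dups = metadata.index[metadata.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    bad = set(metadata["source"]) - SOURCES
    if bad:
        raise ValidationError(f"unknown source values: {sorted(bad)}")
    bad = set(metadata["implant_status"]) - IMPLANT_STATUSES
    if bad:
        raise ValidationError(f"unknown implant_status values: {sorted(bad)}")
    bad = set(metadata["treatment"]) - TREATMENTS
    if bad:
        raise ValidationError(f"unknown treatment values: {sorted(bad)}")
    blanks = metadata["source"] == "blank"
    if (metadata.loc[blanks, "implant_status"] != "not_applicable").any():
        raise ValidationError("blank samples must have implant_status = not_applicable")
    if table is not None:
        tset, mset = set(table.sample_ids), set(metadata.index)
        if tset != mset:
            raise ValidationError(
                "table/metadata sample sets differ: "
                f"only in table: {sorted(tset - mset)}; only in metadata: {sorted(mset - tset)}"
            )
    return metadata


def parse_lineage(taxon: str) -> list[str]:
    """Split a semicolon-separated rank-prefixed lineage into ranks.

    ``"d__Bacteria; p__Firmicutes"`` -> ``["d__Bacteria", "p__Firmicutes"]``.
    Ranks must appear in canonical order with gaps only at the tail.
    """
    parts = [p.strip() for p in str(taxon).split(";") if p.strip()]
    for i, part in enumerate(parts):
        if i >= len(RANK_PREFIXES):
            raise ValidationError(f"lineage {taxon!r} has more than 7 ranks")
        if not part.startswith(RANK_PREFIXES[i]):
            raise ValidationError(
                f"lineage {taxon!r}: rank {i} is {part!r}, expected prefix {RANK_PREFIXES[i]!r}"
            )
    return parts


def validate_annotations(
    annotations: pd.DataFrame, table: FeatureTable | None = None
) -> pd.DataFrame:
    """Validate a feature-annotation frame (index = feature id).

    Required columns: ``taxon`` (rank-prefixed lineage string),
    ``confidence`` in [0, 1], boolean ``host_hit`` and ``has_16s_hit``.
    """
    required = ["taxon", "confidence", "host_hit", "has_16s_hit"]
    missing = [c for c in required if c not in annotations.columns]
    if missing:
        raise ValidationError(f"annotations missing columns: {missing}")
    conf = annotations["confidence"].to_numpy(dtype=float)
    if np.any((conf < 0) | (conf > 1)):
        raise ValidationError("classifier confidence must lie in [0, 1]")
    for taxon in annotations["taxon"]:
        parse_lineage(taxon)
    if table is not None:
        missing_feats = sorted(set(table.feature_ids) - set(annotations.index))
        if missing_feats:
            raise ValidationError(f"features without annotation: {missing_feats}")
    return annotations


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValidationError("distance matrix asymmetric beyond 1e-12")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class HypothesisTestResult:
    """A single hypothesis test, optionally with pairwise follow-ups.

    ``pairwise`` (when present) is a DataFrame with one row per contrast
    and columns including group labels, the statistic, ``p_value`` and
    ``p_adjusted`` (Benjamini-Hochberg unless stated otherwise).
    """

    method: str
    statistic: float
    p_value: float
    df: tuple | float | None = None
    p_adjusted: float | None = None
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)
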