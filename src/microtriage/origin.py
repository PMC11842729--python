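"""Taxon-level origin accounting for implantation-associated features.

After contaminant removal, taxa observed in implanted brains are scored
against two reference sets: the *background* set (taxa of unimplanted
brains) and the *fecal* set (taxa of gut samples).  Taxa present in the
background are shared background features; taxa absent from background
but present in feces are distinct features of gut origin; the remainder
are distinct features of unknown anatomical origin.  A four-set Venn
accounting (background / acute / chronic / fecal) yields the
total / unique / invading / non-invasive bookkeeping, and category
relative abundances are quantified over repeated rarefactions with
Tukey HSD contrasts between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable, RANK_PREFIXES, RANKS, parse_lineage

BACKGROUND_SHARED = "BACKGROUND_SHARED"
DISTINCT_GUT = "DISTINCT_GUT"
DISTINCT_UNKNOWN = "DISTINCT_UNKNOWN"
CATEGORIES = (BACKGROUND_SHARED, DISTINCT_GUT, DISTINCT_UNKNOWN)


def taxon_label(taxon: str, rank: str) -> str:
    """Label of *taxon* at *rank*; features lacking the rank map to an
    ``unclassified_<lowest assigned rank>`` placeholder."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)
    lineage = parse_lineage(taxon)
    if len(lineage) > depth:
        return lineage[depth]
    return f"unclassified_{lineage[-1]}" if lineage else "unclassified_"


def collapse_to_rank(table: FeatureTable, annotations: pd.DataFrame, rank: str = "genus") -> FeatureTable:
    """Sum counts over features sharing a taxon label at *rank*.

    Column sums are preserved exactly; taxa appear in order of first
    occurrence.
    """
    missing = sorted(set(table.feature_ids) - set(annotations.index))
    if missing:
        raise ValueError(f"features without annotation: {missing}")
    labels = [taxon_label(annotations.at[f, "taxon"], rank) for f in table.feature_ids]
    order: dict[str, int] = {}
    for lab in labels:
        order.setdefault(lab, len(order))
    out = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for i, lab in enumerate(labels):
        out[order[lab]] += table.counts[i]
    return FeatureTable(out, list(order), list(table.sample_ids))


def observed_set(table: FeatureTable, metadata: pd.DataFrame, selector) -> set:
    """Taxa with a count >= 1 in at least one sample of the group.

    *selector* is a callable over the metadata frame returning a boolean
    mask, or an explicit list of sample ids.  Computed on the unrarefied
    table.
    """
    if callable(selector):
        ids = list(metadata.index[selector(metadata)])
    else:
        ids = list(selector)
    if not ids:
        raise ValueError("empty sample group")
    sub = table.select_samples(ids)
    present = (sub.counts > 0).any(axis=1)
    return {f for f, p in zip(sub.feature_ids, present) if p}


@dataclass
class VennAccounting:
    """Per-group and cross-group taxon counts of the four-set reading."""

    per_group: dict  # group -> {total, unique, invading, non_invasive}
    distinct_union: set  # invading(acute) | invading(chronic)
    gut_overlap: set  # distinct_union & fecal
    persistent_common: set  # background & acute & chronic
    reappearing: set  # (background & chronic) - acute

    def to_dict(self) -> dict:
        return {
            "per_group": {g: dict(v) for g, v in self.per_group.items()},
            "distinct_union": len(self.distinct_union),
            "gut_overlap": len(self.gut_overlap),
            "persistent_common": len(self.persistent_common),
            "reappearing": len(self.reappearing),
        }


def venn_accounting(background: set, acute: set, chronic: set, fecal: set) -> VennAccounting:
    """Four-set accounting of observed taxa.

    For each implanted group G: invading = G - background,
    non_invasive = G & background (so invading + non_invasive = total);
    unique = G minus the union of the other three sets.
    """
    sets = {"background": set(background), "acute": set(acute),
            "chronic": set(chronic), "fecal": set(fecal)}
    per_group = {}
    for name, g in sets.items():
        others = set().union(*(s for k, s in sets.items() if k != name))
        entry = {"total": len(g), "unique": len(g - others)}
        if name in ("acute", "chronic"):
            entry["invading"] = len(g - sets["background"])
            entry["non_invasive"] = len(g & sets["background"])
        per_group[name] = entry
    distinct_union = (sets["acute"] - sets["background"]) | (sets["chronic"] - sets["background"])
    return VennAccounting(
        per_group=per_group,
        distinct_union=distinct_union,
        gut_overlap=distinct_union & sets["fecal"],
        persistent_common=sets["background"] & sets["acute"] & sets["chronic"],
        reappearing=(sets["background"] & sets["chronic"]) - sets["acute"],
    )


def partition_origin(implanted_taxa: set, background: set, fecal: set) -> pd.Series:
    """Exclusive anatomical-origin category per implanted-brain taxon.

    Background membership takes precedence over fecal membership.
    """
    cats = {}
    for t in implanted_taxa:
        if t in background:
            cats[t] = BACKGROUND_SHARED
        elif t in fecal:
            cats[t] = DISTINCT_GUT
        else:
            cats[t] = DISTINCT_UNKNOWN
    return pd.Series(cats, name="category", dtype=object).sort_index()


def category_abundance(rarefied_tables, partition: pd.Series, metadata: pd.DataFrame,
                       group_col: str = "implant_status") -> dict:
    """Per-sample per-category mean relative abundance over rarefaction
    replicates, plus Tukey HSD group contrasts on replicate-level values.

    *rarefied_tables* is an iterable of equal-depth FeatureTables (one
    per replicate) restricted to the samples of interest.  Taxa missing
    from *partition* (e.g. taxa never observed in implanted samples)
    contribute to no category.  Per sample and replicate the three
    category abundances sum to 1 up to the unpartitioned remainder.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rep_rows = []
    sample_ids = None
    n_reps = 0
    for rep, tab in enumerate(rarefied_tables):
        n_reps += 1
        if sample_ids is None:
            sample_ids = list(tab.sample_ids)
        rel = tab.relative_abundance()
        cats = np.array([partition.get(t, "UNPARTITIONED") for t in tab.feature_ids])
        for cat in CATEGORIES:
            vals = rel[cats == cat].sum(axis=0)
            for s, v in zip(tab.sample_ids, vals):
                rep_rows.append((rep, s, cat, v))
    if n_reps == 0:
        raise ValueError("no rarefaction replicates supplied")
    reps = pd.DataFrame(rep_rows, columns=["replicate", "sample_id", "category", "abundance"])
    per_sample = (
        reps.groupby(["sample_id", "category"], observed=True)["abundance"]
        .mean().unstack().reindex(index=sample_ids, columns=list(CATEGORIES))
    )
    groups = metadata.loc[reps["sample_id"], group_col].to_numpy()
    reps["group"] = groups
    tukey = {}
    for cat in CATEGORIES:
        sub = reps[reps["category"] == cat]
        if sub["group"].nunique() < 2 or sub["abundance"].std() == 0:
            continue
        res = pairwise_tukeyhsd(sub["abundance"].to_numpy(), sub["group"].to_numpy())
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        tukey[cat] = frame
    return {"per_sample": per_sample, "replicates": reps, "tukey": tukey, "n_reps": n_reps}
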