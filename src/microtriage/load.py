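"""Relative microbial load via the 16S:contaminant read ratio.

Without spike-in controls, 16S sequencing cannot measure absolute
microbial load; under a constant-contamination model, however, the
per-sample ratio of amplicon-class reads to contaminant-class reads is
proportional to the latent microbial biomass, so ratios can be compared
across groups (Kruskal-Wallis followed by two-sided Dunn tests with
Benjamini-Hochberg adjustment).  Depth-abundance diagnostics (Spearman
correlation and a LOESS smooth of class relative abundance against
total read count) check the model's signature: contaminant abundance
should fall with depth while amplicon abundance rises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureTable, HypothesisTestResult
from .triage import AMPLICON, HOST_GDNA, TECHNICAL_CONTAMINANT, TriageResult
from ._stats import dunn_test, kruskal_wallis, loess_fit, spearman_correlation

CONTAMINANT_CLASSES = (HOST_GDNA, TECHNICAL_CONTAMINANT)


def load_profiles(table: FeatureTable, triage: TriageResult) -> pd.DataFrame:
    """Per-sample read accounting by triage class.

    Returns a frame indexed by sample id with columns ``amplicon_reads``,
    ``contaminant_reads``, ``total_reads``, ``ratio`` and ``flag``.
    ``ratio`` is amplicon/contaminant; +inf (flagged ``no_contaminant``)
    when contaminant reads are zero, NaN (flagged ``empty``) for
    zero-read samples.
    """
    missing = set(table.feature_ids) - set(triage.classes.index)
    if missing:
        raise ValueError(f"triage does not cover features: {sorted(missing)}")
    cls = triage.classes.loc[table.feature_ids].to_numpy()
    amplicon = table.counts[cls == AMPLICON].sum(axis=0)
    contaminant = table.counts[np.isin(cls, CONTAMINANT_CLASSES)].sum(axis=0)
    total = table.counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(contaminant > 0, amplicon / np.maximum(contaminant, 1), np.inf)
    ratio = np.where(total == 0, np.nan, ratio)
    flag = np.where(total == 0, "empty", np.where(contaminant == 0, "no_contaminant", "ok"))
    return pd.DataFrame(
        {
            "amplicon_reads": amplicon,
            "contaminant_reads": contaminant,
            "total_reads": total,
            "ratio": ratio,
            "flag": flag,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def depth_abundance_correlation(
    table: FeatureTable, triage: TriageResult, target_class: str,
    span: float = 0.75,
) -> HypothesisTestResult:
    """Spearman correlation + LOESS of class relative abundance vs depth.

    Two-sided, tie-corrected Spearman (exact for n <= 9); the LOESS curve
    (local linear, tricube weights) evaluated at the observed depths is
    attached as ``extra["loess"]``.  A constant class abundance is
    degenerate: rho = 0, p = 1 and ``extra["degenerate"]``.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples")
    cls = triage.classes.loc[table.feature_ids].to_numpy()
    if target_class == "CONTAMINANT":
        mask = np.isin(cls, CONTAMINANT_CLASSES)
    else:
        mask = cls == target_class
    depths = table.counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(depths > 0, table.counts[mask].sum(axis=0) / depths, 0.0)
    res = spearman_correlation(depths, rel)
    res.extra["target_class"] = target_class
    res.extra["loess"] = loess_fit(depths, rel, span=span)
    return res


def compare_ratios(profiles: pd.DataFrame, metadata: pd.DataFrame,
                   grouping: str) -> HypothesisTestResult:
    """Kruskal-Wallis across groups of sample ratios + Dunn pairwise
    z-tests with BH adjustment.

    Infinite ratios participate via their ranks (tied at the top); NaN
    ratios (empty samples) are dropped; groups of size < 2 are excluded
    with a warning recorded in ``extra["excluded_groups"]``.
    """
    groups_meta = metadata.loc[profiles.index, grouping]
    values = profiles["ratio"].to_numpy(dtype=float)
    keep = ~np.isnan(values)
    values, labels = values[keep], groups_meta.to_numpy()[keep]
    excluded = []
    group_values = []
    group_names = []
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size < 2:
            excluded.append(str(g))
            continue
        group_values.append(v)
        group_names.append(g)
    if len(group_values) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples each")
    kw = kruskal_wallis(group_values)
    sel = np.isin(labels, group_names)
    pairwise = dunn_test(values[sel], labels[sel])
    return HypothesisTestResult(
        "kruskal-dunn", kw.statistic, kw.p_value, df=kw.df,
        pairwise=pairwise,
        extra={
            "excluded_groups": excluded,
            "group_medians": {
                str(g): float(np.median(v)) for g, v in zip(group_names, group_values)
            },
        },
    )


def box_summary(values) -> dict:
    """Five-number box summary with whiskers at 1.5x the interquartile
    range (clipped to the data), the plotting convention used for ratio
    boxplots."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    finite = v[np.isfinite(v)]
    q1, med, q3 = np.percentile(finite, [25, 50, 75])
    iqr = q3 - q1
    lo = finite[finite >= q1 - 1.5 * iqr].min()
    hi = finite[finite <= q3 + 1.5 * iqr].max()
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(lo), "whisker_high": float(hi),
        "n": int(v.size), "n_infinite": int(np.sum(np.isinf(v))),
    }
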