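"""Contaminant triage of ASV features in low-biomass 16S studies.

Features are partitioned exclusively into three classes with a fixed
precedence cascade:

1. ``HOST_GDNA`` — the host rule fires: the feature hit a host eukaryote
   genome, or it has no 16S reference hit *and* a classifier confidence
   below 10%.
2. ``TECHNICAL_CONTAMINANT`` — among the remaining features, a
   prevalence test (enrichment of presence in no-template blanks, exact
   one-sided Fisher) or a frequency test (relative abundance inversely
   proportional to library depth, the signature of a constant-mass
   contaminant) is significant at p < 0.1 in any (batch x source)
   stratum.  Fecal strata use both tests; brain strata use the
   prevalence test only.  Features observed exclusively in blanks are
   also technical.
3. ``AMPLICON`` — everything else; the substrate of downstream analyses.

The frequency statistic compares two fixed-slope regressions of
log10 relative abundance on log10 depth over the samples where the
feature is present: slope -1 (contaminant: constant absolute template)
versus slope 0 (true amplicon: constant proportion), via the F ratio of
their residual sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    FeatureTable,
    HypothesisTestResult,
    ValidationError,
    validate_annotations,
    validate_metadata,
)
from ._stats import spearman_correlation

HOST_GDNA = "HOST_GDNA"
TECHNICAL_CONTAMINANT = "TECHNICAL_CONTAMINANT"
AMPLICON = "AMPLICON"


@dataclass
class TriageConfig:
    confidence_threshold: float = 0.10  # host rule: low-confidence cutoff
    p_threshold: float = 0.10  # contaminant call threshold for both tests
    min_present: int = 4  # minimum present samples for the frequency test
    presence_min_count: int = 1
    frequency_method: str = "fixed_slope_f"  # or "spearman"


@dataclass
class TriageResult:
    """Exclusive feature partition with per-test minimum p-values."""

    classes: pd.Series  # feature -> class
    prevalence_p: pd.Series  # min over applicable strata; NaN if none
    frequency_p: pd.Series
    config: TriageConfig
    strata: list = field(default_factory=list)  # (batch, source) pairs tested

    def summary(self) -> dict:
        counts = self.classes.value_counts().to_dict()
        return {cls: int(counts.get(cls, 0)) for cls in (HOST_GDNA, TECHNICAL_CONTAMINANT, AMPLICON)}

    def features_in_class(self, cls: str) -> list[str]:
        return list(self.classes.index[self.classes == cls])


def classify_host(host_hit, has_16s_hit, confidence, confidence_threshold: float = 0.10):
    """Host-gDNA rule: genome hit, or no 16S hit with classifier
    confidence below the threshold.  Vectorized over array inputs."""
    host_hit = np.asarray(host_hit, dtype=bool)
    has_16s_hit = np.asarray(has_16s_hit, dtype=bool)
    confidence = np.asarray(confidence, dtype=float)
    out = host_hit | (~has_16s_hit & (confidence < confidence_threshold))
    return bool(out) if out.ndim == 0 else out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def kmer_host_screen(feature_sequence: str, host_reference, k: int = 31) -> bool:
    """Exact k-mer containment screen against a host reference.

    True iff any length-*k* substring of the feature, on either strand,
    occurs in the reference sequence set.  A lightweight alternative to
    an alignment search when nucleotide sequences are available.
    """
    seq = feature_sequence.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    ref_kmers: set[str] = set()
    for ref in host_reference:
        ref = ref.upper()
        for i in range(len(ref) - k + 1):
            ref_kmers.add(ref[i : i + k])
    if not ref_kmers:
        return False
    rc = seq.translate(_COMPLEMENT)[::-1]
    for s in (seq, rc):
        for i in range(len(s) - k + 1):
            if s[i : i + k] in ref_kmers:
                return True
    return False


def prevalence_test(presence_in_blanks: tuple, presence_in_samples: tuple) -> HypothesisTestResult:
    """One-sided exact test for enrichment of presence in blanks.

    Fisher's exact test on the 2x2 presence table, alternative: presence
    more frequent in blanks.  The statistic is the sample odds ratio with
    a 0.5 continuity correction when any margin contains a zero.
    """
    b_pos, b_tot = presence_in_blanks
    s_pos, s_tot = presence_in_samples
    if b_tot < 1 or s_tot < 1:
        raise ValueError("totals must be >= 1")
    a, b = b_pos, b_tot - b_pos
    c, d = s_pos, s_tot - s_pos
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return HypothesisTestResult(
        "prevalence-fisher", float(odds), float(p),
        extra={"blanks": presence_in_blanks, "samples": presence_in_samples},
    )


def _prevalence_p_vector(blank_presence: np.ndarray, sample_presence: np.ndarray,
                         n_blanks: int, n_samples: int) -> np.ndarray:
    """Vectorized one-sided Fisher p across features.

    P(X >= b_pos) for X ~ Hypergeom(N = n_blanks + n_samples,
    K = total positives, n = n_blanks)."""
    total_pos = blank_presence + sample_presence
    n_total = n_blanks + n_samples
    return stats.hypergeom.sf(blank_presence - 1, n_total, total_pos, n_blanks)


def frequency_test(feature_counts, library_depths, min_present: int = 4,
                   method: str = "fixed_slope_f") -> HypothesisTestResult:
    """Depth-dependence test for a single feature.

    Restricted to the samples where the feature is present.  In
    log10-log10 space two fixed-slope, free-intercept models of relative
    abundance versus depth are compared: slope -1 (contaminant) and
    slope 0 (amplicon).  The p-value is the upper tail of
    ``F(n-1, n-1)`` at ``SS_0 / SS_c``; small p means contaminant-like.

    ``method="spearman"`` gives a one-sided Spearman alternative
    (negative correlation of relative abundance with depth).
    """
    counts = np.asarray(feature_counts, dtype=float)
    depths = np.asarray(library_depths, dtype=float)
    if np.any(depths[counts > 0] <= 0):
        raise ValueError("library depths must be positive where the feature is present")
    present = counts > 0
    n = int(present.sum())
    if n < min_present:
        return HypothesisTestResult(
            "frequency", np.nan, np.nan, extra={"applicable": False, "n_present": n}
        )
    y = np.log10(counts[present] / depths[present])
    x = np.log10(depths[present])
    if method == "spearman":
        res = spearman_correlation(x, y)
        # one-sided: contaminant-like iff decreasing
        p = res.p_value / 2 if res.statistic < 0 else 1 - res.p_value / 2
        return HypothesisTestResult(
            "frequency-spearman", res.statistic, float(p),
            extra={"applicable": True, "n_present": n},
        )
    resid_c = (y + x) - (y + x).mean()  # model y = a - x
    resid_0 = y - y.mean()  # model y = b
    ss_c = float(resid_c @ resid_c)
    ss_0 = float(resid_0 @ resid_0)
    if ss_c == 0.0:
        p = 0.0 if ss_0 > 0 else 1.0
        f = np.inf if ss_0 > 0 else 1.0
    else:
        f = ss_0 / ss_c
        p = float(stats.f.sf(f, n - 1, n - 1))
    return HypothesisTestResult(
        "frequency-f", float(f), float(p),
        df=(n - 1, n - 1),
        extra={"applicable": True, "n_present": n, "ss_contaminant": ss_c, "ss_null": ss_0},
    )


def triage_features(table: FeatureTable, metadata: pd.DataFrame,
                    annotations: pd.DataFrame,
                    config: TriageConfig | None = None) -> TriageResult:
    """Run the full triage cascade.  Deterministic.

    Strata are (batch x source) cells of the non-blank samples; blanks
    are matched to strata by their batch label.  A stratum's prevalence
    test applies when it has at least one matched blank; its frequency
    test applies only to fecal strata.  Stratum results combine by
    "any test significant".
    """
    config = config or TriageConfig()
    validate_metadata(metadata, table)
    validate_annotations(annotations, table)
    ann = annotations.loc[table.feature_ids]

    classes = pd.Series(AMPLICON, index=table.feature_ids, name="class")
    host_mask = classify_host(
        ann["host_hit"].to_numpy(), ann["has_16s_hit"].to_numpy(),
        ann["confidence"].to_numpy(), config.confidence_threshold,
    )
    classes[host_mask] = HOST_GDNA

    counts = table.counts
    depths = counts.sum(axis=0)
    meta = metadata.loc[table.sample_ids]
    is_blank = (meta["source"] == "blank").to_numpy()
    presence = counts >= config.presence_min_count

    prevalence_p = pd.Series(np.nan, index=table.feature_ids, name="prevalence_p")
    frequency_p = pd.Series(np.nan, index=table.feature_ids, name="frequency_p")
    strata = []
    candidates = ~host_mask

    for (batch, source), sub in meta[~is_blank].groupby(["batch", "source"], observed=True):
        cols = np.array([table.sample_ids.index(s) for s in sub.index])
        blank_cols = np.flatnonzero(is_blank & (meta["batch"] == batch).to_numpy())
        strata.append((batch, source))
        if blank_cols.size > 0:
            b_pos = presence[:, blank_cols].sum(axis=1)
            s_pos = presence[:, cols].sum(axis=1)
            p_vec = _prevalence_p_vector(b_pos, s_pos, blank_cols.size, cols.size)
            prevalence_p[:] = np.fmin(prevalence_p.to_numpy(), p_vec)  # NaN-aware min
        if source == "fecal":
            stratum_depths = depths[cols]
            for i in np.flatnonzero(candidates):
                if presence[i, cols].sum() < config.min_present:
                    continue
                res = frequency_test(
                    counts[i, cols], stratum_depths,
                    min_present=config.min_present, method=config.frequency_method,
                )
                if res.extra.get("applicable"):
                    prev = frequency_p.iloc[i]
                    if np.isnan(prev) or res.p_value < prev:
                        frequency_p.iloc[i] = res.p_value

    tech = candidates & (
        (prevalence_p.to_numpy() < config.p_threshold)
        | (frequency_p.to_numpy() < config.p_threshold)
    )
    # observed only in blanks -> technical
    in_blanks = presence[:, is_blank].any(axis=1) if is_blank.any() else np.zeros(len(table.feature_ids), bool)
    in_samples = presence[:, ~is_blank].any(axis=1)
    tech |= candidates & in_blanks & ~in_samples
    classes[tech] = TECHNICAL_CONTAMINANT

    # the host rule takes precedence; mask test p-values for host features
    prevalence_p[host_mask] = np.nan
    frequency_p[host_mask] = np.nan
    return TriageResult(classes, prevalence_p, frequency_p, config, strata)
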