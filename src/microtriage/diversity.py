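"""Repeated-rarefaction alpha and beta diversity.

Alpha: Shannon index (natural log by default) and observed-feature
counts per rarefaction replicate, compared by crossed two-way ANOVA
(implant status x treatment, type-II sums of squares) with Tukey HSD
contrasts.  Beta: unweighted UniFrac distances on presence sets per
replicate, principal coordinates (Gower double-centering), and
PERMANOVA with seeded label permutations; replicate p-values are
Benjamini-Hochberg adjusted and both the largest adjusted and the
smallest unadjusted p are reported.

UniFrac and PERMANOVA are computed directly (one post-order presence
propagation over the tree; Anderson's pseudo-F from the distance
matrix) rather than delegated, so they can be validated against
independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import DistanceMatrix, FeatureTable, HypothesisTestResult
from ._stats import bh_adjust

# ---------------------------------------------------------------------------
# rarefaction


def rarefy(sample_counts, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector to *depth* reads without replacement
    (multivariate hypergeometric); deterministic given *seed*."""
    counts = np.asarray(sample_counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads < rarefaction depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefy_table(table: FeatureTable, depth: int, seed=None) -> FeatureTable:
    """Rarefy every sample of a table to a common depth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    totals = table.counts.sum(axis=0)
    low = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if low:
        raise ValueError(f"samples below rarefaction depth {depth}: {low}")
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return FeatureTable(out, list(table.feature_ids), list(table.sample_ids))


@dataclass
class RarefactionEnsemble:
    """Seeded collection of equal-depth rarefied tables.

    ``depth=None`` uses the minimum library depth of the table (the
    convention of repeated-rarefaction workflows).  Iterating ``tables()``
    twice with the same seed yields identical replicates.
    """

    table: FeatureTable
    n_reps: int = 500
    depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth is None:
            self.depth = int(self.table.counts.sum(axis=0).min())
        if self.depth < 1:
            raise ValueError("rarefaction depth must be >= 1")

    def tables(self):
        children = np.random.SeedSequence(self.seed).spawn(self.n_reps)
        for child in children:
            yield rarefy_table(self.table, self.depth, np.random.default_rng(child))


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(counts, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over taxa with p_i > 0.

    Natural log by default; pass ``base=2`` for bits.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base else h


def observed_features(counts) -> int:
    """Number of taxa with a nonzero count."""
    return int(np.count_nonzero(np.asarray(counts)))


def expected_observed_features(counts, depth: int) -> float:
    """Analytic expectation of observed features after rarefaction to
    *depth*: sum_i [1 - C(N - n_i, d) / C(N, d)]."""
    counts = np.asarray(counts, dtype=np.int64)
    n_total = int(counts.sum())

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    probs = np.zeros(counts.size)
    rest = n_total - counts
    ok = rest >= depth
    probs[ok] = np.exp(log_choose(rest[ok], depth) - log_choose(n_total, depth))
    return float(np.sum((counts > 0) * (1.0 - probs)))


def two_way_anova(data: pd.DataFrame, response: str, factor_a: str, factor_b: str,
                  interaction: bool = True) -> pd.DataFrame:
    """Crossed two-way fixed-effects ANOVA with type-II sums of squares.

    Returns the statsmodels ANOVA table (rows: the two main effects, the
    interaction when requested, and the residual).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    op = "*" if interaction else "+"
    model = smf.ols(f"{response} ~ C({factor_a}) {op} C({factor_b})", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def alpha_ensemble(table: FeatureTable, metadata: pd.DataFrame, n_reps: int = 500,
                   depth: int | None = None, seed: int = 0) -> dict:
    """Replicate-level Shannon/observed-feature metrics with two-way
    ANOVA (implant_status x treatment, type II) and Tukey HSD contrasts.

    Returns per-sample means over replicates, the ANOVA tables, and
    Tukey frames on (status/treatment) cell labels.  A constant response
    yields p = 1 by convention; if the design has an empty cell the
    interaction is dropped (noted in ``warnings``).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    ensemble = RarefactionEnsemble(table, n_reps=n_reps, depth=depth, seed=seed)
    rows = []
    for rep, rt in enumerate(ensemble.tables()):
        for j, s in enumerate(rt.sample_ids):
            col = rt.counts[:, j]
            rows.append((rep, s, shannon(col), observed_features(col)))
    long = pd.DataFrame(rows, columns=["replicate", "sample_id", "shannon", "observed"])
    long["implant_status"] = metadata.loc[long["sample_id"], "implant_status"].to_numpy()
    long["treatment"] = metadata.loc[long["sample_id"], "treatment"].to_numpy()
    long["cell"] = long["implant_status"] + "/" + long["treatment"]

    per_sample = long.groupby("sample_id")[["shannon", "observed"]].mean()
    per_sample = per_sample.reindex(table.sample_ids)

    cells = long.drop_duplicates("sample_id").groupby(
        ["implant_status", "treatment"], observed=True
    ).size().unstack()
    full_design = cells.notna().to_numpy().all() if cells.size else False
    warnings = []
    anova, tukey = {}, {}
    for metric in ("shannon", "observed"):
        if long[metric].std() == 0:
            anova[metric] = None
            warnings.append(f"{metric}: constant response, p defined as 1")
            continue
        if not full_design and "interaction dropped (empty design cell)" not in warnings:
            warnings.append("interaction dropped (empty design cell)")
        anova[metric] = two_way_anova(long, metric, "implant_status", "treatment",
                                      interaction=full_design)
        res = pairwise_tukeyhsd(long[metric].to_numpy(), long["cell"].to_numpy())
        tukey[metric] = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return {
        "per_sample": per_sample, "replicates": long, "anova": anova,
        "tukey": tukey, "depth": ensemble.depth, "n_reps": n_reps,
        "warnings": warnings,
    }


# ---------------------------------------------------------------------------
# unweighted UniFrac


@dataclass
class TreeIndex:
    """Flattened branch structure of a midpoint-rooted tree.

    ``leaf_matrix[b, t]`` is True when leaf *t* descends through branch
    *b*; ``lengths[b]`` is that branch's length.
    """

    taxa: list[str]
    lengths: np.ndarray
    leaf_matrix: np.ndarray  # (n_branches, n_taxa) bool
    taxon_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxon_index = {t: i for i, t in enumerate(self.taxa)}


def index_tree(tree: dendropy.Tree, midpoint_root: bool = True) -> TreeIndex:
    """Midpoint-root a copy of *tree* and flatten it for UniFrac."""
    work = tree.clone(depth=1)
    if midpoint_root:
        work.reroot_at_midpoint(update_bipartitions=True)
    # a taxon may sit on an internal node (e.g. when the midpoint falls
    # exactly on a labelled node); it then subtends no branch of its own
    taxa = [nd.taxon.label for nd in work.preorder_node_iter() if nd.taxon is not None]
    tindex = {t: i for i, t in enumerate(taxa)}
    lengths, rows = [], []
    # post-order presence propagation: each node's taxon set is its own
    # taxon plus the union of its children's
    node_leafset: dict = {}
    for node in work.postorder_node_iter():
        vec = np.zeros(len(taxa), dtype=bool)
        if node.taxon is not None:
            vec[tindex[node.taxon.label]] = True
        for child in node.child_nodes():
            vec |= node_leafset[id(child)]
        node_leafset[id(node)] = vec
        if node.parent_node is not None:  # the root has no branch
            lengths.append(float(node.edge.length or 0.0))
            rows.append(vec)
    return TreeIndex(taxa, np.asarray(lengths), np.asarray(rows))


def unweighted_unifrac(presence_a, presence_b, tree) -> float:
    """Unweighted UniFrac between two taxon presence sets.

    Fraction of branch length unique to one sample among the branch
    length leading to any observed taxon; the tree is midpoint-rooted
    first.  *tree* may be a dendropy Tree or a prebuilt TreeIndex.
    """
    index = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    a, b = set(presence_a), set(presence_b)
    if not a | b:
        raise ValueError("both presence sets are empty")
    missing = sorted((a | b) - set(index.taxa))
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    pres = np.zeros((2, len(index.taxa)), dtype=bool)
    for t in a:
        pres[0, index.taxon_index[t]] = True
    for t in b:
        pres[1, index.taxon_index[t]] = True
    dm = unifrac_matrix(pres, index.taxa, index)
    return float(dm.values[0, 1])


def unifrac_matrix(presence: np.ndarray, taxa: list[str], tree,
                   sample_ids: list[str] | None = None) -> DistanceMatrix:
    """All-pairs unweighted UniFrac for a samples x taxa presence matrix.

    Vectorized over branches: with branch-incidence A (samples x
    branches) and lengths w, the unique length between i and j is
    ``s_i + s_j - 2 (A w A^T)_ij`` and the total observed length is
    ``s_i + s_j - (A w A^T)_ij`` where ``s = A w``.
    """
    index = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    presence = np.asarray(presence, dtype=bool)
    missing = sorted(set(taxa) - set(index.taxa))
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    cols = [index.taxon_index[t] for t in taxa]
    full = np.zeros((presence.shape[0], len(index.taxa)), dtype=bool)
    full[:, cols] = presence
    # branch incidence: does any observed taxon of the sample descend here
    a = (full @ index.leaf_matrix.T.astype(np.int64)) > 0
    aw = a * index.lengths
    cross = aw @ a.T  # sum of shared-branch... (i,j): sum_b w_b a_ib a_jb
    s = a @ index.lengths
    unique = s[:, None] + s[None, :] - 2 * cross
    union = s[:, None] + s[None, :] - cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, unique / union, 0.0)
    np.fill_diagonal(d, 0.0)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(presence.shape[0])]
    return DistanceMatrix(list(sample_ids), np.clip(d, 0.0, 1.0))


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    """PCoA output: eigenvalues (descending, negatives retained),
    coordinates for positive axes only, and the proportion of variance
    explained relative to the sum of positive eigenvalues."""

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates via Gower double-centering of -D^2/2."""
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals).max()) if n else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return OrdinationResult(
        eigenvalues=eigvals,
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=axes),
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray,
              ss_total: float) -> float:
    n = d2.shape[0]
    ss_within = 0.0
    for g in groups:
        mask = (labels == g).astype(float)
        n_g = mask.sum()
        ss_within += float(mask @ d2 @ mask) / (2.0 * n_g)
    a = groups.size
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, labels, n_permutations: int = 10000,
              seed: int = 0) -> HypothesisTestResult:
    """Anderson's PERMANOVA computed directly from the distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), so the
    smallest attainable p is 1/(1 + n_permutations).
    """
    labels = np.asarray(labels)
    if labels.size != len(dm.labels):
        raise ValueError("labels length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise ValueError(f"singleton groups not allowed: {small}")
    d2 = dm.values**2
    n = d2.shape[0]
    ss_total = float(d2.sum()) / (2.0 * n)
    f_obs = _pseudo_f(d2, labels, groups, ss_total)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, groups, ss_total) >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return HypothesisTestResult(
        "permanova", float(f_obs), float(p),
        df=(int(groups.size - 1), int(n - groups.size)),
        extra={"n_permutations": n_permutations, "groups": groups.tolist()},
    )


# ---------------------------------------------------------------------------
# beta ensemble


def beta_ensemble(table: FeatureTable, tree, metadata: pd.DataFrame,
                  group_col: str = "implant_status", n_reps: int = 500,
                  depth: int | None = None, seed: int = 0,
                  n_permutations: int = 10000) -> dict:
    """Per-replicate UniFrac -> PERMANOVA over a rarefaction ensemble.

    BH-adjusts the replicate p-values (one family per call) and reports
    both the largest adjusted and the smallest unadjusted p.  The first
    replicate's distance matrix and PCoA are returned for plotting.
    """
    index = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    labels = metadata.loc[table.sample_ids, group_col].to_numpy()
    ensemble = RarefactionEnsemble(table, n_reps=n_reps, depth=depth, seed=seed)
    perm_seeds = np.random.SeedSequence((seed, 1)).generate_state(n_reps) % (2**31)
    p_values, f_values = [], []
    first = None
    for rep, rt in enumerate(ensemble.tables()):
        pres = (rt.counts > 0).T
        dm = unifrac_matrix(pres, rt.feature_ids, index, sample_ids=rt.sample_ids)
        res = permanova(dm, labels, n_permutations=n_permutations, seed=int(perm_seeds[rep]))
        p_values.append(res.p_value)
        f_values.append(res.statistic)
        if first is None:
            first = {"distance_matrix": dm, "pcoa": pcoa(dm)}
    p_values = np.asarray(p_values)
    p_adjusted = bh_adjust(p_values)
    return {
        "p_values": p_values, "p_adjusted": p_adjusted,
        "pseudo_f": np.asarray(f_values),
        "max_adjusted_p": float(p_adjusted.max()),
        "min_raw_p": float(p_values.min()),
        "first_replicate": first, "depth": ensemble.depth,
        "n_reps": n_reps, "n_permutations": n_permutations,
    }
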