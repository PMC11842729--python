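"""Shared statistical helpers: BH adjustment, Spearman with small-n exact
p-values, Dunn's post-hoc test, and a local-linear LOESS smoother."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import HypothesisTestResult


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (one family per call)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def spearman_correlation(x, y, exact_max_n: int = 9) -> HypothesisTestResult:
    """Two-sided Spearman rank correlation.

    Tie-corrected rho (Pearson correlation of ranks).  For n <= *exact_max_n*
    the p-value is exact, from full enumeration of rank permutations of one
    margin; otherwise the usual t approximation is used.  A constant margin
    is degenerate: rho is reported as 0 with p = 1 and a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return HypothesisTestResult(
            "spearman", 0.0, 1.0, df=n - 2, extra={"degenerate": True, "n": n}
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exact permutation null: enumerate all n! orderings of one margin
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        num = ry_c[perms] @ rx_c
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        rhos = num / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "spearman-exact"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), n - 2)) if abs(rho) < 1 else 0.0
        method = "spearman"
    return HypothesisTestResult(method, rho, min(1.0, p), df=n - 2, extra={"n": n})


def kruskal_wallis(groups: list[np.ndarray]) -> HypothesisTestResult:
    """Tie-corrected Kruskal-Wallis H test on >= 2 groups.

    Infinite values are legal (they rank at the top).  Identical value
    multisets across groups yield H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(_rank(values)) == 0:  # all values tied
        return HypothesisTestResult("kruskal-wallis", 0.0, 1.0, df=len(groups) - 1)
    h, p = stats.kruskal(*groups)
    return HypothesisTestResult("kruskal-wallis", float(h), float(p), df=len(groups) - 1)


def dunn_test(values, group_labels) -> pd.DataFrame:
    """Two-sided Dunn post-hoc z-tests on mean ranks with BH adjustment.

    Uses the tie-corrected pooled-rank variance
    ``(N(N+1)/12 - T) * (1/n_i + 1/n_j)`` with ``T = sum(t^3 - t) / (12(N-1))``.
    Returns one row per unordered group pair.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    ranks = _rank(values)
    n_total = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    groups = pd.unique(group_labels)
    mean_ranks = {g: ranks[group_labels == g].mean() for g in groups}
    sizes = {g: int((group_labels == g).sum()) for g in groups}
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        se = math.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def loess_fit(x, y, span: float = 0.75, eval_x=None) -> pd.DataFrame:
    """Local linear (degree-1) LOESS with tricube weights, no robustness
    iterations.

    Returns a frame with columns ``x``, ``fitted`` and ``se`` where ``se`` is
    the pointwise normal-approximation standard error of the local weighted
    least-squares fit (residual scale estimated globally).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if eval_x is None:
        eval_x = x
    eval_x = np.asarray(eval_x, dtype=float)
    n = x.size
    k = max(2, int(math.ceil(span * n)))
    fitted = np.empty(eval_x.size)
    l_norms = np.empty(eval_x.size)  # ||l(x0)|| for the variance of the fit
    for i, x0 in enumerate(eval_x):
        d = np.abs(x - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            u = np.clip(d / dmax, 0, 1)
            w = (1 - u**3) ** 3
        # weighted linear fit y ~ 1 + (x - x0); fitted value is the intercept
        sw = w.sum()
        xc = x - x0
        sx = float(w @ xc)
        sxx = float(w @ (xc * xc))
        sy = float(w @ y)
        sxy = float(w @ (xc * y))
        det = sw * sxx - sx * sx
        if det <= 0:
            li = w / sw
        else:
            # equivalent-kernel weights for the intercept
            li = w * (sxx - sx * xc) / det
        fitted[i] = float(li @ y)
        l_norms[i] = float(np.sqrt(li @ li))
    # global residual scale from the fit at the observed points
    resid = y - np.interp(x, *_sorted(eval_x, fitted)) if eval_x is not x else y - fitted
    dof = max(1, n - 2)
    sigma = math.sqrt(float(resid @ resid) / dof)
    return pd.DataFrame({"x": eval_x, "fitted": fitted, "se": sigma * l_norms})


def _sorted(x, y):
    order = np.argsort(x)
    return x[order], y[order]
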