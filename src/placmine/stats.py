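"""Univariate dual-omics screening statistics.

Per-feature case/control testing with a variance-homogeneity gate:
a feature is called significant only when Levene's test does NOT reject
variance equality (p >= alpha) and the Benjamini-Hochberg adjusted pooled
Student t-test q-value falls below the FDR threshold.  The module also
covers the cohort-description tests (Fisher exact, Wilcoxon rank-sum),
cross-omics overlap at the gene level, methylation-expression correlation,
rank concordance between screens, and hierarchical sample clustering.

All per-feature computations are vectorized across the feature axis so a
full array-scale screen is a single pass of numpy operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "levene_test",
    "student_t_test",
    "bh_adjust",
    "run_differential",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "cross_omics_overlap",
    "meth_expr_correlation",
    "kendall_concordance",
    "hcluster_order",
]

log = logging.getLogger(__name__)

ALPHA_LEVENE = 0.05
Q_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# per-feature tests (vectorized cores; scalar wrappers keep the 1-D contract)

def _levene_matrix(xa: np.ndarray, xb: np.ndarray, center: str = "mean") -> np.ndarray:
    """Levene p-value per row of two (features x samples) blocks.

    W is the one-way ANOVA F statistic on absolute deviations from the
    group center (mean for the original test, median for the
    Brown-Forsythe variant), referred to F(k-1, N-k).
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    loc = np.mean if center == "mean" else np.median
    za = np.abs(xa - loc(xa, axis=1, keepdims=True))
    zb = np.abs(xb - loc(xb, axis=1, keepdims=True))
    ma, mb = za.mean(axis=1), zb.mean(axis=1)
    grand = (za.sum(axis=1) + zb.sum(axis=1)) / (na + nb)
    between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    within = ((za - ma[:, None]) ** 2).sum(axis=1) + ((zb - mb[:, None]) ** 2).sum(axis=1)
    dfb, dfw = 1, na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (between / dfb) / (within / dfw)
    p = sps.f.sf(W, dfb, dfw)
    # all deviations zero in both groups (constant rows): variances equal
    degenerate = (within == 0) & (between == 0)
    p = np.where(degenerate, 1.0, p)
    return p


def levene_test(group_a, group_b, center: str = "mean") -> float:
    """Two-group Levene variance-homogeneity p-value."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    return float(_levene_matrix(a, b, center=center)[0])


def _t_matrix(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sided Student t per row; df = na + nb - 2."""
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    p = 2.0 * sps.t.sf(np.abs(t), df)
    zero_var = pooled == 0
    equal = zero_var & (ma == mb)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    # zero pooled variance with unequal means: degenerate feature, flag NaN
    bad = zero_var & (ma != mb)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return t, p


def student_t_test(group_a, group_b) -> tuple[float, float]:
    """Equal-variance (pooled) two-sided Student t-test.

    The pooled variant is deliberate: features only reach this test after
    passing the Levene homogeneity gate.  Raises on a constant pair of
    groups with unequal means (no variance to test against).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    t, p = _t_matrix(a, b)
    if np.isnan(t[0]):
        raise ValueError("zero pooled variance with unequal means: degenerate feature")
    return float(t[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_differential(
    matrix: pd.DataFrame,
    groups,
    case_label: str = "case",
    control_label: str = "control",
    layer: str = "omics",
    alpha_levene: float = ALPHA_LEVENE,
    q_threshold: float = Q_THRESHOLD,
    levene_center: str = "mean",
) -> pd.DataFrame:
    """Per-feature screen of a features x samples matrix.

    Returns one row per tested feature with ``levene_p``, ``t_stat``,
    ``p_value``, BH ``q_value`` (adjusted across all tested features of
    this layer), ``fold_change`` (case mean / control mean, NaN when the
    control mean is zero), ``diff`` (case mean - control mean) and the
    conjunctive ``significant`` flag.  Features containing missing values
    are excluded and logged.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    labels = set(groups.unique())
    if labels != {case_label, control_label}:
        raise ValueError(
            f"expected exactly the two group labels {case_label!r}/{control_label!r}, got {sorted(labels)}"
        )
    complete = matrix.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("%s: excluding %d features with missing values", layer, n_dropped)
    m = matrix.loc[complete]
    xa = m.loc[:, groups == case_label].to_numpy(dtype=float)
    xb = m.loc[:, groups == control_label].to_numpy(dtype=float)

    levene_p = _levene_matrix(xa, xb, center=levene_center)
    t, p = _t_matrix(xa, xb)
    testable = ~np.isnan(p)
    if (~testable).any():
        log.warning("%s: %d degenerate constant features flagged", layer, int((~testable).sum()))
    q = np.full_like(p, np.nan)
    q[testable] = bh_adjust(p[testable])

    case_mean = xa.mean(axis=1)
    ctrl_mean = xb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(ctrl_mean != 0, case_mean / ctrl_mean, np.nan)
    significant = testable & (levene_p >= alpha_levene) & (q < q_threshold)
    return pd.DataFrame(
        {
            "layer": layer,
            "levene_p": levene_p,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "fold_change": fc,
            "diff": case_mean - ctrl_mean,
            "significant": significant,
        },
        index=pd.Index(m.index, name="feature"),
    )


# ---------------------------------------------------------------------------
# cohort-description tests

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Point-probability-sum convention: the p-value is the total
    hypergeometric probability of all tables (with the observed margins)
    whose point probability does not exceed the observed one, with a 1e-7
    relative tolerance on that comparison.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b, c, d = (int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - k + 1) - gammaln(n - r1 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when the combined sample size is at most 20
    and there are no ties; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# cross-omics integration

@dataclass
class GeneCorrelation:
    r: float
    p: float
    significant: bool
    defined: bool


def cross_omics_overlap(
    meth_stats: pd.DataFrame,
    expr_stats: pd.DataFrame,
    feature_gene_map: pd.Series,
) -> pd.DataFrame:
    """Genes significantly altered in BOTH omics layers.

    For each such gene reports significant/total feature counts per layer
    and majority direction labels (hypo/hyper-methylated from the sign of
    the methylation delta, over/under-expressed from the expression
    delta), mirroring the "(sites count/total)" presentation.
    """
    fmap = feature_gene_map

    def per_layer(stats: pd.DataFrame):
        known = stats.index.intersection(fmap.index)
        missing_sig = stats.index.difference(fmap.index).intersection(
            stats.index[stats["significant"]]
        )
        if len(missing_sig):
            log.warning("%d significant features absent from the gene map; ignored",
                        len(missing_sig))
        sub = stats.loc[known].copy()
        sub["gene"] = fmap.loc[known].to_numpy()
        total = sub.groupby("gene").size()
        sig = sub[sub["significant"]].groupby("gene").size()
        direction = sub[sub["significant"]].groupby("gene")["diff"].apply(
            lambda d: float(np.sign(d).sum())
        )
        return total, sig, direction

    m_total, m_sig, m_dir = per_layer(meth_stats)
    e_total, e_sig, e_dir = per_layer(expr_stats)
    genes = sorted(set(m_sig.index) & set(e_sig.index))
    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g,
                "n_meth_sig": int(m_sig[g]),
                "n_meth_total": int(m_total[g]),
                "n_expr_sig": int(e_sig[g]),
                "n_expr_total": int(e_total[g]),
                "meth_direction": "hypermethylated" if m_dir[g] > 0 else "hypomethylated",
                "expr_direction": "overexpressed" if e_dir[g] > 0 else "underexpressed",
            }
        )
    cols = ["gene", "n_meth_sig", "n_meth_total", "n_expr_sig", "n_expr_total",
            "meth_direction", "expr_direction"]
    return pd.DataFrame(rows, columns=cols).set_index("gene") if rows else (
        pd.DataFrame(columns=cols[1:], index=pd.Index([], name="gene"))
    )


def meth_expr_correlation(
    gene: str,
    meth_stats: pd.DataFrame,
    expr_stats: pd.DataFrame,
    methylome: pd.DataFrame,
    transcriptome: pd.DataFrame,
    feature_gene_map: pd.Series,
    alpha: float = 0.05,
) -> GeneCorrelation:
    """Pearson correlation between a gene's mean significant methylation
    and mean significant expression across all samples."""
    sig_m = [f for f in meth_stats.index[meth_stats["significant"]]
             if feature_gene_map.get(f) == gene]
    sig_e = [f for f in expr_stats.index[expr_stats["significant"]]
             if feature_gene_map.get(f) == gene]
    if not sig_m or not sig_e:
        raise ValueError(f"{gene}: needs >=1 significant feature in each layer")
    x = methylome.loc[sig_m].mean(axis=0).to_numpy()
    y = transcriptome.loc[sig_e].mean(axis=0).to_numpy()
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return GeneCorrelation(np.nan, np.nan, False, False)
    r, p = sps.pearsonr(x, y)
    return GeneCorrelation(float(r), float(p), bool(p < alpha), True)


def kendall_concordance(
    stats_full: pd.DataFrame,
    stats_subset: pd.DataFrame,
    on: str = "t_stat",
) -> tuple[float, float]:
    """Kendall tau-b between per-feature statistics of two screens
    (e.g. the full cohort vs the gestational-age-restricted subset)."""
    shared = stats_full.index.intersection(stats_subset.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared features")
    x = stats_full.loc[shared, on].to_numpy(dtype=float)
    y = stats_subset.loc[shared, on].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    res = sps.kendalltau(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# sample clustering

def hcluster_order(
    matrix: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
) -> dict:
    """Agglomerative clustering of samples on row-standardized features.

    Returns the linkage matrix, the dendrogram leaf order (sample ids) and
    a two-cluster cut label per sample.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN")
    if matrix.shape[1] < 2 or matrix.shape[0] < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    Z = linkage(z.T, method=method, metric=metric)
    order = [matrix.columns[i] for i in leaves_list(Z)]
    two_cut = fcluster(Z, t=2, criterion="maxclust")
    return {
        "linkage": Z,
        "leaf_order": order,
        "two_cluster": pd.Series(two_cut, index=matrix.columns, name="cluster"),
    }
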