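"""Cluster-wise differential features, chain-length profiles, group stats.

``rank_features`` scores every (cluster, feature) pair one-vs-rest with a
two-sided Wilcoxon rank-sum test (tie-corrected normal approximation by
default, exact enumeration for small groups) and Benjamini-Hochberg
adjustment within each cluster.  ``chain_profile`` summarizes the glycogen
DP ladder per group.  ``compare_groups`` covers the Prism-style designs:
Welch t, one-way ANOVA, two-way ANOVA with Holm-Sidak post-hoc tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from statsmodels.stats.multitest import multipletests

from .carbo_masses import PeakPanel
from .preprocess import FeatureMatrix

__all__ = [
    "rank_features",
    "wilcoxon_rank_sum",
    "chain_profile",
    "ChainProfile",
    "total_glycogen",
    "compare_groups",
    "ordered_heatmap",
]


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments.

    Feasible for small groups only; handles ties through midranks.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= d_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_rank_sum(
    x, y, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of the first sample, p value).  ``asymptotic`` uses
    the tie-corrected normal approximation without continuity correction;
    ``exact`` enumerates assignments (any ties included); ``auto`` picks
    exact when both groups have <= 8 observations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if method == "auto":
        method = "exact" if (n1 <= 8 and n2 <= 8) else "asymptotic"
    if method == "exact":
        return float(u1), float(_rank_sum_exact_p(x, y))
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(u1), 1.0  # all observations tied
    z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(min(p, 1.0))


def rank_features(
    fm_or_values,
    labels,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum per (cluster, feature), BH-adjusted.

    Returns a table with columns cluster, feature, u_stat, p, q,
    log2_fc, mean_in, mean_out, sorted by (cluster, q, -|log2_fc|).
    BH correction runs within each cluster across features.
    """
    if isinstance(fm_or_values, FeatureMatrix):
        values = fm_or_values.values
    else:
        values = pd.DataFrame(fm_or_values)
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise ValueError("labels/pixels length mismatch")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    for cid in uniq:
        if (labels == cid).sum() < 2:
            raise ValueError(f"cluster {cid} has fewer than 2 pixels")

    X = values.to_numpy(dtype=np.float64)
    # pseudo-count for fold changes: half the smallest nonzero value
    nonzero = X[X > 0]
    pseudo = nonzero.min() / 2.0 if nonzero.size else 1e-12

    rows = []
    for cid in uniq:
        inside = labels == cid
        Xi, Xo = X[inside], X[~inside]
        pvals = np.empty(X.shape[1])
        ustats = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            ustats[j], pvals[j] = wilcoxon_rank_sum(
                Xi[:, j], Xo[:, j], method=method
            )
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        mean_in = Xi.mean(axis=0)
        mean_out = Xo.mean(axis=0)
        lfc = np.log2((mean_in + pseudo) / (mean_out + pseudo))
        for j, col in enumerate(values.columns):
            rows.append(
                (cid, col, ustats[j], pvals[j], qvals[j], lfc[j],
                 mean_in[j], mean_out[j])
            )
    out = pd.DataFrame(
        rows,
        columns=["cluster", "feature", "u_stat", "p", "q", "log2_fc",
                 "mean_in", "mean_out"],
    )
    out["_abs_fc"] = out["log2_fc"].abs()
    out = (
        out.sort_values(["cluster", "q", "_abs_fc"],
                        ascending=[True, True, False], kind="stable")
        .drop(columns="_abs_fc")
        .reset_index(drop=True)
    )
    return out


@dataclass
class ChainProfile:
    """Mean +/- SEM of each DP rung per group, plus per-pixel totals."""

    dp: list[int]
    mean: pd.DataFrame        # groups x DP
    sem: pd.DataFrame
    total_by_pixel: np.ndarray
    groups: np.ndarray


def total_glycogen(fm: FeatureMatrix) -> np.ndarray:
    """Per-pixel total glycogen: sum over all glycogen_dp panel features."""
    cols = fm.class_columns("glycogen_dp")
    if not cols:
        raise ValueError("panel has no glycogen_dp features")
    return fm.values[cols].to_numpy().sum(axis=1)


def chain_profile(fm: FeatureMatrix, grouping) -> ChainProfile:
    """Per-group DP-ladder profile (mean +/- SEM over pixels)."""
    grouping = np.asarray(grouping)
    if len(grouping) != fm.n_pixels:
        raise ValueError("grouping length mismatch")
    dp_idx = fm.panel.by_class("glycogen_dp")
    if not dp_idx:
        raise ValueError("panel has no glycogen_dp features")
    dp_entries = [fm.panel.entries[i] for i in dp_idx]
    dps = [e.composition.n_hex for e in dp_entries]
    cols = [str(e.nominal) for e in dp_entries]
    V = fm.values[cols].to_numpy()

    uniq = np.unique(grouping)
    means, sems = [], []
    for g in uniq:
        sel = grouping == g
        if not sel.any():
            raise ValueError(f"group {g!r} is empty")
        sub = V[sel]
        means.append(sub.mean(axis=0))
        sems.append(stats.sem(sub, axis=0) if sel.sum() > 1
                    else np.zeros(V.shape[1]))
    return ChainProfile(
        dp=dps,
        mean=pd.DataFrame(means, index=uniq, columns=dps),
        sem=pd.DataFrame(sems, index=uniq, columns=dps),
        total_by_pixel=V.sum(axis=1),
        groups=grouping,
    )


def _holm_sidak(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="holm-sidak")[1]


def compare_groups(
    values,
    groups,
    design: str = "two_sample_t",
    dp=None,
) -> dict:
    """Prism-style group comparisons.

    two_sample_t  Welch two-tailed t-test (2 groups).
    one_way       one-way ANOVA F test + Holm-Sidak pairwise Welch t post-hoc.
    two_way       two-way ANOVA (group x dp) with interaction + per-dp
                  Holm-Sidak comparisons; needs a crossed layout via ``dp``.
    Returns a dict with the omnibus statistic/p and a ``posthoc`` table where
    applicable.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values/groups length mismatch")
    uniq = list(np.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    per_group = [values[groups == g] for g in uniq]
    if any(len(v) < 2 for v in per_group):
        raise ValueError("each group needs at least 2 observations")

    if design == "two_sample_t":
        if len(uniq) != 2:
            raise ValueError("two_sample_t needs exactly 2 groups")
        t, p = stats.ttest_ind(per_group[0], per_group[1], equal_var=False)
        return {"design": design, "statistic": float(t), "p": float(p),
                "groups": uniq}

    if design == "one_way":
        f, p = stats.f_oneway(*per_group)
        rows = []
        raw = []
        pairs = list(itertools.combinations(range(len(uniq)), 2))
        for a, b in pairs:
            t, pp = stats.ttest_ind(per_group[a], per_group[b],
                                    equal_var=False)
            raw.append(pp)
            rows.append([uniq[a], uniq[b], float(t)])
        adj = _holm_sidak(np.asarray(raw))
        posthoc = pd.DataFrame(
            [r + [raw[i], adj[i]] for i, r in enumerate(rows)],
            columns=["group_a", "group_b", "t", "p", "p_adj"],
        )
        return {"design": design, "statistic": float(f), "p": float(p),
                "groups": uniq, "posthoc": posthoc}

    if design == "two_way":
        if dp is None:
            raise ValueError("two_way design needs the dp factor")
        dp = np.asarray(dp)
        if len(dp) != len(values):
            raise ValueError("dp length mismatch")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame({"y": values, "grp": groups.astype(str),
                           "dp": dp.astype(str)})
        counts = df.groupby(["grp", "dp"]).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise ValueError(f"cell {bad} has fewer than 2 observations")
        model = smf.ols("y ~ C(grp) * C(dp)", data=df).fit()
        table = anova_lm(model, typ=2)
        rows, raw = [], []
        for level in np.unique(dp):
            sel = dp == level
            a = values[sel & (groups == uniq[0])]
            b = values[sel & (groups == uniq[1])] if len(uniq) == 2 else None
            if b is None:
                break
            t, pp = stats.ttest_ind(a, b, equal_var=False)
            raw.append(pp)
            rows.append([level, float(t)])
        posthoc = None
        if rows:
            adj = _holm_sidak(np.asarray(raw))
            posthoc = pd.DataFrame(
                [r + [raw[i], adj[i]] for i, r in enumerate(rows)],
                columns=["dp", "t", "p", "p_adj"],
            )
        return {
            "design": design,
            "anova": table,
            "p_interaction": float(table.loc["C(grp):C(dp)", "PR(>F)"]),
            "p_group": float(table.loc["C(grp)", "PR(>F)"]),
            "groups": uniq,
            "posthoc": posthoc,
        }

    raise ValueError(f"unknown design {design!r}")


def ordered_heatmap(
    matrix, top_k: int = 50, rank_by: np.ndarray | None = None
) -> dict:
    """Row/column orderings for a top-k feature heatmap.

    Hierarchical agglomerative clustering with Euclidean distance and Ward
    linkage on both axes; deterministic (ties resolved by label order via a
    stable pre-sort).  ``rank_by`` selects the top_k columns (higher is
    better); default keeps the first top_k.
    """
    M = pd.DataFrame(matrix)
    if M.isna().any().any():
        raise ValueError("matrix contains NaN")
    if top_k > M.shape[1]:
        raise ValueError(
            f"top_k={top_k} exceeds feature count {M.shape[1]}"
        )
    if rank_by is not None:
        rank_by = np.asarray(rank_by, dtype=np.float64)
        order = np.lexsort((np.arange(M.shape[1]), -rank_by))
        cols = sorted(order[:top_k])
        M = M.iloc[:, cols]
    else:
        M = M.iloc[:, :top_k]

    X = M.to_numpy(dtype=np.float64)

    def _order(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 2:
            return np.arange(data.shape[0])
        Z = linkage(data, method="ward", metric="euclidean")
        Z = optimal_leaf_ordering(Z, data)
        return leaves_list(Z)

    return {
        "row_order": _order(X),
        "col_order": _order(X.T),
        "columns": list(M.columns),
    }
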