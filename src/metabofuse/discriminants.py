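"""Discriminant-feature selection: VIP ranking, ANOVA p-values, rank FDR.

The selection route mirrors the classical chemometrics workflow: rank
variables by VIP, take the top k (default 15), test each candidate across
the season groups by one-way ANOVA, keep candidates with p <= 0.05, rank
those from smallest to largest p and attach the Benjamini-Hochberg critical
value FDR_i = (i/m) x Q (Q = 5% by default), retaining candidates with
FDR <= Q.  Note that (i/m) x Q never exceeds Q, so under this verbatim rule
the FDR column is descriptive rather than a further filter; the standard
BH step-up procedure is available as ``method="bh"`` (and is the package's
recommended inferential mode, applied over all tested variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "rank_vip",
    "feature_pvalues",
    "fdr_rank",
    "bh_stepup",
    "select_discriminants",
    "group_summaries",
]


def rank_vip(model, k: int = 15) -> pd.DataFrame:
    """Top-k variables by VIP (descending; ties broken by variable id)."""
    from .mvda import vip_scores

    if k <= 0:
        raise ValueError("k must be positive")
    vip = vip_scores(model)
    df = pd.DataFrame({"variable": vip.index, "VIP": vip.values})
    df = df.sort_values(["VIP", "variable"], ascending=[False, True], kind="mergesort")
    return df.head(k).reset_index(drop=True)


def feature_pvalues(X: pd.DataFrame, classes) -> pd.Series:
    """One-way ANOVA p-value per variable across the class groups.

    Computed vectorized over all variables; groups need at least 2 samples
    each.  Variables with no between- nor within-group variation get p = 1.
    """
    labels = np.asarray(classes)
    Xm = X.to_numpy(dtype=float)
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(inv)
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    n, k = Xm.shape[0], uniq.size
    # group means via indicator matrix
    G = np.zeros((k, n))
    G[inv, np.arange(n)] = 1.0
    group_sums = G @ Xm
    group_means = group_sums / counts[:, None]
    grand_mean = Xm.mean(axis=0)
    ssb = np.sum(counts[:, None] * (group_means - grand_mean) ** 2, axis=0)
    sst = np.sum((Xm - grand_mean) ** 2, axis=0)
    ssw = sst - ssb
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(ssb <= 1e-300 * np.maximum(sst, 1.0), 1.0, p)  # F = 0 -> p = 1
    p = np.where((ssw <= 0) & (ssb > 0), 0.0, p)
    return pd.Series(p, index=X.columns, name="p_value")


def fdr_rank(pvalues: pd.Series, Q: float = 0.05, alpha: float = 0.05) -> pd.DataFrame:
    """Rank-based FDR table: FDR_i = (i/m) x Q over the p <= alpha set.

    Candidates with p <= ``alpha`` are ranked from smallest to largest
    p-value (i = 1..m, m = number of ranked candidates); each receives the
    Benjamini-Hochberg critical value (i/m) x Q, reported to 3 decimals
    (full precision kept in the ``fdr`` column).  ``retained`` is
    FDR <= Q.  An empty post-filter set yields an empty table.
    """
    p = pd.Series(pvalues).astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    kept = p[p <= alpha].sort_values(kind="mergesort")
    m = len(kept)
    if m == 0:
        return pd.DataFrame(
            {
                "variable": pd.Series(dtype=object),
                "p_value": pd.Series(dtype=float),
                "rank": pd.Series(dtype=int),
                "m": pd.Series(dtype=int),
                "fdr": pd.Series(dtype=float),
                "fdr_reported": pd.Series(dtype=float),
                "retained": pd.Series(dtype=bool),
            }
        )
    ranks = np.arange(1, m + 1)
    fdr = ranks / m * Q
    return pd.DataFrame(
        {
            "variable": kept.index,
            "p_value": kept.values,
            "rank": ranks,
            "m": m,
            "fdr": fdr,
            "fdr_reported": np.round(fdr, 3),
            "retained": fdr <= Q,
        }
    ).reset_index(drop=True)


def bh_stepup(pvalues: pd.Series, Q: float = 0.05) -> pd.Series:
    """Standard Benjamini-Hochberg step-up rejection over all inputs.

    Returns a boolean Series (True = rejected at FDR level Q) aligned with
    the input index; m is the total number of tests.
    """
    p = pd.Series(pvalues).astype(float)
    m = len(p)
    order = p.sort_values(kind="mergesort")
    crit = np.arange(1, m + 1) / m * Q
    passing = order.values <= crit
    k = np.max(np.nonzero(passing)[0]) + 1 if passing.any() else 0
    rejected = pd.Series(False, index=p.index)
    if k:
        rejected[order.index[:k]] = True
    return rejected


def select_discriminants(
    vip_top: pd.DataFrame, fdr_table: pd.DataFrame, universe=None
) -> pd.DataFrame:
    """Intersect the top-VIP set with the FDR-retained set, ordered by p.

    Both inputs must come from the same variable universe; when ``universe``
    is given (the ids of the matrix both were computed from) any id outside
    it raises, catching accidental mixing of tables from different runs.
    """
    vip_ids = set(vip_top["variable"])
    if universe is not None:
        universe = set(universe)
        stray = (vip_ids | set(fdr_table.get("variable", []))) - universe
        if stray:
            raise ValueError(f"ids outside the shared variable universe: {sorted(stray)[:5]}")
    if len(fdr_table) == 0:
        return fdr_table.assign(VIP=pd.Series(dtype=float))
    retained = fdr_table[fdr_table["retained"]]
    out = retained[retained["variable"].isin(vip_ids)].copy()
    vip_map = dict(zip(vip_top["variable"], vip_top["VIP"]))
    out["VIP"] = out["variable"].map(vip_map)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


@dataclass
class GroupSummary:
    """Per-feature seasonal summaries: mean +/- SD, ANOVA, Tukey HSD, boxes."""

    stats: pd.DataFrame      # feature x season rows: mean, sd, n, five-number summary
    anova: pd.DataFrame      # feature rows: F, p
    tukey: pd.DataFrame      # feature x pair rows: adjusted p, mean difference


def group_summaries(X: pd.DataFrame, classes, features) -> GroupSummary:
    """Group statistics for selected features across seasons.

    For each feature: per-season mean, SD and n plus box-plot five-number
    summaries; a one-way ANOVA F and p; and Tukey's HSD adjusted p-values
    over all season pairs (studentized-range based, via statsmodels).
    """
    features = list(features)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    labels = np.asarray(classes)
    pvals = feature_pvalues(X[features], labels)

    stat_rows, tukey_rows, anova_rows = [], [], []
    uniq = list(dict.fromkeys(labels))
    for feat in features:
        x = X[feat].to_numpy(dtype=float)
        for season in uniq:
            g = x[labels == season]
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            stat_rows.append(
                {
                    "variable": feat,
                    "season": season,
                    "n": int(g.size),
                    "mean": float(g.mean()),
                    "sd": float(g.std(ddof=1)),
                    "min": float(g.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(g.max()),
                }
            )
        groups = [x[labels == season] for season in uniq]
        F, _ = stats.f_oneway(*groups)
        anova_rows.append({"variable": feat, "F": float(F), "p_value": float(pvals[feat])})
        if np.all([np.allclose(g, g.mean()) for g in groups]) and np.allclose(x, x.mean()):
            # all groups identical and constant: every pairwise contrast is null
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    tukey_rows.append(
                        {
                            "variable": feat,
                            "group1": uniq[i],
                            "group2": uniq[j],
                            "meandiff": 0.0,
                            "p_adj": 1.0,
                        }
                    )
        else:
            res = pairwise_tukeyhsd(x, labels)
            frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
            for row in frame.to_dict("records"):
                tukey_rows.append(
                    {
                        "variable": feat,
                        "group1": str(row["group1"]),
                        "group2": str(row["group2"]),
                        "meandiff": float(row["meandiff"]),
                        "p_adj": float(row["p-adj"]),
                    }
                )
    return GroupSummary(
        stats=pd.DataFrame(stat_rows),
        anova=pd.DataFrame(anova_rows),
        tukey=pd.DataFrame(tukey_rows),
    )
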