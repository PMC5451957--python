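"""Heat-map summaries, cumulative-use ranking and second-stage regression.

Once a "best" partition is fixed, clusters are characterised by where the
within-cluster median of each pesticide's continuous use estimate falls
among the population quartile cut points: "very low" (first quartile)
through "very high" (fourth quartile).  Clusters are ordered by their
median cumulative use, and — for the unsupervised clustering mode — a
second-stage ordinary least squares regression estimates each cluster's
adjusted outcome difference from the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exposure import ExposureTable

__all__ = [
    "HEATMAP_LABELS",
    "heatmap_categories",
    "rank_clusters_by_cumulative",
    "second_stage_regression",
    "plot_heatmap",
]

HEATMAP_LABELS = ["very low", "moderately low", "moderately high", "very high"]


def _lower_median(v: np.ndarray) -> float:
    """Lower middle order statistic; keeps even-sized clusters on an
    observed value so the quartile bin is unambiguous."""
    s = np.sort(np.asarray(v, dtype=float))
    return float(s[(s.size - 1) // 2])


def _bin(value: float, cuts: np.ndarray) -> int:
    return int((value > np.asarray(cuts)).sum()) + 1


def heatmap_categories(
    best: np.ndarray,
    exposure: ExposureTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x pesticide exposure-level labels (plus cumulative column).

    The label is the quartile bin containing the within-cluster median of
    the continuous estimate, judged against the population cut points from
    discretisation; computed from continuous values rather than the
    categorical profiles so tie-collapsing in discretisation cannot move a
    label.  Returns (labels, numeric bins 1..4).
    """
    best = np.asarray(best)
    ids = np.unique(best)
    cols = list(exposure.continuous.columns) + ["cumulative"]
    rows = []
    for c in ids:
        members = best == c
        if not members.any():
            raise ValueError(f"cluster {c} is empty")
        row = [
            _bin(_lower_median(exposure.continuous.loc[members, pest]),
                 exposure.cut_points[pest])
            for pest in exposure.continuous.columns
        ]
        row.append(
            _bin(_lower_median(exposure.cumulative[members]),
                 exposure.cumulative_cut_points)
        )
        rows.append(row)
    numeric = pd.DataFrame(
        rows, index=pd.Index(ids, name="cluster"), columns=cols, dtype=int
    )
    labels = numeric.map(lambda k: HEATMAP_LABELS[k - 1])
    return labels, numeric


def rank_clusters_by_cumulative(
    best: np.ndarray, exposure: ExposureTable
) -> pd.DataFrame:
    """Clusters ordered by descending within-cluster median cumulative kg.

    Reports median and interquartile range per cluster; ties break by
    cluster id (ascending).
    """
    best = np.asarray(best)
    rows = []
    for c in np.unique(best):
        v = exposure.cumulative[best == c].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        rows.append(
            {"cluster": int(c), "n": int(v.size), "median_kg": float(med),
             "iqr_lo": float(q25), "iqr_hi": float(q75)}
        )
    df = pd.DataFrame(rows).sort_values(
        ["median_kg", "cluster"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def second_stage_regression(
    best: np.ndarray,
    outcome,
    confounders: pd.DataFrame | None,
    reference: int,
) -> pd.DataFrame:
    """OLS of the outcome on cluster indicators plus confounders.

    The second-stage analysis used when the outcome was excluded from the
    clustering: each non-reference cluster's coefficient estimates its
    adjusted outcome difference from the reference cluster, with
    normal-theory 95% confidence intervals.
    """
    best = np.asarray(best)
    y = np.asarray(outcome, dtype=float)
    ids = [c for c in np.unique(best)]
    if reference not in ids:
        raise ValueError(f"reference cluster {reference} not present")
    dummies = {
        f"cluster_{c}": (best == c).astype(float) for c in ids if c != reference
    }
    X = pd.DataFrame(dummies, index=pd.RangeIndex(best.size))
    if confounders is not None and len(confounders.columns):
        W = confounders.reset_index(drop=True).astype(float)
        W = W - W.mean()  # centered, matching the clustering-stage convention
        X = pd.concat([X, W], axis=1)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(), pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"singular design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    rows = []
    for c in ids:
        if c == reference:
            rows.append({"cluster": int(c), "estimate": "Ref",
                         "ci_lo": "Ref", "ci_hi": "Ref"})
            continue
        name = f"cluster_{c}"
        rows.append(
            {"cluster": int(c), "estimate": float(res.params[name]),
             "ci_lo": float(ci.loc[name, 0]), "ci_hi": float(ci.loc[name, 1])}
        )
    return pd.DataFrame(rows)


def plot_heatmap(numeric: pd.DataFrame, path) -> None:
    """Render the cluster x pesticide quartile heat map (4-level scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["#ffffff", "#fdd0c0", "#fb8a6a", "#b63b36"])
    fig, ax = plt.subplots(
        figsize=(0.6 * len(numeric.columns) + 2, 0.5 * len(numeric) + 2)
    )
    ax.imshow(numeric.to_numpy(dtype=float), cmap=cmap, vmin=1, vmax=4, aspect="auto")
    ax.set_xticks(range(len(numeric.columns)), numeric.columns, rotation=90)
    ax.set_yticks(range(len(numeric)), [f"CP{c}" for c in numeric.index])
    ax.set_xlabel("pesticide")
    ax.set_ylabel("cluster profile")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
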