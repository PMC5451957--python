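"""Posterior co-clustering, best partition and cluster risk summaries."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .model import MCMCDraws

__all__ = [
    "similarity",
    "best_partition",
    "select_reference_cluster",
    "cluster_outcome_posteriors",
    "compare_partitions",
    "ClusterReport",
]


def similarity(draws: MCMCDraws | np.ndarray) -> np.ndarray:
    """Posterior co-clustering matrix S_ij = Pr(z_i = z_j | data).

    Estimated as the fraction of kept draws in which i and j share a
    component; label-invariant by construction, symmetric, unit diagonal.
    """
    Z = draws.allocations if isinstance(draws, MCMCDraws) else np.asarray(draws)
    if Z.ndim != 2 or Z.shape[0] < 1:
        raise ValueError("need at least one draw of allocations")
    D, n = Z.shape
    S = np.zeros((n, n))
    chunk = max(1, int(2e7 // (n * n)))
    for lo in range(0, D, chunk):
        z = Z[lo : lo + chunk]
        S += (z[:, :, None] == z[:, None, :]).sum(axis=0)
    return S / D


def _ls_scores(Z: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Least-squares distance of each sampled partition to S (Dahl 2006)."""
    D, n = Z.shape
    B = 1.0 - 2.0 * S  # score_t = sum_{z_i=z_j} B_ij + const
    scores = np.empty(D)
    chunk = max(1, int(2e7 // (n * n)))
    for lo in range(0, D, chunk):
        z = Z[lo : lo + chunk]
        eq = z[:, :, None] == z[:, None, :]
        scores[lo : lo + chunk] = (eq * B[None, :, :]).sum(axis=(1, 2))
    return scores + (S * S).sum()


def _pam(D: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Partitioning around medoids on a dissimilarity matrix (greedy build
    + swap); returns labels 0..k-1."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(dmin - D[:, j], 0.0).sum() if j not in medoids else -1.0
            for j in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size:
                within = D[np.ix_(members, members)].sum(axis=1)
                new[c] = members[int(np.argmin(within))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def _relabel(z: np.ndarray) -> np.ndarray:
    """Map labels to consecutive 1..B in order of first appearance."""
    _, idx = np.unique(z, return_index=True)
    order = z[np.sort(idx)]
    lut = {c: i + 1 for i, c in enumerate(order)}
    return np.array([lut[c] for c in z], dtype=np.int64)


def best_partition(
    S: np.ndarray,
    draws: MCMCDraws | None = None,
    method: str = "least-squares-draw",
    k_range: range | None = None,
) -> np.ndarray:
    """Representative "hard" partition from the co-clustering matrix.

    * ``least-squares-draw`` (default): among the sampled partitions, pick
      the one minimising sum_ij (1[z_i = z_j] - S_ij)^2.
    * ``medoids``: partition around medoids on 1 - S over ``k_range``
      cluster counts and pick the k minimising the same criterion.

    Returns labels renumbered 1..B in order of first appearance.
    """
    S = np.asarray(S)
    if method == "least-squares-draw":
        if draws is None:
            raise ValueError("least-squares-draw requires the MCMC draws")
        Z = draws.allocations if isinstance(draws, MCMCDraws) else np.asarray(draws)
        scores = _ls_scores(Z, S)
        return _relabel(Z[int(np.argmin(scores))])
    if method == "medoids":
        Dmat = 1.0 - S
        k_range = k_range if k_range is not None else range(1, min(11, S.shape[0] + 1))
        best_lab, best_score = None, np.inf
        for k in k_range:
            lab = _pam(Dmat, k) if k > 1 else np.zeros(S.shape[0], dtype=int)
            score = _ls_scores(lab[None, :], S)[0]
            if score < best_score:
                best_lab, best_score = lab, score
        return _relabel(best_lab)
    raise ValueError(f"unknown method {method!r}")


def select_reference_cluster(best: np.ndarray, profiles) -> int:
    """Cluster with the highest share of lowest-quartile observations.

    For each cluster, the mean over members and pesticides of the indicator
    that the profile sits in category 1; ties break to the smallest cluster
    id.  This is the low-exposure baseline used for risk characterisation.
    """
    best = np.asarray(best)
    X = profiles.to_numpy() if isinstance(profiles, pd.DataFrame) else np.asarray(profiles)
    if best.size == 0:
        raise ValueError("empty partition")
    ids = np.unique(best)
    share = {c: float((X[best == c] == 1).mean()) for c in ids}
    top = max(share.values())
    return int(min(c for c in ids if share[c] == top))


@dataclasses.dataclass
class ClusterReport:
    """Per-cluster adjusted-outcome posteriors against the reference.

    ``table`` mirrors the usual risk-characterisation layout: cluster size,
    posterior mean and 95% credible interval of the adjusted expected
    outcome at baseline confounder values, difference versus the reference
    cluster, and the posterior probability of a deficit.  The reference row
    prints "Ref".
    """

    best_partition: np.ndarray
    reference: int
    cluster_ids: np.ndarray
    value_draws: np.ndarray  # (D, B) adjusted expected outcome per cluster
    diff_draws: np.ndarray  # (D, B) difference vs reference
    baseline_draws: np.ndarray  # (D,) unweighted across-cluster mean
    table: pd.DataFrame

    def deficit_probability(self, cluster: int) -> float:
        j = int(np.where(self.cluster_ids == cluster)[0][0])
        if cluster == self.reference:
            return float("nan")
        return float((self.diff_draws[:, j] < 0).mean())


def cluster_outcome_posteriors(
    draws: MCMCDraws, best: np.ndarray, reference: int
) -> ClusterReport:
    """Adjusted-outcome posterior for each best-partition cluster.

    For every kept sweep t and best-cluster c the adjusted expected outcome
    is the mean over subjects i in c of theta_{z_i^(t)}^(t), i.e. the
    expected response at baseline confounder values (discrete at reference
    level, continuous at their means) while cluster-assignment uncertainty
    within the sweep is retained.  The overall baseline is the unweighted
    across-cluster mean of these values at each sweep.
    """
    if draws.theta is None:
        raise ValueError("outcome was not included in the fit")
    best = np.asarray(best)
    ids = np.unique(best)
    if reference not in ids:
        raise ValueError(f"reference cluster {reference} not in best partition")
    theta_subj = np.take_along_axis(
        draws.theta, draws.allocations.astype(np.int64), axis=1
    )  # (D, n)
    H = (best[:, None] == ids[None, :]).astype(float)  # (n, B)
    H /= H.sum(axis=0, keepdims=True)
    vals = theta_subj @ H  # (D, B)
    ref_j = int(np.where(ids == reference)[0][0])
    diffs = vals - vals[:, [ref_j]]
    baseline = vals.mean(axis=1)

    rows = []
    for j, c in enumerate(ids):
        v = vals[:, j]
        d = diffs[:, j]
        is_ref = c == reference
        rows.append(
            {
                "cluster": int(c),
                "n": int((best == c).sum()),
                "adjusted_mean": float(v.mean()),
                "adjusted_lo": float(np.quantile(v, 0.025)),
                "adjusted_hi": float(np.quantile(v, 0.975)),
                "diff_vs_ref": "Ref" if is_ref else float(d.mean()),
                "diff_lo": "Ref" if is_ref else float(np.quantile(d, 0.025)),
                "diff_hi": "Ref" if is_ref else float(np.quantile(d, 0.975)),
                "prob_deficit": "Ref" if is_ref else float((d < 0).mean()),
            }
        )
    return ClusterReport(
        best_partition=best,
        reference=int(reference),
        cluster_ids=ids,
        value_draws=vals,
        diff_draws=diffs,
        baseline_draws=baseline,
        table=pd.DataFrame(rows),
    )


def compare_partitions(a, b) -> tuple[pd.DataFrame, float]:
    """Cross-tabulation (with totals) and Adjusted Rand Index of two
    partitions of the same subjects."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions cover different subjects")
    tab = pd.crosstab(
        pd.Series(a, name="partition_a"),
        pd.Series(b, name="partition_b"),
        margins=True,
        margins_name="Total",
    )
    return tab, float(adjusted_rand_score(a, b))
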