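"""Gaussian kernel machine regression with hierarchical variable selection.

The outcome is modelled as Y = h(z) + W beta + eps with h a smooth function
of the exposure vector z, given a Gaussian-process prior whose covariance
is lambda * sigma^2 * K, K(z_i, z_j) = exp(-sum_p r_p (z_ip - z_jp)^2).
h is never sampled pointwise: it is marginalised, so the working likelihood
is Y ~ N(W beta, sigma^2 (I + lambda K)).

Hierarchical (grouped) variable selection handles collinearity: each
exposure group (e.g. a chemical class) carries a Bernoulli activity
indicator, and an active group contributes exactly one member with nonzero
smoothness parameter r_p — grouped exposures never enter the same model.
Group posterior inclusion probabilities (PIPs) rank classes; conditional
PIPs rank members within a class.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KernelModelConfig",
    "KernelDraws",
    "PIPReport",
    "marginal_loglik",
    "fit_kernel_model",
    "pip_report",
]


@dataclasses.dataclass
class KernelModelConfig:
    """Settings for the kernel-machine sampler.

    ``groups`` maps every exposure name to its group label.  ``r_max`` is
    the upper bound of the Uniform(0, r_max) prior on a selected member's
    smoothness parameter; activation moves propose r from a log-uniform
    proposal on [r_prop_lo, r_max] (with full proposal correction), which
    mixes far better than proposing from the flat prior.
    """

    groups: dict[str, str]
    group_prior_prob: float = 0.5
    r_max: float = 100.0
    r_prop_lo: float = 0.01
    n_iter: int = 2000
    n_burnin: int = 500
    beta_sd: float = 100.0
    sigma2_shape: float = 2.5
    sigma2_scale: float | None = None  # None -> shape * var(y)
    lambda_shape: float = 1.0
    lambda_rate: float = 1.0
    rw_scale_r: float = 0.7  # log-scale RW sd for r refresh
    rw_scale_lambda: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.group_prior_prob < 1.0:
            raise ValueError("group_prior_prob must lie in (0, 1)")
        if self.n_iter <= 0 or self.n_burnin < 0:
            raise ValueError("iteration counts must be positive")


@dataclasses.dataclass
class KernelDraws:
    group_names: list[str]
    exposure_names: list[str]
    members: dict[str, list[int]]  # group -> exposure column indices
    active: np.ndarray  # (D, G) bool
    member: np.ndarray  # (D, G) selected column index, -1 when inactive
    r: np.ndarray  # (D, P)
    beta: np.ndarray  # (D, q)
    sigma2: np.ndarray  # (D,)
    lam: np.ndarray  # (D,)
    acceptance: dict[str, float]


@dataclasses.dataclass
class PIPReport:
    group_pips: pd.Series  # group -> [0, 1]
    conditional_pips: pd.DataFrame  # exposure, group, conditional_pip (NaN if never active)


def marginal_loglik(
    y: np.ndarray,
    W: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
    lam: float,
    K: np.ndarray,
) -> float:
    """log N(y; W beta, sigma^2 (I + lambda K)) via Cholesky."""
    n = y.size
    M = np.eye(n) + lam * K
    L = np.linalg.cholesky(M)
    e = y - W @ beta
    u = np.linalg.solve(L, e)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(
        -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + u @ u / sigma2)
    )


def _kernel(d2: np.ndarray, r: np.ndarray) -> np.ndarray:
    """K = exp(-sum_p r_p d2_p) from precomputed squared distances (P,n,n)."""
    act = np.nonzero(r)[0]
    if act.size == 0:
        n = d2.shape[1]
        return np.ones((n, n))
    return np.exp(-np.tensordot(r[act], d2[act], axes=1))


def _chol_terms(M: np.ndarray, e: np.ndarray) -> tuple[float, float]:
    L = np.linalg.cholesky(M)
    u = np.linalg.solve(L, e)
    return 2.0 * np.log(np.diag(L)).sum(), float(u @ u)


def fit_kernel_model(
    exposures: pd.DataFrame,
    outcome,
    confounders: pd.DataFrame | None,
    config: KernelModelConfig,
) -> KernelDraws:
    """Metropolis-within-Gibbs sampler for the marginalised kernel model.

    Exposures are standardised (mean 0, sd 1) internally; confounders gain
    an intercept column.  Every exposure must belong to exactly one group.
    """
    Z = exposures.to_numpy(dtype=float)
    names = [str(c) for c in exposures.columns]
    n, P = Z.shape
    sd = Z.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant exposure column cannot be standardised")
    Z = (Z - Z.mean(axis=0)) / sd
    if np.unique(Z, axis=0).shape[0] < n:
        logger.warning("duplicate exposure rows: kernel cannot separate them")

    unassigned = [p for p in names if p not in config.groups]
    if unassigned:
        raise ValueError(f"exposures without a group: {unassigned}")
    group_names = sorted(set(config.groups[p] for p in names))
    members = {
        g: [j for j, p in enumerate(names) if config.groups[p] == g]
        for g in group_names
    }
    G = len(group_names)

    y = np.asarray(outcome, dtype=float).ravel()
    if confounders is not None and len(confounders.columns):
        Wd = confounders.to_numpy(dtype=float)
        W = np.column_stack([np.ones(n), Wd - Wd.mean(axis=0)])
    else:
        W = np.ones((n, 1))
    q = W.shape[1]

    rng = np.random.default_rng(config.seed)
    d2 = np.stack([(Z[:, [p]] - Z[:, [p]].T) ** 2 for p in range(P)])

    sig_a = config.sigma2_shape
    sig_b = (
        config.sigma2_scale
        if config.sigma2_scale is not None
        else config.sigma2_shape * float(np.var(y))
    )
    p_on = config.group_prior_prob
    log_L = np.log(config.r_max / config.r_prop_lo)  # log-uniform proposal width

    # state
    active = np.zeros(G, dtype=bool)
    member = np.full(G, -1, dtype=np.int64)
    r = np.zeros(P)
    beta = np.zeros(q)
    beta[0] = float(y.mean())
    sigma2 = float(np.var(y))
    lam = 1.0

    K = _kernel(d2, r)

    def _ll(K_, beta_, sigma2_, lam_):
        logdet, quad = _chol_terms(np.eye(n) + lam_ * K_, y - W @ beta_)
        return -0.5 * (n * np.log(2 * np.pi * sigma2_) + logdet + quad / sigma2_)

    ll = _ll(K, beta, sigma2, lam)

    D = config.n_iter
    out_active = np.zeros((D, G), dtype=bool)
    out_member = np.full((D, G), -1, dtype=np.int64)
    out_r = np.zeros((D, P))
    out_beta = np.zeros((D, q))
    out_sig = np.zeros(D)
    out_lam = np.zeros(D)
    acc = {"toggle": 0.0, "switch": 0.0, "r_rw": 0.0, "lambda": 0.0}
    n_prop = {k: 0 for k in acc}

    for it in range(config.n_burnin + D):
        # --- group indicators: birth/death per group ---
        for gi, g in enumerate(group_names):
            mem = members[g]
            if not active[gi]:
                j = mem[int(rng.integers(len(mem)))]
                r_new = config.r_prop_lo * np.exp(log_L * rng.random())
                r_prop = r.copy()
                r_prop[j] = r_new
                K_prop = _kernel(d2, r_prop)
                ll_prop = _ll(K_prop, beta, sigma2, lam)
                # prior(r)/proposal(r) = (1/r_max) / (1/(r ln L))
                log_acc = (
                    ll_prop - ll
                    + np.log(p_on / (1 - p_on))
                    + np.log(r_new * log_L / config.r_max)
                )
                n_prop["toggle"] += 1
                if np.log(rng.random()) < log_acc:
                    active[gi], member[gi] = True, j
                    r, K, ll = r_prop, K_prop, ll_prop
                    acc["toggle"] += 1
            else:
                j = member[gi]
                r_prop = r.copy()
                r_prop[j] = 0.0
                K_prop = _kernel(d2, r_prop)
                ll_prop = _ll(K_prop, beta, sigma2, lam)
                log_acc = (
                    ll_prop - ll
                    + np.log((1 - p_on) / p_on)
                    - np.log(r[j] * log_L / config.r_max)
                )
                n_prop["toggle"] += 1
                if np.log(rng.random()) < log_acc:
                    active[gi], member[gi] = False, -1
                    r, K, ll = r_prop, K_prop, ll_prop
                    acc["toggle"] += 1

            if active[gi] and len(mem) > 1:
                # member switch with fresh r from the log-uniform proposal
                j_old = member[gi]
                others = [m for m in mem if m != j_old]
                j_new = others[int(rng.integers(len(others)))]
                r_new = config.r_prop_lo * np.exp(log_L * rng.random())
                r_prop = r.copy()
                r_prop[j_old] = 0.0
                r_prop[j_new] = r_new
                K_prop = _kernel(d2, r_prop)
                ll_prop = _ll(K_prop, beta, sigma2, lam)
                log_acc = ll_prop - ll + np.log(r_new) - np.log(r[j_old])
                n_prop["switch"] += 1
                if np.log(rng.random()) < log_acc:
                    member[gi] = j_new
                    r, K, ll = r_prop, K_prop, ll_prop
                    acc["switch"] += 1

            if active[gi]:
                # log-scale random walk refresh of the active r
                j = member[gi]
                r_new = r[j] * np.exp(config.rw_scale_r * rng.normal())
                n_prop["r_rw"] += 1
                if r_new < config.r_max:
                    r_prop = r.copy()
                    r_prop[j] = r_new
                    K_prop = _kernel(d2, r_prop)
                    ll_prop = _ll(K_prop, beta, sigma2, lam)
                    log_acc = ll_prop - ll + np.log(r_new) - np.log(r[j])
                    if np.log(rng.random()) < log_acc:
                        r, K, ll = r_prop, K_prop, ll_prop
                        acc["r_rw"] += 1

        # --- lambda: log random walk ---
        lam_new = lam * np.exp(config.rw_scale_lambda * rng.normal())
        ll_new = _ll(K, beta, sigma2, lam_new)
        log_acc = (
            ll_new - ll
            + config.lambda_shape * (np.log(lam_new) - np.log(lam))
            - config.lambda_rate * (lam_new - lam)
        )
        n_prop["lambda"] += 1
        if np.log(rng.random()) < log_acc:
            lam, ll = lam_new, ll_new
            acc["lambda"] += 1

        # --- beta, sigma2: conjugate given M = I + lambda K ---
        M = np.eye(n) + lam * K
        Lc = np.linalg.cholesky(M)
        Wt = np.linalg.solve(Lc, W)
        yt = np.linalg.solve(Lc, y)
        A = Wt.T @ Wt / sigma2 + np.eye(q) / config.beta_sd**2
        b = Wt.T @ yt / sigma2
        La = np.linalg.cholesky(A)
        mu = np.linalg.solve(A, b)
        beta = mu + np.linalg.solve(La.T, rng.normal(size=q))
        e = yt - Wt @ beta
        quad = float(e @ e)
        sigma2 = float(
            (sig_b + 0.5 * quad) / rng.standard_gamma(sig_a + 0.5 * n)
        )
        ll = _ll(K, beta, sigma2, lam)

        k = it - config.n_burnin
        if k >= 0:
            out_active[k] = active
            out_member[k] = member
            out_r[k] = r
            out_beta[k] = beta
            out_sig[k] = sigma2
            out_lam[k] = lam

    return KernelDraws(
        group_names=group_names,
        exposure_names=names,
        members=members,
        active=out_active,
        member=out_member,
        r=out_r,
        beta=out_beta,
        sigma2=out_sig,
        lam=out_lam,
        acceptance={k: acc[k] / max(1, n_prop[k]) for k in acc},
    )


def pip_report(draws: KernelDraws) -> PIPReport:
    """Group and within-group conditional posterior inclusion probabilities.

    Group PIP: fraction of kept draws with the group active.  Conditional
    PIP: among group-active draws, the fraction selecting each member
    (sums to 1 within a group); NaN for every member of a group that was
    never active.
    """
    if draws.active.shape[0] < 1:
        raise ValueError("need at least one kept draw")
    gp = pd.Series(
        draws.active.mean(axis=0), index=draws.group_names, name="group_pip"
    )
    rows = []
    for gi, g in enumerate(draws.group_names):
        sel = draws.member[draws.active[:, gi], gi]
        for j in draws.members[g]:
            rows.append(
                {
                    "exposure": draws.exposure_names[j],
                    "group": g,
                    "conditional_pip": (
                        float((sel == j).mean()) if sel.size else float("nan")
                    ),
                }
            )
    return PIPReport(group_pips=gp, conditional_pips=pd.DataFrame(rows))
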