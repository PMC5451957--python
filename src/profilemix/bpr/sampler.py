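"""Blocked Gibbs sampler for the profile-regression model.

Model (truncated stick-breaking representation with C components):

* stick fractions v_c ~ Beta(1, alpha), psi_c = v_c prod_{l<c}(1 - v_l),
  v_C = 1; alpha ~ Gamma(a_alpha, b_alpha) (conjugate update given v);
* per-component category probabilities phi_cp. ~ Dirichlet(a, ..., a);
* allocation z_i | psi, phi*, theta, beta, sigma ~ multinomial over the C
  components, combining the categorical likelihood of the profile x_i with
  the Gaussian response likelihood of Y_i when the outcome is included;
* response Y_i = theta_{z_i} + W_i beta + eps_i, eps ~ N(0, sigma^2), with
  conjugate Normal/Normal/Inverse-Gamma updates for theta, beta, sigma^2;
* continuous variable selection: latent zeta_p in (0,1) with Beta prior
  mixes the component-specific phi with the marginal category frequencies
  rho: phi*_cpk = zeta_p phi_cpk + (1 - zeta_p) rho_pk.  The mixture is
  handled by data augmentation — a latent source indicator u_ip says
  whether x_ip came from the component-specific distribution (probability
  zeta_p) or the marginal — after which phi and zeta are both conjugate
  (Dirichlet / Beta Gibbs updates).

The O(n C P) allocation scan is numba-jitted; everything else is
vectorised numpy.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from numba import njit

from .model import BPRConfig, BPRPriors, MCMCDraws

logger = logging.getLogger(__name__)

_TINY = 1e-300


@njit(cache=True)
def _alloc_scan(logpsi, logphistar, x, r, theta, sigma, include_outcome, u,
                z, counts, rsum, catcounts, w):
    """Sample all allocations and accumulate sufficient statistics."""
    n, P = x.shape
    C = logpsi.shape[0]
    counts[:] = 0
    rsum[:] = 0.0
    catcounts[:] = 0.0
    for i in range(n):
        m = -1e308
        for c in range(C):
            s = logpsi[c]
            for p in range(P):
                s += logphistar[c, p, x[i, p]]
            if include_outcome:
                d = (r[i] - theta[c]) / sigma
                s -= 0.5 * d * d
            w[c] = s
            if s > m:
                m = s
        tot = 0.0
        for c in range(C):
            w[c] = np.exp(w[c] - m)
            tot += w[c]
        t = u[i] * tot
        acc = 0.0
        zi = C - 1
        for c in range(C):
            acc += w[c]
            if acc >= t:
                zi = c
                break
        z[i] = zi
        counts[zi] += 1
        rsum[zi] += r[i]
        for p in range(P):
            catcounts[zi, p, x[i, p]] += 1.0


@dataclasses.dataclass
class _Hyper:
    """Numeric prior values after resolving data-driven defaults."""

    alpha_shape: float
    alpha_rate: float
    alpha_fixed: float | None
    a_dir: float
    theta_mean: float
    theta_sd: float
    beta_sd: float
    sig_shape: float
    sig_scale: float
    zeta_a: float
    zeta_b: float

    @classmethod
    def resolve(cls, priors: BPRPriors, y: np.ndarray | None) -> "_Hyper":
        if y is not None and y.size > 1:
            ymean, ysd = float(np.mean(y)), float(np.std(y))
            yvar = float(np.var(y))
        else:
            ymean, ysd, yvar = 0.0, 1.0, 1.0
        return cls(
            alpha_shape=priors.alpha_shape,
            alpha_rate=priors.alpha_rate,
            alpha_fixed=priors.alpha_fixed,
            a_dir=priors.dirichlet_mass,
            theta_mean=priors.theta_mean if priors.theta_mean is not None else ymean,
            theta_sd=priors.theta_sd if priors.theta_sd is not None else 2.0 * max(ysd, 1e-8),
            beta_sd=priors.beta_sd,
            sig_shape=priors.sigma2_shape,
            sig_scale=(
                priors.sigma2_scale
                if priors.sigma2_scale is not None
                else priors.sigma2_shape * max(yvar, 1e-8)
            ),
            zeta_a=priors.zeta_a,
            zeta_b=priors.zeta_b,
        )


@dataclasses.dataclass
class _State:
    """Current parameter values of the Markov chain."""

    v: np.ndarray  # (C-1,) stick fractions
    alpha: float
    phi: np.ndarray  # (C, P, K)
    zeta: np.ndarray | None  # (P,) or None
    theta: np.ndarray  # (C,)
    beta: np.ndarray  # (q,)
    sigma2: float
    z: np.ndarray  # (n,)

    def psi(self) -> np.ndarray:
        C = self.v.size + 1
        psi = np.empty(C)
        rem = 1.0
        for c in range(C - 1):
            psi[c] = self.v[c] * rem
            rem *= 1.0 - self.v[c]
        psi[C - 1] = rem
        return psi


def sample_prior_state(
    hyper: _Hyper, C: int, P: int, K: int, q: int, n: int,
    rng: np.random.Generator, selection: bool,
) -> _State:
    alpha = (
        hyper.alpha_fixed
        if hyper.alpha_fixed is not None
        else rng.gamma(hyper.alpha_shape, 1.0 / hyper.alpha_rate)
    )
    v = rng.beta(1.0, alpha, size=C - 1)
    g = rng.standard_gamma(np.full((C, P, K), hyper.a_dir))
    phi = g / g.sum(axis=2, keepdims=True)
    zeta = rng.beta(hyper.zeta_a, hyper.zeta_b, size=P) if selection else None
    theta = rng.normal(hyper.theta_mean, hyper.theta_sd, size=C)
    beta = rng.normal(0.0, hyper.beta_sd, size=q)
    sigma2 = hyper.sig_scale / rng.standard_gamma(hyper.sig_shape)
    return _State(v=v, alpha=float(alpha), phi=phi, zeta=zeta,
                  theta=theta, beta=beta, sigma2=float(sigma2),
                  z=np.zeros(n, dtype=np.int64))


def _phistar(state: _State, rho: np.ndarray) -> np.ndarray:
    if state.zeta is None:
        return state.phi
    zt = state.zeta[None, :, None]
    return zt * state.phi + (1.0 - zt) * rho[None, :, :]


def sweep(
    state: _State,
    x: np.ndarray,  # (n, P) int64 0-based categories
    y: np.ndarray | None,
    W: np.ndarray,  # (n, q)
    rho: np.ndarray,  # (P, K)
    hyper: _Hyper,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One full scan of all conditional updates, in place.

    Returns (counts, catcounts) of the new allocation for reuse by callers.
    """
    n, P = x.shape
    C = state.phi.shape[0]
    K = state.phi.shape[2]
    include_outcome = y is not None

    # allocation scan
    psi = state.psi()
    logpsi = np.log(np.clip(psi, _TINY, None))
    logphistar = np.log(np.clip(_phistar(state, rho), _TINY, None))
    r = (y - W @ state.beta) if include_outcome else np.zeros(n)
    counts = np.zeros(C, dtype=np.int64)
    rsum = np.zeros(C)
    catcounts = np.zeros((C, P, K))
    wbuf = np.empty(C)
    _alloc_scan(
        logpsi, logphistar, x, r, state.theta,
        float(np.sqrt(state.sigma2)), include_outcome,
        rng.random(n), state.z, counts, rsum, catcounts, wbuf,
    )

    # stick fractions and DP concentration
    tail = counts[::-1].cumsum()[::-1]
    state.v = rng.beta(1.0 + counts[:-1], state.alpha + tail[1:])
    state.v = np.clip(state.v, 1e-12, 1.0 - 1e-12)
    if hyper.alpha_fixed is None:
        rate = hyper.alpha_rate - np.log1p(-state.v).sum()
        state.alpha = float(rng.gamma(hyper.alpha_shape + C - 1, 1.0 / rate))

    # component category probabilities (and selection weights)
    if state.zeta is None:
        g = rng.standard_gamma(hyper.a_dir + catcounts)
        state.phi = np.clip(g / np.clip(g.sum(axis=2, keepdims=True), _TINY, None), _TINY, None)
    else:
        # Data augmentation: each observation x_ip is drawn from the
        # component-specific phi with probability zeta_p, else from the
        # marginal rho.  Given latent source indicators u_ip, phi and zeta
        # are both conjugate (Dirichlet / Beta), which mixes across the
        # zeta ~ 0 region where the likelihood is flat in phi.
        pidx = np.arange(P)[None, :]
        phi_at = state.phi[state.z[:, None], pidx, x]  # (n, P)
        rho_at = rho[pidx, x]
        num = state.zeta[None, :] * phi_at
        den = num + (1.0 - state.zeta[None, :]) * rho_at
        u = rng.random((n, P)) < num / np.clip(den, _TINY, None)

        selcounts = np.zeros((C, P, K))
        zi = np.broadcast_to(state.z[:, None], (n, P))[u]
        pi = np.broadcast_to(pidx, (n, P))[u]
        np.add.at(selcounts, (zi, pi, x[u]), 1.0)
        g = rng.standard_gamma(hyper.a_dir + selcounts)
        state.phi = np.clip(g / np.clip(g.sum(axis=2, keepdims=True), _TINY, None), _TINY, None)

        n_sel = u.sum(axis=0)
        state.zeta = np.clip(
            rng.beta(hyper.zeta_a + n_sel, hyper.zeta_b + n - n_sel),
            1e-12, 1.0 - 1e-12,
        )

    # response sub-model
    if include_outcome:
        prec = 1.0 / hyper.theta_sd**2 + counts / state.sigma2
        var = 1.0 / prec
        mean = var * (hyper.theta_mean / hyper.theta_sd**2 + rsum / state.sigma2)
        state.theta = mean + np.sqrt(var) * rng.normal(size=C)

        q = W.shape[1]
        if q:
            resid_t = y - state.theta[state.z]
            A = W.T @ W / state.sigma2 + np.eye(q) / hyper.beta_sd**2
            b = W.T @ resid_t / state.sigma2
            L = np.linalg.cholesky(A)
            mu = np.linalg.solve(A, b)
            state.beta = mu + np.linalg.solve(L.T, rng.normal(size=q))
        resid = y - state.theta[state.z] - W @ state.beta
        state.sigma2 = float(
            (hyper.sig_scale + 0.5 * resid @ resid)
            / rng.standard_gamma(hyper.sig_shape + 0.5 * n)
        )

    return counts, catcounts


def _prepare_inputs(profiles, outcome, confounders):
    """Validate and encode profiles/outcome/confounders as arrays."""
    if isinstance(profiles, pd.DataFrame):
        pest_names = [str(c) for c in profiles.columns]
        subject_ids = [str(i) for i in profiles.index]
        xraw = profiles.to_numpy()
    else:
        xraw = np.asarray(profiles)
        pest_names = [f"x{p + 1}" for p in range(xraw.shape[1])]
        subject_ids = [str(i) for i in range(xraw.shape[0])]
    xraw = xraw.astype(np.int64)
    if xraw.min() < 1:
        raise ValueError("profile categories must lie in 1..K")
    K = int(xraw.max())
    x = xraw - 1

    y = None
    if outcome is not None:
        y = np.asarray(outcome, dtype=float).ravel()
        if not np.isfinite(y).all():
            raise ValueError("outcome contains non-finite values")
        if y.size != x.shape[0]:
            raise ValueError("outcome length does not match profiles")

    conf_names: list[str] = []
    means: dict[str, float] = {}
    if confounders is None:
        W = np.zeros((x.shape[0], 0))
    else:
        if isinstance(confounders, pd.DataFrame):
            conf_names = [str(c) for c in confounders.columns]
            W = confounders.to_numpy(dtype=float)
        else:
            W = np.asarray(confounders, dtype=float)
            conf_names = [f"w{j + 1}" for j in range(W.shape[1])]
        if W.shape[0] != x.shape[0]:
            raise ValueError("confounders length does not match profiles")
        W = W.copy()
        for j, name in enumerate(conf_names):
            col = W[:, j]
            if not set(np.unique(col)) <= {0.0, 1.0}:
                m = float(col.mean())
                W[:, j] = col - m
                means[name] = m
        if W.shape[1] and np.linalg.matrix_rank(W) < W.shape[1]:
            warnings.warn(
                "confounder matrix is rank-deficient; the Gaussian prior on "
                "beta ridge-stabilises the update"
            )
    return x, K, y, W, pest_names, subject_ids, conf_names, means


def fit(profiles, outcome=None, confounders=None, config: BPRConfig | None = None) -> MCMCDraws:
    """Run the blocked Gibbs sampler and return kept draws.

    ``profiles``: (n, P) categorical matrix with entries 1..K (DataFrame
    column names become pesticide names).  ``outcome``: optional continuous
    response; when None (or config.outcome_included is False) the mixture
    is fit unsupervised.  Continuous confounder columns are centered on
    their means here, and the applied centering is recorded on the result.
    """
    config = config if config is not None else BPRConfig()
    x, K, y, W, pest_names, subject_ids, conf_names, means = _prepare_inputs(
        profiles, outcome, confounders
    )
    if not config.outcome_included:
        y = None
    include_outcome = y is not None
    n, P = x.shape
    C = config.truncation_level
    q = W.shape[1]

    hyper = _Hyper.resolve(config.priors, y)
    rng = np.random.default_rng(config.seed)
    selection = config.variable_selection == "continuous"

    if config.rho is not None:
        rho = np.asarray(config.rho, dtype=float)
        if rho.shape != (P, K):
            raise ValueError(f"rho must have shape ({P}, {K})")
    else:
        rho = np.stack([
            np.bincount(x[:, p], minlength=K) / n for p in range(P)
        ])
    rho = np.clip(rho, _TINY, None)

    state = sample_prior_state(hyper, C, P, K, q, n, rng, selection)
    thin = config.resolved_thin()
    n_kept = max(1, config.n_sweeps // thin)

    Z = np.empty((n_kept, n), dtype=np.int16)
    TH = np.empty((n_kept, C)) if include_outcome else None
    B = np.empty((n_kept, q)) if include_outcome else None
    SG = np.empty(n_kept) if include_outcome else None
    AL = np.empty(n_kept)
    ZE = np.empty((n_kept, P)) if selection else None
    PH = np.empty((n_kept, C, P, K), dtype=np.float32)

    kept = 0
    max_occ = 0
    total = config.n_burnin + config.n_sweeps
    for sweep_idx in range(total):
        counts, _ = sweep(state, x, y, W, rho, hyper, rng)
        occ = int(np.max(np.nonzero(counts)[0])) if counts.any() else 0
        max_occ = max(max_occ, occ)
        if config.log_every and (sweep_idx + 1) % config.log_every == 0:
            logger.info(
                "sweep %d/%d: %d occupied clusters, sigma=%.3f",
                sweep_idx + 1, total, int((counts > 0).sum()),
                float(np.sqrt(state.sigma2)) if include_outcome else float("nan"),
            )
        post = sweep_idx - config.n_burnin
        if post >= 0 and post % thin == 0 and kept < n_kept:
            Z[kept] = state.z
            AL[kept] = state.alpha
            PH[kept] = state.phi
            if include_outcome:
                TH[kept] = state.theta
                B[kept] = state.beta
                SG[kept] = np.sqrt(state.sigma2)
            if selection:
                ZE[kept] = state.zeta
            kept += 1

    if max_occ >= C - 5:
        warnings.warn(
            f"top occupied component index {max_occ} is close to the "
            f"truncation level {C}; increase truncation_level"
        )
    return MCMCDraws(
        allocations=Z[:kept],
        theta=TH[:kept] if include_outcome else None,
        beta=B[:kept] if include_outcome else None,
        sigma=SG[:kept] if include_outcome else None,
        alpha=AL[:kept],
        zeta=ZE[:kept] if selection else None,
        phi=PH[:kept],
        subject_ids=subject_ids,
        pesticide_names=pest_names,
        confounder_names=conf_names,
        confounder_means=means,
        outcome_included=include_outcome,
        K=K,
        rho=rho,
        max_occupied=max_occ,
        acceptance={},
    )
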