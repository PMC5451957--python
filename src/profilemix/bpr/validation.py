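"""Sampler validation by successive-conditional simulation.

The "getting it right" scheme of Geweke (2004): draw parameters from the
prior, then repeatedly (i) regenerate data from the model given the current
parameters and (ii) apply one full scan of the posterior transition kernels
given that data.  If every conditional update is correctly implemented and
exactly invariant, the marginal distribution of the parameters along this
chain is the prior, so chain moments must agree with direct prior draws up
to Monte-Carlo error.  A bug in any update shows up as a systematic drift.
"""

from __future__ import annotations

import numpy as np

from .model import BPRPriors
from .sampler import _Hyper, _phistar, sample_prior_state, sweep

__all__ = ["successive_conditional_simulation"]


def _generate_data(state, rho, W, rng, K):
    """Draw (x, y) from the model given the current parameter state."""
    n = state.z.size
    P = state.phi.shape[1]
    psi = state.psi()
    state.z = rng.choice(psi.size, size=n, p=psi / psi.sum())
    phistar = _phistar(state, rho)  # (C, P, K)
    u = rng.random((n, P))
    cdf = np.cumsum(phistar, axis=2)
    x = np.empty((n, P), dtype=np.int64)
    for p in range(P):
        x[:, p] = (u[:, p, None] > cdf[state.z, p, :-1]).sum(axis=1)
    y = state.theta[state.z] + W @ state.beta + rng.normal(
        scale=np.sqrt(state.sigma2), size=n
    )
    return x, y


def successive_conditional_simulation(
    n_cycles: int = 5000,
    n: int = 8,
    P: int = 2,
    K: int = 3,
    C: int = 8,
    q: int = 2,
    priors: BPRPriors | None = None,
    selection: bool = True,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Run the successive-conditional chain and matching prior draws.

    Returns a dict with chain draws (``alpha``, ``sigma``, ``zeta``) and
    direct prior draws (``alpha_prior``, ``sigma_prior``, ``zeta_prior``)
    of the same length, for moment comparison by the caller.  The marginal
    category frequencies rho are fixed (uniform) so the selection mixture
    is a coherent generative model, and all data-driven prior defaults are
    replaced by fixed numeric values.
    """
    priors = priors if priors is not None else BPRPriors(
        theta_mean=0.0, theta_sd=2.0, beta_sd=2.0,
        sigma2_shape=3.0, sigma2_scale=2.0,
    )
    if priors.theta_mean is None or priors.theta_sd is None or priors.sigma2_scale is None:
        raise ValueError("successive-conditional run needs fully numeric priors")
    hyper = _Hyper.resolve(priors, None)
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(n, q))  # fixed design across the whole run
    rho = np.full((P, K), 1.0 / K)

    state = sample_prior_state(hyper, C, P, K, q, n, rng, selection)
    alpha = np.empty(n_cycles)
    sigma = np.empty(n_cycles)
    zeta = np.empty((n_cycles, P)) if selection else None
    for t in range(n_cycles):
        x, y = _generate_data(state, rho, W, rng, K)
        sweep(state, x, y, W, rho, hyper, rng)
        alpha[t] = state.alpha
        sigma[t] = np.sqrt(state.sigma2)
        if selection:
            zeta[t] = state.zeta

    prior_alpha = np.empty(n_cycles)
    prior_sigma = np.empty(n_cycles)
    prior_zeta = np.empty((n_cycles, P)) if selection else None
    for t in range(n_cycles):
        s = sample_prior_state(hyper, C, P, K, q, n, rng, selection)
        prior_alpha[t] = s.alpha
        prior_sigma[t] = np.sqrt(s.sigma2)
        if selection:
            prior_zeta[t] = s.zeta

    out = {
        "alpha": alpha,
        "sigma": sigma,
        "alpha_prior": prior_alpha,
        "sigma_prior": prior_sigma,
    }
    if selection:
        out["zeta"] = zeta
        out["zeta_prior"] = prior_zeta
    return out
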