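"""Configuration and draw containers for the profile-regression sampler."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class BPRPriors:
    """Hyperparameters; None entries default to data-driven values at fit.

    * DP concentration alpha ~ Gamma(alpha_shape, alpha_rate), or fixed at
      ``alpha_fixed``.
    * Per-category Dirichlet mass ``dirichlet_mass`` on the cluster
      category probabilities phi.
    * Cluster outcome means theta_c ~ Normal(theta_mean, theta_sd^2);
      defaults: sample mean of Y and twice its sample SD.
    * Confounder effects beta ~ Normal(0, beta_sd^2) elementwise.
    * Residual variance sigma^2 ~ Inverse-Gamma(sigma2_shape, sigma2_scale);
      default scale: sigma2_shape * sample variance of Y.
    * Selection weights zeta_p ~ Beta(zeta_a, zeta_b).
    """

    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    alpha_fixed: float | None = None
    dirichlet_mass: float = 0.5
    theta_mean: float | None = None
    theta_sd: float | None = None
    beta_sd: float = 10.0
    sigma2_shape: float = 2.5
    sigma2_scale: float | None = None
    zeta_a: float = 0.5
    zeta_b: float = 0.5


@dataclasses.dataclass
class BPRConfig:
    """Sampler settings.

    Defaults follow the motivating analysis (20,000 burn-in, 200,000
    sweeps); tests and the example pipeline use far fewer.  ``max_kept``
    caps stored draws regardless of n_sweeps (bounded memory); ``thin``
    overrides it explicitly.
    """

    n_burnin: int = 20_000
    n_sweeps: int = 200_000
    thin: int | None = None
    max_kept: int = 5_000
    truncation_level: int = 50
    outcome_included: bool = True
    variable_selection: str = "none"  # or "continuous"
    priors: BPRPriors = dataclasses.field(default_factory=BPRPriors)
    #: fixed marginal category frequencies for the selection mixture;
    #: None -> empirical frequencies of the data
    rho: np.ndarray | None = None
    seed: int = 0
    log_every: int = 0  # sweeps between progress log lines; 0 = silent

    def __post_init__(self) -> None:
        if self.n_sweeps <= 0 or self.n_burnin < 0:
            raise ValueError("counts must be positive")
        if self.truncation_level < 2:
            raise ValueError("truncation_level must be >= 2")
        if self.variable_selection not in ("none", "continuous"):
            raise ValueError("variable_selection must be 'none' or 'continuous'")

    def resolved_thin(self) -> int:
        if self.thin is not None:
            return max(1, int(self.thin))
        return max(1, self.n_sweeps // self.max_kept)


@dataclasses.dataclass
class MCMCDraws:
    """Kept post-burn-in draws from the blocked Gibbs sampler.

    Shapes: allocations (D, n); theta (D, C); beta (D, q); sigma (D,);
    alpha (D,); zeta (D, P) or None; phi (D, C, P, K) float32.
    ``confounder_means`` records the centering applied to continuous
    confounders before fitting.
    """

    allocations: np.ndarray
    theta: np.ndarray | None
    beta: np.ndarray | None
    sigma: np.ndarray | None
    alpha: np.ndarray
    zeta: np.ndarray | None
    phi: np.ndarray
    subject_ids: list[str]
    pesticide_names: list[str]
    confounder_names: list[str]
    confounder_means: dict[str, float]
    outcome_included: bool
    K: int
    rho: np.ndarray
    max_occupied: int
    acceptance: dict[str, float]

    @property
    def n_kept(self) -> int:
        return self.allocations.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.allocations.shape[1]

    def beta_trace(self) -> pd.DataFrame:
        """Confounder-effect draws as a tidy frame for trace diagnostics."""
        if self.beta is None:
            raise ValueError("outcome was not included in this fit")
        return pd.DataFrame(self.beta, columns=self.confounder_names)
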