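# Methods

This package analyses joint residential exposure to agricultural pesticide
mixtures: it builds buffer-weighted pregnancy-average use estimates from
application records, clusters the resulting exposure profiles with an
outcome-supervised Dirichlet-process mixture, characterises cluster risk
against a low-exposure reference, ranks exposures with a grouped
kernel-machine model, and tests spatial clustering with Moran's I. This
note records the models, their assumptions, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Exposure construction

For subject *i* with residence at planar coordinates (x, y), the estimate
for pesticide *p* is built from use-report records (one-square-mile
section, date, active ingredient, kilograms):

1. Every section overlapping the 1-km disk around the residence receives a
   weight equal to the fraction of its land area inside the disk. The disk
   is a 512-segment polygon (`quad_segs=128`), whose area error (~2.5e-5
   relative) is negligible against the 1e-3 accuracy the package tests
   against an independent Monte-Carlo area oracle.
2. Applications dated inside a trimester (intersected with the occupancy
   window of the then-current residence) contribute kg x weight. Dates are
   closed on both interval ends; an application on a shared boundary date
   counts once, to the earlier interval. Overlapping residence windows are
   an error (ambiguous location), not a warning.
3. A trimester qualifies if it has >= 75 days of known residential
   location; subjects with >= 2 qualifying trimesters get the mean of the
   qualifying trimester sums, others are excluded.
4. Pesticides are retained when the population median is positive and the
   75th percentile is at least twice the 25th (inclusive; q25 = 0 with a
   positive median counts as infinite contrast — several real actives have
   exactly this shape and were retained in the motivating analysis).
5. Retained estimates are discretised at the empirical 25/50/75 percentiles
   (linear interpolation) into categories 1..4 with half-open bins
   (-inf, q25], (q25, q50], (q50, q75], (q75, inf). Tied cut points
   collapse categories deterministically.

The percentile definition and both boundary conventions are pinned choices:
the quantities they affect (quartile boundaries, boundary-dated
applications) move under alternative definitions, so they are fixed and
documented rather than left to library defaults.

## Profile regression

Profiles x_i = (x_i1..x_iP), x_ip in 1..K, are modelled by a
Dirichlet-process mixture in truncated stick-breaking form with C = 50
components: v_c ~ Beta(1, alpha), psi_c = v_c prod_{l<c}(1 - v_l),
alpha ~ Gamma(2, 1); within component c, x_ip ~ Categorical(phi_cp.),
phi_cp. ~ Dirichlet(0.5, ..., 0.5). When the outcome is included, Y_i =
theta_{z_i} + W_i beta + eps_i with eps ~ N(0, sigma^2), so allocations are
informed by both the profile and the outcome ("outcome feedback"). Priors:
theta_c ~ N(mean(Y), (2 sd(Y))^2), beta ~ N(0, 10^2) on centred
confounders, sigma^2 ~ Inv-Gamma(2.5, 2.5 var(Y)); all overridable.
Continuous confounders are centred by the sampler itself and the applied
centring is recorded on the result, so "expected outcome at baseline"
means discrete confounders at reference level and continuous at their
means.

Inference is blocked Gibbs: a numba-compiled allocation scan, conjugate
updates for v, alpha, phi, theta, beta, sigma^2. Truncation adequacy is
monitored (warning when the top occupied component index approaches C).
Defaults are 20,000 burn-in and 200,000 sweeps (the scale of the
motivating analysis); the stored chain is capped at 5,000 draws by default
for bounded memory.

**Variable selection (continuous).** A latent weight zeta_p in (0, 1) with
Beta(0.5, 0.5) prior mixes the component-specific categorical distribution
with the fixed marginal category frequencies rho_pk: phi*_cpk = zeta_p
phi_cpk + (1 - zeta_p) rho_pk. The mixture is sampled by data
augmentation: a per-observation source indicator u_ip (component-specific
with probability zeta_p, marginal otherwise) restores full conjugacy —
phi from Dirichlet(0.5 + selected counts), zeta_p from
Beta(0.5 + sum u, 0.5 + n - sum u). An earlier Metropolis variant
(random-walk on logit zeta with Metropolis-corrected phi) mixed so poorly
that zeta could stall near 0 for cluster-informative covariates: with
zeta ~ 0 the likelihood is flat in phi, phi relaxes to its prior, and no
single-site move can lift zeta again. The augmented sampler has no such
trap. rho is treated as a fixed plug-in (empirical frequencies by default,
overridable), which also makes the model a coherent generative model for
the prior-recovery validation below. The posterior mean of zeta_p is
reported as each pesticide's clustering-inclusion weight; no numeric
equivalence with other implementations' "inclusion probabilities" is
claimed.

**Summaries.** Co-clustering S_ij is the fraction of kept draws with
z_i = z_j. The "best" partition is, by default, the sampled partition
minimising sum_ij (1[z_i = z_j] - S_ij)^2 (Dahl's least-squares draw); a
partitioning-around-medoids alternative on 1 - S over a range of cluster
counts is provided, scored by the same criterion. Per kept sweep, each
best-cluster's adjusted expected outcome is the mean of theta_{z_i} over
its members, retaining within-sweep allocation uncertainty; differences
are taken against the reference cluster (highest share of lowest-quartile
observations, ties to the smallest id) and deficit probabilities are the
fraction of sweeps below the reference. The unsupervised mode (outcome
excluded) feeds a second-stage OLS of the outcome on cluster indicators
plus confounders, and partitions from the two modes are compared by
cross-tabulation and Adjusted Rand Index.

**Validation.** Three layers, run routinely in the test suite: (i) at
n = 6 the sampler's co-clustering probabilities are checked against exact
enumeration over all 203 set partitions under the Chinese-restaurant prior
with marginalised Dirichlet-multinomial likelihood (the truncation error
of the C = 50 stick-breaking representation is far below the +-0.03
tolerance); (ii) a successive-conditional ("getting it right") simulation
— sample parameters from the prior, regenerate data, apply one full
update scan, repeat — must keep alpha, sigma and zeta distributed as
their priors to within 3 autocorrelation-adjusted Monte-Carlo SEs, which
jointly validates every conditional update; (iii) parameter recovery on
the planted-effect preset described below.

## Cluster characterisation

Heat-map labels are computed from the continuous estimates, not the
categorical profiles: the label is the quartile bin (population cut
points) containing the within-cluster median, so tie-collapsing during
discretisation cannot move a label. Even-sized clusters use the lower
middle order statistic, keeping the median on an observed value and the
bin assignment unambiguous. Clusters are ranked by within-cluster median
cumulative use (descending, ties by cluster id).

## Kernel-machine model

Y = h(z) + W beta + eps, with h given a Gaussian-process prior with
covariance lambda sigma^2 K, K(z_i, z_j) = exp(-sum_p r_p (z_ip -
z_jp)^2) on standardised exposures. h is never sampled pointwise; all
inference uses the marginalised likelihood Y ~ N(W beta, sigma^2 (I +
lambda K)) (smaller state, directly testable against a dense multivariate
normal density). Hierarchical variable selection encodes the strictest
reading of "grouped exposures may not enter the same model": each group
has a Bernoulli(0.5) activity indicator and an active group contributes
exactly one member with r_p ~ Uniform(0, 100). Activation proposes r from
a log-uniform density on [0.01, 100] with the full proposal correction —
a pure-mixing choice; the posterior is unchanged. beta and sigma^2 are
conjugate given the marginal covariance; lambda and active r move by
log-scale random walks.

lambda ~ Gamma(1, 1) (mean 1) is a deliberate calibration: with a diffuse
lambda prior the log-determinant (Occam) penalty of an active kernel term
systematically depresses null-data group PIPs below the prior inclusion
probability; with mean-1 lambda the kernel can shrink away under null data
and PIPs stay near the prior, while strong signals still drive the
relevant group's PIP to ~1. Group PIPs are the fraction of kept draws
with the group active; conditional PIPs are computed among group-active
draws (and are reported as undefined, not zero, for never-active groups).
No numeric PIP values from any particular dataset are claimed — only
ranking behaviour, which is what the tests assert.

## Spatial statistics

Global Moran's I = (n/S0) sum w_ij z_i z_j / sum z_i^2 on centred values;
E[I] = -1/(n-1). Local I_i = (z_i/m2) sum_j w_ij z_j satisfies
sum_i I_i = S0 I. Weights are explicit configuration — k-nearest (k = 8,
row-standardised) by default, since residences are irregular points and
k-nearest cannot produce islands; distance-band and rook-on-grid are
available, and islands raise an error naming the offending points.
Inference is by random permutation with the +1 correction
p = (1 + #{|I*| >= |I|})/(n_perm + 1) (default 9,999 permutations,
two-sided); local tests use conditional permutation (hold z_i, permute the
rest) with optional Benjamini-Hochberg adjustment. Kernel density
surfaces use a Gaussian kernel with a metric bandwidth on a padded grid
(integral within 2% of 1 when padding >= 4 bandwidths). No numeric
reproduction of any particular study's Moran statistics is claimed; the
weights scheme of the motivating analysis is unstated, so the scheme used
is always recorded in the output metadata.

## Synthetic data

`generate_use_report_scenario` emulates the structure of use-report data:
a grid of one-square-mile sections (default 12 x 8, side 1609.34 m),
biweekly application events, and per-section kilograms that are
zero-inflated log-normal — matching the right-skewed, zero-heavy shape of
real per-pesticide summaries (e.g. a median near zero with a mean tens of
times larger for the most inflated actives). Within-chemical-class
correlation comes from a one-factor copula: a shared per-section Gaussian
factor per class (default loading sqrt(0.8)) drives both the
use/no-use threshold and the log-magnitude, reproducing the block
correlation structure of real between-pesticide Spearman matrices (OPs
pairwise ~0.7-0.9). Default zero-inflation is 0.3, raised to 0.6-0.75
for the actives whose real 25th percentile is zero (naled, malathion,
thiodicarb, cypermethrin, esfenvalerate). Latent use patterns are
assigned to contiguous grid bands and residences are placed inside their
cluster's band, so cumulative use is spatially autocorrelated by
construction — making the spatial-clustering analysis reproducible in
simulation. The outcome is FSIQ-scale: 100 + cluster effect + linear
confounder term + N(0, noise_sd^2), with a 10-confounder set mirroring
the covariates of the motivating cohort design; the general default
noise_sd = 10 reflects a realistic adjusted-IQ residual scale.

`generate_profiles_direct` bypasses the GIS chain and draws categorical
profiles given cluster labels. The named recovery preset
(`fsiq_recovery_preset`) plants 3 balanced clusters with effects
(0, -6.9, -6.4) — deficits at the scale reported for the highest-use
profile clusters in the motivating analysis — n = 300, 10 confounders,
per-cluster category distributions peaked (0.7) on a signature quartile
with the low-use cluster peaked on quartile 1, and noise_sd = 4.0. The
preset's noise is set so the standard error of a cluster-mean difference
(~0.6 IQ points at n = 300/3 clusters) sits well inside the +-1.5 recovery
band: the preset tests the sampler's ability to recover planted effects,
not robustness to irreducible noise.

**What passing tests do not show.** The generator has no volatility,
degradation, deposition or application-method physics, no crop rotation,
no geodesic coordinates, and independence between the confounders and the
exposure process; recovery results on it demonstrate correctness of the
inference machinery under the model's own assumptions, not performance on
real exposure misclassification or confounding structure.

## Problem sizes used by the routine checks

The enumeration oracle runs at n = 6 (203 partitions, 100,000 sweeps);
recovery uses 20 replicates of the n = 300 preset at 2,000 burn-in /
20,000 sweeps with the stored chain thinned to 2,000 draws; the
prior-recovery simulation runs 5,000 cycles at n = 8; kernel-model checks
use n = 100 (null, 2,500 iterations) and n = 150 (signal, 20 x 800
iterations); permutation calibration uses 200 null replicates at n = 60
with 199 permutations; the end-to-end pipeline example uses n = 120 with
500/5,000 sweeps. These sizes were chosen so each check has the power to
fail visibly while the whole suite stays quick to run.

## Known limitations

* The truncated stick-breaking sampler has no label-swap or split-merge
  moves; co-clustering summaries are label-invariant, but at much larger n
  mode exploration would benefit from such moves.
* The kernel model's n^3 Cholesky per proposal limits it to a few hundred
  subjects — the intended regime for cohort data of this kind.
* Conditional PIPs are exchangeable across perfectly collinear group
  members (~0.5/0.5 for a duplicated pair); this is the designed
  behaviour, not an identifiability failure, and mirrors why grouped
  selection is used in the first place.
* The second-stage regression ignores clustering uncertainty by design
  (it conditions on the hard best partition), which is exactly the
  limitation the outcome-supervised mode exists to avoid.
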