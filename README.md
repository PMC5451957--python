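# profilemix

Joint analysis of residential pesticide-use profiles and a continuous
health outcome.

Epidemiologic studies of agricultural communities face a recurring
problem: people are exposed to many pesticides at once, use of different
actives is highly correlated (Spearman ρ of 0.7–0.9 within a chemical
class is typical), and single-pollutant regressions cannot disentangle
them. `profilemix` implements a multipollutant workflow for this setting,
aimed at environmental epidemiologists working with use-report data
(e.g. California PUR records) and geocoded residences:

1. **Exposure assessment** (`profilemix.exposure`) — buffer-weighted,
   pregnancy-average use estimates: kilograms applied in each
   one-square-mile section are weighted by the fraction of section area
   inside a 1-km disk around the maternal residence, summed within
   trimesters (≥ 75 days of known residence per trimester, ≥ 2 qualifying
   trimesters), averaged, filtered for contrast (median > 0 and
   q75 ≥ 2·q25), and discretised into quartile categories.
2. **Bayesian profile regression** (`profilemix.bpr`) — an
   outcome-supervised Dirichlet-process mixture over the categorical
   profiles x_i = (x_i1…x_iP):

       v_c ~ Beta(1, α),  ψ_c = v_c ∏_{l<c}(1−v_l),   α ~ Gamma(2, 1)
       x_ip | z_i = c ~ Categorical(φ*_cp·)
       Y_i = θ_{z_i} + W_i β + ε_i,   ε_i ~ N(0, σ²)
       φ*_cpk = ζ_p φ_cpk + (1−ζ_p) ρ_pk        (continuous variable selection)

   fit by blocked Gibbs on a truncated stick-breaking representation.
   Posterior co-clustering probabilities yield a "best" partition
   (least-squares draw or medoids); each cluster's adjusted expected
   outcome is summarised against the lowest-exposure reference cluster,
   with deficit probabilities. A sensitivity mode refits without the
   outcome and cross-tabulates the two partitions.
3. **Cluster characterisation** (`profilemix.characterize`) — quartile
   heat-map labels ("very low" … "very high"), cumulative-use ranking,
   and the second-stage OLS used with the unsupervised partition.
4. **Kernel-machine variable importance** (`profilemix.bkmr`) — Gaussian
   kernel machine regression, Y = h(z) + Wβ + ε with
   K(z_i,z_j) = exp(−Σ_p r_p (z_ip−z_jp)²), with hierarchical variable
   selection: each chemical class carries an activity indicator and an
   active class contributes exactly one member, yielding group and
   conditional posterior inclusion probabilities (PIPs).
5. **Spatial statistics** (`profilemix.spatial`) — global and local
   Moran's I with permutation inference, and kernel-density surfaces of
   cluster residences.
6. **Synthetic scenarios** (`profilemix.datagen`) — zero-inflated
   log-normal use reports with a one-factor within-class copula, spatially
   contiguous planted clusters, and an FSIQ-scale outcome with planted
   cluster effects, so the whole chain is testable with known ground
   truth.

## Worked example

Run the shipped 120-subject scenario end to end (a few minutes):

```sh
profilemix run-all --config examples/small_scenario.yaml --outdir runs/demo
```

The run directory contains, among other artifacts, `cluster_report.csv`
(cluster-level adjusted outcome vs the reference), `heatmap.csv`,
`partition_crosstab.csv` (with vs without outcome feedback),
`bkmr_group_pips.csv`, `moran.json` and a `report.md` that renders them.
Selected rows of the cluster table printed by this exact command:

```
 cluster  n  adjusted_mean  diff_vs_ref  diff_lo  diff_hi  prob_deficit
       2 34      93.121818       -6.585  -11.669   -1.536        0.9932
       6 31      99.707134          Ref      Ref      Ref           Ref
       8  8      88.483232      -11.224  -19.120   -3.483        0.9972
```

Cluster 6 is the automatically selected low-exposure reference. The
generator planted deficits of −6.9 and −6.4 on its two high-use spatial
patterns; the largest recovered high-use cluster (n = 34) shows −6.6
(95% CrI −11.7, −1.5) with posterior deficit probability 0.99, while
small splinter clusters (n ≤ 8) carry correspondingly wide intervals.
`moran.json` from the same run reports strong spatial clustering of
cumulative use (I = 0.638, permutation p = 0.001 at 999 permutations) —
the planted patterns are spatially contiguous — and a much weaker signal
for the outcome (I = 0.107).

Reruns with the same master seed are byte-identical: one seed
deterministically derives every stage seed, and `manifest.json` records
the resolved config plus a checksum for every artifact.

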