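# Methods

## Family metrics

The analysis table has one row per family and is assembled from four
species-level inputs: a checklist (species → family/order, accepted-name
flag, horticulture flag, coverage flag), a long-format occurrence table
of (species, region, status ∈ {native, naturalized}) records, a region
table with precomputed areas (total, tropical, temperate, km²), and a
dated family-level Newick tree. Regions are assumed non-overlapping and
their tropical/temperate split is consumed as given (no GIS is done
here); the two zonal areas must sum to the total within 1e-6 relative.

A family enters the analysis only if it has at least `min_richness = 50`
accepted species, is a tip of the tree, has a positive stem age, and has
at least one species with native-range records. Every exclusion is
logged with its first failing criterion. Only accepted species count in
any denominator.

* **Diversification rate.** Stem-age method-of-moments estimator
  r = ln(n(1−ε)+ε)/t with ε the assumed relative extinction μ/λ. Both
  bounds ε = 0 and ε = 0.9 are computed; the ε = 0.9 column is the
  analysis predictor, the ε = 0 column is carried for comparison. For
  species-rich families (n ≥ 1000) the two bounds differ by less than
  ~35% relative, so the choice of bound does not drive the analysis.
* **Range sizes.** A species' range is the summed area of its native
  regions (an upper bound on the true range, since presence anywhere in
  a region counts the whole region). Species with no native records are
  *excluded* from family means rather than zero-filled — a missing
  distribution is not a zero range. Family means are arithmetic means
  over the remaining species; tropical/temperate means use the zonal
  area components, which sum to the total by construction. A
  coverage-subset utility compares range distributions between species
  with complete vs partial global information as a bias check.
* **Naturalization success.** (naturalized species / total species) ×
  total naturalized (species, region) records. The record count sums
  per-species distinct-region counts over the family's naturalized
  species; regions shared by several species are *not* deduplicated
  (each (species, region) establishment is evidence of success). The
  index is 0 exactly when no species is naturalized.
* **Horticultural use.** Proportion of the family's accepted species in
  the horticulture compilation.

## Transforms and design matrix

Area predictors span orders of magnitude and are log10(x+1)-transformed;
the two proportions-derived quantities (horticultural use, and the
response index) are sqrt-transformed; the diversification rate enters
untransformed. All main-effect predictors are then standardized to
mean 0, SD 1 (n−1 denominator). Interaction columns are elementwise
products of the standardized parents and are not re-standardized, so
main-effect coefficients remain interpretable at the interaction's zero
point. The response is transformed but not standardized (configurable).
Transforms are overrideable per column in the run config. A Pearson
correlation audit of all predictor pairs reports the strongest
off-diagonal entry.

Model 1 is {rate, mean range, horticulture}; model 2 replaces the
pooled range with its tropical/temperate split and adds rate × range
interactions; model 3 instead adds rate × horticulture.

## Phylogenetic covariance

The random-effect structure is the tip-by-tip matrix of shared
root-to-MRCA path lengths, rescaled entrywise by 1/√(d_i d_j) to unit
diagonal (correlation form). Rescaling makes σ²_p comparable across
trees and handles non-ultrametric inputs; it is the package's choice —
an unscaled covariance is equivalent up to a rescaling of σ²_p on
ultrametric trees. Multifurcations are allowed; pruning to the analysis
families re-roots at the subset's MRCA (shared basal history, constant
across the subset, drops out). Eigenvalues below 1e-8 are clamped there
(logged); matrices with eigenvalues below −1e-8 are rejected.

## The Gibbs sampler

The model y = Xβ + u + e with u ~ N(0, σ²_p A), e ~ N(0, σ²_e I) has
conjugate full conditionals throughout:

* (β, u) jointly Gaussian via the mixed-model normal equations;
* σ²_p ~ InvGamma((ν+q)/2, (νV + uᵀA⁻¹u)/2);
* σ²_e ~ InvGamma((ν+n)/2, (νV + rᵀr)/2), r = y − Xβ − u.

Priors: scalar inverse-Wishart(V = 1, ν = 0.002) on each variance —
i.e. the inverse-gamma reduction above — and N(0, 1e10) per fixed
effect (effectively flat). The joint (β, u) block is sampled exactly by
working in the eigenbasis of A (or the group-incidence basis for the
order-level GLMM), where the random-effect block of the precision is
diagonal: β is drawn from its Schur-complement marginal and u | β from
a diagonal Gaussian. This is an algebraic reformulation, not an
approximation, and brings the per-iteration cost to O(q p²). The inner
loop is numba-compiled; chains are bit-reproducible for a given seed.

Initialization: β at the least-squares solution, u = 0, both variances
at half the response variance scaled by (0.1, 1, 10) across the three
chains to give overdispersed starts for the convergence diagnostics.
Production settings are 520 000 iterations, burn-in 20 000, thinning
100, three chains (5 000 retained draws per chain); the analysis
scripts, the model-selection sweeps, and the simulation studies use the
shortened 52 000 / 2 000 / 10 settings, which retain the same 5 000
draws per chain at a tenth of the autocorrelation-averaging budget.

Summaries pool chains after burn-in/thinning: posterior mean, 95%
highest-posterior-density interval (quantile intervals available),
effective sample size from the autocorrelation time (capped at the
retained draw count), and pMCMC = 2·min(Pr(>0), Pr(<0)) floored at
2/draws and reported as "< floor" at the floor. The order-level
validation GLMM replaces A by a family-to-order incidence structure
with a single group variance; the sampler is otherwise identical.

## Diagnostics and model selection

Gelman–Rubin PSRF per parameter uses √(((n−1)/n·W + B/n)/W); the
multivariate factor is the Brooks–Gelman largest-eigenvalue form with
the (m+1)/m correction. Ratios are floored at 1 (values below 1 are
estimator noise). Convergence requires multivariate PSRF < 1.1. DIC is
D̄ + pD with the plug-in pD = D̄ − D(θ̄) evaluated at the posterior
means of (β, u, σ²_e); the deviance is the Gaussian conditional
deviance given the fitted random effects. Stepwise selection fits every
predictor subset that includes the diversification rate and ranks by
DIC (ascending), at the shortened settings by default.

Note that conditional-likelihood DIC discriminates nested fixed effects
well when the random effect is phylogenetically structured, but poorly
in the degenerate A = I case, where a saturated tip-level effect can
absorb an iid covariate; the selection studies therefore simulate on
trees, matching the analysis setting.

## Synthetic data

The generator emulates the shape of the real inputs at explicit,
seed-reproducible parameters:

* **Tree**: forward Gillespie birth–death (defaults λ = 0.06, μ = 0.03
  per Myr), conditioned on the target tip count by stopping at the
  first moment the extant count reaches it and extending terminal
  branches by an Exp(n(λ+μ)) time; extinct lineages are pruned, so tip
  stem ages are divergence times from the extant sister clade.
* **Regions**: 60 regions, log-normal areas (log-mean 12, log-SD 1.2 →
  median ~163 000 km²), Beta(0.8, 0.8) tropical fraction.
* **Richness**: a log-normal target (log-mean ln 400, log-SD 1.2,
  clipped to [50, 30 000]) sets each family's size; the implied true
  rate r = ln(n)/t is recorded and the realized richness re-derives
  from round(exp(r·t)·log-normal noise), so the stem estimator at ε = 0
  recovers r up to the noise. 15% of families are forced below the
  50-species filter to exercise the exclusion logic, and ~3% extra
  unaccepted names per family exercise the accepted-only counting.
* **Response (inverse construction)**: the latent family score
  s = intercept + xᵀβ + u + e is drawn on the sqrt-index scale with the
  *pipeline's own* standardized predictors x, Brownian tip effects u
  (covariance σ²_p A) and Gaussian noise e (defaults β = (0.5, 0.4,
  0.38), intercept 6, σ²_p = σ²_e = 1, chosen at the effect magnitudes
  the design is meant to detect). Naturalized counts are then chosen so
  the recomputed index satisfies √I = s up to integer rounding: with
  naturalized fraction ~0.2 the rounding error on √I is below ~0.03.
  Residuals that would drive √I negative are resampled (logged, capped).
  This makes the Gaussian PGLMM exactly well-specified on the generated
  data, so interval calibration is a meaningful check.

What the generator does *not* emulate: spatial autocorrelation and
dispersal limitation in occupancy, recording bias between regions,
taxonomic error, and trait-driven (non-Brownian) phylogenetic signal.
Passing tests therefore demonstrate that the estimator, aggregation and
sampler are correct under the stated model, not that the model is
adequate for any particular real data set.

## Numerical choices and limitations

* Master seed → per-component seeds via CRC-32 of the component name;
  all randomness flows from explicit seeds, never the wall clock.
* Simulation-study sizes (200 calibration replicates at 168 tips with
  single chains; 50 DIC replicates at 100 tips) were chosen to keep the
  Monte-Carlo error of coverage estimates near 1.5% while remaining
  single-CPU-friendly.
* HPD intervals are computed by the shortest-window scan on sorted
  pooled draws; degenerate (constant) draw sets return a point interval.
* The pipeline exits nonzero if any requested model fails the PSRF
  threshold; partial outputs are kept with a FAILED marker naming the
  stage.
* Real-data reproduction requires the published family table and dated
  tree as inputs; the package reads them in the documented CSV/Newick
  formats but does not bundle them.
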