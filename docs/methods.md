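# Methods

`basinrates` reproduces, on fully synthetic data, an assemblage-level
analysis of recent speciation rates: per-species ("tip") speciation-rate
statistics are read off a time-calibrated phylogeny, averaged over the
species co-occurring in each drainage basin, and regressed on biotic
(trait-evolution rates, species diversity) and abiotic (climate, habitat)
basin covariates, with the explained variance decomposed by hierarchical
partitioning (lmg) and group-level commonality analysis.

## Tip speciation rates

For tip *i* with root-to-tip edge lengths `l_1` (pendant) … `l_N`
(rootmost), the equal-splits statistic is

    ES_i = sum_j l_j * 2^-(j-1),      DR_i = 1 / ES_i   (My^-1)

The weight halves each time a split is crossed rootward (pendant-first
indexing — the standard convention; the alternative root-first indexing
changes ES by a bounded factor and nothing qualitative). A k-furcation is
treated as (k−1) simultaneous splits: crossing it divides the weight by
`2^(k-1)`, and it contributes (k−1) nodes to the node-density numerator.
The node-density rate is the number of splits on the root-to-tip path
divided by the root-to-tip distance. The implementation is cross-checked
in the tests against `picante::evol.distinct(type="equal.splits")`.

Under pure birth the *harmonic* mean of tip DR (equivalently `1 / mean
ES`) recovers the true speciation rate to within about 1%; the arithmetic
mean is characteristically inflated by a factor ≈ 1.4 because DR is the
reciprocal of a positive random variable. Both facts are asserted in the
test suite; wherever a single rate-recovery number is quoted it is the
harmonic mean.

## Trait-evolution rates

The per-tip trait-rate proxy is the squared standardized independent
contrast at the tip's parent node (Felsenstein's pruning pass; sister
tips of a cherry share one contrast). Each standardized contrast has
variance exactly σ² under single-rate Brownian motion, so the squared
contrast is an unbiased — though individually χ²₁-noisy — local estimate
of the Brownian rate in trait-units²·My⁻¹. This is deliberately the
simplest defensible per-tip σ² proxy; it stands in for posterior-mean
tip rates from shift-model MCMC machinery, which is out of scope here.

## Imputation and missingness diagnostics

Missing trait values are imputed per trait under single-rate Brownian
motion: the root mean by GLS and σ² by the contrasts (REML) estimator
over observed tips, then each missing tip is filled with the conditional
mean of the implied multivariate normal given the observed tips
(covariance = σ² × shared-path-length matrix), with the conditional SD
reported per imputation. Imputation is univariate per trait, keeping a
closed-form test surface; multivariate imputation is a non-goal.

Phylogenetic clumping of the missingness pattern is scored with the
Fritz–Purvis D statistic: the observed sum of sister-clade differences of
nodal values (daughters averaged rootward), scaled between a
label-permutation null (E[D] = 1) and a Brownian-threshold null matched
to the observed prevalence (E[D] = 0). The Brownian null labels the upper
tail True — the orientation convention; `d_obs` and the permutation null
are exactly class-symmetric.

## Basin-level analysis

Per-basin summaries are the mean (or, for the speciation rate, optionally
median/min/max) of per-species values over the species present; inverse
range-size weights `w_s = 1/(number of basins occupied by s)` are the
configurable reading of "down-weight wide-ranging species". Species
density corrects richness for area by `SD = SR / A^z` with the
species–area exponent z (default 0.3, within the empirical 0.25–0.50
band). Soil diversity is the Shannon index (nats) of substrate-type
composition.

The regression surface: all predictors (and the response) are z-scored
with the sample (n−1) SD, basin area log10-transformed first. Predictors
with VIF ≥ 5 are removed iteratively, highest first, refitting each
round. Coefficients carry two-sided t-based 95% CIs with no multiplicity
correction. lmg shares are computed by weighted subset enumeration (2^p
fits, weights `|S|!(p−|S|−1)!/p!`), equal to averaging incremental R²
over all p! orderings; the brute-force all-orderings oracle is retained
in the tests. Commonality components across the four mechanism groups
come from Möbius inversion of the group-union R² lattice; negative shared
components (suppression) are reported raw with a flag. Moran's I on the
OLS residuals uses row-standardized k-nearest-neighbour weights (k = 8;
directed graph, exactly k neighbours per row, distance ties broken by
index) with a two-sided permutation p (999 permutations, seeded).

## The synthetic study system

The generator emulates the statistical structure the analysis assumes,
at desk scale, with every truth emitted for recovery tests:

* **Tree.** A crown clade of age 32 My under birth–death (λ₀ = 0.14,
  μ = 0.03 My⁻¹) with Poisson rate shifts (η = 0.05 My⁻¹ branch⁻¹); each
  shift draws a fresh λ = λ₀·m with m log-normal (median 1, log-SD 1.2,
  clamped to [0.05, 20]). Extinction is constant across regimes (the
  analysis targets speciation, not extinction, geography). Extinct
  lineages are simulated and pruned, so estimators face extant-only
  trees; accepted trees have 250–800 tips ("a clade of a few hundred
  species") and a surviving crown. Shifts land mid-branch; after pruning,
  each branch is painted with the regime at its tipward end and that
  painting is the generative truth for the trait model, so the painted
  model is exactly the one simulated.
* **Traits.** Log10 body size evolves with the regime-linked rate
  σ²(λ) = σ²₀·(λ/λ₀)² (σ²₀ = 0.01 log₁₀-units²·My⁻¹); the quadratic link
  is deliberately stronger than proportionality so the trait channel
  carries a recoverable signal through the χ²-noisy per-tip rate proxy
  (see "What recovery tests show" below). Body size is emitted on the
  raw cm scale so the pipeline's log10 step has real work. The other four
  traits evolve at constant σ² = 0.01; relative eye size is built as
  0.9 × elongation plus its own Brownian residual, giving the VIF screen
  a realistic near-duplicate pair. 5% of each trait is masked at random.
* **Landscape.** 100 basins on a jittered 10×10 lattice; elevation rises
  linearly along x to 4000 m (noise SD 200 m); temperature follows a
  5.5 °C/km lapse rate with weather noise (SD 12 °C); stream gradient is
  a noisy derivative of elevation; area, runoff and soil composition are
  pure noise. Elevation is thus the single abiotic driver; everything
  else is noise or a noisy derivative.
* **Occupancy.** Each species occupies a contiguous set (nearest
  neighbours of a home basin; range sizes log-normal, median ≈ 7
  basins). The home's elevation rank is coupled to the species' regime
  rate through a latent Gaussian with a species-level term (strength
  ρ = 0.30) plus a clade-level term (strength 0.85) shared within
  phylogenetic blocks of ≤ 10 tips — related lineages radiate in place,
  so basin composition carries lineage-level noise that does not average
  out (the *Orestias*-like endemic-radiation structure). Bounding the
  block size keeps any single clade from dominating the placement noise.

Determinism: every stage consumes a `numpy` generator seeded from the
config; a fixed seed reproduces all tables byte-for-byte.

## What the recovery tests do and do not show

Closed-form and oracle checks (equal-splits values, BM tip covariance,
conditional-mean imputation, lmg vs all-orderings, commonality vs
inclusion–exclusion, Moran null, D-statistic calibration) are sharp and
seed-stable.

The end-to-end headline — the body-size-rate predictor carrying the
largest lmg share with elevation the leading abiotic share — is only
partially recoverable at this scale, and the package reports that
honestly rather than smoothing it over. The reason is structural: the
per-tip proxies are noisy (tip-level correlation with the true rates
≈ 0.3–0.4 for DR and ≈ 0.2–0.3 for squared contrasts), and because
co-occurring species are phylogenetically clustered, their estimation
errors are correlated within basins and do not average out, while
elevation enters the design noise-free. Any elevation→composition
coupling strong enough to make elevation reliably the top abiotic
predictor therefore also lets it outrank the trait-rate predictor in
most seeds; weakening the coupling flips which clause fails. Basin-level
*sign* recovery (rates and trait rates increasing with elevation) holds
in ≈ 85–95% of seeds; the full ranking conjunction holds in ≈ 20–30%.
Smoothed tip-rate estimators (posterior means under an explicit shift
model) would close this gap; they are out of scope by design. The
acceptance tests encode the ranking targets at their stated thresholds
and are expected to fail them — a documented property of this estimator
stack at this scale, not a defect of the pipeline machinery.

Real data differ from this generator in ways the tests cannot speak to:
river networks are not lattices, ranges are shaped by dispersal and
drainage history rather than radial contiguity, sampling is incomplete
and spatially biased, and empirical rate estimates are smoothed by the
inference machinery that produced them.

## Numerical choices and degenerate inputs

Branch lengths must be strictly positive (no unit-length defaulting —
rates carry My units); the Newick writer emits 9 significant digits, so
round-trips are exact to ~1e-7 relative. Zero-variance design columns,
single-class indicators, all-zero soil rows, empty post-filter matrices
and singular covariances are errors, never silent defaults. Polytomies
are accepted on input and folded sequentially (in child order) in the
contrasts pass; the simulator emits strictly bifurcating trees. VIF ties
are broken by column order; knn distance ties by point index; the
thresholded Brownian null of the D statistic takes exactly the observed
number of positives (upper tail).
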