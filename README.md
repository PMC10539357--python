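# basinrates

Why do some regions accumulate species faster than others? `basinrates`
is an analysis pipeline for the assemblage-level macroecology of recent
speciation: it reads per-species ("tip") speciation-rate statistics off a
time-calibrated phylogeny, maps them onto drainage-basin assemblages, and
asks how much of their geographic variation is carried by rates of
morphological evolution, diversity-dependence, climate, and habitat. It
is aimed at phylogenetic macroecologists who want the full chain —
tree → tip rates → trait rates and imputation → basin summaries →
regression surface — as tested, seedable code, together with a synthetic
generator that makes every stage verifiable against closed forms and
parameter recovery.

## The statistics at the core

* **Tip speciation rate (equal splits / DR).** For tip *i* with
  root-to-tip edge lengths `l_1` (pendant) … `l_N`:
  `ES_i = Σ_j l_j · 2^-(j-1)` and `DR_i = 1/ES_i` (My⁻¹); a node-density
  rate (splits on the path / path length) serves as the concordance
  check.
* **Tip trait-evolution rate.** The squared standardized independent
  contrast at the tip's parent — an unbiased per-tip estimate of the
  Brownian rate σ² (trait-units²·My⁻¹).
* **Brownian imputation.** Missing trait values are filled with the
  conditional mean of the BM multivariate normal given observed tips
  (covariance σ²·V, V the shared-path-length matrix); the Fritz–Purvis
  *D* statistic tests whether missingness is phylogenetically clustered.
* **Regression surface.** Basin-level standardized OLS with VIF < 5
  screening; hierarchical partitioning (lmg: `share_k = Σ_S w(|S|)
  [R²(S∪k) − R²(S)]`, summing to R²); commonality analysis of unique and
  shared R² across the four mechanism groups; Moran's *I* on residuals;
  rate-vs-coordinate correlations.
* **Synthetic generator.** Birth–death trees with Poisson rate-shift
  regimes, regime-linked Brownian body-size evolution, and an
  elevation-structured landscape in which fast-speciating, fast-evolving
  lineages preferentially occupy upland basins.

See `docs/methods.md` for conventions, parameter defaults and the honest
account of what the recovery tests show.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic system (seed 11) and write their tables under
`results/analysis/`:

```sh
cd analysis
python 01_simulate_dataset.py
python 02_tip_rates.py
python 05_fit_model.py   # (03, 04 compute the intermediate tables)
```

`01` prints the study system:

```
591 extant species over 32.0 My, 100 basins
true speciation-rate range across tips: 229.8-fold
regimes represented at the tips: 70
```

`02` shows the tip-rate stage — DR spans a wide range, agrees with the
node-density estimator, and tracks the true regime rates:

```
DR across 591 tips: 0.0423-10.3419 My^-1 (245-fold); harmonic mean 0.4440
DR vs node-density Spearman rho = 0.744 (cross-estimator concordance)
DR vs true regime rate Spearman rho = 0.789
```

`05` fits the regression surface. On this seed the model explains 76% of
the variance in basin mean speciation rate; elevation carries the
largest lmg share, with most explained variance shared between habitat
and trait-evolution predictors, and the residuals retain positive
spatial autocorrelation:

```
model R^2 = 0.764 over 100 basins
  elevation                +0.842 [+0.678, +1.007]
lmg shares (% of explained variance):
elevation                  61.3
rate_maxillary_length      19.5
largest shared component: habitat & morphological-evolution = 0.2078
Moran's I on residuals = +0.3112 (E[I] = -0.0101, p = 0.001)
```

Which predictor ends up on top varies across seeds — the generator's
rate proxies are deliberately noisy at the species level — and
`analysis/06_sensitivity.py` probes how the ranking responds to the
basin statistic (mean/median/min/max), minimum-richness filters,
range-size weighting and exclusion of the fastest taxa.

The same pipeline runs as one command over a YAML config, on synthetic
or user data (Newick tree + TSV trait/incidence/basin tables):

```sh
basinrates run-all --config configs/default.yaml --out results/run
basinrates sweep   --config configs/default.yaml --out results/sweep
```

## Layout

```
src/basinrates/     treeio, simulate, tiprates, traits, assemblage,
                    inference, pipeline, cli
analysis/           numbered narrative drivers (01 … 06)
tests/              unit, property and acceptance suites
scripts/            acceptance.py
configs/            example run configuration
docs/methods.md     model, conventions, limitations
```
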