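# Default run: simulate the synthetic study system and fit the surface.
# Replace the simulate block with tree_path/traits_path/incidence_path/
# basins_path to analyze your own data.
simulate:
  seed: 11
seed: 11
basin_stat: mean          # mean | median | min | max (speciation-rate summary)
rate_column: DR           # DR | node_density
use_density: false        # true -> species density SD = SR / A^z replaces SR
z_exponent: 0.3
min_species: 1
weight_by_range: false    # inverse range-size weighting of basin summaries
vif_threshold: 5.0
alpha: 0.05
moran_k: 8
moran_permutations: 999
d_permutations: 199
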