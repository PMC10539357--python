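"""Join species-level rates to basins: assemblage means, richness, soil
diversity; the geographic fields of the analysis."""

import numpy as np
import pandas as pd

from basinrates.pipeline import assemble_design
from basinrates.tiprates import tip_rate_table
from basinrates.treeio import parse_newick
from common import RESULTS, run_config

tree = parse_newick((RESULTS / "data" / "tree.nwk").read_text())
incidence = pd.read_csv(RESULTS / "data" / "incidence.tsv", sep="\t", index_col=0)
basins = pd.read_csv(RESULTS / "data" / "basins.tsv", sep="\t", index_col=0)
tip_rates = pd.read_csv(RESULTS / "tip_rates.tsv", sep="\t", index_col=0)
trait_rates = pd.read_csv(RESULTS / "trait_rates.tsv", sep="\t", index_col=0)

summary, design, response, centroids, flog = assemble_design(
    tree, tip_rates, trait_rates, incidence, basins, run_config()
)
summary.join(centroids).to_csv(RESULTS / "basin_summary.tsv", sep="\t")

def r(a, b):
    return np.corrcoef(a, b)[0, 1]

print(f"{len(summary)} basins; richness {summary['species_richness'].min():.0f}-"
      f"{summary['species_richness'].max():.0f}")
print(f"basin mean DR range: {response.max() / response.min():.1f}-fold")
print("elevation correlations (the spatial coupling of the model):")
print(f"  mean speciation rate  r = {r(response, summary['elevation']):+.3f}")
print(f"  mean body-size rate   r = {r(summary['rate_body_size'], summary['elevation']):+.3f}")
print(f"  temperature           r = {r(summary['temperature'], summary['elevation']):+.3f}")
print(f"written {RESULTS / 'basin_summary.tsv'}")
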