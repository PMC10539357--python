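"""The statistical core: standardized OLS of basin mean speciation rate on
eleven-ish biotic and abiotic predictors, VIF screening, lmg hierarchical
partitioning, four-group commonality analysis, and spatial diagnostics."""

import pandas as pd

from basinrates.pipeline import GROUPS, assemble_design, fit_surface
from basinrates.tiprates import tip_rate_table
from basinrates.treeio import parse_newick
from common import RESULTS, run_config

tree = parse_newick((RESULTS / "data" / "tree.nwk").read_text())
incidence = pd.read_csv(RESULTS / "data" / "incidence.tsv", sep="\t", index_col=0)
basins = pd.read_csv(RESULTS / "data" / "basins.tsv", sep="\t", index_col=0)
tip_rates = pd.read_csv(RESULTS / "tip_rates.tsv", sep="\t", index_col=0)
trait_rates = pd.read_csv(RESULTS / "trait_rates.tsv", sep="\t", index_col=0)

cfg = run_config()
summary, design, response, centroids, _ = assemble_design(
    tree, tip_rates, trait_rates, incidence, basins, cfg
)
fit = fit_surface(design, response, centroids, cfg, n_species=tree.n_tips)

(RESULTS / "fit_report.json").write_text(fit.to_json())

print(f"model R^2 = {fit.ols.r_squared:.3f} over {fit.n_basins} basins")
if not fit.vif_removed.empty:
    print("removed by VIF screen:",
          ", ".join(f"{r.predictor} ({r.VIF:.1f})" for r in fit.vif_removed.itertuples()))
print("\nstandardized coefficients (95% CI):")
co = fit.ols.coefficients
for name, row in co.iterrows():
    flag = "" if row["significant"] else "  NS"
    print(f"  {name:24s} {row['coef']:+.3f} [{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]{flag}")
print("\nlmg shares (% of explained variance):")
print(fit.lmg.sort_values("share", ascending=False)["pct_of_r2"].round(1).to_string())
print("\ncommonality components (unique rows are per-group unique R^2):")
print(fit.commonality[fit.commonality["unique"]]["component"].round(4).to_string())
shared = fit.commonality[~fit.commonality["unique"]]["component"]
print(f"largest shared component: {shared.idxmax()} = {shared.max():.4f}")
print(f"\nMoran's I on residuals = {fit.moran.I:+.4f} "
      f"(E[I] = {fit.moran.expected:+.4f}, p = {fit.moran.p_value:.3f})")
print("coordinate trends of the rate field:")
print(fit.coordinate_corr.round(4).to_string())
print(f"\nwritten {RESULTS / 'fit_report.json'}")
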