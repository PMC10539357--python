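"""End-to-end orchestration: data (synthetic or on disk) -> tip rates ->
trait rates and imputation -> basin summaries -> regression surface.

The pipeline is deterministic given the configured seeds: the simulation
block's seed governs data generation and the run seed governs the
analysis-stage resampling (missingness-D permutations, Moran
permutations).  Every run can write its intermediate tables, a JSON fit
report and a manifest (config hash, version, dropped records) so any
stage can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemblage import (
    FilterLog,
    filter_and_exclude,
    range_size_weights,
    richness_and_density,
    shannon_soil_diversity,
    summarize_rates_by_basin,
)
from .inference import (
    MoranResult,
    OLSReport,
    coordinate_correlation,
    fit_standardized_ols,
    group_commonality,
    lmg_partition,
    morans_i,
    spatial_weights,
    standardize,
    vif_screen,
    vif_table,
)
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset
from .tiprates import tip_rate_table
from .traits import (
    TraitTable,
    impute_traits_bm,
    log10_body_size,
    missingness_d,
    trait_rate_table,
)
from .treeio import Phylogeny, parse_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "FitReport", "run_pipeline", "sweep", "GROUPS"]

#: predictor -> mechanism group (the four-way grouping of the commonality
#: analysis: trait-evolution rates, diversity-dependence, climate, habitat)
GROUPS: dict[str, str] = {
    "rate_body_size": "morphological-evolution",
    "rate_body_elongation": "morphological-evolution",
    "rate_oral_gape_position": "morphological-evolution",
    "rate_maxillary_length": "morphological-evolution",
    "rate_eye_size": "morphological-evolution",
    "species_richness": "diversity-dependence",
    "species_density": "diversity-dependence",
    "temperature": "climate",
    "runoff": "climate",
    "area": "habitat",
    "elevation": "habitat",
    "soil_shannon": "habitat",
    "stream_gradient": "habitat",
}


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: either a simulation block or four input paths."""

    simulate: SimulationConfig | None = None
    tree_path: str | None = None
    traits_path: str | None = None
    incidence_path: str | None = None
    basins_path: str | None = None
    # analysis options
    seed: int = 0
    basin_stat: str = "mean"  # summary of the per-species speciation rate
    rate_column: str = "DR"
    use_density: bool = False
    z_exponent: float = 0.3
    min_species: int = 1
    drop_taxa: tuple[str, ...] = ()
    drop_basins: tuple[str, ...] = ()
    weight_by_range: bool = False
    vif_threshold: float = 5.0
    alpha: float = 0.05
    moran_k: int = 8
    moran_permutations: int = 999
    d_permutations: int = 199
    compute_missingness_d: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = any(
            p is not None
            for p in (self.tree_path, self.traits_path, self.incidence_path, self.basins_path)
        )
        if (self.simulate is None) == (not has_paths):
            raise ValueError("exactly one of simulate block / input paths required")
        if has_paths and None in (
            self.tree_path,
            self.traits_path,
            self.incidence_path,
            self.basins_path,
        ):
            raise ValueError("all four input paths are required together")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        for key in ("drop_taxa", "drop_basins"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class FitReport:
    """Machine-readable regression surface of one run."""

    ols: OLSReport
    vif_initial: pd.Series
    vif_removed: pd.DataFrame
    vif_final: pd.Series
    lmg: pd.DataFrame
    commonality: pd.DataFrame
    moran: MoranResult
    coordinate_corr: pd.DataFrame
    n_basins: int
    n_species: int

    def to_dict(self) -> dict:
        return {
            "n_basins": self.n_basins,
            "n_species": self.n_species,
            "r_squared": self.ols.r_squared,
            "coefficients": _df_records(self.ols.coefficients.rename_axis("predictor")),
            "vif_initial": self.vif_initial.round(12).to_dict(),
            "vif_removed": _df_records(self.vif_removed),
            "vif_final": self.vif_final.round(12).to_dict(),
            "lmg": _df_records(self.lmg.reset_index()),
            "lmg_r_squared": self.lmg.attrs.get("r_squared"),
            "commonality": _df_records(self.commonality.reset_index()),
            "moran": {
                "I": self.moran.I,
                "expected": self.moran.expected,
                "p_value": self.moran.p_value,
                "n_perm": self.moran.n_perm,
            },
            "coordinate_correlation": _df_records(self.coordinate_corr.reset_index()),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kw)


def _df_records(df: pd.DataFrame) -> list[dict]:
    out = df.copy()
    if out.index.name is not None:
        out = out.reset_index()
    recs = out.to_dict(orient="records")
    for r in recs:
        for k, v in r.items():
            if isinstance(v, (np.floating,)):
                r[k] = float(v)
            elif isinstance(v, (np.integer,)):
                r[k] = int(v)
            elif isinstance(v, (np.bool_,)):
                r[k] = bool(v)
    return recs


@dataclass
class PipelineResult:
    config: RunConfig
    tree: Phylogeny
    tip_rates: pd.DataFrame
    trait_rates: pd.DataFrame
    imputation_report: pd.DataFrame
    missingness: dict[str, dict]
    basin_summary: pd.DataFrame
    design: pd.DataFrame
    response: pd.Series
    fit: FitReport
    filter_log: FilterLog
    dataset: SyntheticDataset | None = None


# ---------------------------------------------------------------------------
# stages


def load_inputs(config: RunConfig):
    """Load tree/traits/incidence/basins from disk (TSV + Newick)."""
    tree = parse_newick(Path(config.tree_path).read_text())
    traits = pd.read_csv(config.traits_path, sep="\t", index_col=0)
    incidence = pd.read_csv(config.incidence_path, sep="\t", index_col=0)
    if set(incidence.columns) - set(tree.tip_labels):
        # long form: basin, species [, present]
        raw = pd.read_csv(config.incidence_path, sep="\t")
        if {"basin", "species"} <= set(raw.columns):
            raw["present"] = 1
            incidence = (
                raw.pivot_table(index="basin", columns="species", values="present", fill_value=0)
                .astype(int)
            )
    basins = pd.read_csv(config.basins_path, sep="\t", index_col=0)
    return tree, traits, incidence, basins


def prepare_species_tables(
    tree: Phylogeny,
    traits_raw: pd.DataFrame,
    config: RunConfig,
):
    """Tip rates, trait preprocessing + imputation, tip trait rates.

    These are per-species quantities: independent of the basin options, so
    sensitivity sweeps over basin statistics reuse them unchanged.
    """
    tip_rates = tip_rate_table(tree)
    table = TraitTable(traits_raw)
    table = log10_body_size(table)
    missingness: dict[str, dict] = {}
    if config.compute_missingness_d:
        for col in table.frame.columns:
            miss = table.frame[col].isna()
            if 0 < miss.sum() < len(miss):
                d = missingness_d(
                    tree,
                    miss,
                    n_perm=config.d_permutations,
                    seed=_stage_seed(config.seed, f"missD:{col}"),
                )
                missingness[col] = {
                    "D": d.D,
                    "p_lt_random": d.p_lt_random,
                    "p_gt_bm": d.p_gt_bm,
                }
    completed, report = impute_traits_bm(tree, table)
    trait_rates = trait_rate_table(tree, completed.frame)
    return tip_rates, completed, report, trait_rates, missingness


def assemble_design(
    tree: Phylogeny,
    tip_rates: pd.DataFrame,
    trait_rates: pd.DataFrame,
    incidence: pd.DataFrame,
    basins: pd.DataFrame,
    config: RunConfig,
):
    """Basin summaries + design matrix + response under the run's options."""
    keep = [sp for sp in incidence.columns if sp in set(tree.tip_labels)]
    incidence = incidence[keep]
    incidence, flog = filter_and_exclude(
        incidence,
        min_species=config.min_species,
        drop_taxa=list(config.drop_taxa),
        drop_basins=list(config.drop_basins),
    )
    weights = range_size_weights(incidence) if config.weight_by_range else None

    rate = tip_rates[config.rate_column]
    response = summarize_rates_by_basin(
        incidence, rate.rename("speciation_rate"), stat=config.basin_stat, weights=weights
    )
    summary = pd.DataFrame(index=response.index)
    summary[f"{config.basin_stat}_speciation_rate"] = response
    for col in trait_rates.columns:
        summary[col] = summarize_rates_by_basin(
            incidence, trait_rates[col], stat="mean", weights=weights
        )
    rd = richness_and_density(
        incidence, basins["area"], z=config.z_exponent if config.use_density else 0.0
    ).loc[response.index]
    summary["species_richness"] = rd["SR"]
    if config.use_density:
        summary["species_density"] = rd["SD"]
    soil_cols = [c for c in basins.columns if c.startswith("soil_")]
    if soil_cols:
        summary["soil_shannon"] = shannon_soil_diversity(basins.loc[response.index, soil_cols])
    for col in ("temperature", "runoff", "area", "elevation", "stream_gradient"):
        if col in basins.columns:
            summary[col] = basins.loc[response.index, col]
    centroids = basins.loc[response.index, ["x", "y"]]

    predictors = [c for c in summary.columns if c in GROUPS]
    if config.use_density:
        predictors = [c for c in predictors if c != "species_richness"]
    design = summary[predictors]
    return summary, design, response, centroids, flog


def fit_surface(
    design: pd.DataFrame,
    response: pd.Series,
    centroids: pd.DataFrame,
    config: RunConfig,
    n_species: int,
) -> FitReport:
    """Standardize, screen, fit, partition, and run spatial diagnostics."""
    X = standardize(design, log_cols=("area",) if "area" in design.columns else ())
    y = standardize(response.to_frame("speciation_rate")) ["speciation_rate"]
    vif0 = vif_table(X)
    X_red, removed = vif_screen(X, threshold=config.vif_threshold)
    vif1 = vif_table(X_red)
    ols = fit_standardized_ols(y, X_red, alpha=config.alpha)
    lmg = lmg_partition(y, X_red)
    groups = {c: GROUPS[c] for c in X_red.columns}
    common = group_commonality(y, X_red, groups)
    W = spatial_weights(centroids.to_numpy(), method="knn", k=config.moran_k)
    moran = morans_i(
        ols.residuals.to_numpy(),
        W,
        n_perm=config.moran_permutations,
        seed=_stage_seed(config.seed, "moran"),
    )
    coord = coordinate_correlation(y, centroids)
    return FitReport(
        ols=ols,
        vif_initial=vif0,
        vif_removed=removed,
        vif_final=vif1,
        lmg=lmg,
        commonality=common,
        moran=moran,
        coordinate_corr=coord,
        n_basins=len(y),
        n_species=n_species,
    )


def _stage_seed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; write outputs when ``out_dir`` is set."""
    dataset = None
    if config.simulate is not None:
        dataset = generate_dataset(config.simulate)
        tree = dataset.tree
        traits_raw = dataset.traits_observed
        incidence, basins = dataset.incidence, dataset.basins
    else:
        tree, traits_raw, incidence, basins = load_inputs(config)
        keep = [sp for sp in tree.tip_labels if sp in traits_raw.index]
        if len(keep) < tree.n_tips:
            from .treeio import prune_to_taxa

            tree = prune_to_taxa(tree, keep)

    tip_rates, completed, report, trait_rates, missingness = prepare_species_tables(
        tree, traits_raw, config
    )
    summary, design, response, centroids, flog = assemble_design(
        tree, tip_rates, trait_rates, incidence, basins, config
    )
    fit = fit_surface(design, response, centroids, config, n_species=tree.n_tips)

    result = PipelineResult(
        config=config,
        tree=tree,
        tip_rates=tip_rates,
        trait_rates=trait_rates,
        imputation_report=report.table,
        missingness=missingness,
        basin_summary=summary.join(centroids),
        design=design,
        response=response,
        fit=fit,
        filter_log=flog,
        dataset=dataset,
    )
    if config.out_dir is not None:
        write_outputs(result, Path(config.out_dir))
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.tip_rates.to_csv(out_dir / "tip_rates.tsv", sep="\t")
    result.trait_rates.to_csv(out_dir / "trait_rates.tsv", sep="\t")
    result.imputation_report.to_csv(out_dir / "imputation_report.tsv", sep="\t", index=False)
    result.basin_summary.to_csv(out_dir / "basin_summary.tsv", sep="\t")
    result.design.to_csv(out_dir / "design_matrix.tsv", sep="\t")
    (out_dir / "fit_report.json").write_text(result.fit.to_json())
    (out_dir / "missingness_d.json").write_text(
        json.dumps(result.missingness, sort_keys=True, indent=2)
    )
    cfg = result.config.to_dict()
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "dropped": dataclasses.asdict(result.filter_log),
        "status": "OK",
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str)
    )
    if result.dataset is not None:
        from .treeio import write_newick

        (out_dir / "tree.nwk").write_text(write_newick(result.dataset.tree))
        result.dataset.traits_observed.to_csv(out_dir / "traits_observed.tsv", sep="\t")
        result.dataset.truth.to_csv(out_dir / "truth.tsv", sep="\t")
        result.dataset.incidence.to_csv(out_dir / "incidence.tsv", sep="\t")
        result.dataset.basins.to_csv(out_dir / "basins.tsv", sep="\t")


# ---------------------------------------------------------------------------
# sensitivity sweeps


def sweep(
    config: RunConfig,
    basin_stats: tuple[str, ...] = ("mean", "median"),
    min_species_values: tuple[int, ...] = (1, 10, 15, 20),
) -> pd.DataFrame:
    """Re-run the assemble+fit stages over a grid of robustness options.

    The simulated data and per-species tables are computed once and shared
    across the grid (they do not depend on the swept options).  Returns one
    row per grid cell with the model R^2 and the lmg ranking.
    """
    if config.simulate is not None:
        dataset = generate_dataset(config.simulate)
        tree = dataset.tree
        traits_raw, incidence, basins = (
            dataset.traits_observed,
            dataset.incidence,
            dataset.basins,
        )
    else:
        tree, traits_raw, incidence, basins = load_inputs(config)
    tip_rates, completed, report, trait_rates, _ = prepare_species_tables(
        tree, traits_raw, config.replace(compute_missingness_d=False)
    )
    rows = []
    for stat in basin_stats:
        for ms in min_species_values:
            cfg = config.replace(basin_stat=stat, min_species=ms, out_dir=None)
            summary, design, response, centroids, _ = assemble_design(
                tree, tip_rates, trait_rates, incidence, basins, cfg
            )
            fit = fit_surface(design, response, centroids, cfg, n_species=tree.n_tips)
            ranking = fit.lmg["share"].sort_values(ascending=False)
            body = fit.ols.coefficients["coef"].get("rate_body_size", np.nan)
            rows.append(
                {
                    "basin_stat": stat,
                    "min_species": ms,
                    "n_basins": fit.n_basins,
                    "r_squared": fit.ols.r_squared,
                    "top_lmg_1": ranking.index[0],
                    "top_lmg_2": ranking.index[1],
                    "coef_rate_body_size": float(body),
                }
            )
    return pd.DataFrame(rows)
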