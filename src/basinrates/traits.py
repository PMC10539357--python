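"""Trait preprocessing, tip trait-evolution rates, Brownian imputation and
phylogenetic-missingness diagnostics.

The per-tip trait-evolution rate is the squared *standardized independent
contrast* at the tip's parent node: under single-rate Brownian motion each
standardized contrast has variance sigma^2 exactly, so the squared
contrast attributed to a tip is an unbiased (if individually noisy) local
estimate of the trait rate in trait-units^2 My^-1.

Missing values are imputed under single-rate Brownian motion: the root
mean is estimated by GLS and the rate by the contrasts (REML) estimator
from the observed tips, and each missing tip is filled with the
conditional mean of the implied multivariate normal given the observed
tips (covariance = sigma^2 times the shared-path-length matrix).

Whether the *pattern* of missingness is phylogenetically clustered is
scored with the Fritz-Purvis D statistic, scaled between two simulated
nulls so that label-shuffling missingness has E[D] = 1 and Brownian
(threshold) missingness has E[D] = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .treeio import Phylogeny

__all__ = [
    "TraitTable",
    "log10_body_size",
    "tip_trait_rate",
    "trait_rate_table",
    "impute_traits_bm",
    "missingness_d",
    "DStatistic",
]

BODY_SIZE_COLUMN = "body_size"


@dataclass
class TraitTable:
    """Species x trait values (NaN = missing) plus transform bookkeeping."""

    frame: pd.DataFrame
    body_size_column: str = BODY_SIZE_COLUMN
    body_size_log10: bool = False

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate species ids in trait table")

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    def restrict_to(self, tree: Phylogeny) -> "TraitTable":
        missing = set(self.frame.index) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"trait table species absent from tree: {sorted(missing)[:5]}")
        return self


def log10_body_size(table: TraitTable) -> TraitTable:
    """Replace the body-size column by its log10; refuse re-application.

    Non-positive lengths are reported by species name; missing values stay
    missing; other traits are untouched.
    """
    if table.body_size_log10:
        raise ValueError("body size is already log10-transformed")
    col = table.body_size_column
    if col not in table.frame.columns:
        raise KeyError(f"no column {col!r} in trait table")
    vals = table.frame[col]
    bad = vals.index[(vals <= 0).fillna(False)]
    if len(bad):
        raise ValueError(f"non-positive body size for species {list(bad[:5])}")
    out = table.frame.copy()
    out[col] = np.log10(vals)
    return TraitTable(out, body_size_column=col, body_size_log10=True)


# ---------------------------------------------------------------------------
# Independent contrasts


def _contrasts(tree: Phylogeny, values: np.ndarray):
    """Felsenstein's pruning pass.

    Returns ``(contrasts, tip_rate)`` where ``contrasts`` is the array of
    standardized contrasts (one per split; polytomies are folded
    sequentially in child order, yielding k-1 contrasts) and ``tip_rate``
    assigns to each tip the squared contrast computed at its parent node.
    """
    n = tree.n_nodes
    x = np.zeros(n)
    v = np.zeros(n)  # adjusted variance of the node's value, incl. its branch
    tips = tree.tip_indices
    tip_pos = {int(t): r for r, t in enumerate(tips)}
    x[tips] = values
    contrasts: list[float] = []
    tip_rate = np.full(tips.shape[0], np.nan)

    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            v[node] = tree.branch_length[node]
            continue
        c0 = kids[0]
        xv, vv = x[c0], v[c0]
        members = [c0]
        for c in kids[1:]:
            s = (x[c] - xv) / math.sqrt(v[c] + vv)
            contrasts.append(s)
            for m in (*members, c):
                if m in tip_pos:
                    tip_rate[tip_pos[m]] = s * s
            xv = (xv / vv + x[c] / v[c]) / (1.0 / vv + 1.0 / v[c])
            vv = vv * v[c] / (vv + v[c])
            members = []  # the folded pseudo-node is not a tip
        x[node] = xv
        v[node] = vv + (tree.branch_length[node] if node != tree.root else 0.0)
    return np.array(contrasts), tip_rate


def tip_trait_rate(tree: Phylogeny, values: pd.Series) -> pd.Series:
    """Per-tip trait-evolution rate: squared standardized terminal contrast.

    ``values`` must cover every tip with no missing entries (impute first).
    Sister tips in a cherry share the same contrast, hence the same rate.
    Rates are >= 0 by construction and have expectation sigma^2 under
    single-rate Brownian motion.
    """
    aligned = values.reindex(tree.tip_labels)
    if aligned.isna().any():
        bad = list(aligned.index[aligned.isna()][:5])
        raise ValueError(f"missing trait values (impute first): {bad}")
    _, rate = _contrasts(tree, aligned.to_numpy(dtype=float))
    return pd.Series(rate, index=pd.Index(tree.tip_labels, name="species"), name="rate")


def trait_rate_table(tree: Phylogeny, traits: pd.DataFrame) -> pd.DataFrame:
    """Tip trait rates for every trait column (prefixing ``rate_``)."""
    return pd.DataFrame(
        {f"rate_{col}": tip_trait_rate(tree, traits[col]) for col in traits.columns}
    )


# ---------------------------------------------------------------------------
# Brownian imputation


@dataclass
class ImputationReport:
    """Per-trait BM parameter estimates and per-imputation uncertainty."""

    table: pd.DataFrame  # species, trait, imputed value, conditional SD
    bm_parameters: pd.DataFrame  # trait -> mu_hat, sigma2_hat, n_observed


def impute_traits_bm(
    tree: Phylogeny, table: TraitTable
) -> tuple[TraitTable, ImputationReport]:
    """Fill missing trait values with BM conditional means, per trait.

    For each trait with missing entries: the root mean is the GLS mean and
    the rate the contrasts (REML) estimator over observed tips; missing
    tips get the conditional mean given the observed tips under the implied
    multivariate normal, with the conditional SD reported per imputation.
    Requires >= 3 observed tips and < 50% missing per trait.
    """
    absent = sorted(set(tree.tip_labels) - set(table.frame.index))
    if absent:
        raise ValueError(f"tips without any trait row: {absent[:5]}")
    frame = table.frame.reindex(tree.tip_labels)
    V = tree.vcv()
    out = frame.copy()
    rows = []
    params = {}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        n_obs = int(obs.sum())
        if n_obs == len(vals):
            params[col] = {"mu_hat": np.nan, "sigma2_hat": np.nan, "n_observed": n_obs}
            continue
        if n_obs < 3:
            raise ValueError(f"trait {col!r}: fewer than 3 observed tips")
        if n_obs < 0.5 * len(vals):
            raise ValueError(f"trait {col!r}: more than 50% missing")
        mu, sig2, imputed, cond_sd = _bm_conditional(V, vals, obs)
        out.loc[out.index[~obs], col] = imputed
        for sp, val, sd in zip(frame.index[~obs], imputed, cond_sd):
            rows.append({"species": sp, "trait": col, "imputed": val, "conditional_sd": sd})
        params[col] = {"mu_hat": mu, "sigma2_hat": sig2, "n_observed": n_obs}
    report = ImputationReport(
        table=pd.DataFrame(rows, columns=["species", "trait", "imputed", "conditional_sd"]),
        bm_parameters=pd.DataFrame(params).T.rename_axis("trait"),
    )
    completed = TraitTable(
        out,
        body_size_column=table.body_size_column,
        body_size_log10=table.body_size_log10,
    )
    return completed, report


def _bm_conditional(V: np.ndarray, vals: np.ndarray, obs: np.ndarray):
    """GLS mean, REML rate and conditional mean/SD of the missing tips."""
    Voo = V[np.ix_(obs, obs)]
    Vmo = V[np.ix_(~obs, obs)]
    Vmm = V[np.ix_(~obs, ~obs)]
    xo = vals[obs]
    try:
        cf = cho_factor(Voo)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance among observed tips") from exc
    ones = np.ones_like(xo)
    Vi1 = cho_solve(cf, ones)
    mu = float(xo @ Vi1 / (ones @ Vi1))
    resid = xo - mu
    Vir = cho_solve(cf, resid)
    n_obs = xo.shape[0]
    sig2 = float(resid @ Vir / (n_obs - 1))
    cond_mean = mu + Vmo @ Vir
    cond_cov = sig2 * (Vmm - Vmo @ cho_solve(cf, Vmo.T))
    cond_sd = np.sqrt(np.clip(np.diag(cond_cov), 0.0, None))
    return mu, sig2, cond_mean, cond_sd


# ---------------------------------------------------------------------------
# Fritz-Purvis D


@dataclass
class DStatistic:
    """Fritz-Purvis D with its two simulated nulls.

    ``p_lt_random`` is the fraction of label-permutation null datasets at
    least as clumped as observed (small -> reject D = 1 downward);
    ``p_gt_bm`` is the fraction of Brownian-threshold null datasets at
    least as overdispersed as observed (small -> reject D = 0 upward).
    """

    D: float
    d_obs: float
    d_random_mean: float
    d_bm_mean: float
    p_lt_random: float
    p_gt_bm: float
    d_random: np.ndarray = field(repr=False, default=None)
    d_bm: np.ndarray = field(repr=False, default=None)


def _sister_diff_sums(tree: Phylogeny, X: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of child deviations from the node mean.

    ``X`` is (n_tips, R); returns the d score per replicate.  For a
    bifurcation the node's contribution is |x1 - x2|; a k-furcation
    contributes the mean-absolute deviation times k.
    """
    n = tree.n_nodes
    R = X.shape[1]
    vals = np.zeros((n, R))
    vals[tree.tip_indices] = X
    d = np.zeros(R)
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        kv = vals[kids]
        m = kv.mean(axis=0)
        d += np.abs(kv - m).sum(axis=0)
        vals[node] = m
    return d


def missingness_d(
    tree: Phylogeny,
    indicator: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> DStatistic:
    """Fritz-Purvis D for a binary tip indicator (e.g. "trait missing").

    ``D = (d_obs - mean d_BM) / (mean d_random - mean d_BM)`` where
    ``d`` is the sum of sister-clade differences of nodal values obtained
    by averaging daughters rootward; ``d_random`` comes from shuffling the
    indicator across tips and ``d_BM`` from thresholding unit-rate Brownian
    tip values at the observed prevalence (the *upper* tail is labelled
    True — the documented orientation convention; relabelling classes
    changes neither d_obs nor the random null).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    ind = indicator.reindex(tree.tip_labels)
    if ind.isna().any():
        raise ValueError("indicator must cover every tip")
    states = ind.to_numpy(dtype=bool)
    k = int(states.sum())
    n = states.shape[0]
    if k == 0 or k == n:
        raise ValueError("indicator must contain both classes")
    rng = np.random.default_rng(seed)

    d_obs = float(_sister_diff_sums(tree, states.astype(float)[:, None])[0])

    # random null: label permutations
    P = np.empty((n, n_perm))
    base = states.astype(float)
    for j in range(n_perm):
        P[:, j] = rng.permutation(base)
    d_random = _sister_diff_sums(tree, P)

    # BM null: threshold unit-rate Brownian tip values at prevalence k/n
    A = tree.path_matrix()
    sd = np.sqrt(tree.branch_length)
    inc = rng.standard_normal((tree.n_nodes, n_perm)) * sd[:, None]
    tipvals = A @ inc
    if tree.root_length > 0:
        tipvals += math.sqrt(tree.root_length) * rng.standard_normal(n_perm)[None, :]
    order = np.argsort(tipvals, axis=0)
    thresh = np.take_along_axis(tipvals, order[n - k][None, :], axis=0)
    B = (tipvals >= thresh).astype(float)
    d_bm = _sister_diff_sums(tree, B)

    mean_rand = float(d_random.mean())
    mean_bm = float(d_bm.mean())
    denom = mean_rand - mean_bm
    if abs(denom) < 1e-12:
        raise ValueError("degenerate nulls: random and BM d means coincide")
    D = (d_obs - mean_bm) / denom
    p_lt_random = (1 + int((d_random <= d_obs).sum())) / (n_perm + 1)
    p_gt_bm = (1 + int((d_bm >= d_obs).sum())) / (n_perm + 1)
    return DStatistic(
        D=float(D),
        d_obs=d_obs,
        d_random_mean=mean_rand,
        d_bm_mean=mean_bm,
        p_lt_random=float(p_lt_random),
        p_gt_bm=float(p_gt_bm),
        d_random=d_random,
        d_bm=d_bm,
    )
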