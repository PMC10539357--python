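"""Synthetic data generator: shift birth-death trees, regime-linked traits,
elevation-structured landscapes and occupancy.

The generator emulates the data-generating process the downstream analysis
assumes: a clade of a few hundred extant species produced by a birth-death
process with discrete rate regimes; a continuous (log body size) trait
evolving by Brownian motion whose rate is linked to the speciation rate of
the regime; and drainage basins along an elevation gradient in which
high-elevation basins are preferentially occupied by species from fast
regimes.  Elevation is the single driving covariate of the landscape; the
other basin covariates are either noise or noisy derivatives of elevation,
so end-to-end recovery tests have an unambiguous expected winner.

Everything is deterministic under a fixed seed, and the true regime of
every tip (speciation rate, trait rate, trait values) is emitted alongside
the observable data so parameter-recovery tests can score estimators.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .treeio import Phylogeny, RegimePainting

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_shift_tree",
    "simulate_bm_traits",
    "simulate_landscape_and_ranges",
    "introduce_missingness",
    "generate_dataset",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = (
    "body_size",
    "body_elongation",
    "oral_gape_position",
    "maxillary_length",
    "eye_size",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study system.

    Tree process: a crown clade of age ``crown_age`` My evolves under a
    birth-death process with base speciation rate ``lambda0`` and constant
    extinction rate ``mu0`` (both My^-1).  Rate-shift events arrive as a
    Poisson process with intensity ``eta`` (shifts My^-1 branch^-1); each
    shift assigns the lineage a fresh regime with speciation rate
    ``lambda0 * m`` where ``m`` is log-normal with median ``shift_median``
    and log-SD ``shift_sdlog``.  The regime's body-size Brownian rate is
    linked as ``sigma2_body * (lambda/lambda0) ** trait_link_power``.
    Extinct lineages are simulated and pruned, so estimators face the
    extant-only condition of empirical time trees.

    Landscape: ``n_basins`` basins on a jittered square lattice with a
    linear elevation gradient up to ``elev_max`` m; temperature follows a
    lapse rate with weather noise, stream gradient is a noisy derivative of
    elevation, and area / runoff / soil composition are pure noise.
    Species occupy a spatially contiguous set of basins (nearest neighbours
    of a home basin); the home basin's elevation rank is coupled to the
    species' regime speciation rate with strength ``preference_strength``
    (0 = none, 1 = deterministic).
    """

    seed: int = 0
    # -- tree process
    crown_age: float = 32.0
    lambda0: float = 0.14
    mu0: float = 0.03
    eta: float = 0.05
    shift_median: float = 1.0
    shift_sdlog: float = 1.2
    shift_multiplier_min: float = 0.05
    shift_multiplier_max: float = 20.0
    min_tips: int = 250
    max_tips: int = 800
    expected_tips_cap: float = 20_000.0
    hard_tip_cap: int = 30_000
    max_tree_retries: int = 500
    # -- traits
    trait_link_power: float = 2.0
    sigma2_body: float = 0.01
    sigma2_other: float = 0.01
    eye_coupling: float = 0.9
    sigma2_eye_resid: float = 0.002
    root_body_log10: float = 1.0
    missing_fraction: float = 0.05
    # -- landscape
    n_basins: int = 100
    elev_max: float = 4000.0
    elev_noise_sd: float = 200.0
    temp_sea_level: float = 26.0
    temp_lapse_per_km: float = 5.5
    temp_noise_sd: float = 12.0
    area_meanlog: float = 22.3
    area_sdlog: float = 1.0
    runoff_meanlog: float = 6.0
    runoff_sdlog: float = 0.5
    gradient_per_m: float = 0.002
    gradient_noise_sd: float = 7.0
    n_soil_types: int = 8
    soil_samples: int = 60
    soil_dirichlet: float = 2.0
    # -- occupancy
    preference_strength: float = 0.30
    clade_dispersal_sd: float = 0.85
    clade_block_size: int = 10
    range_meanlog: float = 1.8
    range_sdlog: float = 1.1
    max_range_retries: int = 20

    def validate(self) -> None:
        if self.lambda0 <= 0 or self.mu0 < 0 or self.eta < 0:
            raise ValueError("rates must satisfy lambda0 > 0, mu0 >= 0, eta >= 0")
        if self.crown_age <= 0:
            raise ValueError("crown_age must be > 0")
        if self.sigma2_body <= 0 or self.sigma2_other <= 0:
            raise ValueError("trait rates must be > 0")
        if not 0.0 <= self.preference_strength <= 1.0:
            raise ValueError("preference_strength must lie in [0, 1]")
        if self.n_basins < 10:
            raise ValueError("need n_basins >= 10")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Birth-death tree with rate shifts


def simulate_shift_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Phylogeny, RegimePainting]:
    """Simulate an extant-only ultrametric tree with painted rate regimes.

    The complete lineage history (including extinct lineages and shift
    points) is simulated forward in time from two crown lineages, then
    pruned to the extant tips.  A pruned branch may have spanned several
    regimes; the painting assigns it the regime in effect at its tipward
    end, and that painting *is* the truth handed to the trait simulator.
    Attempts where the crown fails to survive (either crown lineage leaves
    no extant descendant) or whose extant size falls outside the
    ``[min_tips, max_tips]`` study window are retried up to
    ``max_tree_retries``.
    """
    config.validate()
    expected = 2.0 * math.exp((config.lambda0 - config.mu0) * config.crown_age)
    if expected > config.expected_tips_cap:
        raise SimulationError(
            f"expected tip count {expected:.0f} exceeds cap {config.expected_tips_cap:.0f}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    for _ in range(config.max_tree_retries):
        result = _attempt_tree(config, rng)
        if result is not None:
            return result
    raise SimulationError(
        f"no surviving clade with >= {config.min_tips} tips after "
        f"{config.max_tree_retries} attempts"
    )


def _attempt_tree(config: SimulationConfig, rng: np.random.Generator):
    T = config.crown_age
    lam0, mu0, eta = config.lambda0, config.mu0, config.eta
    sig0 = config.sigma2_body

    # regime table; id 0 = base regime
    reg_lam = [lam0]
    reg_mu = [mu0]
    reg_sig = [sig0]

    # node arrays of the complete (event) tree
    parent: list[int] = [-1]
    t_start: list[float] = [0.0]
    t_end: list[float] = [0.0]
    regime: list[int] = [0]
    extant: list[bool] = [False]

    def new_node(p: int, t0: float, r: int) -> int:
        parent.append(p)
        t_start.append(t0)
        t_end.append(t0)
        regime.append(r)
        extant.append(False)
        return len(parent) - 1

    # two crown lineages
    stack = [new_node(0, 0.0, 0), new_node(0, 0.0, 0)]
    n_extant = 0
    while stack:
        node = stack.pop()
        t, r = t_start[node], regime[node]
        lam, mu = reg_lam[r], reg_mu[r]
        total = lam + mu + eta
        dt = rng.exponential(1.0 / total) if total > 0 else math.inf
        if t + dt >= T:
            t_end[node] = T
            extant[node] = True
            n_extant += 1
            continue
        t_end[node] = t + dt
        u = rng.random() * total
        if u < lam:  # speciation
            stack.append(new_node(node, t + dt, r))
            stack.append(new_node(node, t + dt, r))
        elif u < lam + mu:  # extinction
            pass
        else:  # rate shift: fresh draw around the base rate
            m = math.exp(math.log(config.shift_median) + config.shift_sdlog * rng.standard_normal())
            m = min(max(m, config.shift_multiplier_min), config.shift_multiplier_max)
            lam_new = lam0 * m
            sig_new = sig0 * (lam_new / lam0) ** config.trait_link_power
            reg_lam.append(lam_new)
            reg_mu.append(mu0)
            reg_sig.append(sig_new)
            stack.append(new_node(node, t + dt, len(reg_lam) - 1))
        if len(parent) > config.hard_tip_cap:
            return None  # runaway attempt; retry

    if not max(2, config.min_tips) <= n_extant <= config.max_tips:
        return None
    # both crown lineages must survive, else the crown node is not the MRCA
    surv = _has_extant_descendant(parent, extant)
    if not (surv[1] and surv[2]):
        return None

    return _prune_event_tree(
        parent, t_start, t_end, regime, extant, reg_lam, reg_mu, reg_sig
    )


def _has_extant_descendant(parent: list[int], extant: list[bool]) -> np.ndarray:
    n = len(parent)
    out = np.array(extant, dtype=bool)
    # children were appended after parents, so a reverse sweep suffices
    for i in range(n - 1, 0, -1):
        if out[i]:
            out[parent[i]] = True
    return out


def _prune_event_tree(parent, t_start, t_end, regime, extant, reg_lam, reg_mu, reg_sig):
    n = len(parent)
    keep = _has_extant_descendant(parent, extant)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        if keep[i]:
            children[parent[i]].append(i)

    # the event-tree root (crown node) always has its two surviving children
    parent_out: list[int] = []
    bl_out: list[float] = []
    reg_out: list[int] = []
    labels_out: list[str | None] = []
    # iterative emit: (node, parent_index_in_output, accumulated_length)
    work = [(0, -1, 0.0)]
    while work:
        node, pidx, acc = work.pop()
        kids = children[node]
        while len(kids) == 1:  # suppress unary shift nodes / pruned splits
            node = kids[0]
            acc += t_end[node] - t_start[node]
            kids = children[node]
        idx = len(parent_out)
        parent_out.append(pidx)
        bl_out.append(acc if pidx >= 0 else 0.0)
        reg_out.append(regime[node])  # regime at the tipward end of the branch
        labels_out.append(None)
        for c in kids:
            work.append((c, idx, t_end[c] - t_start[c]))

    tip_counter = 0
    is_tip = [True] * len(parent_out)
    for p in parent_out:
        if p >= 0:
            is_tip[p] = False
    width = max(4, len(str(sum(is_tip))))
    for i, tip in enumerate(is_tip):
        if tip:
            labels_out[i] = f"s{tip_counter:0{width}d}"
            tip_counter += 1

    if any(b <= 0 for i, b in enumerate(bl_out) if parent_out[i] >= 0):
        return None  # degenerate zero-length branch; retry

    tree = Phylogeny(np.array(parent_out), np.array(bl_out), labels_out)
    painting = RegimePainting(
        np.array(reg_out),
        np.array(reg_lam),
        np.array(reg_mu),
        np.array(reg_sig),
    )
    return tree, painting


# ---------------------------------------------------------------------------
# Brownian traits on a painted tree


def simulate_bm_traits(
    tree: Phylogeny,
    painting: RegimePainting,
    root_state: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Simulate a Brownian trait along the painted tree.

    The increment on each branch is Normal(0, sigma2_regime * length); tips
    return the summed increments plus ``root_state``.  If the tree carries a
    root stem, the stem contributes variance under the root branch's regime.
    Returns a Series indexed by tip label.
    """
    painting.validate_for(tree)
    if rng is None:
        rng = np.random.default_rng()
    sig2 = painting.branch_sigma2()
    n = tree.n_nodes
    sd = np.sqrt(sig2 * tree.branch_length)
    inc = rng.standard_normal(n) * sd
    x = np.zeros(n)
    stem_inc = 0.0
    if tree.root_length > 0:
        stem_inc = rng.standard_normal() * math.sqrt(sig2[tree.root] * tree.root_length)
    for i in tree.postorder[::-1]:  # preorder
        if i == tree.root:
            x[i] = root_state + stem_inc
        else:
            x[i] = x[tree.parent[i]] + inc[i]
    return pd.Series(x[tree.tip_indices], index=tree.tip_labels, name="trait")


def constant_painting(
    tree: Phylogeny, sigma2: float, lam: float = 1.0, mu: float = 0.0
) -> RegimePainting:
    """Single-regime painting covering the whole tree (utility)."""
    return RegimePainting(
        np.zeros(tree.n_nodes, dtype=np.int64),
        np.array([lam]),
        np.array([mu]),
        np.array([sigma2]),
    )


# ---------------------------------------------------------------------------
# Landscape and occupancy


def simulate_landscape_and_ranges(
    tree: Phylogeny,
    painting: RegimePainting,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the basin covariate table and the basin x species incidence.

    Basins sit on a jittered square lattice; elevation increases linearly
    along the x axis with Gaussian noise.  Each species receives a home
    basin whose elevation *rank* is coupled to the species' regime
    speciation rate with strength ``preference_strength``, and occupies the
    contiguous set of its range-size nearest basins around the home.  The
    whole assignment is redrawn (up to ``max_range_retries``) if any basin
    ends up unoccupied.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    B = config.n_basins
    nx = math.ceil(math.sqrt(B))
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(nx, dtype=float))
    x = gx.ravel()[:B] + rng.uniform(-0.1, 0.1, B)
    y = gy.ravel()[:B] + rng.uniform(-0.1, 0.1, B)

    elev = config.elev_max * (x - x.min()) / max(x.max() - x.min(), 1e-12)
    elev = np.clip(elev + rng.normal(0.0, config.elev_noise_sd, B), 0.0, None)
    temp = (
        config.temp_sea_level
        - config.temp_lapse_per_km * elev / 1000.0
        + rng.normal(0.0, config.temp_noise_sd, B)
    )
    area = np.exp(rng.normal(config.area_meanlog, config.area_sdlog, B))
    runoff = np.exp(rng.normal(config.runoff_meanlog, config.runoff_sdlog, B))
    gradient = np.clip(
        config.gradient_per_m * elev + rng.normal(0.0, config.gradient_noise_sd, B),
        0.01,
        None,
    )
    soil_p = rng.dirichlet(
        np.full(config.n_soil_types, config.soil_dirichlet), size=B
    )
    soil = np.vstack([rng.multinomial(config.soil_samples, p) for p in soil_p])

    basin_ids = [f"b{i:03d}" for i in range(B)]
    basins = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "elevation": elev,
            "temperature": temp,
            "area": area,
            "runoff": runoff,
            "stream_gradient": gradient,
        },
        index=pd.Index(basin_ids, name="basin"),
    )
    for k in range(config.n_soil_types):
        basins[f"soil_{k}"] = soil[:, k]

    species = tree.tip_labels
    lam_tip = painting.tip_lambda(tree)
    loglam = np.log(lam_tip)
    sd = loglam.std()
    z = (loglam - loglam.mean()) / sd if sd > 0 else np.zeros_like(loglam)
    rho = config.preference_strength
    # clade placement effect: related species radiate in place, so basin
    # composition carries lineage-level noise that does not average out.
    # The placement unit is a phylogenetic block of bounded size, so no
    # single giant clade dominates the noise.
    tau = min(config.clade_dispersal_sd, math.sqrt(max(1.0 - rho * rho, 0.0)))
    resid_sd = math.sqrt(max(1.0 - rho * rho - tau * tau, 0.0))
    tip_block = _phylo_blocks(tree, config.clade_block_size)
    n_blocks = int(tip_block.max()) + 1
    rank_to_basin = np.argsort(elev)
    dists = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    near = np.argsort(dists, axis=1, kind="stable")  # ties broken by index

    S = len(species)
    for _ in range(config.max_range_retries):
        clade_eff = rng.standard_normal(n_blocks)[tip_block]
        eps = rng.standard_normal(S)
        u = norm.cdf(rho * z + tau * clade_eff + resid_sd * eps)
        home = rank_to_basin[np.round(u * (B - 1)).astype(int)]
        zr = rng.standard_normal(S)
        nbas = 1 + np.floor(np.exp(config.range_meanlog + config.range_sdlog * zr))
        nbas = np.minimum(nbas.astype(int), B)
        inc = np.zeros((B, S), dtype=np.int8)
        for j in range(S):
            inc[near[home[j], : nbas[j]], j] = 1
        if inc.sum(axis=1).min() >= 1:
            incidence = pd.DataFrame(
                inc, index=pd.Index(basin_ids, name="basin"), columns=species
            )
            return basins, incidence
    raise SimulationError(
        f"unoccupied basin persisted after {config.max_range_retries} assignment draws"
    )


# ---------------------------------------------------------------------------
# Missingness


def introduce_missingness(
    traits: pd.Series,
    fraction: float,
    mode: str = "random",
    tree: Phylogeny | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Mask exactly ``floor(fraction * n)`` values of a trait Series.

    ``mode="random"`` masks a uniform subset; ``mode="clustered"`` (requires
    ``tree``) concentrates the masked tips inside one clade: the internal
    node whose clade size is closest to the target is chosen, tips inside it
    are masked first, and any remainder is drawn at random outside.
    Returns ``(masked_series, boolean mask of masked tips)``; the input is
    the recoverable truth.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    n = len(traits)
    m = int(math.floor(fraction * n))
    if m >= n:
        raise ValueError("fraction would mask every tip")
    if rng is None:
        rng = np.random.default_rng()
    mask = pd.Series(False, index=traits.index)
    if m == 0:
        return traits.copy(), mask
    if mode == "random":
        idx = rng.choice(n, size=m, replace=False)
        mask.iloc[np.sort(idx)] = True
    elif mode == "clustered":
        if tree is None:
            raise ValueError("clustered mode requires the tree")
        clade = _closest_clade(tree, m)
        clade_labels = [lbl for lbl in clade if lbl in traits.index]
        take = rng.permutation(clade_labels)[: min(m, len(clade_labels))]
        mask.loc[list(take)] = True
        short = m - int(mask.sum())
        if short > 0:
            rest = [lbl for lbl in traits.index if not mask.loc[lbl]]
            extra = rng.choice(len(rest), size=short, replace=False)
            mask.loc[[rest[i] for i in extra]] = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = traits.copy()
    out[mask] = np.nan
    return out, mask


def _phylo_blocks(tree: Phylogeny, max_size: int) -> np.ndarray:
    """Partition tips into contiguous clades of at most ``max_size`` tips.

    Greedy postorder: a clade becomes a block when absorbing it into its
    parent would exceed ``max_size``.  Returns a block id per tip (ordered
    as ``tip_indices``).
    """
    n = tree.n_nodes
    size = np.zeros(n, dtype=int)
    block = np.full(n, -1, dtype=int)
    next_block = 0
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            size[i] = 1
            continue
        total = sum(size[c] for c in kids)
        if total > max_size or i == tree.root:
            for c in kids:
                if size[c] > 0:  # close each still-open child clade
                    block[c] = next_block
                    next_block += 1
            size[i] = 0
        else:
            size[i] = total
    out = np.zeros(tree.n_tips, dtype=int)
    for r, t in enumerate(tree.tip_indices):
        i = t
        while block[i] < 0:
            i = tree.parent[i]
        out[r] = block[i]
    return out


def _closest_clade(tree: Phylogeny, target: int) -> list[str]:
    """Tip labels of the internal-node clade whose size is nearest ``target``."""
    sizes = np.zeros(tree.n_nodes, dtype=int)
    tipsets: dict[int, list[str]] = {}
    for i in tree.postorder:
        if not tree.children[i]:
            sizes[i] = 1
            tipsets[i] = [tree.labels[i]]
        else:
            sizes[i] = sum(sizes[c] for c in tree.children[i])
            tipsets[i] = [lbl for c in tree.children[i] for lbl in tipsets[c]]
    best, best_gap = None, None
    for i in range(tree.n_nodes):
        if tree.children[i] and i != tree.root:
            gap = abs(sizes[i] - target)
            if best_gap is None or gap < best_gap:
                best, best_gap = i, gap
    assert best is not None
    return tipsets[best]


# ---------------------------------------------------------------------------
# Full dataset


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SimulationConfig
    tree: Phylogeny
    painting: RegimePainting
    traits_true: pd.DataFrame
    traits_observed: pd.DataFrame
    missing_mask: pd.DataFrame
    basins: pd.DataFrame
    incidence: pd.DataFrame
    truth: pd.DataFrame = field(default=None)  # per-species true lambda / sigma2


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate tree, traits (with missingness), landscape and occupancy.

    Body size evolves under the regime-linked rate and is reported on the
    raw (cm) scale so the pipeline's log10 preprocessing applies; the other
    four traits evolve under constant rates, with relative eye size built as
    a near-copy of body elongation (coupling ``eye_coupling``) so that the
    collinearity screen has realistic work to do.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree, painting = simulate_shift_tree(config, rng)

    body_log = simulate_bm_traits(tree, painting, config.root_body_log10, rng)
    elong = simulate_bm_traits(tree, constant_painting(tree, config.sigma2_other), 5.0, rng)
    gape = simulate_bm_traits(tree, constant_painting(tree, config.sigma2_other), 0.5, rng)
    maxil = simulate_bm_traits(tree, constant_painting(tree, config.sigma2_other), 1.0, rng)
    eye_resid = simulate_bm_traits(
        tree, constant_painting(tree, config.sigma2_eye_resid), 0.0, rng
    )
    eye = config.eye_coupling * (elong - 5.0) + eye_resid + 1.0

    traits_true = pd.DataFrame(
        {
            "body_size": np.power(10.0, body_log),
            "body_elongation": elong,
            "oral_gape_position": gape,
            "maxillary_length": maxil,
            "eye_size": eye,
        }
    )
    traits_true.index.name = "species"

    observed = {}
    mask = {}
    for col in TRAIT_COLUMNS:
        obs, mk = introduce_missingness(
            traits_true[col], config.missing_fraction, "random", tree, rng
        )
        observed[col] = obs
        mask[col] = mk
    traits_observed = pd.DataFrame(observed)
    missing_mask = pd.DataFrame(mask)

    basins, incidence = simulate_landscape_and_ranges(tree, painting, config, rng)

    truth = pd.DataFrame(
        {
            "true_lambda": painting.tip_lambda(tree),
            "true_sigma2_body": painting.sigma2[
                painting.branch_regime[tree.tip_indices]
            ],
            "true_body_log10": body_log.to_numpy(),
        },
        index=pd.Index(tree.tip_labels, name="species"),
    )

    return SyntheticDataset(
        config=config,
        tree=tree,
        painting=painting,
        traits_true=traits_true,
        traits_observed=traits_observed,
        missing_mask=missing_mask,
        basins=basins,
        incidence=incidence,
        truth=truth,
    )
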