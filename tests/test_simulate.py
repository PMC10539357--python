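"""Synthetic-data generator: closed-form and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import geom, ks_2samp, pearsonr

from basinrates.simulate import (
    SimulationConfig,
    constant_painting,
    generate_dataset,
    introduce_missingness,
    simulate_bm_traits,
    simulate_landscape_and_ranges,
    simulate_shift_tree,
)
from basinrates.treeio import RegimePainting, is_ultrametric, write_newick
from tests.conftest import gillespie_crown_surviving


class TestShiftTree:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=42)
        t1, p1 = simulate_shift_tree(cfg)
        t2, p2 = simulate_shift_tree(cfg)
        assert write_newick(t1) == write_newick(t2)
        assert np.array_equal(p1.branch_regime, p2.branch_regime)
        assert np.array_equal(p1.lam, p2.lam)

    def test_extant_only_ultrametric(self):
        tree, _ = simulate_shift_tree(SimulationConfig(seed=1))
        ok, dev = is_ultrametric(tree, rel_tol=1e-9)
        assert ok, dev
        assert tree.root_age == pytest.approx(SimulationConfig().crown_age)

    def test_yule_growth_matches_geometric_closed_form(self):
        """Pure-birth tip counts: each crown lineage is Geometric(e^{-lam*t})."""
        lam, T, reps = 0.1, 25.0, 400
        cfg = SimulationConfig(
            seed=0, lambda0=lam, mu0=0.0, eta=0.0, crown_age=T,
            min_tips=2, max_tips=10**6,
        )
        rng = np.random.default_rng(cfg.seed)
        sims = np.array(
            [simulate_shift_tree(cfg, rng)[0].n_tips for _ in range(reps)]
        )
        # oracle: sum of two iid geometric draws, sampled independently
        orng = np.random.default_rng(123)
        p = math.exp(-lam * T)
        oracle = geom.rvs(p, size=(50_000, 2), random_state=orng).sum(axis=1)
        se = math.sqrt(
            np.log(sims).var() / reps + np.log(oracle).var() / oracle.shape[0]
        )
        assert abs(np.log(sims).mean() - np.log(oracle).mean()) < 4 * se

    def test_birth_death_matches_gillespie_oracle(self):
        """Extant-count distribution equals an event-by-event simulator's."""
        lam, mu, T, reps = 0.15, 0.05, 18.0, 400
        cfg = SimulationConfig(
            seed=3, lambda0=lam, mu0=mu, eta=0.0, crown_age=T,
            min_tips=2, max_tips=10**6, max_tree_retries=10**6,
        )
        rng = np.random.default_rng(cfg.seed)
        mine = np.array(
            [simulate_shift_tree(cfg, rng)[0].n_tips for _ in range(reps)]
        )
        orng = np.random.default_rng(17)
        brute = np.array(
            [gillespie_crown_surviving(orng, lam, mu, T) for _ in range(reps)]
        )
        assert ks_2samp(mine, brute).pvalue > 0.01

    def test_shifted_tip_fraction_increases_with_eta(self):
        fracs = []
        for eta in (0.005, 0.02, 0.08):
            vals = []
            for seed in range(6):
                cfg = SimulationConfig(
                    seed=seed, eta=eta, shift_median=4.0, shift_sdlog=0.0,
                    lambda0=0.1, mu0=0.0, crown_age=25.0, min_tips=50, max_tips=5000,
                )
                tree, painting = simulate_shift_tree(cfg)
                vals.append((painting.branch_regime[tree.tip_indices] != 0).mean())
            fracs.append(np.mean(vals))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_expected_tip_cap_errors(self):
        cfg = SimulationConfig(lambda0=1.0, mu0=0.0, crown_age=30.0)
        with pytest.raises(Exception, match="cap"):
            simulate_shift_tree(cfg)


class TestBMTraits:
    def test_zero_rate_gives_root_state(self, balanced_four_tree):
        painting = constant_painting(balanced_four_tree, sigma2=0.0)
        x = simulate_bm_traits(balanced_four_tree, painting, root_state=3.25,
                               rng=np.random.default_rng(0))
        assert np.allclose(x, 3.25)

    def test_tip_covariance_matches_shared_path_lengths(self, balanced_four_tree):
        """Empirical tip covariance equals the BM closed form [[2,1],[1,2]] blocks."""
        painting = constant_painting(balanced_four_tree, sigma2=1.0)
        rng = np.random.default_rng(7)
        X = np.stack(
            [
                simulate_bm_traits(balanced_four_tree, painting, 0.0, rng).to_numpy()
                for _ in range(5000)
            ]
        )
        V = np.cov(X.T)
        expected = np.array(
            [[2, 1, 0, 0], [1, 2, 0, 0], [0, 0, 2, 1], [0, 0, 1, 2]], dtype=float
        )
        assert np.allclose(V, expected, atol=0.15)

    def test_two_regime_variance_ordering(self, balanced_four_tree):
        """sigma^2 ratio 10: the fast clade shows larger tip variance."""
        t = balanced_four_tree
        # clade (A,B) = regime 1 (fast), clade (C,D) = regime 0
        regime = np.zeros(t.n_nodes, dtype=int)
        ab = [i for i in range(t.n_nodes) if t.labels[i] in ("A", "B")]
        for i in ab:
            regime[i] = 1
            regime[t.parent[i]] = 1
        painting = RegimePainting(
            regime, np.array([1.0, 1.0]), np.zeros(2), np.array([1.0, 10.0])
        )
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(200):
            x = simulate_bm_traits(t, painting, 0.0, rng)
            wins += x[["A", "B"]].var() > x[["C", "D"]].var()
        assert wins / 200 > 0.7  # one df per clade; ordering still dominates

    def test_unpainted_branch_errors(self, balanced_four_tree):
        bad = RegimePainting(
            np.zeros(3, dtype=int), np.array([1.0]), np.array([0.0]), np.array([1.0])
        )
        with pytest.raises(ValueError):
            simulate_bm_traits(balanced_four_tree, bad, 0.0)


@pytest.fixture(scope="module")
def tree_painting():
    return simulate_shift_tree(SimulationConfig(seed=8))


class TestLandscape:

    def _basin_lambda_elev_r(self, tree, painting, cfg, rng):
        basins, inc = simulate_landscape_and_ranges(tree, painting, cfg, rng)
        lam = painting.tip_lambda(tree)
        M = inc.to_numpy().astype(float)
        mean_lam = M @ lam / M.sum(axis=1)
        return pearsonr(mean_lam, basins["elevation"]).statistic

    def test_no_preference_no_signal(self, tree_painting):
        tree, painting = tree_painting
        cfg = SimulationConfig(seed=8, preference_strength=0.0, n_basins=100)
        rng = np.random.default_rng(100)
        rs = [self._basin_lambda_elev_r(tree, painting, cfg, rng) for _ in range(50)]
        assert abs(np.mean(rs)) < 0.1

    def test_max_preference_strong_signal(self, tree_painting):
        tree, painting = tree_painting
        cfg = SimulationConfig(seed=8, preference_strength=1.0, n_basins=100)
        rng = np.random.default_rng(101)
        rs = [self._basin_lambda_elev_r(tree, painting, cfg, rng) for _ in range(10)]
        assert np.mean(rs) > 0.5

    def test_heavier_range_tail_increases_occupancy_variance(self, tree_painting):
        tree, painting = tree_painting
        out = []
        for sdlog in (0.5, 1.1, 1.6):
            cfg = SimulationConfig(seed=8, range_sdlog=sdlog)
            _, inc = simulate_landscape_and_ranges(
                tree, painting, cfg, np.random.default_rng(7)
            )
            out.append(inc.sum(axis=0).var())
        assert out[0] < out[1] < out[2]

    def test_every_basin_and_species_occupied(self, tree_painting):
        tree, painting = tree_painting
        basins, inc = simulate_landscape_and_ranges(
            tree, painting, SimulationConfig(seed=8), np.random.default_rng(5)
        )
        assert (inc.sum(axis=0) >= 1).all()  # every species somewhere
        assert (inc.sum(axis=1) >= 1).all()  # every basin occupied
        assert (basins["area"] > 0).all()
        assert (basins["elevation"] >= 0).all()


class TestMissingness:
    @pytest.fixture()
    def traits(self):
        return pd.Series(np.arange(200, dtype=float), index=[f"s{i:04d}" for i in range(200)])

    def test_zero_fraction_identity(self, traits):
        out, mask = introduce_missingness(traits, 0.0, rng=np.random.default_rng(0))
        assert out.equals(traits)
        assert mask.sum() == 0

    def test_exact_count(self, traits):
        out, mask = introduce_missingness(traits, 0.1, rng=np.random.default_rng(1))
        assert mask.sum() == 20
        assert out.isna().sum() == 20

    def test_clustered_mode_masks_a_clade(self):
        tree, _ = simulate_shift_tree(SimulationConfig(seed=4))
        vals = pd.Series(0.0, index=tree.tip_labels)
        out, mask = introduce_missingness(
            vals, 0.2, mode="clustered", tree=tree, rng=np.random.default_rng(2)
        )
        assert mask.sum() == int(0.2 * tree.n_tips)

    def test_full_mask_errors(self, traits):
        with pytest.raises(ValueError):
            introduce_missingness(traits, 1.0)


class TestDataset:
    def test_determinism_and_truth_tables(self):
        a = generate_dataset(SimulationConfig(seed=21))
        b = generate_dataset(SimulationConfig(seed=21))
        pd.testing.assert_frame_equal(a.traits_observed, b.traits_observed)
        pd.testing.assert_frame_equal(a.basins, b.basins)
        pd.testing.assert_frame_equal(a.incidence, b.incidence)
        assert set(a.truth.columns) >= {"true_lambda", "true_sigma2_body"}
        assert (a.truth["true_lambda"] > 0).all()
        # trait-rate link: sigma2 proportional to lambda^power
        cfg = a.config
        expect = cfg.sigma2_body * (a.truth["true_lambda"] / cfg.lambda0) ** cfg.trait_link_power
        assert np.allclose(a.truth["true_sigma2_body"], expect)

    def test_body_size_positive_raw_scale(self):
        ds = generate_dataset(SimulationConfig(seed=22))
        assert (ds.traits_true["body_size"] > 0).all()
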