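"""Synthetic study generator: trees, traits, environment, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import commstruct as cs
from commstruct.nulls import derive_rng
from commstruct.synthetic import _limiting_similarity_draw


class TestYule:
    def test_shape_and_ultrametric(self):
        t = cs.simulate_yule(5, seed=0)
        assert t.n_tips == 5
        n_internal = sum(
            1 for n in t.dendropy_tree.preorder_internal_node_iter()
        )
        assert n_internal == 4
        depths = t._node_depths()
        tips = [depths[l] for l in t.dendropy_tree.leaf_node_iter()]
        assert np.ptp(tips) < 1e-9

    def test_deterministic(self):
        assert cs.simulate_yule(20, seed=5).newick() == \
            cs.simulate_yule(20, seed=5).newick()

    def test_pool_scale(self):
        t = cs.simulate_yule(389, seed=1, depth=1.0)
        assert t.n_tips == 389
        assert t.depth() == pytest.approx(1.0)
        labels = t.tip_labels
        assert len(set(labels)) == 389 and all(l.startswith("sp") for l in labels)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            cs.simulate_yule(1, seed=0)


class TestBm:
    def test_small_sigma_limit(self):
        t = cs.simulate_yule(10, seed=0, depth=1.0)
        x = cs.evolve_bm(t, 1e-12, root=3.0, seed=1)
        np.testing.assert_allclose(x.values, 3.0, atol=1e-4)

    def test_tip_variance_matches_closed_form(self):
        """On a star tree of depth T, tip values are iid N(root, sigma2*T)."""
        star = cs.parse_newick(
            "(" + ",".join(f"s{i}:2.5" for i in range(50)) + ");")
        draws = np.concatenate([
            cs.evolve_bm(star, 1.2, seed=rep).values for rep in range(40)
        ])  # 2000 iid tip values
        assert draws.var() == pytest.approx(1.2 * 2.5, rel=0.1)

    def test_covariance_ordering_follows_tree(self):
        """Sister tips covary more than distant tips, matching the
        phylogenetic covariance matrix."""
        t = cs.parse_newick("((A:1,B:1):3,(C:1,D:1):3);")
        reps = np.array([
            cs.evolve_bm(t, 1.0, seed=rep).loc[["A", "B", "C"]].values
            for rep in range(2000)
        ])
        cov = np.cov(reps, rowvar=False)
        assert cov[0, 1] > cov[0, 2] + 0.5  # C[A,B]=3, C[A,C]=0

    def test_bad_sigma(self):
        t = cs.simulate_yule(5, seed=0)
        with pytest.raises(ValueError):
            cs.evolve_bm(t, 0.0)


class TestOu:
    def _tree(self):
        return cs.simulate_yule(30, seed=3, depth=1.0)

    def test_zero_strength_reduces_to_bm(self):
        t = self._tree()
        out = cs.evolve_ou_gradient(
            t, 0.0, 1.0, lambda e: 99.0, {"p1": 2000.0}, seed=5)
        # same substream discipline as a BM run with matching rng
        bm = cs.evolve_bm(t, 1.0, rng=derive_rng(5, "ou", "p1"))
        np.testing.assert_allclose(out["p1"].values, bm.loc[out["p1"].index].values)

    def test_large_strength_pins_to_optimum(self):
        t = self._tree()
        out = cs.evolve_ou_gradient(
            t, 500.0, 1.0, lambda e: e / 1000.0, {"p1": 2000.0}, seed=6)
        np.testing.assert_allclose(out["p1"].values, 2.0, atol=0.2)

    def test_distance_to_optimum_decreases_with_strength(self):
        t = self._tree()
        mse = []
        for strength in (0.5, 2.0, 8.0):
            ds = []
            for rep in range(30):
                out = cs.evolve_ou_gradient(
                    t, strength, 1.0, lambda e: 4.0, {"p1": 0.0},
                    seed=100 + rep)
                ds.append(np.mean((out["p1"].values - 4.0) ** 2))
            mse.append(np.mean(ds))
        assert mse[0] > mse[1] > mse[2]


class TestEnv:
    def test_swc_correlation_calibration(self):
        env = cs.generate_env(1000, seed=1)
        r, _ = stats.pearsonr(env.column("elevation"), env.column("SWC"))
        assert 0.845 <= r <= 0.945

    def test_zero_target_independent(self):
        env = cs.generate_env(1000, seed=2, corr_targets={"SWC": 0.0})
        r, _ = stats.pearsonr(env.column("elevation"), env.column("SWC"))
        assert abs(r) < 0.1

    def test_elevation_bounds(self):
        env = cs.generate_env(500, elevation_range=(1140.0, 3480.0), seed=3)
        elev = env.column("elevation")
        assert elev.min() >= 1140.0 and elev.max() <= 3480.0

    def test_infeasible_target_named(self):
        with pytest.raises(ValueError, match="SWC"):
            cs.generate_env(10, corr_targets={"SWC": 0.999}, seed=0)


class TestAssemble:
    def _pool(self, n=60, seed=0):
        t = cs.simulate_yule(n, seed=seed, depth=1.0)
        return t, cs.evolve_bm(t, 1.0, seed=seed + 1)

    def test_strength_zero_inclusion_uniform(self):
        """Under every regime at strength 0, per-species inclusion counts
        are uniform (chi-square over 5,000 plots)."""
        t, x = self._pool(40)
        env = cs.generate_env(5000, seed=4, corr_targets={})
        for regime in ("neutral", "filtering", "limiting_similarity"):
            comm = cs.assemble(x, env, regime=regime, strength=0.0,
                               richness_range=(8, 12), seed=11)
            counts = comm.data["species"].value_counts()
            counts = counts.reindex(x.index, fill_value=0)
            chi2, p = stats.chisquare(counts)
            assert p > 1e-3, regime

    def test_filtering_shrinks_plot_variance(self):
        t, x = self._pool(100, seed=2)
        env = cs.generate_env(100, seed=5, corr_targets={})
        comm = cs.assemble(x, env, regime="filtering", strength=4.0,
                           richness_range=(10, 20), seed=12)
        pool_var = x.var(ddof=0)
        frac = np.mean([
            x.loc[comm.species_in(p)].var(ddof=0) < pool_var
            for p in comm.plots
        ])
        assert frac >= 0.95

    def test_limiting_similarity_spreads_minimum_gap(self):
        t, x = self._pool(100, seed=3)
        env = cs.generate_env(100, seed=6, corr_targets={})
        neutral = cs.assemble(x, env, regime="neutral", strength=0.0,
                              richness_range=(10, 15), seed=13)
        spaced = cs.assemble(x, env, regime="limiting_similarity", strength=2.0,
                             richness_range=(10, 15), seed=14)

        def min_gap(comm, p):
            vals = np.sort(x.loc[comm.species_in(p)].values)
            return np.diff(vals).min()

        neutral_med = np.median([min_gap(neutral, p) for p in neutral.plots])
        frac = np.mean([
            min_gap(spaced, p) > neutral_med for p in spaced.plots
        ])
        assert frac >= 0.95

    def test_unseatable_richness_raises(self):
        x = pd.Series(np.linspace(0, 1, 20), index=[f"s{i}" for i in range(20)])
        rng = derive_rng(0, "t")
        with pytest.raises(RuntimeError, match="lower the regime strength"):
            _limiting_similarity_draw(x.values, 15, 0.5, rng, max_restarts=5)


class TestScenario:
    def test_default_shape(self, tmp_path):
        cfg = cs.ScenarioConfig(seed=0)
        study = cs.scenario_suite(cfg, outdir=tmp_path)
        assert study.tree.n_tips == 389
        assert len(study.community.plots) == 40
        assert len(study.community.all_species) <= 148
        for name in ("pool.nwk", "traits.tsv", "env.tsv", "community.tsv",
                     "truth.tsv"):
            assert (tmp_path / name).exists()

    def test_seed_reproduces_files_bitwise(self, tmp_path):
        cfg = cs.ScenarioConfig(n_pool=40, n_observed=30, n_plots=6,
                                richness_range=(5, 10), seed=9)
        a, b = tmp_path / "a", tmp_path / "b"
        cs.scenario_suite(cfg, outdir=a)
        cs.scenario_suite(cfg, outdir=b)
        for f in a.iterdir():
            assert f.read_bytes() == (b / f.name).read_bytes()

    def test_outputs_pass_validators(self):
        cfg = cs.ScenarioConfig(n_pool=50, n_observed=40, n_plots=8,
                                richness_range=(5, 10), seed=3)
        study = cs.scenario_suite(cfg)
        # re-validating through the table constructors must not raise
        cs.CommunityTable(study.community.data)
        cs.TraitTable(study.traits.data)
        cs.EnvTable(study.env.data)
        assert set(study.community.all_species) <= set(study.tree.tip_labels)
        for p in study.community.plots:
            k = len(study.community.species_in(p))
            assert 5 <= k <= 10

    def test_strength_zero_regimes_indistinguishable(self):
        """KS test on per-plot MNTD over one shared pool: strength-0
        filtering and limiting similarity vs neutral (different draw seeds)."""
        t = cs.simulate_yule(60, seed=21, depth=1.0)
        x = cs.evolve_bm(t, 1.0, seed=22)
        env = cs.generate_env(400, seed=23, corr_targets={})
        dm = t.patristic_matrix()

        def mntds(regime, seed):
            comm = cs.assemble(x, env, regime=regime, strength=0.0,
                               richness_range=(6, 12), seed=seed)
            return [cs.mntd(comm.species_in(p), dm) for p in comm.plots]

        base = mntds("neutral", 31)
        for regime, seed in [("filtering", 32), ("limiting_similarity", 33)]:
            _, p = stats.ks_2samp(base, mntds(regime, seed))
            assert p > 1e-3, regime
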