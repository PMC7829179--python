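import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphospace import (
    SimConfig,
    bin_plots_to_intervals,
    brownian_trait,
    gen_climate,
    gen_four_transects,
    gen_phylo_bm,
    gen_pure_birth_tree,
    gen_trait_table,
    gen_transect,
)


class TestTraitGeneration:
    def test_marginal_frequencies_at_large_n(self):
        cfg = SimConfig(n_species_pool=10000, peak_richness=40)
        t = gen_trait_table(cfg, 1)
        for name, probs in cfg.marginals.items():
            freq = t.data[name].value_counts(normalize=True)
            for level, p in probs.items():
                assert freq.get(level, 0.0) == pytest.approx(p, abs=0.02)
        lengths = t.data["laminar_length"]
        assert lengths.min() >= 1.0 and lengths.max() <= 600.0

    def test_deterministic_given_seed(self):
        cfg = SimConfig()
        assert gen_trait_table(cfg, 7).data.equals(gen_trait_table(cfg, 7).data)

    def test_degenerate_marginal_constant_column(self):
        cfg = SimConfig(marginals={
            "rhizome_type": {1: 1.0},
            "laminar_dissection": {0: 0.3, 1: 0.4, 2: 0.3},
            "laminar_texture": {1: 0.3, 2: 0.4, 3: 0.3},
            "hydathodes": {0: 0.5, 1: 0.5},
        })
        t = gen_trait_table(cfg, 2)
        assert (t.data["rhizome_type"] == 1).all()

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(marginals={
                "rhizome_type": {0: 0.6, 1: 0.6},
                "laminar_dissection": {0: 1.0},
                "laminar_texture": {1: 1.0},
                "hydathodes": {0: 1.0},
            })


class TestCommunityGeneration:
    def test_richness_imposed_by_hump(self):
        cfg = SimConfig()
        traits = gen_trait_table(cfg, 3)
        com = gen_transect(cfg, traits, 4)
        for a in bin_plots_to_intervals(com):
            assert a.richness == cfg.target_richness(a.midpoint)

    def test_four_plots_per_interval(self):
        cfg = SimConfig()
        com = gen_transect(cfg, gen_trait_table(cfg, 3), 4)
        for a in bin_plots_to_intervals(com):
            assert len(a.plot_ids) == 4

    def test_deterministic_given_seed(self):
        cfg = SimConfig(phi=0.5)
        traits = gen_trait_table(cfg, 9)
        c1 = gen_transect(cfg, traits, 11)
        c2 = gen_transect(cfg, traits, 11)
        assert c1.incidence.equals(c2.incidence)
        assert c1.meta.equals(c2.meta)

    def test_filtering_sorts_traits_along_elevation(self):
        """At phi=1 co-occurring species cluster on the latent axis."""
        from morphospace.simulate import latent_axis, optimal_elevations

        cfg = SimConfig(phi=1.0, filter_width=100.0)
        traits = gen_trait_table(cfg, 5)
        com = gen_transect(cfg, traits, 6)
        opt = dict(zip(traits.species_ids, optimal_elevations(traits, cfg)))
        spreads, rng_spreads = [], []
        rng = np.random.default_rng(0)
        for a in bin_plots_to_intervals(com):
            member_opt = [opt[s] for s in a.species]
            random_opt = [opt[s] for s in rng.choice(
                traits.species_ids, size=a.richness, replace=False)]
            spreads.append(np.std(member_opt))
            rng_spreads.append(np.std(random_opt))
        assert np.mean(spreads) < 0.5 * np.mean(rng_spreads)

    def test_four_transect_preset(self):
        traits, com, cfgs = gen_four_transects(seed=2)
        assert set(com.transects) == {"ECU", "MX", "PNG", "UG"}
        assert len(cfgs) == 4
        assemblages = bin_plots_to_intervals(com)
        assert {a.transect for a in assemblages} == set(com.transects)


class TestPhylogenySimulation:
    def test_pure_birth_topology(self):
        tree = gen_pure_birth_tree(20, rng=1)
        leaves = [l for l in tree.leaf_node_iter()]
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 20
        # n - 1 bifurcations in a rooted binary tree
        assert len([n for n in internal if len(n.child_nodes()) == 2]) == 19
        assert all((l.edge.length or 0) > 0 for l in leaves)

    def test_zero_rate_constant_trait(self):
        tree = gen_pure_birth_tree(10, rng=2)
        x = brownian_trait(tree, rate=0.0, rng=3, root_value=1.5)
        assert np.allclose(x, 1.5)

    def test_bm_variance_scales_with_depth(self):
        """Squared contrasts regress on 1 with slope ~ the BM rate."""
        from morphospace.phylosignal import pic_coefficients

        sq = []
        for i in range(200):
            rng = np.random.default_rng(600 + i)
            cfg = SimConfig(bm_rate=2.5)
            tree, x = gen_phylo_bm(cfg, rng, n_tips=16)
            c, tips = pic_coefficients(tree)
            # standardized contrasts have variance sigma^2 under BM
            sq.extend((c @ x[tips].to_numpy()) ** 2)
        assert np.mean(sq) == pytest.approx(2.5, rel=0.1)


class TestClimate:
    def test_lapse_rate(self):
        cfg = SimConfig(elevation_min=0.0, elevation_max=1000.0)
        cl = gen_climate(cfg, 1, noise_sd=0.0)
        mat = cl.set_index("midpoint_m")["MAT"]
        assert mat.loc[200.0] == pytest.approx(26.0 - 5.5 * 0.2)

    def test_one_row_per_interval(self):
        cfg = SimConfig()
        cl = gen_climate(cfg, 1)
        assert len(cl) == len(cfg.interval_grid())

    def test_bryophyte_cover_increases_with_elevation(self):
        cl = gen_climate(SimConfig(), 2)
        rho = stats.spearmanr(cl["midpoint_m"], cl["bryophyte_cover"]).statistic
        assert rho > 0.8
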