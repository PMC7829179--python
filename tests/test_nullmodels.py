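import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from morphospace import (
    SimConfig,
    bin_plots_to_intervals,
    gen_trait_table,
    gen_transect,
    gower_dissimilarity,
    pcoa,
    ses,
    shuffle_trait_labels,
)
from morphospace.nullmodels import _two_sided_p

from conftest import make_traits


@pytest.fixture(scope="module")
def small_world():
    cfg = SimConfig(n_species_pool=40, peak_richness=15, base_richness=6,
                    elevation_max=2400.0)
    rng = np.random.default_rng(77)
    traits = gen_trait_table(cfg, rng)
    community = gen_transect(cfg, traits, rng)
    assemblages = bin_plots_to_intervals(community)
    ordination = pcoa(gower_dissimilarity(traits), n_axes=5)
    return cfg, traits, community, assemblages, ordination


class TestShuffle:
    def test_trait_rows_conserved(self, rng):
        t = gen_trait_table(SimConfig(n_species_pool=30, peak_richness=20), rng)
        sh = shuffle_trait_labels(t, rng)
        a = t.data.sort_values(list(t.data.columns)).reset_index(drop=True)
        b = sh.data.sort_values(list(t.data.columns)).reset_index(drop=True)
        assert a.equals(b)
        assert sorted(sh.species_ids) == sorted(t.species_ids)

    def test_seed_reproducibility(self):
        t = gen_trait_table(SimConfig(n_species_pool=30, peak_richness=20), 5)
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        assert shuffle_trait_labels(t, r1).species_ids == \
               shuffle_trait_labels(t, r2).species_ids
        # two draws from one stream differ
        s1 = shuffle_trait_labels(t, r1)
        s2 = shuffle_trait_labels(t, r1)
        assert s1.species_ids != s2.species_ids

    def test_single_species_identity(self):
        t = make_traits({"A": (1, 0, 1, 10.0, 0)})
        assert shuffle_trait_labels(t, np.random.default_rng(0)).species_ids == ["A"]


def test_shuffle_commutes_with_ordination(rng):
    """Gower+PCoA on a label-shuffled table equals a row permutation of
    the original: distances are label-independent."""
    t = gen_trait_table(SimConfig(n_species_pool=12, peak_richness=10), rng)
    sh = shuffle_trait_labels(t, rng)
    # reorder the shuffled table back into the original id order: species s
    # now carries the trait row of the species at position perm[s]
    perm = [sh.species_ids.index(s) for s in t.species_ids]
    d_orig = gower_dissimilarity(t).values
    d_sub = gower_dissimilarity(sh.subset(t.species_ids)).values
    assert np.allclose(d_sub, d_orig[np.ix_(perm, perm)], atol=1e-12)
    # and the PCoA configurations are congruent (inter-point distances match)
    rec_orig = squareform(pdist(pcoa(gower_dissimilarity(t)).coordinates))
    rec_sub = squareform(pdist(pcoa(gower_dissimilarity(sh.subset(t.species_ids))).coordinates))
    assert np.allclose(rec_sub, rec_orig[np.ix_(perm, perm)], atol=1e-8)


class TestSes:
    def test_arithmetic_definition(self):
        # SES = (obs - mean) / sd on a constructed null
        null = np.array([2.0, 3.0, 4.0])
        ses_val = (5.0 - null.mean()) / null.std(ddof=1)
        assert ses_val == pytest.approx(2.0)

    @staticmethod
    def _assemblage(species):
        import pandas as pd

        from morphospace import IntervalAssemblage

        return IntervalAssemblage(
            transect="T1", index=1, lower=0.0, upper=400.0, plot_ids=[],
            species=list(species), incidence=pd.DataFrame(columns=list(species)),
        )

    def test_full_pool_assemblage_flagged(self, small_world):
        cfg, traits, community, assemblages, ordination = small_world
        a = self._assemblage(traits.species_ids)
        out = ses([a], traits, "mNND", n_reps=19, rng=1, ordination=ordination,
                  pool="global")
        assert out[0].flag == "zero_null_sd"
        assert np.isnan(out[0].ses)

    def test_feve_undefined_small_assemblage_flagged(self, small_world):
        cfg, traits, community, assemblages, ordination = small_world
        a = self._assemblage(traits.species_ids[:2])
        out = ses([a], traits, "FEve", n_reps=9, rng=1, ordination=ordination)
        assert out[0].flag == "undefined"

    def test_deterministic_given_seed(self, small_world):
        cfg, traits, community, assemblages, ordination = small_world
        r1 = ses(assemblages, traits, "mNND", n_reps=49, rng=11, ordination=ordination)
        r2 = ses(assemblages, traits, "mNND", n_reps=49, rng=11, ordination=ordination)
        assert [x.ses for x in r1] == [x.ses for x in r2]

    def test_permutation_route_matches_literal_shuffle(self, small_world):
        """Row-permutation nulls equal literally reordinating shuffled traits."""
        cfg, traits, community, assemblages, ordination = small_world
        a = assemblages[2]
        rng = np.random.default_rng(3)
        sh = shuffle_trait_labels(traits, rng)
        # literal route: recompute ordination from the shuffled table
        o_lit = pcoa(gower_dissimilarity(sh.subset(traits.species_ids)), n_axes=5)
        from morphospace.indices import nnd
        lit = nnd(o_lit.points(a.species))[0]
        # permutation route: look up the same species' new trait rows
        mapping = dict(zip(sh.species_ids, traits.species_ids))
        donors = [mapping[s] for s in a.species]
        perm = nnd(ordination.points(donors))[0]
        assert lit == pytest.approx(perm, abs=1e-8)

    def test_ses_sign_flips_with_negated_index(self, small_world):
        cfg, traits, community, assemblages, ordination = small_world
        out = ses(assemblages, traits, "mNND", n_reps=99, rng=5, ordination=ordination)
        for r in out:
            if np.isfinite(r.ses):
                neg_ses = (-r.observed - (-r.null_mean)) / r.null_sd
                assert neg_ses == pytest.approx(-r.ses)

    def test_p_and_ses_agree_in_direction(self, small_world):
        cfg, traits, community, assemblages, ordination = small_world
        out = ses(assemblages, traits, "mNND", n_reps=199, rng=7, ordination=ordination)
        for r in out:
            if np.isfinite(r.ses) and abs(r.ses) > 2.5:
                assert r.p < 0.1

    def test_fric_and_feve_indices_run(self, small_world):
        cfg, traits, community, assemblages, ordination = small_world
        for name in ("FRic", "FEve"):
            out = ses(assemblages[:2], traits, name, n_reps=19, rng=2,
                      ordination=ordination)
            assert len(out) == 2
            assert all(np.isfinite(r.ses) or r.flag for r in out)


def test_two_sided_p_rank_convention():
    null = np.arange(1.0, 100.0)  # 99 nulls
    # observed above every null: floor at 2/(n+1), never exactly 0
    assert _two_sided_p(1000.0, null) == pytest.approx(2 / 100)
    # observed at the median: p capped at 1
    assert _two_sided_p(50.0, null) == pytest.approx(1.0)
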