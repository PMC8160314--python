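"""Synthetic-community generator: trees, traits, pools, regimes."""

import numpy as np
import pandas as pd
import pytest

import commassembly as ca
from commassembly.errors import ValidationError
from commassembly.simulate import _selection_weights


class TestSimulateTree:
    def test_tip_count_and_unique_labels(self):
        tree = ca.simulate_tree(5, seed=0)
        tips = [t.name for t in tree.tips()]
        assert len(tips) == 5 and len(set(tips)) == 5

    def test_same_seed_identical_newick(self):
        a = str(ca.simulate_tree(16, seed=4))
        b = str(ca.simulate_tree(16, seed=4))
        assert a == b

    def test_branch_lengths_strictly_positive(self):
        tree = ca.simulate_tree(24, seed=1)
        assert all(n.length > 0 for n in tree.traverse(include_self=False))

    def test_minimum_tips(self):
        with pytest.raises(ValidationError):
            ca.simulate_tree(2, seed=0)

    def test_depth_grows_with_tip_count(self):
        # Yule expectation: mean root-to-tip depth ~ harmonic growth in n
        def mean_depth(n, seeds=60):
            out = []
            for s in range(seeds):
                tree = ca.simulate_tree(n, seed=s)
                depths = {id(tree): 0.0}
                for node in tree.preorder(include_self=False):
                    depths[id(node)] = depths[id(node.parent)] + node.length
                out.append(np.mean([depths[id(t)] for t in tree.tips()]))
            return np.mean(out)

        assert mean_depth(32) > mean_depth(8)


class TestEvolveTrait:
    def test_same_seed_identical(self):
        tree = ca.simulate_tree(12, seed=2)
        a = ca.evolve_trait(tree, 1.0, seed=3)
        b = ca.evolve_trait(tree, 1.0, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_small_sigma_keeps_traits_near_root(self):
        tree = ca.simulate_tree(12, seed=2)
        traits = ca.evolve_trait(tree, 1e-8, seed=3)
        assert np.abs(traits.to_numpy()).max() < 1e-6

    def test_non_positive_sigma_rejected(self):
        tree = ca.simulate_tree(4, seed=0)
        with pytest.raises(ValidationError):
            ca.evolve_trait(tree, 0.0, seed=1)

    def test_brownian_covariance_proportional_to_shared_path(self):
        tree = ca.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        draws = np.array(
            [ca.evolve_trait(tree, 1.0, seed=s).reindex(list("ABCD")).to_numpy()
             for s in range(2000)]
        )
        cov = np.cov(draws.T)
        # shared path to root: 1 for (A,B) and (C,D); 0 across the split;
        # total variance per tip = 2
        assert cov[0, 1] == pytest.approx(1.0, abs=0.15)
        assert cov[2, 3] == pytest.approx(1.0, abs=0.15)
        assert cov[0, 2] == pytest.approx(0.0, abs=0.15)
        assert cov[0, 0] == pytest.approx(2.0, abs=0.3)

    def test_conserved_trait_constant_within_deep_clades(self):
        tree = ca.simulate_tree(32, seed=5)
        cons, clades = ca.conserved_trait(tree, 1.0, seed=6, depth_fraction=0.5)
        assert len(set(np.round(cons.to_numpy(), 12))) == len(clades)


class TestMakePool:
    def test_normalised_and_positive(self):
        tree = ca.simulate_tree(20, seed=1)
        pool = ca.make_pool(tree, seed=2)
        assert pool.sum() == pytest.approx(1.0)
        assert (pool > 0).all()

    def test_heavy_tail(self):
        tree = ca.simulate_tree(40, seed=3)
        pool = ca.make_pool(tree, seed=4)
        assert pool.max() > pool.mean()


class TestSimulateCommunity:
    @pytest.mark.parametrize("regime", list(ca.simulate.REGIMES))
    def test_samples_sum_to_depth(self, regime):
        sc = ca.Scenario(regime=regime, n_taxa_pool=32, n_samples=4, depth=400, seed=1)
        ds = ca.simulate_dataset(sc)
        assert (ds.table.sample_totals() == 400).all()
        assert (ds.truth["regime"] == regime).all()

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValidationError):
            ca.Scenario(regime="chaos")

    def test_bit_reproducible_under_seed(self):
        sc = ca.Scenario(regime="dispersal_limitation", n_taxa_pool=32, n_samples=4,
                         depth=400, seed=9)
        a = ca.simulate_dataset(sc)
        b = ca.simulate_dataset(sc)
        assert a.table == b.table
        assert str(a.tree) == str(b.tree)

    def test_wide_niche_reduces_to_pool_weights(self):
        pool = np.array([0.5, 0.3, 0.2])
        traits = np.array([-1.0, 0.0, 1.0])
        w = _selection_weights(pool, traits, opt=0.0, width=1e6)
        assert np.abs(w - pool).max() < 1e-9

    def test_dispersal_limitation_cross_subpool_bray_curtis_near_one(self):
        sc = ca.Scenario(regime="dispersal_limitation", n_taxa_pool=64, n_samples=6,
                         depth=1000, seed=3)
        ds = ca.simulate_dataset(sc)
        blocks = ds.truth["block"]
        mat = ds.table.matrix.astype(float)
        ids = ds.table.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if blocks[ids[i]] != blocks[ids[j]]:
                    assert ca.bray_curtis(mat[:, i], mat[:, j]) > 0.9

    def test_homogeneous_selection_requires_tree(self):
        tree = ca.simulate_tree(16, seed=0)
        pool = ca.make_pool(tree, seed=1)
        traits = ca.evolve_trait(tree, 1.0, seed=2)
        sc = ca.Scenario(regime="homogeneous_selection", n_taxa_pool=16, n_samples=4,
                         depth=400, seed=3)
        with pytest.raises(ValidationError, match="tree"):
            ca.simulate_community(pool, traits, "homogeneous_selection", sc)


class TestTaxonomyFromTree:
    def test_families_partition_all_tips(self):
        tree = ca.simulate_tree(48, seed=7)
        tax = ca.taxonomy_from_tree(tree)
        tips = {t.name for t in tree.tips()}
        assert set(tax.lineages) == tips
        fams = {tax.rank(t, "family") for t in tips}
        assert all(f != "" for f in fams)
        assert 1 < len(fams) < len(tips)

    def test_families_are_clades(self):
        tree = ca.simulate_tree(48, seed=8)
        tax = ca.taxonomy_from_tree(tree)
        clades = ca.build_clades(tax, "family")
        # each family's tips must form a connected subtree: their LCA
        # contains no tips from other families
        for taxa in clades.clades.values():
            lca = tree.lca([tree.find(t) for t in taxa])
            lca_tips = {t.name for t in lca.tips()} if not lca.is_tip() else {lca.name}
            assert lca_tips == set(taxa)


class TestPaperShapedPreset:
    def test_shape_and_metadata(self):
        table, tree, tax, meta, truth = ca.paper_shaped_dataset(
            seed=1, n_taxa_pool=96, depth=600
        )
        assert len(table.sample_ids) == 24
        groups = meta.groups(["position", "nucleic_acid"])
        assert len(groups) == 4
        assert all(len(v) == 6 for v in groups.values())
        ca.validate_cross_references(table, tree=tree, tax=tax, meta=meta)
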