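"""Phylogenetic null models: cophenetic distances, MNTD/NTI, betaMNTD/betaNTI."""

import numpy as np
import pandas as pd
import pytest

import commassembly as ca
from commassembly.errors import UndefinedStatisticError, ValidationError
from commassembly.phylo import PhyloDistanceMatrix, cophenetic_distances


def brute_force_patristic(tree):
    """Independent oracle: d(a,b) = depth(a) + depth(b) - 2 depth(lca)."""
    depths = {}
    parents = {}
    for node in tree.preorder(include_self=False):
        parent = node.parent
        depths[id(node)] = depths.get(id(parent), 0.0) + (node.length or 0.0)
        parents[id(node)] = parent
    tips = list(tree.tips())

    def ancestors(node):
        out = [id(node)]
        while id(node) in parents:
            node = parents[id(node)]
            out.append(id(node))
        return out

    names = [t.name for t in tips]
    mat = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(tips):
        anc_a = ancestors(a)
        for j, b in enumerate(tips):
            if i >= j:
                continue
            anc_b = set(ancestors(b))
            lca = next(x for x in anc_a if x in anc_b)
            d = depths[id(a)] + depths[id(b)] - 2 * depths.get(lca, 0.0)
            mat[i, j] = mat[j, i] = d
    return names, mat


class TestCophenetic:
    def test_hand_values(self, three_tip_tree):
        dist = cophenetic_distances(three_tip_tree)
        assert dist.between("B", "C") == pytest.approx(1.0)
        assert dist.between("A", "B") == pytest.approx(2.0)
        assert dist.between("A", "C") == pytest.approx(2.0)

    def test_star_tree_all_distance_two(self):
        tree = ca.parse_newick("(A:1,B:1,C:1,D:1);")
        dist = cophenetic_distances(tree)
        off = dist.data[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_matches_brute_force_on_random_trees(self):
        for seed in range(5):
            tree = ca.simulate_tree(6, seed=seed)
            dist = cophenetic_distances(tree)
            names, mat = brute_force_patristic(tree)
            order = [names.index(t) for t in dist.taxon_ids]
            assert np.allclose(dist.data, mat[np.ix_(order, order)], atol=1e-12)

    def test_ultrametric_three_point_condition(self):
        # on a clock-like tree the two largest pairwise distances tie
        tree = ca.parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        dist = cophenetic_distances(tree)
        for trio in [("A", "B", "C"), ("A", "C", "D"), ("B", "C", "D")]:
            ds = sorted(
                [dist.between(trio[0], trio[1]), dist.between(trio[0], trio[2]),
                 dist.between(trio[1], trio[2])]
            )
            assert ds[1] == pytest.approx(ds[2])


class TestMNTD:
    def _dist(self):
        return PhyloDistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )

    def test_hand_example(self):
        d = self._dist()
        assert ca.mntd([1, 1, 1], d) == pytest.approx((2 + 2 + 4) / 3)

    def test_two_taxa_equals_distance(self):
        d = self._dist()
        assert ca.mntd([1, 1, 0], d) == pytest.approx(2.0)
        assert ca.mntd([5, 1, 0], d, abundance_weighted=True) == pytest.approx(2.0)

    def test_weighted_limit_toward_single_taxon(self):
        d = self._dist()
        heavy = ca.mntd([999, 0, 1], d, abundance_weighted=True)
        assert heavy == pytest.approx(4.0, rel=0.01)  # ~ nearest distance of A (to C)

    def test_fewer_than_two_taxa_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ca.mntd([1, 0, 0], self._dist())


class TestBetaMNTD:
    def _dist(self):
        return PhyloDistanceMatrix(
            ["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]])
        )

    def test_singleton_pair(self):
        d = self._dist()
        assert ca.beta_mntd([1, 0], [0, 1], d) == pytest.approx(2.0)

    def test_identical_membership_zero(self):
        d = self._dist()
        assert ca.beta_mntd([3, 1], [1, 4], d) == 0.0

    def test_symmetry_on_random_fixtures(self, rng):
        tree = ca.simulate_tree(12, seed=3)
        dist = cophenetic_distances(tree)
        for _ in range(20):
            x = rng.integers(0, 5, 12)
            y = rng.integers(0, 5, 12)
            if x.sum() == 0 or y.sum() == 0:
                continue
            ab = ca.beta_mntd(x, y, dist)
            ba = ca.beta_mntd(y, x, dist)
            assert ab == pytest.approx(ba, abs=1e-14)
            assert ab >= 0.0


class TestNTI:
    def test_deterministic_under_seed(self, rng):
        ds = ca.simulate_dataset(ca.Scenario(regime="pure_drift", n_taxa_pool=24,
                                             n_samples=4, depth=300, seed=5))
        a = ca.nti(ds.table, ds.tree, reps=99, seed=11)
        b = ca.nti(ds.table, ds.tree, reps=99, seed=11)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_clustered_sample_has_positive_nti(self):
        tree = ca.simulate_tree(64, seed=2)
        tips = sorted(t.name for t in tree.tips())
        # one sample confined to a small clade; broad samples define the pool
        clade = next(
            n for n in tree.preorder(include_self=False)
            if not n.is_tip() and 6 <= n.count(tips=True) <= 10
        )
        clade_tips = [t.name for t in clade.tips()]
        rng = np.random.default_rng(4)
        cols = {"clustered": pd.Series(0, index=tips)}
        cols["clustered"][clade_tips] = 1
        for j in range(4):
            v = pd.Series(0, index=tips)
            v[rng.choice(tips, 20, replace=False)] = 1
            cols[f"broad{j}"] = v
        table = ca.AbundanceTable(pd.DataFrame(cols))
        res = ca.nti(table, tree, reps=999, seed=9)
        assert res.table.loc["clustered", "nti"] > 2

    def test_taxon_missing_from_tree_raises(self, three_tip_tree):
        table = ca.AbundanceTable(
            pd.DataFrame({"S1": [1, 1], "S2": [1, 1]}, index=["A", "ZZ"])
        )
        with pytest.raises(ValidationError, match="ZZ"):
            ca.nti(table, three_tip_tree, reps=9, seed=0)


class TestBetaNTI:
    def test_identical_membership_pair_flagged_undefined(self):
        tree = ca.parse_newick("(A:1,(B:0.5,C:0.5):0.5);")
        table = ca.AbundanceTable(
            pd.DataFrame({"S1": [2, 3, 0], "S2": [4, 1, 0]}, index=["A", "B", "C"])
        )
        res = ca.beta_nti(table, tree, reps=49, seed=0)
        assert np.isnan(res.pairs["bnti"].iloc[0])

    def test_matches_naive_reimplementation(self):
        """Vectorised null equals a per-pair loop given the same permutations."""
        ds = ca.simulate_dataset(ca.Scenario(regime="pure_drift", n_taxa_pool=6,
                                             n_samples=4, depth=300, seed=8))
        table, tree = ds.table, ds.tree
        reps, seed = 199, 13
        res = ca.beta_nti(table, tree, reps=reps, seed=seed)

        dist = cophenetic_distances(tree)
        order = {t: i for i, t in enumerate(dist.taxon_ids)}
        D = dist.data
        n = D.shape[0]
        perms = np.argsort(np.random.default_rng(seed).random((reps, n)), axis=1)
        mat = table.matrix.astype(float)
        pos = np.array([order[t] for t in table.taxon_ids])

        def naive_bmntd(Dm, xi, yi, fx, fy):
            mins_x = [min(Dm[a, b] for b in yi) for a in xi]
            mins_y = [min(Dm[a, b] for a in xi) for b in yi]
            return 0.5 * (np.dot(fx, mins_x) + np.dot(fy, mins_y))

        k = 0
        for i in range(len(table.sample_ids)):
            for j in range(i + 1, len(table.sample_ids)):
                xi = pos[np.flatnonzero(mat[:, i] > 0)]
                yi = pos[np.flatnonzero(mat[:, j] > 0)]
                fx = mat[mat[:, i] > 0, i] / mat[:, i].sum()
                fy = mat[mat[:, j] > 0, j] / mat[:, j].sum()
                null = np.array([naive_bmntd(D, p[xi], p[yi], fx, fy) for p in perms])
                row = res.pairs.iloc[k]
                assert row["null_mean"] == pytest.approx(null.mean(), abs=1e-12)
                assert row["null_sd"] == pytest.approx(null.std(ddof=1), abs=1e-12)
                k += 1

    def test_symmetric_results_independent_of_weighting_flag_shape(self):
        ds = ca.simulate_dataset(ca.Scenario(regime="pure_drift", n_taxa_pool=16,
                                             n_samples=4, depth=300, seed=3))
        res = ca.beta_nti(ds.table, ds.tree, reps=49, seed=5, abundance_weighted=False)
        assert (res.pairs["bmntd_obs"] >= 0).all()
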