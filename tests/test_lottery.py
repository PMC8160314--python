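"""Competitive lottery model: clades, winner calls, prevalence/diversity."""

import math

import numpy as np
import pandas as pd
import pytest

import commassembly as ca
from commassembly.errors import ValidationError


@pytest.fixture
def family_taxonomy():
    return ca.TaxonomyMap(
        {
            "a1": ("Bacteria", "", "", "", "F1", "G1", ""),
            "a2": ("Bacteria", "", "", "", "F1", "G2", ""),
            "b1": ("Bacteria", "", "", "", "F2", "G3", ""),
            "u1": ("Bacteria", "", "", "", "", "", ""),
        }
    )


class TestBuildClades:
    def test_family_grouping(self, family_taxonomy):
        clades = ca.build_clades(family_taxonomy, "family")
        assert set(clades.clades) == {"F1", "F2"}
        assert sorted(clades.clades["F1"]) == ["a1", "a2"]
        assert clades.n_unassigned == 1

    def test_genus_level_gives_finer_partition(self, family_taxonomy):
        fam = ca.build_clades(family_taxonomy, "family")
        gen = ca.build_clades(family_taxonomy, "genus")
        assert len(gen.clades) > len(fam.clades)

    def test_all_empty_rank_warns(self):
        tax = ca.TaxonomyMap({"x": ("Bacteria",)})
        with pytest.warns(UserWarning):
            clades = ca.build_clades(tax, "species")
        assert clades.clades == {}

    def test_invalid_rank(self, family_taxonomy):
        with pytest.raises(ValidationError):
            ca.build_clades(family_taxonomy, "tribe")


def toy_lottery():
    """4 samples, 2 clades, hand-computable winner structure.

    Clade F1 (members a1, a2): shares 19/20, 8/10, 9/10, 19/20 ->
    winners in S1 and S4 only (0.95 > 0.9; 0.8 and exactly 0.9 are not).
    Clade F2 (members b1, b2): b1 always 100% -> wins everywhere.
    """
    counts = pd.DataFrame(
        {
            "S1": [19, 1, 12, 0],
            "S2": [8, 2, 15, 0],
            "S3": [9, 1, 11, 0],
            "S4": [1, 19, 20, 0],
        },
        index=["a1", "a2", "b1", "b2"],
    )
    table = ca.AbundanceTable(counts)
    clades = ca.CladeMap({"F1": ["a1", "a2"], "F2": ["b1", "b2"]}, "family")
    return table, clades


class TestDetectWinners:
    def test_hand_computed_calls(self):
        table, clades = toy_lottery()
        res = ca.detect_winners(table, clades, threshold=0.90, min_clade_reads=10)
        f1 = res.calls[res.calls["clade"] == "F1"].set_index("sample")
        assert f1.loc["S1", "winner"] == "a1" and f1.loc["S1", "share"] == pytest.approx(0.95)
        assert f1.loc["S2", "winner"] == ""      # 0.80
        assert f1.loc["S3", "winner"] == ""      # exactly 0.90: strict bound
        assert f1.loc["S4", "winner"] == "a2"
        assert set(res.winners("F2")) == {"b1"} and len(res.winners("F2")) == 4

    def test_min_reads_floor_excludes_samples(self):
        table, clades = toy_lottery()
        res = ca.detect_winners(table, clades, min_clade_reads=16)
        assert res.eligible_samples("F1") == ["S1", "S4"]

    def test_threshold_monotonicity(self):
        table, clades = toy_lottery()
        previous = None
        for thr in [0.6, 0.7, 0.8, 0.9, 0.95]:
            res = ca.detect_winners(table, clades, threshold=thr, min_clade_reads=5)
            winners = {(r.sample, r.clade) for r in res.calls.itertuples() if r.winner}
            if previous is not None:
                assert winners <= previous
            previous = winners

    def test_invalid_threshold(self):
        table, clades = toy_lottery()
        with pytest.raises(ValidationError):
            ca.detect_winners(table, clades, threshold=0.4)


class TestPrevalenceDiversity:
    def test_prevalence_arithmetic(self):
        table, clades = toy_lottery()
        res = ca.detect_winners(table, clades, min_clade_reads=10)
        assert ca.winner_prevalence(res, "F1") == pytest.approx(2 / 4)
        assert ca.winner_prevalence(res, "F2") == pytest.approx(1.0)

    def test_single_winner_identity_diversity_zero(self):
        table, clades = toy_lottery()
        res = ca.detect_winners(table, clades, min_clade_reads=10)
        assert ca.winner_diversity(res, "F2") == 0.0

    def test_alternating_winners_diversity(self):
        # winners [a1, a2, a1, a2]: H = ln 2, normalised by ln 4 -> 0.5
        counts = pd.DataFrame(
            {f"S{j}": [19, 1] if j % 2 == 0 else [1, 19] for j in range(4)},
            index=["a1", "a2"],
        )
        res = ca.detect_winners(
            ca.AbundanceTable(counts), ca.CladeMap({"F": ["a1", "a2"]}, "family")
        )
        assert ca.winner_diversity(res, "F") == pytest.approx(math.log(2) / math.log(4))

    def test_never_eligible_is_nan(self):
        table, clades = toy_lottery()
        res = ca.detect_winners(table, clades, min_clade_reads=1000)
        assert math.isnan(ca.winner_prevalence(res, "F1"))

    def test_invariance_to_sample_order_and_relabeling(self):
        table, clades = toy_lottery()
        res1 = ca.detect_winners(table, clades)
        shuffled = ca.AbundanceTable(table.counts[["S3", "S1", "S4", "S2"]])
        res2 = ca.detect_winners(shuffled, clades)
        for clade in ("F1", "F2"):
            assert ca.winner_prevalence(res1, clade) == ca.winner_prevalence(res2, clade)
            assert ca.winner_diversity(res1, clade) == ca.winner_diversity(res2, clade)


class TestStatusChanges:
    def test_subset_all_and_none_patterns(self):
        table, clades = toy_lottery()
        res_all = ca.detect_winners(table, clades, min_clade_reads=10)
        # category where F1 never wins (only its non-winning samples)
        sub = ca.AbundanceTable(table.counts[["S2", "S3"]])
        res_sub = ca.detect_winners(sub, clades, min_clade_reads=10)
        changes = ca.winner_status_changes({"settled": res_all, "floating": res_sub})
        by_clade = changes.set_index("clade")
        assert by_clade.loc["F2", "status"] == "winner_in_all"
        assert by_clade.loc["F1", "status"] == "winner_in_subset"
        assert by_clade.loc["F1", "categories_won"] == "settled"

    def test_requires_two_categories(self):
        table, clades = toy_lottery()
        res = ca.detect_winners(table, clades)
        with pytest.raises(ValidationError):
            ca.winner_status_changes({"only": res})
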