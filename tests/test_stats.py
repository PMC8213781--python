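"""Fisher/BH machinery and the contrasting-pairs test against oracles."""

import math
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecisminer.model import ParameterError
from ecisminer.simulate import make_tree_traits
from ecisminer.stats import (
    bh_adjust,
    fisher_exact_2x2,
    genus_enrichment,
    max_contrasting_pairs,
    trait_association,
)
from oracles import bh_step_up, brute_contrasting_pairs, fisher_two_sided_enum


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestFisher:
    def test_total_presence_gives_infinite_odds_ratio(self):
        # every genome of the genus carries the locus, none elsewhere missing
        oratio, p = fisher_exact_2x2(18, 0, 1231, 63507)
        assert math.isinf(oratio) and p < 1e-20

    def test_total_absence_gives_zero_odds_ratio(self):
        oratio, p = fisher_exact_2x2(0, 18355, 1249, 45152)
        assert oratio == 0.0 and p < 1e-100

    def test_symmetric_table(self):
        oratio, p = fisher_exact_2x2(1, 1, 1, 1)
        assert oratio == 1.0 and p == 1.0

    def test_zero_over_zero_is_nan(self):
        oratio, _ = fisher_exact_2x2(0, 5, 0, 5)
        assert math.isnan(oratio)

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2(-1, 1, 1, 1)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        _, p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_two_sided_enum(a, b, c, d), rel=1e-12)

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_transpose_and_row_swap_symmetries(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        oratio, p = fisher_exact_2x2(a, b, c, d)
        _, p_t = fisher_exact_2x2(a, c, b, d)  # transpose
        assert p == pytest.approx(p_t, rel=1e-9)
        or_swap, _ = fisher_exact_2x2(c, d, a, b)  # swap rows
        if oratio not in (0.0,) and math.isfinite(oratio) and not math.isnan(oratio):
            assert or_swap == pytest.approx(1 / oratio)


class TestBH:
    def test_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([0.05, 0.5]) == pytest.approx([0.10, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle(self, ps):
        assert bh_adjust(ps) == pytest.approx(bh_step_up(ps), rel=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q = bh_adjust(ps)
        q_perm = bh_adjust([ps[i] for i in perm])
        assert [q[i] for i in perm] == pytest.approx(list(q_perm))


class TestGenusEnrichment:
    def test_enriched_genus_matches_oracle(self):
        presence = {f"A{i}": 1 for i in range(10)}
        presence.update({f"B{i}": 1 if i < 10 else 0 for i in range(990)})
        taxonomy = {g: ("GenusA" if g.startswith("A") else "GenusB") for g in presence}
        df = genus_enrichment(presence, taxonomy).set_index("genus")
        row = df.loc["GenusA"]
        assert (row.a, row.b, row.c, row.d) == (10, 0, 10, 980)
        assert row.p == pytest.approx(fisher_two_sided_enum(10, 0, 10, 980), rel=1e-12)
        assert math.isinf(row.odds_ratio)

    def test_small_genus_not_reportable(self):
        presence = {f"A{i}": 1 for i in range(9)}
        presence.update({f"B{i}": 0 for i in range(100)})
        taxonomy = {g: g[0] for g in presence}
        df = genus_enrichment(presence, taxonomy).set_index("genus")
        assert df.loc["A"].q < 0.001 and not df.loc["A"].reportable

    def test_unknown_genome_in_taxonomy_warns(self):
        with pytest.warns(UserWarning, match="absent from presence"):
            genus_enrichment({"G1": 1, "G2": 0}, {"G1": "x", "G2": "x", "G3": "y"})


class TestContrastingPairs:
    def test_scattered_association(self):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0}
        ps = max_contrasting_pairs(tree_of("((A,B),(C,D));"), geno, dict(geno))
        assert (ps.max_pairs, ps.best_support) == (2, 2)
        assert ps.p_best == pytest.approx(0.25)

    def test_clade_confounded_collapses_to_one_pair(self):
        geno = {"A": 1, "B": 1, "C": 0, "D": 0}
        ps = max_contrasting_pairs(tree_of("((A,B),(C,D));"), geno, dict(geno))
        assert ps.max_pairs == 1

    def test_monomorphic_genotype_gives_na(self):
        geno = {"A": 0, "B": 0, "C": 0, "D": 0}
        ps = max_contrasting_pairs(tree_of("((A,B),(C,D));"), geno, dict(geno))
        assert ps.max_pairs == 0 and math.isnan(ps.p_best)

    def test_opposing_association_has_zero_support(self):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0}
        pheno = {k: 1 - v for k, v in geno.items()}
        ps = max_contrasting_pairs(tree_of("((A,B),(C,D));"), geno, pheno)
        assert (ps.max_pairs, ps.best_support, ps.worst_support) == (2, 0, 0)

    def test_extra_table_entries_pruned_with_warning(self):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0, "GHOST": 1}
        with pytest.warns(UserWarning, match="absent from tree"):
            ps = max_contrasting_pairs(tree_of("((A,B),(C,D));"), geno, dict(geno))
        assert ps.max_pairs == 2

    def test_polytomy_allows_two_pairs_through_one_node(self):
        geno = {"A": 1, "B": 0, "C": 1, "D": 0}
        ps = max_contrasting_pairs(tree_of("(A,B,C,D);"), geno, dict(geno))
        assert ps.max_pairs == 2

    def test_matches_brute_force_on_random_trees(self):
        rnd = random.Random(7)
        for trial in range(60):
            n = rnd.randint(4, 10)
            tree, traits = make_tree_traits(1000 + trial, n, "null")
            geno = traits["ecis"].to_dict()
            pheno = traits["trait"].to_dict()
            ps = max_contrasting_pairs(tree, geno, pheno)
            assert (
                ps.max_pairs, ps.best_support, ps.worst_support
            ) == brute_contrasting_pairs(tree, geno, pheno)

    def test_clade_confounding_regardless_of_tip_count(self):
        for n in (8, 16, 24):
            tree, traits = make_tree_traits(n, n, "clade_confounded")
            ps = max_contrasting_pairs(
                tree, traits["ecis"].to_dict(), traits["trait"].to_dict()
            )
            assert ps.max_pairs == 1

    def test_independent_association_pairs_every_tip(self):
        tree, traits = make_tree_traits(3, 16, "independent_assoc")
        ps = max_contrasting_pairs(
            tree, traits["ecis"].to_dict(), traits["trait"].to_dict()
        )
        assert (ps.max_pairs, ps.best_support, ps.worst_support) == (8, 8, 8)


class TestTraitAssociation:
    def test_reports_both_statistics(self):
        tree, traits = make_tree_traits(21, 16, "independent_assoc")
        df = trait_association(tree, traits, "ecis")
        row = df.iloc[0]
        assert row.trait == "trait"
        assert row.max_pairs == 8 and row.p_best < 0.01
        assert row.fisher_q < 0.01 and math.isinf(row.odds_ratio)
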