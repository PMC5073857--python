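import itertools
import random

import pytest

from evorank.phylo_io import GAP, MISSING, TimeTree, TreeNode, parse_newick
from evorank.site_evolution import (
    LESS,
    ULTRA,
    UNCLASSIFIED,
    WELL,
    classify_conservation,
    count_substitutions_fitch,
    evol_rate,
    evol_span,
    prune_to_present,
    site_evolution,
)
from evorank.synthetic import simulate_time_tree

from conftest import brute_force_parsimony, make_column


class TestPruneToPresent:
    def test_all_present_is_identity(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": "G", "D": "G"})
        pruned = prune_to_present(four_taxon_tree, col)
        assert sorted(pruned.leaf_labels()) == ["B", "C", "D", "H"]
        assert pruned.total_time_my == pytest.approx(1200.0)

    def test_sister_pair_drops_internal_edges(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": GAP, "D": GAP})
        pruned = prune_to_present(four_taxon_tree, col)
        assert sorted(pruned.leaf_labels()) == ["B", "H"]
        assert pruned.total_time_my == pytest.approx(200.0)

    def test_cross_pair_collapses_path(self, four_taxon_tree):
        col = make_column({"H": "A", "B": GAP, "C": "G", "D": MISSING})
        pruned = prune_to_present(four_taxon_tree, col)
        assert sorted(pruned.leaf_labels()) == ["C", "H"]
        # path H—root—C: 100+400 on each side, collapsed into two 500-My edges
        lengths = sorted(l.branch_length_my for l in pruned.leaves())
        assert lengths == pytest.approx([500.0, 500.0])
        assert pruned.total_time_my == pytest.approx(1000.0)

    def test_reference_only_is_single_leaf_zero_time(self, four_taxon_tree):
        col = make_column({"H": "A", "B": GAP, "C": GAP, "D": GAP})
        pruned = prune_to_present(four_taxon_tree, col)
        assert pruned.leaf_labels() == ["H"]
        assert pruned.total_time_my == 0.0

    def test_missing_treated_as_absent(self, four_taxon_tree):
        gap_col = make_column({"H": "A", "B": GAP, "C": "G", "D": GAP})
        n_col = make_column({"H": "A", "B": MISSING, "C": "G", "D": MISSING})
        p1 = prune_to_present(four_taxon_tree, gap_col)
        p2 = prune_to_present(four_taxon_tree, n_col)
        assert p1.to_newick() == p2.to_newick()


class TestFitchCount:
    def test_one_substitution(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": "G", "D": "G"})
        assert count_substitutions_fitch(four_taxon_tree, col) == 1

    def test_no_change_when_identical(self, four_taxon_tree):
        col = make_column({"H": "T", "B": "T", "C": "T", "D": "T"})
        assert count_substitutions_fitch(four_taxon_tree, col) == 0

    def test_incompatible_pattern_needs_two(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "G", "C": "A", "D": "G"})
        assert count_substitutions_fitch(four_taxon_tree, col) == 2

    def test_leaf_without_base_is_contract_violation(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": "G", "D": GAP})
        with pytest.raises(ValueError, match="pruning contract"):
            count_substitutions_fitch(four_taxon_tree, col)

    def test_bounds(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "C", "C": "G", "D": "T"})
        n = count_substitutions_fitch(four_taxon_tree, col)
        assert 4 - 1 <= n <= 4 - 1  # 4 distinct bases on 4 leaves

    def test_exhaustive_oracle_four_leaves(self, four_taxon_tree):
        """Fitch count equals the brute-force minimum for every labeling."""
        for bases in itertools.product("ACGT", repeat=4):
            col = make_column(dict(zip("HBCD", bases)))
            assert count_substitutions_fitch(
                four_taxon_tree, col
            ) == brute_force_parsimony(four_taxon_tree, col)

    def test_oracle_on_random_trees_and_polytomy(self):
        rng = random.Random(42)
        trees = [simulate_time_tree(n, 100.0, seed=s) for n, s in [(5, 1), (6, 2)]]
        # explicit polytomy: ((A,B,C),D,E)
        poly = TimeTree(
            TreeNode(
                children=[
                    TreeNode(
                        branch_length_my=10,
                        children=[
                            TreeNode(label="A", branch_length_my=5),
                            TreeNode(label="B", branch_length_my=5),
                            TreeNode(label="C", branch_length_my=5),
                        ],
                    ),
                    TreeNode(label="D", branch_length_my=15),
                    TreeNode(label="E", branch_length_my=15),
                ]
            )
        )
        trees.append(poly)
        for tree in trees:
            labels = tree.leaf_labels()
            for _ in range(60):
                bases = {l: rng.choice("ACGT") for l in labels}
                col = make_column({**bases, labels[0]: bases[labels[0]]},
                                  ref=labels[0])
                assert count_substitutions_fitch(tree, col) == \
                    brute_force_parsimony(tree, col)


class TestEvolRate:
    def test_definition_on_four_taxon_tree(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": "G", "D": "G"})
        # 1 substitution over 1200 My = 1.2 Gy
        assert evol_rate(four_taxon_tree, col) == pytest.approx(1 / 1.2)

    def test_zero_for_identical_column(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": "A", "D": "A"})
        assert evol_rate(four_taxon_tree, col) == 0.0

    def test_denominator_is_pruned_subtree_time(self, four_taxon_tree):
        col = make_column({"H": "A", "B": GAP, "C": "G", "D": GAP})
        # 1 substitution over the 1000-My H—C path
        assert evol_rate(four_taxon_tree, col) == pytest.approx(1.0)

    def test_reference_only_is_undefined_not_zero(self, four_taxon_tree):
        col = make_column({"H": "A", "B": GAP, "C": GAP, "D": GAP})
        assert evol_rate(four_taxon_tree, col) is None

    def test_rate_ignores_gapped_taxa(self, four_taxon_tree):
        """Rating a gappy column equals rating its pruned subtree directly."""
        col = make_column({"H": "A", "B": "G", "C": GAP, "D": GAP})
        pruned = prune_to_present(four_taxon_tree, col)
        assert evol_rate(four_taxon_tree, col) == pytest.approx(
            count_substitutions_fitch(pruned, col)
            / (pruned.total_time_my / 1000.0)
        )


class TestEvolSpan:
    def test_all_present_fraction_one(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "C", "C": "G", "D": "T"})
        frac, my = evol_span(four_taxon_tree, col)
        assert frac == pytest.approx(1.0)
        assert my == pytest.approx(1200.0)

    def test_sister_pair_fraction(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": GAP, "D": GAP})
        frac, my = evol_span(four_taxon_tree, col)
        assert my == pytest.approx(200.0)
        assert frac == pytest.approx(200 / 1200)

    def test_reference_only_fraction_zero(self, four_taxon_tree):
        col = make_column({"H": "A", "B": GAP, "C": GAP, "D": GAP})
        assert evol_span(four_taxon_tree, col) == (0.0, 0.0)

    def test_removing_a_taxon_never_increases_span(self):
        tree = simulate_time_tree(8, 100.0, seed=7)
        labels = tree.leaf_labels()
        residues = {l: "A" for l in labels}
        prev, _ = evol_span(tree, make_column(residues, ref=labels[0]))
        for drop in labels[1:]:
            residues = {**residues, drop: GAP}
            frac, _ = evol_span(tree, make_column(residues, ref=labels[0]))
            assert 0.0 <= frac <= prev <= 1.0
            prev = frac


class TestClassifyConservation:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (0.0, ULTRA),
            (0.5, WELL),
            (1.0, WELL),
            (1.000001, LESS),
            (2.3, LESS),
        ],
    )
    def test_boundaries(self, rate, expected):
        assert classify_conservation(rate) == expected

    def test_undefined_rate_unclassified(self):
        assert classify_conservation(None) == UNCLASSIFIED

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            classify_conservation(-0.1)


class TestSiteEvolutionBundle:
    def test_consistency_of_fields(self, four_taxon_tree):
        col = make_column({"H": "A", "B": "A", "C": "G", "D": "G"})
        ev = site_evolution(four_taxon_tree, col)
        assert ev.evol_span_fraction == pytest.approx(
            ev.evol_span_my / four_taxon_tree.total_time_my
        )
        assert (ev.evol_rate == 0) == (ev.n_substitutions == 0)
        assert ev.conservation_class == classify_conservation(ev.evol_rate)
        assert ev.n_present_taxa == 4
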