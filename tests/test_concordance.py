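"""Quartet counts, CF tables, bootstrap intervals, consensus trees."""
import itertools

import dendropy
import numpy as np
import pytest

from quartetcf.concordance import (QuartetCFTable, bootstrap_cf, cf_table,
                                   canonical_quartet, majority_consensus,
                                   quartet_counts, quartet_resolution)
from quartetcf.netmodel import expected_cf_quartet_tree
from quartetcf.simulate import (SimulationConfig, aulophallus_network,
                                simulate_gene_trees)
from quartetcf.treeio import GeneTreeSet, leaf_labels, parse_newick

from conftest import trees_from_newicks


QUARTET = ("A", "B", "H", "O")  # canonical order; resolutions AB|HO, AH|BO, AO|BH


class TestQuartetCounts:
    def test_half_half_split(self, half_half_loci):
        qc = quartet_counts(half_half_loci, ("H", "A", "B", "O"))
        assert qc.quartet == QUARTET
        # 4 loci pair H with A (res AH|BO), 4 pair H with B (res AO|BH == BH|AO)
        assert qc.counts.tolist() == [0.0, 4.0, 4.0]
        assert qc.n_resolved == 8 and qc.n_loci == 8

    def test_identical_loci(self):
        gts = GeneTreeSet.from_trees(trees_from_newicks(["((A,B),(H,O));"] * 5))
        qc = quartet_counts(gts, QUARTET)
        assert qc.counts.tolist() == [5.0, 0.0, 0.0]

    def test_posterior_sample_fractional_counts(self):
        def sample(freqs):
            newicks = (["((A,B),(H,O));"] * freqs[0]
                       + ["((A,H),(B,O));"] * freqs[1]
                       + ["((A,O),(B,H));"] * freqs[2])
            return trees_from_newicks(newicks)

        gts = GeneTreeSet([
            ("L1", sample((9, 1, 0))),
            ("L2", sample((5, 5, 0))),
            ("L3", sample((10, 0, 0))),
        ])
        qc = quartet_counts(gts, QUARTET)
        assert qc.counts == pytest.approx([2.4, 0.6, 0.0])
        assert qc.n_resolved == 3

    def test_missing_taxon_locus_counted_in_n_loci_only(self):
        trees = trees_from_newicks(["((A,B),(H,O));", "((A,B),C);"])
        gts = GeneTreeSet.from_trees(trees)
        qc = quartet_counts(gts, QUARTET)
        assert qc.n_loci == 2 and qc.n_resolved == 1

    def test_unresolved_excluded_or_split(self):
        trees = trees_from_newicks(["(A,B,H,O);", "((A,B),(H,O));"])
        gts = GeneTreeSet.from_trees(trees)
        assert quartet_counts(gts, QUARTET).n_resolved == 1
        qc = quartet_counts(gts, QUARTET, unresolved="split")
        assert qc.n_resolved == 2
        assert qc.counts == pytest.approx([4.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0])

    def test_errors(self, half_half_loci):
        with pytest.raises(ValueError, match="duplicate"):
            quartet_counts(half_half_loci, ("A", "A", "B", "O"))
        with pytest.raises(ValueError, match="absent"):
            quartet_counts(half_half_loci, ("A", "B", "H", "ZZZ"))


class TestCFTable:
    def test_normalization(self, half_half_loci):
        tab = cf_table(half_half_loci, [QUARTET])
        cf, n_eff = tab.row(QUARTET)
        assert cf == pytest.approx([0.0, 0.5, 0.5])
        assert n_eff == 8

    def test_all_quartets_on_six_taxa(self):
        gts = GeneTreeSet.from_trees(
            trees_from_newicks(["(((A,B),(C,D)),(E,F));"] * 3))
        tab = cf_table(gts, "all")
        assert len(tab) == 15  # C(6,4)
        assert np.allclose(tab.cf.sum(axis=1), 1.0)

    def test_canonicalization_is_label_order_invariant(self, half_half_loci):
        for perm in itertools.permutations(QUARTET):
            tab = cf_table(half_half_loci, [perm])
            cf, _ = tab.row(QUARTET)
            assert cf == pytest.approx([0.0, 0.5, 0.5])

    def test_csv_round_trip(self, half_half_loci, tmp_path):
        tab = cf_table(half_half_loci, "all")
        path = tmp_path / "cf.csv"
        tab.to_csv(path)
        again = QuartetCFTable.from_csv(path)
        assert again.quartets == tab.quartets
        assert np.allclose(again.cf, tab.cf)
        header = path.read_text().splitlines()[0]
        assert header == "taxon1,taxon2,taxon3,taxon4,CF12_34,CF13_24,CF14_23,ngenes"

    def test_simulated_cfs_match_closed_form(self):
        # species-tree quartet with internal branch t = 1
        net = aulophallus_network(1.0, 1.0, 8.0)
        gts = simulate_gene_trees(SimulationConfig(net, 4000, seed=42))
        cf, n = cf_table(gts, [QUARTET]).row(QUARTET)
        expect = expected_cf_quartet_tree(1.0)
        se = np.sqrt(expect * (1 - expect) / n)
        # resolution AH|BO is the major one (gamma = 1 keeps H with A)
        assert abs(cf[1] - expect[0]) < 3 * se[0]
        assert cf[1] >= max(cf[0], cf[2])  # major CF dominates in expectation


class TestBootstrap:
    def test_identical_loci_degenerate(self):
        gts = GeneTreeSet.from_trees(trees_from_newicks(["((A,B),(H,O));"] * 6))
        ivs = bootstrap_cf(gts, QUARTET, n_boot=200, seed=1)
        assert ivs[0] == (1.0, 1.0)
        assert ivs[1] == (0.0, 0.0) and ivs[2] == (0.0, 0.0)

    def test_unseen_category_never_appears(self, half_half_loci):
        ivs = bootstrap_cf(half_half_loci, QUARTET, n_boot=2000, seed=3)
        assert ivs[0][1] == 0.0  # AB|HO never observed -> upper bound 0

    def test_deterministic_given_seed(self, half_half_loci):
        a = bootstrap_cf(half_half_loci, QUARTET, n_boot=100, seed=5)
        b = bootstrap_cf(half_half_loci, QUARTET, n_boot=100, seed=5)
        assert a == b

    def test_widths_shrink_with_more_loci(self):
        net = aulophallus_network(0.5, 1.0, 1.0)
        widths = {}
        for n_loci in (8, 32):
            gts = simulate_gene_trees(SimulationConfig(net, n_loci, seed=17))
            ivs = bootstrap_cf(gts, QUARTET, n_boot=600, seed=23)
            widths[n_loci] = np.mean([hi - lo for lo, hi in ivs])
        assert widths[32] < widths[8]

    def test_single_locus_warns(self):
        gts = GeneTreeSet.from_trees(trees_from_newicks(["((A,B),(H,O));"]))
        with pytest.warns(UserWarning, match="one locus"):
            bootstrap_cf(gts, QUARTET, n_boot=10, seed=0)


def _nontrivial_splits(tree):
    labs = sorted(leaf_labels(tree))
    n = len(labs)
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        s = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(s) <= n - 2:
            out.add(min(s, frozenset(labs) - s, key=sorted))
    return out


class TestMajorityConsensus:
    def test_identical_trees_any_threshold(self):
        trees = trees_from_newicks(["(((A,B),C),(D,E));"] * 4)
        for th in (0.51, 0.85, 1.0):
            cons = majority_consensus(trees, th)
            assert _nontrivial_splits(cons) == _nontrivial_splits(trees[0])

    def test_75pct_clade_vs_85pct_threshold(self):
        trees = trees_from_newicks(
            ["((A,B),(C,(D,E)));"] * 6 + ["((A,C),(B,(D,E)));"] * 2)
        ab = frozenset({"A", "B"})
        assert ab in _nontrivial_splits(majority_consensus(trees, 0.6))
        assert ab in _nontrivial_splits(majority_consensus(trees, 0.75))  # tie kept
        assert ab not in _nontrivial_splits(majority_consensus(trees, 0.85))

    def test_even_conflict_collapses(self):
        trees = trees_from_newicks(
            ["((A,B),(C,D));"] * 4 + ["((A,C),(B,D));"] * 4)
        cons = majority_consensus(trees, 0.51)
        assert _nontrivial_splits(cons) == set()

    def test_threshold_one_equals_strict_consensus_oracle(self):
        trees = trees_from_newicks([
            "(((A,B),C),((D,E),F));",
            "(((A,B),D),((C,E),F));",
            "(((A,B),E),((C,D),F));",
        ])
        strict = set.intersection(*(set(_nontrivial_splits(t)) for t in trees))
        assert _nontrivial_splits(majority_consensus(trees, 1.0)) == strict

    def test_mixed_leaf_sets_error_lists_difference(self):
        trees = trees_from_newicks(["((A,B),(C,D));", "((A,B),(C,E));"])
        with pytest.raises(ValueError, match="'D', 'E'"):
            majority_consensus(trees, 0.6)

    def test_threshold_bounds(self):
        trees = trees_from_newicks(["((A,B),(C,D));"])
        for bad in (0.5, 0.0, 1.2):
            with pytest.raises(ValueError):
                majority_consensus(trees, bad)
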