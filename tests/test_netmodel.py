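"""Expected CFs, pseudolikelihood, AIC, optimization, edge editing, geography."""
import math

import numpy as np
import pytest

from quartetcf.concordance import QuartetCFTable, cf_table
from quartetcf.netmodel import (add_hybrid_edge, aic, expected_cf_network,
                                expected_cf_quartet_tree, expected_cf_table,
                                fit_r2, flag_geography, optimize_params,
                                pseudolik, remove_hybrid_edge,
                                search_hybrid_edges)
from quartetcf.simulate import (SimulationConfig, aulophallus_network,
                                backbone_network, backbone_tree,
                                simulate_gene_trees)
from quartetcf.treeio import ApproximationWarning, parse_extended_newick

QUARTET = ("A", "B", "H", "O")


def topology_signature(net):
    """Weighted multiset of displayed-tree split sets (topology-only)."""
    sig = []
    for tree, w in net.displayed_trees():
        labs = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        splits = set()
        for node in tree.postorder_node_iter():
            if node.is_leaf() or node is tree.seed_node:
                continue
            s = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(s) <= len(labs) - 2:
                splits.add(min(s, frozenset(labs) - s, key=sorted))
        sig.append((round(w, 9), frozenset(splits)))
    return sorted(sig, key=repr)


class TestExpectedCFTree:
    @pytest.mark.parametrize("t,major", [
        (0.0, 1.0 / 3.0),
        (1.0, 1.0 - 2.0 / 3.0 * math.exp(-1)),
        (math.inf, 1.0),
    ])
    def test_closed_form(self, t, major):
        cf = expected_cf_quartet_tree(t)
        assert cf[0] == pytest.approx(major)
        assert cf[1] == cf[2] == pytest.approx((1 - major) / 2)
        assert cf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_t_one_printed_values(self):
        assert expected_cf_quartet_tree(1.0) == pytest.approx(
            [0.754747, 0.122626, 0.122626], abs=5e-7)

    def test_negative_t_error(self):
        with pytest.raises(ValueError):
            expected_cf_quartet_tree(-0.1)


class TestExpectedCFNetwork:
    def test_symmetric_hybrid_long_branches(self):
        net = aulophallus_network(0.5, 30.0, 30.0)
        cf = expected_cf_network(net, QUARTET)
        # AB|HO ~ 0; AH|BO = AO|BH = 0.5
        assert cf == pytest.approx([0.0, 0.5, 0.5], abs=1e-9)

    def test_gamma_one_reduces_to_tree_formula(self):
        net = aulophallus_network(1.0, 0.7, 3.0)
        cf = expected_cf_network(net, QUARTET)
        tree_cf = expected_cf_quartet_tree(0.7)
        assert cf[1] == pytest.approx(tree_cf[0])
        assert sorted(cf) == pytest.approx(sorted(tree_cf))

    def test_mixture_hand_arithmetic(self):
        # gamma = 0.3 toward A, internal lengths 0.5 / 1.0:
        # 0.3 * CF(t=0.5) + 0.7 * CF(t=1.0) component-wise by resolution
        net = aulophallus_network(0.3, 0.5, 1.0)
        cf = expected_cf_network(net, QUARTET)
        assert cf == pytest.approx([0.14649, 0.26453, 0.58898], abs=5e-6)

    def test_rows_sum_to_one_and_gamma_bounds_reduce(self):
        for gamma in (0.0, 0.25, 1.0):
            net = aulophallus_network(gamma, 0.8, 1.7)
            cf = expected_cf_network(net, QUARTET)
            assert cf.sum() == pytest.approx(1.0, abs=1e-12)
        tab = expected_cf_table(backbone_network(0.3), "all")
        assert np.allclose(tab.cf.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_simulator_frequencies(self):
        net = backbone_network(0.3)
        gts = simulate_gene_trees(SimulationConfig(net, 8000, seed=101))
        obs = cf_table(gts, "all")
        model = expected_cf_table(net, "all")
        se = np.sqrt(np.maximum(model.cf * (1 - model.cf), 1e-12) / 8000)
        z = np.abs(obs.cf - model.cf) / np.maximum(se, 1e-9)
        # 45 cells; allow the usual multiple-comparison slack
        assert np.max(z) < 4.5

    def test_exactness_warning_when_hybrid_subtends_two(self):
        # hybrid ancestor of a 2-leaf clade within the quartet
        text = ("((((X,Y))#H1:::0.6,A),(#H1:::0.4,B),O);")
        net = parse_extended_newick(text)
        with pytest.warns(ApproximationWarning):
            expected_cf_network(net, ("X", "Y", "A", "B"))

    def test_unknown_taxon_error(self):
        net = aulophallus_network(0.5, 1.0, 1.0)
        with pytest.raises(ValueError, match="absent"):
            expected_cf_network(net, ("A", "B", "H", "Z"))


class TestScoring:
    def test_pseudolik_hand_value(self):
        # one quartet, n_eff = 8, obs = model = (0.5, 0.5, 0)
        net = aulophallus_network(0.5, 30.0, 30.0)
        tab = QuartetCFTable([QUARTET], np.array([[0.0, 0.5, 0.5]]), np.array([8.0]))
        assert pseudolik(net, tab) == pytest.approx(8 * math.log(0.5), abs=1e-6)

    def test_gibbs_inequality(self):
        net = aulophallus_network(0.3, 0.5, 1.0)
        model = expected_cf_table(net, "all", n_eff=np.ones(1) * 8)
        best = pseudolik(net, model)
        rng = np.random.default_rng(0)
        for _ in range(20):
            other = aulophallus_network(rng.uniform(0, 1), rng.uniform(0, 3),
                                        rng.uniform(0, 3))
            assert pseudolik(other, model) <= best + 1e-9

    def test_linearity_in_n_eff(self):
        net = aulophallus_network(0.4, 1.0, 1.0)
        tab1 = expected_cf_table(net, "all", n_eff=np.full(1, 8.0))
        tab2 = QuartetCFTable(tab1.quartets, tab1.cf, tab1.n_eff * 2)
        assert pseudolik(net, tab2) == pytest.approx(2 * pseudolik(net, tab1))

    def test_aic_formula(self):
        assert aic(-18390.36, 1) == pytest.approx(36782.72)
        assert aic(0.0, 0) == 0.0
        assert aic(-5.0, 3) - aic(-5.0, 2) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            aic(1.0, -1)

    def test_r2_perfect_fit(self):
        net = backbone_network(0.3)
        tab = expected_cf_table(net, "all", n_eff=np.full(15, 8.0))
        assert fit_r2(tab, net) == pytest.approx(1.0)

    def test_r2_true_tree_beats_wrong_tree(self):
        true = backbone_tree()
        gts = simulate_gene_trees(SimulationConfig(true, 3000, seed=55))
        obs = cf_table(gts, "all")
        wrong = parse_extended_newick(
            "(O:3,((A:1,E:1):1,(B:1.5,(C:1,D:1):0.5):1):1);")
        assert fit_r2(obs, true) > fit_r2(obs, wrong)

    def test_r2_constant_obs_undefined(self):
        net = aulophallus_network(0.5, 0.0, 0.0)
        tab = QuartetCFTable([QUARTET], np.full((1, 3), 1 / 3), np.array([8.0]))
        with pytest.raises(ValueError, match="constant"):
            fit_r2(tab, net)


class TestOptimize:
    def test_parameter_recovery_from_analytic_cfs(self):
        true = aulophallus_network(0.3, 0.5, 1.0)
        tab = expected_cf_table(true, "all", n_eff=np.full(1, 1000.0))
        fit = optimize_params(true, tab, seed=1)
        net = fit.network
        h = net.hybrid_nodes[0]
        gamma_a = min(e.gamma for e in net.parent_edges[h])
        assert abs(gamma_a - 0.3) < 0.02
        lengths = sorted(net.edges[i].length for i in (2, 3))
        assert abs(lengths[0] - 0.5) < 0.05 and abs(lengths[1] - 1.0) < 0.05
        assert fit.aic == pytest.approx(-2 * fit.pseudolik + 2 * fit.k, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_start_at_optimum_stays(self):
        net = aulophallus_network(0.4, 0.8, 1.2)
        tab = expected_cf_table(net, "all", n_eff=np.full(1, 500.0))
        fit = optimize_params(net, tab, seed=2, n_starts=1)
        assert fit.pseudolik == pytest.approx(pseudolik(net, tab), abs=1e-6)

    def test_tree_cfs_leave_no_reticulation_signal(self):
        # fitting a k = 1 topology to exact tree CFs cannot beat the tree itself
        tree = backbone_tree()
        tab = expected_cf_table(tree, "all", n_eff=np.full(15, 1000.0))
        fit_tree = optimize_params(tree, tab, seed=3)
        fit_net = optimize_params(backbone_network(0.3), tab, seed=3)
        assert fit_net.pseudolik <= fit_tree.pseudolik + 1e-6
        assert fit_net.pseudolik == pytest.approx(fit_tree.pseudolik, abs=1e-3)

    def test_non_identifiable_edges_flagged(self):
        true = aulophallus_network(0.3, 0.5, 1.0)
        tab = expected_cf_table(true, "all", n_eff=np.full(1, 100.0))
        fit = optimize_params(true, tab, seed=4, n_starts=2)
        # the root-side and hybrid edges never sit on a quartet internal path
        assert fit.non_identifiable


class TestEdgeEditing:
    def test_remove_only_hybrid_gives_tree(self):
        net = aulophallus_network(0.3, 0.5, 1.0)
        tree = remove_hybrid_edge(net, "H1")
        assert tree.k == 0
        assert sorted(tree.leaf_labels) == ["A", "B", "H", "O"]

    def test_remove_then_readd_is_isomorphic(self):
        net = backbone_network(0.3)
        pruned = remove_hybrid_edge(net, "H1")
        assert pruned.k == 0
        # re-attach: minor edge from E's pendant edge to D's pendant edge
        by_leaf = {pruned.nodes[e.child]: e.id for e in pruned.edges.values()
                   if not pruned.children_edges[e.child]}
        readded = add_hybrid_edge(pruned, by_leaf["E"], by_leaf["D"], gamma=0.3)
        assert readded.k == 1
        assert topology_signature(readded) == topology_signature(net)

    def test_remove_one_of_many_keeps_other_gammas(self, k3_network_text):
        net = parse_extended_newick(k3_network_text)
        assert net.k == 3
        out = remove_hybrid_edge(net, "H2")
        assert out.k == 2
        gammas = sorted(out.major_edge(h).gamma for h in out.hybrid_nodes)
        assert gammas == pytest.approx([0.6, 0.7])

    def test_unknown_id_error(self):
        net = aulophallus_network(0.3, 0.5, 1.0)
        with pytest.raises(KeyError):
            remove_hybrid_edge(net, "H9")

    def test_add_rejects_cycle_breaking_attachments(self):
        tree = backbone_tree()
        with pytest.raises(ValueError):
            add_hybrid_edge(tree, 3, 3)


class TestSearch:
    def test_hmax_zero_single_fit(self):
        tree = backbone_tree()
        tab = expected_cf_table(tree, "all", n_eff=np.full(15, 100.0))
        fits = search_hybrid_edges(tree, tab, hmax=0, seed=0)
        assert len(fits) == 1 and fits[0].k == 0

    def test_recovers_planted_edge_from_analytic_cfs(self):
        true = backbone_network(0.3)
        tab = expected_cf_table(true, "all", n_eff=np.full(15, 10000.0))
        fits = search_hybrid_edges(backbone_tree(), tab, hmax=1, seed=0)
        assert [f.k for f in fits] == [0, 1]
        assert fits[1].aic < fits[0].aic  # reticulation preferred
        # the recovered minor displayed tree groups D with E, as planted
        best = fits[1].network
        assert topology_signature(best) == topology_signature(
            backbone_network(min(e.gamma for e in
                                 best.parent_edges[best.hybrid_nodes[0]])))

    def test_refuses_too_many_taxa(self):
        text = "(" + ",".join(f"T{i}" for i in range(12)) + ");"
        net = parse_extended_newick(text)
        tab = expected_cf_table(backbone_tree(), "all", n_eff=np.full(15, 8.0))
        with pytest.raises(ValueError, match="desk-scale"):
            search_hybrid_edges(net, tab, hmax=1, seed=0)


class TestGeography:
    def test_disjoint_regions_flagged(self):
        net = aulophallus_network(0.3, 0.5, 1.0)
        regions = {"H": {"CentralAmerica"}, "A": {"CentralAmerica"},
                   "B": {"NorthOfTMVB"}, "O": {"NorthOfTMVB"}}
        # minor edge donor side is A's lineage: Central America vs ... recipient
        # clade {H} is Central America too -> overlapping, not flagged
        assert flag_geography(net, regions) == []
        regions_far = {"H": {"NorthOfTMVB"}, "A": {"CentralAmerica"},
                       "B": {"SouthOfTMVB"}, "O": {"SouthOfTMVB"}}
        assert flag_geography(net, regions_far) == ["H1"]

    def test_overlapping_union_not_flagged(self):
        net = backbone_network(0.3)
        regions = {lab: {"shared"} for lab in net.leaf_labels}
        assert flag_geography(net, regions) == []

    def test_missing_assignment_names_taxa(self):
        net = backbone_network(0.3)
        regions = {lab: {"r"} for lab in net.leaf_labels if lab != "D"}
        with pytest.raises(ValueError, match="D"):
            flag_geography(net, regions)
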