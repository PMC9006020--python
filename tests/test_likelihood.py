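"""Pruning engine, optimizers, site rates and tree search.

The pruning likelihood is checked against (a) brute-force enumeration of
internal-state assignments with Pade-expm transition matrices and (b)
frozen log-likelihoods computed independently with R/phangorn's pml on the
same fixed alignment, tree and model.
"""

import math

import numpy as np
import pytest

from phylodissect import build_model
from phylodissect.likelihood import (
    LikelihoodError,
    SearchSettings,
    TreeLikelihood,
    estimate_site_rates,
    ml_distance_matrix,
    ml_tree_search,
    nj_tree,
    optimize_branch_lengths,
    optimize_parameters,
    site_log_likelihoods,
)
from phylodissect.simulate import simulate_alignment
from phylodissect.supermatrix import GeneAlignment
from phylodissect.treeops import PhyloTree, robinson_foulds

from oracles import all_unrooted_topologies, brute_force_site_lnl

# fixed 5-taxon fixture; phangorn pml reference values were computed on
# exactly these sequences, this tree, and LG with the stated gamma settings
PHANGORN_TREE = "((A:0.2,B:0.3):0.15,C:0.25,(D:0.1,E:0.4):0.3);"
PHANGORN_ROWS = {
    "A": "IQADFDGASNQSLTKMRFLTAKAGENSGVLKKMVLCGRVGMEVMQIVYLNDYMDPKLGGC",
    "B": "FEAEFDGASNQTITKVRSLTGKSGENSGVLKKIHAVGRVDMETMSRVYLNDYLDMKMGGC",
    "C": "LQAGFENASNQSITKPRLLTDKAGETTGVLKKMHFCGRIEMETMRTVYLNEYLDTRISGC",
    "D": "RHADFEPASNKSLTKPRLLTGKAGANSGVLRKMDNCGRVDMEKMSTVYLNDYLDDRGGGT",
    "E": "RHAEFTAASNKTPTKPRLLTGKAGANSGVLKKMDTAARVDMERMRTLYLNDYLDPAGSGR",
}
PHANGORN_LNL_G4 = -485.1663414597  # LG, k=4, alpha=0.6
PHANGORN_LNL_K1 = -499.3823398684  # LG, k=1


@pytest.fixture(scope="module")
def phangorn_fixture():
    aln = GeneAlignment(
        "xcheck", list(PHANGORN_ROWS), [PHANGORN_ROWS[t] for t in PHANGORN_ROWS]
    )
    return aln, PhyloTree.from_newick(PHANGORN_TREE)


class TestSiteLogLikelihoods:
    def test_matches_phangorn_reference(self, phangorn_fixture):
        aln, tree = phangorn_fixture
        _, total_g4 = site_log_likelihoods(aln, tree, build_model("LG", k=4, alpha=0.6))
        _, total_k1 = site_log_likelihoods(aln, tree, build_model("LG", k=1))
        assert total_g4 == pytest.approx(PHANGORN_LNL_G4, abs=1e-6)
        assert total_k1 == pytest.approx(PHANGORN_LNL_K1, abs=1e-6)

    def test_matches_brute_force_with_missing_data(self, tree5):
        aln = GeneAlignment(
            "t", ["A", "B", "C", "D", "E"],
            ["ARN-C", "RRQXW", "AANDC", "YRNDC", "ARKDC"],
        )
        model = build_model("LG", k=4, alpha=0.6)
        sites, total = site_log_likelihoods(aln, tree5, model)
        oracle = brute_force_site_lnl(aln, tree5, model)
        assert np.allclose(sites, oracle, rtol=1e-8)
        assert total == pytest.approx(oracle.sum(), rel=1e-10)

    def test_two_taxa_zero_branch_identity(self):
        aln = GeneAlignment("t", ["A", "B"], ["A", "A"])
        tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
        _, total = site_log_likelihoods(aln, tree, build_model("Poisson", k=1))
        assert total == pytest.approx(math.log(1 / 20), abs=1e-12)

    def test_all_missing_column_contributes_zero(self, tree5):
        aln = GeneAlignment(
            "t", ["A", "B", "C", "D", "E"], ["-A", "-R", "XN", "?D", "*C"]
        )
        sites, _ = site_log_likelihoods(aln, tree5, build_model("LG", k=4, alpha=1.0))
        assert sites[0] == pytest.approx(0.0, abs=1e-12)

    def test_site_sum_equals_total(self, aln6, tree6, lg_g4):
        sites, total = site_log_likelihoods(aln6, tree6, lg_g4)
        assert total == float(sites.sum())

    def test_invariant_to_newick_rerooting(self, phangorn_fixture):
        aln, _ = phangorn_fixture
        model = build_model("LG", k=4, alpha=0.6)
        # the same unrooted tree written with three different rootings
        variants = [
            PHANGORN_TREE,
            "(C:0.25,(A:0.2,B:0.3):0.15,(D:0.1,E:0.4):0.3);",
            "((D:0.1,E:0.4):0.3,C:0.25,(B:0.3,A:0.2):0.15);",
            "(D:0.1,(C:0.25,(A:0.2,B:0.3):0.15):0.3,E:0.4);",
        ]
        totals = [
            site_log_likelihoods(aln, PhyloTree.from_newick(v), model)[1]
            for v in variants
        ]
        assert np.allclose(totals, totals[0], atol=1e-9)

    def test_leaf_without_row_is_an_error(self, tree5):
        aln = GeneAlignment("t", ["A", "B", "C", "D"], ["AR", "RR", "AA", "YR"])
        with pytest.raises(LikelihoodError, match="E"):
            site_log_likelihoods(aln, tree5, build_model("Poisson", k=1))


class TestBranchOptimization:
    def test_two_taxon_distance_matches_grid_oracle(self):
        model = build_model("LG", k=4, alpha=0.8)
        tree = PhyloTree.from_newick("(A:0.3,B:0.3);")
        aln, _ = simulate_alignment(tree, model, 3000, seed=5)
        fitted, _ = optimize_branch_lengths(aln, tree, model)
        (u, v) = fitted.edges()[0]
        t_hat = fitted.adj[u][v]
        # dense grid + golden refinement on the same likelihood surface
        grid = np.linspace(1e-6, 3.0, 2000)
        vals = []
        probe = tree.copy()
        (a, b) = probe.edges()[0]
        for t in grid:
            probe.set_length(a, b, t)
            vals.append(site_log_likelihoods(aln, probe, model)[1])
        t_grid = grid[int(np.argmax(vals))]
        assert t_hat == pytest.approx(t_grid, abs=2e-3)

    def test_identical_sequences_hit_lower_bound(self):
        aln = GeneAlignment("t", ["A", "B", "C", "D"], ["ARND"] * 4)
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        fitted, _ = optimize_branch_lengths(aln, tree, build_model("LG", k=1))
        for u, v in fitted.edges():
            assert fitted.adj[u][v] <= 1e-6

    def test_ascent_property(self, aln6, tree6, lg_g4):
        start = tree6.copy()
        for u, v in start.edges():
            start.set_length(u, v, 0.5)  # deliberately wrong lengths
        _, before = site_log_likelihoods(aln6, start, lg_g4)
        _, after = optimize_branch_lengths(aln6, start, lg_g4)
        assert after >= before


class TestParameterOptimization:
    def test_alpha_recovery_small(self, tree6):
        model = build_model("LG", k=4, alpha=0.8)
        aln, _ = simulate_alignment(tree6, model, 3000, seed=11)
        fitted_model, _, _ = optimize_parameters(
            aln, tree6, build_model("LG", k=4, alpha=2.0)
        )
        assert 0.55 <= fitted_model.alpha <= 1.1

    def test_k1_fits_branches_only(self, aln6, tree6):
        model = build_model("LG", k=1)
        fitted_model, _, lnl = optimize_parameters(aln6, tree6, model)
        assert fitted_model.k == 1
        assert np.isfinite(lnl)


@pytest.fixture(scope="module")
def rate_fixture(tree6):
    model = build_model("LG", k=4, alpha=0.5)
    aln, truth = simulate_alignment(tree6, model, 1500, seed=19)
    rates = estimate_site_rates(aln, tree6, model)
    return aln, truth, rates


class TestSiteRates:
    def test_identical_columns_get_identical_rates(self, tree6):
        aln = GeneAlignment(
            "t", ["A", "B", "C", "D", "E", "F"],
            ["AAR", "AAR", "RAN", "RAN", "AAD", "AAD"],
        )
        rates = estimate_site_rates(aln, tree6, build_model("LG", k=4, alpha=0.7))
        # columns 0 and 1: different letters but col1/col2? craft identical pair
        aln2 = GeneAlignment(
            "t", ["A", "B", "C", "D", "E", "F"],
            ["AA", "AA", "RR", "RR", "AA", "DD"],
        )
        r2 = estimate_site_rates(aln2, tree6, build_model("LG", k=4, alpha=0.7))
        assert r2.rates[0] == pytest.approx(r2.rates[1], rel=1e-12)

    def test_constant_column_slower_than_variable(self, tree6):
        aln = GeneAlignment(
            "t", ["A", "B", "C", "D", "E", "F"],
            ["AR", "AN", "AD", "AC", "AQ", "AE"],
        )
        rates = estimate_site_rates(aln, tree6, build_model("LG", k=4, alpha=0.7))
        assert rates.rates[0] < rates.rates[1]

    def test_rate_correlates_with_truth(self, rate_fixture):
        _, truth, rates = rate_fixture
        corr = np.corrcoef(rates.rates, truth.site_rates)[0, 1]
        assert corr > 0.6

    def test_mean_rate_bounded(self, rate_fixture, tree6):
        _, _, rates = rate_fixture
        model = build_model("LG", k=4, alpha=0.5)
        assert 0 < rates.rates.mean() <= model.rates.max()

    def test_ranking_ties_break_by_column_index(self):
        from phylodissect.likelihood import SiteRateVector

        srv = SiteRateVector(rates=np.array([0.5, 2.0, 0.5, 2.0]))
        assert srv.ranking.tolist() == [1, 3, 0, 2]
        assert srv.removal_indices(0.5).tolist() == [1, 3]
        assert srv.kept_indices(0.5).tolist() == [0, 2]

    def test_k1_rejected(self, aln6, tree6):
        with pytest.raises(LikelihoodError):
            estimate_site_rates(aln6, tree6, build_model("LG", k=1))


class TestTreeSearch:
    def test_four_taxa_picks_best_of_three(self):
        true = PhyloTree.from_newick("((A:0.2,B:0.2):0.3,C:0.2,D:0.2);")
        model = build_model("LG", k=1)
        aln, _ = simulate_alignment(true, model, 800, seed=3)
        found, lnl = ml_tree_search(aln, model)
        best = -np.inf
        for topo in all_unrooted_topologies(["A", "B", "C", "D"]):
            _, cand = optimize_branch_lengths(aln, topo, model)
            best = max(best, cand)
        assert lnl == pytest.approx(best, abs=0.02)
        assert robinson_foulds(found, true) == 0

    def test_six_taxon_recovery(self, tree6):
        model = build_model("LG", k=4, alpha=0.8)
        aln, _ = simulate_alignment(tree6, model, 2000, seed=23)
        found, _ = ml_tree_search(aln, model, settings=SearchSettings.fast())
        assert robinson_foulds(found, tree6) == 0

    def test_deterministic_given_inputs(self, aln6, lg_g4):
        t1, l1 = ml_tree_search(aln6, lg_g4, settings=SearchSettings.fast())
        t2, l2 = ml_tree_search(aln6, lg_g4, settings=SearchSettings.fast())
        assert t1.to_newick() == t2.to_newick()
        assert l1 == l2

    def test_too_few_taxa_rejected(self):
        aln = GeneAlignment("t", ["A", "B", "C"], ["AR", "RR", "AA"])
        with pytest.raises(LikelihoodError):
            ml_tree_search(aln, build_model("Poisson", k=1))

    def test_spr_mode_recovers_topology(self, tree6, lg_g4):
        from dataclasses import replace

        aln, _ = simulate_alignment(tree6, lg_g4, 1500, seed=29)
        settings = replace(SearchSettings.fast(), spr=True)
        found, _ = ml_tree_search(aln, lg_g4, settings=settings)
        assert robinson_foulds(found, tree6) == 0

    def test_leaf_prune_and_reinsert_round_trip(self, tree6):
        from phylodissect.likelihood import _detach_leaf, _insert_leaf
        from phylodissect.treeops import bipartition_set

        leaf = tree6.node_of("C")
        pruned, pendant, origin = _detach_leaf(tree6, leaf)
        assert sorted(pruned.labels.values()) == ["A", "B", "D", "E", "F"]
        # reinserting on the healed edge restores the original topology
        (u, v) = next(
            (u, v) for u, v in pruned.edges()
            if pruned.side_leaves(u, v) in ({"D"}, frozenset({"D"}))
        )
        back = _insert_leaf(pruned, u, v, "C", pendant)
        assert {b.side for b in bipartition_set(back)} == {
            b.side for b in bipartition_set(tree6)
        }


class TestDistancesAndNJ:
    def test_distance_matrix_symmetric_zero_diagonal(self, aln6, lg_g4):
        dist, taxa = ml_distance_matrix(aln6, lg_g4)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0)
        assert taxa == aln6.taxa

    def test_nj_recovers_clear_topology(self, tree6, lg_g4):
        aln, _ = simulate_alignment(tree6, lg_g4, 3000, seed=31)
        dist, taxa = ml_distance_matrix(aln, lg_g4)
        tree = nj_tree(dist, taxa)
        assert robinson_foulds(tree, tree6) == 0


class TestModelObject:
    def test_fit_summary_roundtrip(self, aln6, tree6):
        res = TreeLikelihood(aln6, "LG+G4+F").fit(
            settings=SearchSettings.fast(), seed=0
        )
        assert robinson_foulds(res.tree, tree6) == 0
        assert res.alpha is not None
        text = res.summary()
        assert "log-likelihood" in text and "LG+G4" in text
        # results expose consistent site-level diagnostics
        sites = res.site_loglikes()
        assert sites.shape == (aln6.length,)
        assert float(sites.sum()) == pytest.approx(res.llf, abs=0.5)

    def test_loglike_requires_tree(self, aln6):
        with pytest.raises(LikelihoodError):
            TreeLikelihood(aln6, "LG+G4").loglike()

    def test_brlens_mode(self, aln6, tree6, lg_g4):
        res = TreeLikelihood(aln6, lg_g4, tree=tree6).fit(search="brlens")
        assert robinson_foulds(res.tree, tree6) == 0
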