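"""BUM fit, tau/score contracts, MWCS search, FDR scan, active modules."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pinmod import module_detection as md
from pinmod import synthetic
from pinmod.benchmark import bum_recovery


def draw_bum(rng, n, lam, a):
    signal = rng.random(n) >= lam
    p = rng.uniform(0, 1, n)
    p[signal] = rng.beta(a, 1.0, int(signal.sum()))
    return np.clip(p, 1e-300, 1.0)


def exhaustive_mwcs(g, scores):
    """Independent oracle: enumerate every connected induced subgraph."""
    best = 0.0
    nodes = list(g.nodes)
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if nx.is_connected(g.subgraph(sub)):
                best = max(best, sum(scores[n] for n in sub))
    return best


class TestFitBum:
    def test_pure_noise_density_near_one(self, rng):
        p = rng.uniform(0, 1, 10_000)
        fit = md.fit_bum(p)
        dens = md.bum_density(0.5, fit.lambda_mix, fit.a_shape)
        assert abs(dens - 1.0) < 0.1

    def test_parameter_recovery(self):
        fits = [bum_recovery(seed, lambda_mix=0.7, a_shape=0.2, n=10_000)
                for seed in range(5)]
        assert abs(np.mean([f.a_shape for f in fits]) - 0.2) < 0.05
        assert abs(np.mean([f.lambda_mix for f in fits]) - 0.7) < 0.1

    def test_likelihood_beats_reference_point(self, rng):
        p = draw_bum(rng, 2000, 0.6, 0.3)
        fit = md.fit_bum(p)
        ref = np.log(md.bum_density(p, 0.5, 0.5)).sum()
        assert fit.log_likelihood >= ref

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            md.fit_bum([0.5] * 100)
        with pytest.raises(ValueError):
            md.fit_bum(np.linspace(0.1, 0.9, 10))


class TestTauThreshold:
    fit = md.BumFit(lambda_mix=0.7, a_shape=0.2, log_likelihood=0.0,
                    n_points=1000)

    def test_monotone_in_fdr(self):
        taus = [md.tau_threshold(self.fit, f) for f in (1e-4, 1e-3, 1e-2)]
        assert taus[0] < taus[1] < taus[2]

    def test_matches_numeric_fdr_inversion(self):
        # oracle: solve  pi_ub * tau / F(tau) = fdr  by root finding
        lam, a = self.fit.lambda_mix, self.fit.a_shape
        pi_ub = lam + (1 - lam) * a

        def fdr_at(tau, target):
            F = lam * tau + (1 - lam) * tau**a
            return pi_ub * tau / F - target

        for fdr in (1e-4, 1e-2):
            oracle = optimize.brentq(fdr_at, 1e-12, 1 - 1e-12, args=(fdr,),
                                     xtol=1e-15)
            assert md.tau_threshold(self.fit, fdr) == pytest.approx(
                oracle, rel=1e-8)

    def test_out_of_range_rejected(self):
        for bad in (0.0, 1.0, -1, 2):
            with pytest.raises(ValueError):
                md.tau_threshold(self.fit, bad)


class TestScoreNodes:
    fit = md.BumFit(lambda_mix=0.7, a_shape=0.2, log_likelihood=0.0,
                    n_points=1000)

    def _net(self, pvals):
        g = nx.path_graph(len(pvals))
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        tab = pd.DataFrame({"gene": sorted(g.nodes),
                            "p_value": pvals,
                            "log_fc": np.zeros(len(pvals))})
        return g, tab

    def test_zero_at_tau_negative_at_one(self):
        tau = md.tau_threshold(self.fit, 0.01)
        g, tab = self._net([tau, 1.0, tau / 10])
        scored = md.score_nodes(g, tab, self.fit, 0.01)
        assert scored.scores["G0"] == pytest.approx(0.0, abs=1e-12)
        assert scored.scores["G1"] < 0
        assert scored.scores["G2"] > 0

    def test_formula_oracle(self, rng):
        pvals = rng.uniform(1e-8, 1, 100)
        g, tab = self._net(pvals)
        scored = md.score_nodes(g, tab, self.fit, 1e-3)
        tau = md.tau_threshold(self.fit, 1e-3)
        for gene, p in zip(sorted(g.nodes), pvals):
            expected = (self.fit.a_shape - 1) * (math.log(p) - math.log(tau))
            assert scored.scores[gene] == pytest.approx(expected, abs=1e-12)

    def test_sign_consistency_with_tau(self, rng):
        pvals = rng.uniform(1e-8, 1, 200)
        g, tab = self._net(pvals)
        scored = md.score_nodes(g, tab, self.fit, 1e-2)
        tau = md.tau_threshold(self.fit, 1e-2)
        for gene, p in zip(sorted(g.nodes), pvals):
            assert np.sign(scored.scores[gene]) == np.sign(tau - p) or (
                abs(p - tau) < 1e-12
            )

    def test_missing_pvalue_gets_negative_score(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        tab = pd.DataFrame({"gene": ["G0"], "p_value": [0.001],
                            "log_fc": [1.0]})
        scored = md.score_nodes(g, tab, self.fit, 0.01)
        assert scored.scores["G2"] < 0


class TestMaxScoringSubnetwork:
    def _scored(self, g, scores):
        return md.ScoredNetwork(network=g, scores=scores, fdr=0.01)

    def test_all_negative_gives_empty_module(self):
        g = nx.path_graph(4)
        m = md.max_scoring_subnetwork(self._scored(g, {n: -1.0 for n in g}))
        assert m.size == 0 and m.aggregate_score == 0.0

    def test_isolated_positive_component(self):
        g = nx.path_graph(5)  # 0-1-2-3-4
        scores = {0: 2.0, 1: 3.0, 2: -10.0, 3: 1.0, 4: -1.0}
        m = md.max_scoring_subnetwork(self._scored(g, scores))
        assert m.genes == frozenset({0, 1})
        assert m.aggregate_score == pytest.approx(5.0)

    def test_profitable_bridge_taken(self):
        g = nx.path_graph(3)
        scores = {0: 2.0, 1: -0.5, 2: 2.0}
        m = md.max_scoring_subnetwork(self._scored(g, scores))
        assert m.genes == frozenset({0, 1, 2})
        assert m.aggregate_score == pytest.approx(3.5)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.55)),
                                seed=int(rng.integers(1 << 30)))
        scores = {v: float(rng.normal(0, 2)) for v in g.nodes}
        m = md.max_scoring_subnetwork(self._scored(g, scores))
        assert m.aggregate_score == pytest.approx(
            exhaustive_mwcs(g, scores), abs=1e-9)

    def test_heuristic_path_on_large_graph_connected(self):
        # large enough to bypass the exact solver
        g = synthetic.generate_scale_free_network(300, 2, seed=0)
        rng = np.random.default_rng(0)
        scores = {v: float(rng.normal(-1, 1.5)) for v in g.nodes}
        m = md.max_scoring_subnetwork(
            md.ScoredNetwork(network=g, scores=scores, fdr=0.01))
        if m.size:
            assert nx.is_connected(g.subgraph(m.genes))
            assert m.aggregate_score == pytest.approx(
                sum(scores[n] for n in m.genes))


class TestFdrScan:
    def _instance(self, seed):
        g = synthetic.generate_scale_free_network(400, 2, seed=seed)
        truth = synthetic.make_truth(g, 15, 0.7, 0.2, seed=seed)
        stats = synthetic.simulate_gene_stats(g, truth, 0.2, 4.0, seed=seed)
        return g, truth, stats

    def test_perfect_recovery_row(self):
        g, truth, stats = self._instance(0)
        # force truth p-values tiny and background large: module exactly
        stats.loc[stats["gene"].isin(truth.module_genes), "p_value"] = 1e-12
        stats.loc[~stats["gene"].isin(truth.module_genes), "p_value"] = \
            np.random.default_rng(0).uniform(0.5, 1.0,
                                             (~stats["gene"].isin(truth.module_genes)).sum())
        scan = md.fdr_scan(g, stats, fdr_grid=(1e-6, 1e-3),
                           truth=set(truth.module_genes))
        best = scan.rows["f1"].max()
        assert best == pytest.approx(1.0)

    def test_module_size_monotone_in_fdr(self):
        for seed in range(10):
            g, truth, stats = self._instance(seed)
            fit = md.fit_bum(stats["p_value"])
            scan = md.fdr_scan(g, stats, fit=fit,
                               fdr_grid=(1e-8, 1e-5, 1e-3, 1e-2, 0.05))
            sizes = scan.rows.sort_values("fdr")["module_size"].to_numpy()
            assert (np.diff(sizes) >= 0).all()

    def test_size_band_selection_without_truth(self):
        g, truth, stats = self._instance(3)
        # sharpen the signal so the module is recoverable at loose FDRs
        in_mod = stats["gene"].isin(truth.module_genes)
        stats.loc[in_mod, "p_value"] = 1e-12
        stats.loc[~in_mod, "p_value"] = np.random.default_rng(3).uniform(
            0.5, 1.0, (~in_mod).sum())
        scan = md.fdr_scan(g, stats, fdr_grid=(1e-6, 1e-3, 0.05),
                           size_band=(5, 100))
        # smallest FDR whose module lands in the band is selected
        sizes = dict(zip(scan.rows["fdr"], scan.rows["module_size"]))
        in_band = [f for f, s in sizes.items() if 5 <= s <= 100]
        assert in_band and scan.fdr == min(in_band)
        assert 5 <= scan.module.size <= 100
        # with an unattainable band the size closest to its midpoint wins
        tight = md.fdr_scan(g, stats, fdr_grid=(1e-6, 1e-3, 0.05),
                            size_band=(1, 2))
        assert tight.module.size == min(
            sizes.values(), key=lambda s: abs(s - 1.5))

    def test_empty_grid_rejected(self):
        g, truth, stats = self._instance(1)
        with pytest.raises(ValueError):
            md.fdr_scan(g, stats, fdr_grid=())


class TestActiveModules:
    def test_null_scores_small(self):
        g = synthetic.generate_scale_free_network(150, 2, seed=0)
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stats = pd.DataFrame({
                "gene": sorted(g.nodes),
                "p_value": np.full(g.number_of_nodes(),
                                   rng.uniform(0.3, 0.7)),
                "log_fc": np.zeros(g.number_of_nodes()),
            })
            mods = md.active_modules(g, stats, n_modules=2, seed=seed)
            for m in mods:
                worst = max(worst, abs(m.calibrated_score))
        assert worst < 3.0

    def test_planted_clique_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(80, 0.05, seed=seed)
            clique = list(range(80, 86))
            g.add_edges_from((a, b) for i, a in enumerate(clique)
                             for b in clique[i + 1:])
            g.add_edge(0, clique[0])
            g = nx.relabel_nodes(g, {i: f"G{i:03d}" for i in g.nodes})
            clique_names = {f"G{i:03d}" for i in clique}
            p = rng.uniform(0.2, 1.0, g.number_of_nodes())
            stats = pd.DataFrame({"gene": sorted(g.nodes), "p_value": p,
                                  "log_fc": np.zeros(len(p))})
            stats.loc[stats["gene"].isin(clique_names), "p_value"] = 1e-6
            mods = md.active_modules(g, stats, n_modules=1, max_depth=2,
                                     seed=seed)
            if mods and len(mods[0].genes & clique_names) >= 0.8 * len(clique_names):
                hits += 1
        assert hits >= 16

    def test_zero_overlap_modules_disjoint(self, small_scenario):
        from pinmod.diffexpr import de_test
        stats = de_test(small_scenario.control, small_scenario.treated)
        mods = md.active_modules(small_scenario.network, stats,
                                 n_modules=4, overlap=0.0, seed=1)
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                assert not (a.genes & b.genes)

    def test_deterministic_under_seed(self, small_scenario):
        from pinmod.diffexpr import de_test
        stats = de_test(small_scenario.control, small_scenario.treated)
        a = md.active_modules(small_scenario.network, stats, seed=7)
        b = md.active_modules(small_scenario.network, stats, seed=7)
        assert [m.genes for m in a] == [m.genes for m in b]
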