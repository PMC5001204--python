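"""Generators: determinism, distributional correctness, planted structure."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from pinmod import synthetic
from pinmod.diffexpr import de_test


def edge_set(g):
    return {tuple(sorted(e)) for e in g.edges}


class TestScaleFreeNetwork:
    def test_m1_yields_tree(self):
        g = synthetic.generate_scale_free_network(5, 1, seed=1)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 4
        assert nx.is_tree(g)

    def test_edge_count_closed_form(self):
        # preferential attachment with m edges per new node: m*(n-m) edges
        g = synthetic.generate_scale_free_network(200, 2, seed=7)
        assert g.number_of_nodes() == 200
        assert g.number_of_edges() == 2 * (200 - 2)

    def test_simple_connected_deterministic(self):
        g1 = synthetic.generate_scale_free_network(120, 3, seed=5)
        g2 = synthetic.generate_scale_free_network(120, 3, seed=5)
        assert edge_set(g1) == edge_set(g2)
        assert nx.is_connected(g1)
        assert nx.number_of_selfloops(g1) == 0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_scale_free_network(3, 3, seed=0)
        with pytest.raises(ValueError):
            synthetic.generate_scale_free_network(10, 0, seed=0)


class TestPlantModule:
    def test_single_node(self):
        g = synthetic.generate_scale_free_network(50, 2, seed=0)
        assert len(synthetic.plant_module(g, 1, seed=0)) == 1

    def test_whole_path_graph(self, path_graph):
        assert synthetic.plant_module(path_graph, 5, seed=3) == set(path_graph)

    def test_connected_induced_subgraph(self):
        g = synthetic.generate_scale_free_network(200, 2, seed=9)
        module = synthetic.plant_module(g, 20, seed=9)
        assert len(module) == 20
        assert nx.is_connected(g.subgraph(module))

    def test_oversized_module_rejected(self, path_graph):
        with pytest.raises(ValueError):
            synthetic.plant_module(path_graph, 6, seed=0)


class TestGeneStats:
    def _setup(self, n=400, size=12, seed=2):
        g = synthetic.generate_scale_free_network(n, 2, seed=seed)
        truth = synthetic.make_truth(g, size, 0.7, 0.2, seed=seed)
        return g, truth

    def test_beta_limit_is_uniform(self):
        # a -> 1 makes the signal component uniform too
        g = synthetic.generate_scale_free_network(10_050, 2, seed=3)
        truth = synthetic.make_truth(g, 10_000, 0.7, 0.2, seed=3)
        stats = synthetic.simulate_gene_stats(g, truth, 1 - 1e-9, 2.0, seed=4)
        module_p = stats.loc[stats["gene"].isin(truth.module_genes), "p_value"]
        ks = sps.kstest(module_p, "uniform").statistic
        assert ks < 1.36 / np.sqrt(len(module_p))  # 5% critical value

    def test_module_pvalue_mean_matches_beta_moment(self):
        a = 0.2
        g = synthetic.generate_scale_free_network(10_050, 2, seed=5)
        truth = synthetic.make_truth(g, 10_000, 0.7, a, seed=5)
        stats = synthetic.simulate_gene_stats(g, truth, a, 2.0, seed=6)
        mp = stats.loc[stats["gene"].isin(truth.module_genes), "p_value"]
        se = mp.std() / np.sqrt(len(mp))
        assert abs(mp.mean() - a / (1 + a)) < 3 * se

    def test_background_uniform_across_seeds(self):
        # without planted signal, ~95% of seeds should pass a 5% KS test
        g = synthetic.generate_scale_free_network(300, 2, seed=1)
        truth = synthetic.make_truth(g, 1, 0.7, 0.2, seed=1)
        passes = 0
        for s in range(100):
            stats = synthetic.simulate_gene_stats(g, truth, 0.2, 2.0, seed=s)
            bg = stats.loc[~stats["gene"].isin(truth.module_genes), "p_value"]
            passes += sps.kstest(bg, "uniform").pvalue > 0.05
        assert passes >= 90

    def test_signs_follow_truth_and_determinism(self):
        g, truth = self._setup()
        s1 = synthetic.simulate_gene_stats(g, truth, 0.2, 4.0, seed=8)
        s2 = synthetic.simulate_gene_stats(g, truth, 0.2, 4.0, seed=8)
        assert s1.equals(s2)
        mod = s1[s1["gene"].isin(truth.module_genes)]
        for row in mod.itertuples():
            assert np.sign(row.log_fc) == truth.module_signs[row.gene]

    def test_invalid_shape_rejected(self):
        g, truth = self._setup()
        with pytest.raises(ValueError):
            synthetic.simulate_gene_stats(g, truth, 1.5, 2.0, seed=0)


class TestExpressionMatrices:
    def test_null_effect_gives_uniform_de_pvalues(self):
        g = synthetic.generate_scale_free_network(2000, 2, seed=0)
        truth = synthetic.make_truth(g, 50, 0.7, 0.2, seed=0)
        c, t = synthetic.simulate_expression_matrices(
            truth, sorted(g.nodes), n_reps=7, effect_logfc=0.0, seed=1
        )
        stats = de_test(c, t)
        assert sps.kstest(stats["p_value"], "uniform").pvalue > 0.05

    def test_power_at_study_conditions(self):
        # effect 4 at sd 0.5 with n=7 has enormous noncentrality: nearly
        # every module gene should clear p < 0.01
        recovered, total = 0, 0
        for s in range(20):
            g = synthetic.generate_scale_free_network(100, 2, seed=s)
            truth = synthetic.make_truth(g, 20, 0.7, 0.2, seed=s)
            c, t = synthetic.simulate_expression_matrices(
                truth, sorted(g.nodes), n_reps=7, effect_logfc=4.0,
                noise_sd=0.5, seed=s,
            )
            stats = de_test(c, t)
            mod = stats[stats["gene"].isin(truth.module_genes)]
            recovered += (mod["p_value"] < 0.01).sum()
            total += len(mod)
        assert recovered / total > 0.95

    def test_determinism_and_replicate_guard(self):
        g = synthetic.generate_scale_free_network(30, 2, seed=0)
        truth = synthetic.make_truth(g, 5, 0.7, 0.2, seed=0)
        a = synthetic.simulate_expression_matrices(truth, sorted(g.nodes), seed=9)
        b = synthetic.simulate_expression_matrices(truth, sorted(g.nodes), seed=9)
        assert a[0].equals(b[0]) and a[1].equals(b[1])
        with pytest.raises(ValueError):
            synthetic.simulate_expression_matrices(
                truth, sorted(g.nodes), n_reps=1, seed=0
            )


class TestMirnaLayer:
    def _truth(self, seed=0):
        g = synthetic.generate_scale_free_network(200, 2, seed=seed)
        return g, synthetic.make_truth(g, 20, 0.7, 0.2, seed=seed)

    def test_zero_significant_fraction_binomial_bound(self):
        g, truth = self._truth()
        counts = []
        for s in range(50):
            stats, _ = synthetic.simulate_mirna_layer(
                truth, n_mirnas=60, frac_significant=0.0, seed=s,
                gene_universe=sorted(g.nodes),
            )
            counts.append((stats["p_value"] < 0.05).sum())
        mean = np.mean(counts)
        bound = 0.05 * 60 + 3 * np.sqrt(0.05 * 0.95 * 60 / 50)
        assert mean <= bound

    def test_anti_correlation_by_construction(self):
        g, truth = self._truth(seed=4)
        stats, pairs = synthetic.simulate_mirna_layer(
            truth, n_mirnas=30, frac_significant=0.5, seed=4,
            gene_universe=sorted(g.nodes),
        )
        fc = dict(zip(stats["mirna"], stats["fold_change"]))
        for m, targets in truth.mirna_targets.items():
            for gene in targets:
                sign = truth.module_signs[gene]
                assert (fc[m] > 1) == (sign < 0)

    def test_sources_and_determinism(self):
        g, truth = self._truth(seed=6)
        s1, p1 = synthetic.simulate_mirna_layer(truth, 20, seed=6,
                                                gene_universe=sorted(g.nodes))
        s2, p2 = synthetic.simulate_mirna_layer(truth, 20, seed=6,
                                                gene_universe=sorted(g.nodes))
        assert s1.equals(s2) and p1.equals(p2)
        assert p1["sources"].apply(
            lambda s: 1 <= len(s) <= 4 and s <= set(synthetic.SOURCE_DB_NAMES)
        ).all()


class TestPathwaySets:
    def test_enriched_sets_oversample_module(self):
        g = synthetic.generate_scale_free_network(300, 2, seed=2)
        truth = synthetic.make_truth(g, 30, 0.7, 0.2, seed=2)
        coll = synthetic.generate_pathway_sets(
            sorted(g.nodes), truth, n_sets=12, set_size_range=(8, 20),
            enriched_sets=4, seed=2,
        )
        assert len(truth.enriched_pathway_ids) == 4
        for pid in truth.enriched_pathway_ids:
            genes = coll.genes_of(pid)
            assert len(genes & truth.module_genes) >= len(genes) / 2
        assert truth.pathway_membership.keys() == coll.sets.keys()

    def test_exact_module_set_has_point_tail_p(self):
        from scipy.special import comb
        from pinmod.enrichment import PathwayCollection, hypergeometric_enrich

        universe = [f"G{i}" for i in range(20)]
        module = set(universe[:5])
        coll = PathwayCollection(
            sets={"m": ("m", "KEGG", frozenset(module))},
            universe=frozenset(universe),
        )
        rows = hypergeometric_enrich(module, coll)
        assert rows.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5))

    def test_determinism_and_size_guard(self):
        g = synthetic.generate_scale_free_network(60, 2, seed=0)
        truth = synthetic.make_truth(g, 6, 0.7, 0.2, seed=0)
        c1 = synthetic.generate_pathway_sets(sorted(g.nodes), truth, 5, (4, 10), 1, 3)
        truth2 = synthetic.make_truth(g, 6, 0.7, 0.2, seed=0)
        c2 = synthetic.generate_pathway_sets(sorted(g.nodes), truth2, 5, (4, 10), 1, 3)
        assert c1.sets == c2.sets
        with pytest.raises(ValueError):
            synthetic.generate_pathway_sets(sorted(g.nodes), truth, 5, (4, 100), 1, 0)
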