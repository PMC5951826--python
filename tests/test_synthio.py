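"""Synthetic network / p-value / expression / segment generators."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from modseeker import synthio
from modseeker.synthio import SynthConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 1},
            {"network_model": "small-world"},
            {"network_model": "random-uniform-edges", "edge_param": 1.5},
            {"signal_alpha": 1.0},
            {"planted_module_size": 300},
            {"n_replicates_per_group": 1},
            {"gain_fraction": 1.2},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestGenerateNetwork:
    def test_edge_probability_one_gives_complete_graph(self):
        config = SynthConfig(
            n_genes=5, network_model="random-uniform-edges", edge_param=1.0,
            planted_module_size=0,
        )
        graph = synthio.generate_network(config)
        assert graph.number_of_edges() == 10

    def test_edge_probability_zero_gives_no_edges(self):
        config = SynthConfig(
            n_genes=4, network_model="random-uniform-edges", edge_param=0.0,
            planted_module_size=0,
        )
        assert synthio.generate_network(config).number_of_edges() == 0

    def test_edge_count_near_binomial_expectation(self):
        config = SynthConfig(
            n_genes=200, network_model="random-uniform-edges", edge_param=0.05, seed=7
        )
        graph = synthio.generate_network(config)
        n_pairs = 200 * 199 // 2
        expected = 0.05 * n_pairs
        sd = (n_pairs * 0.05 * 0.95) ** 0.5
        assert abs(graph.number_of_edges() - expected) <= 3 * sd

    def test_same_seed_gives_identical_graph(self):
        config = SynthConfig(seed=11)
        g1 = synthio.generate_network(config)
        g2 = synthio.generate_network(config)
        assert set(g1.edges) == set(g2.edges)

    def test_simple_graph_with_stable_ids(self):
        graph = synthio.generate_network(SynthConfig(seed=2))
        assert not any(a == b for a, b in graph.edges)
        assert all(isinstance(v, str) and v.startswith("g") for v in graph.nodes)


class TestPlantModule:
    def test_size_zero_and_one(self, path_graph):
        assert synthio.plant_module(path_graph, 0, seed=1) == set()
        module = synthio.plant_module(path_graph, 1, seed=1)
        assert len(module) == 1

    def test_three_of_four_path_nodes_are_contiguous(self, path_graph):
        valid = {
            frozenset(c)
            for c in itertools.combinations("abcd", 3)
            if nx.is_connected(path_graph.subgraph(c))
        }
        for seed in range(10):
            module = synthio.plant_module(path_graph, 3, seed=seed)
            assert frozenset(module) in valid

    def test_oversized_module_reports_component_size(self, path_graph):
        with pytest.raises(ValueError, match="largest component has 4"):
            synthio.plant_module(path_graph, 5, seed=0)

    def test_planted_module_always_connected(self):
        for seed in range(10):
            config = SynthConfig(seed=seed)
            network = synthio.generate_network(config)
            module = synthio.plant_module(network, 15, seed=seed)
            assert len(module) == 15
            assert nx.is_connected(network.subgraph(module))


class TestGeneratePvalues:
    def test_all_planted_mean_matches_beta_expectation(self):
        config = SynthConfig(
            n_genes=20_000, network_model="random-uniform-edges", edge_param=0.0, seed=5
        )
        network = synthio.generate_network(config)
        pvals = synthio.generate_pvalues(network, set(network.nodes), 0.3, seed=5)
        values = np.array(list(pvals.values()))
        mean_expected = 0.3 / 1.3
        se = values.std() / len(values) ** 0.5
        assert abs(values.mean() - mean_expected) <= 3 * se

    def test_no_planted_gives_uniform_mean(self):
        config = SynthConfig(
            n_genes=20_000, network_model="random-uniform-edges", edge_param=0.0, seed=6
        )
        network = synthio.generate_network(config)
        values = np.array(list(synthio.generate_pvalues(network, set(), 0.5, seed=6).values()))
        se = values.std() / len(values) ** 0.5
        assert abs(values.mean() - 0.5) <= 3 * se

    def test_alpha_near_one_indistinguishable_from_uniform(self):
        config = SynthConfig(
            n_genes=1000, network_model="random-uniform-edges", edge_param=0.0, seed=7
        )
        network = synthio.generate_network(config)
        nodes = sorted(network.nodes)
        planted = set(nodes[:500])
        pvals = synthio.generate_pvalues(network, planted, 0.999, seed=7)
        signal = [pvals[g] for g in nodes[:500]]
        background = [pvals[g] for g in nodes[500:]]
        assert sps.ks_2samp(signal, background).pvalue > 0.05

    def test_planted_gene_outside_network_rejected(self, path_graph):
        with pytest.raises(ValueError, match="absent"):
            synthio.generate_pvalues(path_graph, {"zz"}, 0.3, seed=0)


class TestGenerateExpression:
    def test_planted_shift_recovered_with_many_replicates(self):
        config = SynthConfig(
            n_genes=50,
            network_model="random-uniform-edges",
            edge_param=0.2,
            planted_module_size=10,
            effect_size_log2=2.0,
            noise_sd=0.1,
            n_replicates_per_group=50,
            seed=9,
        )
        network = synthio.generate_network(config)
        planted = synthio.plant_module(network, 10, seed=9)
        expr, groups = synthio.generate_expression(config, planted)
        treated = expr.loc[:, groups == "treated"].mean(axis=1)
        control = expr.loc[:, groups == "control"].mean(axis=1)
        diffs = (treated - control).loc[sorted(planted)]
        assert diffs.between(1.9, 2.1).all()

    def test_null_genes_centred_at_zero(self):
        config = SynthConfig(
            n_genes=1000,
            network_model="random-uniform-edges",
            edge_param=0.0,
            planted_module_size=0,
            effect_size_log2=0.0,
            n_replicates_per_group=30,
            seed=10,
        )
        expr, groups = synthio.generate_expression(config, set())
        diff = expr.loc[:, groups == "treated"].mean(axis=1) - expr.loc[
            :, groups == "control"
        ].mean(axis=1)
        se = config.noise_sd * (2 / 30) ** 0.5
        assert abs(diff.mean()) <= 3 * se / len(expr) ** 0.5


class TestGenerateSegments:
    def test_gain_fraction_one_all_called_gain(self):
        from modseeker import cnastage

        config = SynthConfig(gain_fraction=1.0, gain_mean_shift=1.0, noise_sd=0.01, seed=1)
        segments = synthio.generate_segments(config, n_samples=50)
        labels = cnastage.label_gain(segments)
        assert all(v == "gain" for v in labels.values())

    def test_gain_fraction_zero_no_gain_labels(self):
        from modseeker import cnastage

        config = SynthConfig(gain_fraction=0.0, noise_sd=0.01, seed=2)
        segments = synthio.generate_segments(config, n_samples=50)
        labels = cnastage.label_gain(segments)
        assert sum(v == "gain" for v in labels.values()) == 0

    def test_gain_fraction_recovered_within_three_se(self):
        from modseeker import cnastage

        config = SynthConfig(gain_fraction=0.66, gain_mean_shift=1.0, noise_sd=0.05, seed=3)
        segments = synthio.generate_segments(config, n_samples=500)
        labels = cnastage.label_gain(segments)
        frac = sum(v == "gain" for v in labels.values()) / 500
        se = (0.66 * 0.34 / 500) ** 0.5
        assert abs(frac - 0.66) <= 3 * se

    def test_empty_region_rejected(self):
        config = SynthConfig(seed=4)
        with pytest.raises(ValueError, match="empty region"):
            synthio.generate_segments(config, 10, region=("20", 100, 50))


class TestDeterminism:
    def test_identical_config_serialises_byte_identically(self, tmp_path):
        config = SynthConfig(seed=123)
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        synthio.write_dataset(synthio.generate_dataset(config), a_dir)
        synthio.write_dataset(synthio.generate_dataset(config), b_dir)
        for name in ("expression.tsv", "groups.tsv", "edges.tsv", "pvalues.tsv", "segments.tsv", "truth.json"):
            assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes()

    def test_streams_are_independent(self):
        """P-values do not change when only the expression stage consumes more."""
        config_a = SynthConfig(seed=42, n_replicates_per_group=2)
        config_b = SynthConfig(seed=42, n_replicates_per_group=8)
        net = synthio.generate_network(config_a)
        planted = synthio.plant_module(net, 15, seed=42)
        pa = synthio.generate_pvalues(net, planted, 0.2, seed=42)
        pb = synthio.generate_pvalues(net, planted, 0.2, seed=42)
        assert pa == pb
        ea, _ = synthio.generate_expression(config_a, planted)
        eb, _ = synthio.generate_expression(config_b, planted)
        assert ea.iloc[0, 0] == eb.iloc[0, 0]


class TestMixtureRecoveryFromGenerator:
    def test_fitted_alpha_close_to_generating_alpha(self):
        from modseeker import bumscore

        config = SynthConfig(
            n_genes=10_000,
            network_model="random-uniform-edges",
            edge_param=0.0,
            signal_alpha=0.25,
            seed=21,
        )
        network = synthio.generate_network(config)
        nodes = sorted(network.nodes)
        planted = set(nodes[: len(nodes) // 2])  # known planted fraction 0.5
        pvals = synthio.generate_pvalues(network, planted, 0.25, seed=21)
        fit = bumscore.fit_bum(list(pvals.values()))
        assert abs(fit.alpha - 0.25) < 0.05
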