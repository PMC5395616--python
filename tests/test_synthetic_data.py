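"""Generators: determinism, planted-truth consistency, parameter validation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regionppi.hit_filter import filter_hits
from regionppi.set_comparison import region_enriched_proteins
from regionppi.synthetic_data import (
    SyntheticSpec,
    ba_edge_count,
    gen_abundance_matrix,
    gen_background_graph,
    gen_detection_table,
    gen_gene_sets,
    sample_power_law,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_tg_only=-1), "n_tg_only"),
            (dict(graph_nodes=5, graph_attach=5), "graph_nodes"),
            (dict(planted_alpha=1.0), "planted_alpha"),
            (dict(n_enriched_per_region=-2), "n_enriched_per_region"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SyntheticSpec(**kwargs)


class TestDetectionTable:
    def test_study_composition(self):
        table = gen_detection_table(SyntheticSpec(seed=1))
        assert len(table) == 396
        assert (table.wt_seq_count == 0).sum() == 137

    def test_zero_spec_gives_empty_table(self):
        table = gen_detection_table(
            SyntheticSpec(n_tg_only=0, n_shared_pass=0, n_shared_fail=0)
        )
        assert table.empty

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = SyntheticSpec(n_tg_only=10, n_shared_pass=5, n_shared_fail=5, seed=7)
        a, b = gen_detection_table(spec), gen_detection_table(spec)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(sep="\t") == b.to_csv(sep="\t")

    def test_filter_recovers_planted_classes(self):
        """The real hit filter recovers exactly n_tg_only + n_shared_pass."""
        for seed in (0, 5, 99):
            spec = SyntheticSpec(n_tg_only=40, n_shared_pass=25, n_shared_fail=60, seed=seed)
            table = gen_detection_table(spec)
            result = filter_hits(table)
            assert len(result.hits) == 65
            by_class = table.set_index("protein_id").planted_class
            assert {p for p in result.hits if by_class[p] == "shared_fail"} == set()

    def test_shared_pass_rows_pass_under_both_count_rules(self):
        spec = SyntheticSpec(n_tg_only=0, n_shared_pass=200, n_shared_fail=0, seed=3)
        table = gen_detection_table(spec)
        for rule in ("ratio", "difference"):
            assert len(filter_hits(table, count_rule=rule).hits) == 200

    def test_shared_fail_violates_exactly_one_criterion(self):
        spec = SyntheticSpec(n_tg_only=0, n_shared_pass=0, n_shared_fail=150, seed=4)
        table = gen_detection_table(spec)
        result = filter_hits(table)
        n_single_violation = sum(
            d.criterion_count_ok != d.criterion_intensity_ok for d in result.decisions
        )
        assert n_single_violation == 150


class TestBackgroundGraph:
    def test_edge_count_closed_form(self):
        spec = SyntheticSpec(graph_nodes=1000, graph_attach=5, seed=3)
        g = gen_background_graph(spec)
        assert g.number_of_nodes() == 1000
        assert g.number_of_edges() == ba_edge_count(spec) == 5 * (1000 - 5)

    def test_simple_connected(self):
        g = gen_background_graph(SyntheticSpec(graph_nodes=300, graph_attach=4, seed=1))
        assert nx.is_connected(g)
        assert nx.number_of_selfloops(g) == 0

    def test_two_node_graph_single_edge(self):
        g = gen_background_graph(SyntheticSpec(graph_nodes=2, graph_attach=1))
        assert g.number_of_edges() == 1

    def test_custom_node_names(self):
        names = [f"PROT{i}" for i in range(50)]
        g = gen_background_graph(
            SyntheticSpec(graph_nodes=50, graph_attach=3, seed=2), node_names=names
        )
        assert set(g.nodes) == set(names)
        with pytest.raises(ValueError, match="node_names"):
            gen_background_graph(
                SyntheticSpec(graph_nodes=50, graph_attach=3), node_names=names[:10]
            )

    def test_seed_determinism(self):
        spec = SyntheticSpec(graph_nodes=200, graph_attach=3, seed=8)
        assert sorted(gen_background_graph(spec).edges) == sorted(gen_background_graph(spec).edges)


class TestAbundanceMatrix:
    def test_round_trip_recovery(self):
        spec = SyntheticSpec(n_proteins=200, n_regions=3, n_enriched_per_region=10, seed=6)
        matrix, planted = gen_abundance_matrix(spec)
        assert region_enriched_proteins(matrix) == planted
        assert all(len(s) == 10 for s in planted.values())

    def test_planted_sets_disjoint(self):
        spec = SyntheticSpec(n_proteins=500, n_regions=5, n_enriched_per_region=20, seed=2)
        _, planted = gen_abundance_matrix(spec)
        all_planted = [p for s in planted.values() for p in s]
        assert len(all_planted) == len(set(all_planted)) == 100

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="n_regions"):
            gen_abundance_matrix(SyntheticSpec(n_regions=2))

    def test_seed_determinism(self):
        spec = SyntheticSpec(n_proteins=50, n_regions=4, n_enriched_per_region=3, seed=12)
        (a, pa), (b, pb) = gen_abundance_matrix(spec), gen_abundance_matrix(spec)
        pd.testing.assert_frame_equal(a, b)
        assert pa == pb


class TestGeneSets:
    def test_query_must_be_subset_of_universe(self):
        with pytest.raises(ValueError, match="subset"):
            gen_gene_sets(SyntheticSpec(), {"X"}, {"A", "B"})

    def test_empty_collection_request(self):
        universe = {f"G{i}" for i in range(100)}
        sets = gen_gene_sets(
            SyntheticSpec(), set(list(universe)[:10]), universe, n_null=0, n_planted=0
        )
        assert sets == {}

    def test_planted_overlap_forced_above_expectation(self):
        universe = {f"G{i:04d}" for i in range(1000)}
        query = set(sorted(universe)[:150])
        sets = gen_gene_sets(
            SyntheticSpec(seed=3), query, universe, n_null=5, n_planted=1, set_size=40
        )
        planted = sets["PLANTED_01"]["members"]
        expectation = 40 * 150 / 1000
        assert len(planted & query) >= 3 * expectation
        assert len(planted) == 40
        for i in range(5):
            assert len(sets[f"NULL_{i + 1:02d}"]["members"]) == 40


class TestPowerLawSampler:
    def test_support_and_determinism(self):
        a = sample_power_law(2.5, 100, seed=1)
        b = sample_power_law(2.5, 100, seed=1)
        assert (a >= 1).all()
        assert (a == b).all()

    def test_alpha_must_exceed_one(self):
        with pytest.raises(ValueError):
            sample_power_law(1.0, 10, seed=0)
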