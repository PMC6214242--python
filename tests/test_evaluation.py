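import math

import numpy as np
import pandas as pd
import pytest

import brute
from sitegraphs.evaluation import (
    CandidateSet,
    build_hit_rate_table,
    correlate_hit_rates,
    correlate_indices,
    find_candidates,
    hit_rate,
    spearman,
    summarize,
    summarize_graphs,
)
from sitegraphs.graphs import EcoGraph, SpeciesOccupancy


def graph(nodes, edges, kind="similarity", **params):
    params.setdefault("distance_threshold_km", 30.0)
    return EcoGraph(kind=kind, nodes=tuple(nodes), edges=frozenset(edges),
                    params=params)


class TestHitRate:
    def test_sample_species_counts(self):
        """A 15-edge species graph with 8 hits rates 8/15."""
        nodes = [f"n{i}" for i in range(16)]
        species_edges = {(f"n{i}", f"n{i+1}") for i in range(15)}
        sim_edges = {(f"n{i}", f"n{i+1}") for i in range(8)}
        m, h, rate = hit_rate(
            graph(nodes, species_edges, kind="full_single_species"),
            graph(nodes, sim_edges),
        )
        assert (m, h) == (15, 8)
        assert rate == pytest.approx(8 / 15)

    def test_containment_and_disjoint(self):
        nodes = "abcd"
        sp = graph(nodes, {("a", "b"), ("c", "d")})
        assert hit_rate(sp, graph(nodes, {("a", "b"), ("c", "d"), ("b", "c")})).rate == 1.0
        assert hit_rate(sp, graph(nodes, {("a", "c")})).rate == 0.0

    def test_zero_edges_undefined(self):
        r = hit_rate(graph("ab", set()), graph("ab", {("a", "b")}))
        assert r.m == 0 and math.isnan(r.rate)

    def test_threshold_mismatch_rejected(self):
        a = graph("ab", set(), distance_threshold_km=30.0)
        b = graph("ab", set(), distance_threshold_km=10.0)
        with pytest.raises(ValueError, match="thresholds differ"):
            hit_rate(a, b)


class TestSummarize:
    def test_density_one_gives_nhr_equal_to_R(self):
        ev = summarize([0.5, 0.7], E=706, n=706)
        assert ev.nhr == pytest.approx(ev.R)

    def test_nan_rates_excluded_from_average(self):
        ev = summarize([0.5, math.nan, 1.0], E=100, n=200)
        assert ev.R == pytest.approx(0.75)
        assert ev.density == pytest.approx(0.5)
        assert ev.nhr == pytest.approx(1.5)

    def test_identity_nhr_times_density(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            rates = rng.uniform(0, 1, size=10)
            n = int(rng.integers(10, 1000))
            E = int(rng.integers(1, n + 1))
            ev = summarize(rates.tolist(), E=E, n=n)
            assert abs(ev.nhr * ev.density - ev.R) < 1e-9

    def test_zero_E_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            summarize([0.5], E=0, n=10)


class TestSpearman:
    def test_identity_and_reversal(self):
        assert spearman([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        a = [1, 2, 2, 4]
        b = [1, 3, 2, 4]
        assert spearman(a, b) == pytest.approx(brute.spearman_rho(a, b))

    def test_random_columns_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.integers(0, 6, size=20).astype(float)
            b = rng.integers(0, 6, size=20).astype(float)
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            assert spearman(a, b) == pytest.approx(
                brute.spearman_rho(a, b), abs=1e-12
            )

    def test_listwise_nan_deletion(self):
        a = [1, 2, math.nan, 4, 5]
        b = [2, 3, 9, 5, math.nan]
        assert spearman(a, b) == pytest.approx(
            brute.spearman_rho([1, 2, 4], [2, 3, 5])
        )

    def test_too_few_pairs_and_constant_column(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestCorrelationTables:
    def make_tables(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(30)]
        tables = {}
        for label in ("g1", "g2"):
            tables[label] = pd.DataFrame(
                {
                    "degree": rng.integers(0, 8, size=30),
                    "betweenness": rng.uniform(0, 1, size=30),
                },
                index=pd.Index(nodes, name="node"),
            )
        return tables

    def test_graph_vs_itself_is_one(self):
        tables = self.make_tables()
        out = correlate_indices(
            {"a": tables["g1"], "b": tables["g1"]}, "degree", [("a", "b")]
        )
        assert out["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_matches_oracle_with_node_alignment(self):
        tables = self.make_tables()
        shuffled = tables["g2"].sample(frac=1.0, random_state=0)
        out = correlate_indices(
            {"a": tables["g1"], "b": shuffled}, "degree", [("a", "b")]
        )
        aligned = shuffled.loc[tables["g1"].index, "degree"]
        assert out["spearman_rho"].iloc[0] == pytest.approx(
            brute.spearman_rho(tables["g1"]["degree"].tolist(), aligned.tolist())
        )

    def test_hit_rate_columns(self):
        table = pd.DataFrame(
            {
                "edges": [3, 5, 7],
                "rate_a": [0.1, 0.5, 0.9],
                "rate_b": [0.9, 0.5, 0.1],
            },
            index=["s1", "s2", "s3"],
        )
        out = correlate_hit_rates(table, [("a", "b")])
        assert out["spearman_rho"].iloc[0] == pytest.approx(-1.0)


class TestHitRateTable:
    def test_table_and_summary(self, full_bundle):
        from sitegraphs.graphs import (
            build_raw_distance,
            build_similarity_graph,
            build_single_species,
            species_occupancy,
        )
        from sitegraphs.io_tables import compute_distances
        from sitegraphs.similarity import pairwise_similarity
        from sitegraphs.vectors import build_vector_set

        sites = list(full_bundle.sites)
        D = compute_distances(sites)
        raw = build_raw_distance(sites, D, 30.0)
        S = pairwise_similarity(
            build_vector_set(full_bundle.compositions, sites, "habitat", "binary"),
            "jaccard",
        )
        sim = {"habitat_jaccard": build_similarity_graph(sites, D, S, 30.0, 0.5)}
        occs = species_occupancy(full_bundle.compositions)
        species_graphs = {
            code: build_single_species(occ, D, 30.0, full=True)
            for code, occ in list(occs.items())[:25]
        }
        table = build_hit_rate_table(species_graphs, sim)
        # recompute each cell independently via set intersections
        for code, sg in species_graphs.items():
            expected_h = len(sg.edges & sim["habitat_jaccard"].edges)
            assert table.loc[code, "hits_habitat_jaccard"] == expected_h
            assert table.loc[code, "edges"] == len(sg.edges)
        summary = summarize_graphs(table, sim, raw)
        row = summary.loc["habitat_jaccard"]
        assert row["relative_density"] == pytest.approx(
            len(sim["habitat_jaccard"].edges) / len(raw.edges)
        )
        assert row["normalized_hit_rate"] * row["relative_density"] == (
            pytest.approx(row["avg_hit_rate"], abs=1e-9)
        )


class TestCandidates:
    def test_minimal_instance(self):
        occ = SpeciesOccupancy("sp", frozenset({"a", "b"}))
        sp_graph = graph(["a", "b"], {("a", "b")}, kind="single_species")
        sim = graph(["a", "b", "c"], {("b", "c")})
        (cs,) = find_candidates(sp_graph, occ, sim)
        assert cs.component == {"a", "b"}
        assert cs.candidates == {("b", "c")}

    def test_no_leaving_edge_gives_empty_set(self):
        occ = SpeciesOccupancy("sp", frozenset({"a", "b"}))
        sp_graph = graph(["a", "b"], {("a", "b")}, kind="single_species")
        sim = graph(["a", "b", "c"], {("a", "b")})
        (cs,) = find_candidates(sp_graph, occ, sim)
        assert cs.candidates == frozenset()

    def test_isolated_occupied_node_forms_component(self):
        occ = SpeciesOccupancy("sp", frozenset({"a"}))
        sp_graph = graph(["a"], set(), kind="single_species")
        sim = graph(["a", "b"], {("a", "b")})
        (cs,) = find_candidates(sp_graph, occ, sim)
        assert cs.component == {"a"}
        assert cs.candidates == {("a", "b")}

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            nodes, sim_edges = brute.random_graph(rng, max_nodes=8)
            if not nodes:
                continue
            occupied = {v for v in nodes if rng.random() < 0.4}
            sp_edges = {
                (a, b) for a, b in sim_edges if a in occupied and b in occupied
            }
            occ = SpeciesOccupancy("sp", frozenset(occupied))
            sp_graph = graph(sorted(occupied), sp_edges, kind="single_species")
            sim = graph(nodes, sim_edges)
            result = find_candidates(sp_graph, occ, sim)
            seen_components = set()
            for cs in result:
                seen_components.add(frozenset(cs.component))
                expected = brute.candidate_pairs(
                    cs.component, occupied, nodes, sim_edges
                )
                assert set(cs.candidates) == expected
                for i, j in cs.candidates:
                    assert i in cs.component
                    assert j not in cs.component
                    assert j not in occupied
            assert len(seen_components) == len(result)
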