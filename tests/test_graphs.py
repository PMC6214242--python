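import numpy as np
import pytest

from sitegraphs.graphs import (
    EcoGraph,
    SpeciesOccupancy,
    build_raw_distance,
    build_similarity_graph,
    build_single_species,
    edge_count_sweep,
    species_occupancy,
)
from sitegraphs.io_tables import DistanceMatrix, compute_distances
from sitegraphs.similarity import pairwise_similarity
from sitegraphs.vectors import build_vector_set


def dm(ids, entries):
    values = np.zeros((len(ids), len(ids)))
    for (a, b), d in entries.items():
        i, j = ids.index(a), ids.index(b)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(site_ids=tuple(ids), values=values)


@pytest.fixture(scope="module")
def landscape_parts(full_bundle):
    sites = list(full_bundle.sites)
    D = compute_distances(sites)
    S = pairwise_similarity(
        build_vector_set(full_bundle.compositions, sites, "habitat", "binary"),
        "jaccard",
    )
    return sites, D, S


class TestEcoGraph:
    def test_rejects_self_loops_and_unknown_nodes(self):
        with pytest.raises(ValueError, match="self-loop"):
            EcoGraph("raw_distance", ("a",), frozenset({("a", "a")}))
        with pytest.raises(ValueError, match="unknown node"):
            EcoGraph("raw_distance", ("a",), frozenset({("a", "b")}))

    def test_edge_is_unordered(self):
        g = EcoGraph("raw_distance", ("a", "b"), frozenset({("a", "b")}))
        assert g.has_edge("b", "a")


class TestRawDistance:
    def test_direct_thresholding(self):
        D = dm(["a", "b", "c"], {("a", "b"): 10, ("b", "c"): 20, ("a", "c"): 40})
        g = build_raw_distance(["a", "b", "c"], D, 30)
        assert g.edges == {("a", "b"), ("b", "c")}

    def test_threshold_inclusive(self):
        D = dm(["a", "b"], {("a", "b"): 30.0})
        assert build_raw_distance(["a", "b"], D, 30.0).n_edges == 1

    def test_zero_threshold_keeps_partner_edges(self, landscape_parts):
        sites, D, _ = landscape_parts
        g = build_raw_distance(sites, D, 0.0)
        partner_pairs = {
            tuple(sorted((s.site_id, p)))
            for s in sites
            for p in s.zero_distance_partners
        }
        assert partner_pairs <= set(g.edges)

    def test_matches_pair_enumeration(self, landscape_parts):
        sites, D, _ = landscape_parts
        g = build_raw_distance(sites, D, 30.0)
        ids = [s.site_id for s in sites]
        expected = {
            tuple(sorted((ids[i], ids[j])))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if D.values[i, j] <= 30.0
        }
        assert set(g.edges) == expected


class TestSingleSpecies:
    def test_minimal_case(self):
        D = dm(["a", "b", "c"], {("a", "b"): 10, ("b", "c"): 5, ("a", "c"): 12})
        occ = SpeciesOccupancy("sp1", frozenset({"a", "b"}))
        g = build_single_species(occ, D, 30)
        assert g.nodes == ("a", "b")
        assert g.edges == {("a", "b")}

    def test_full_variant_keeps_all_nodes(self, landscape_parts):
        sites, D, _ = landscape_parts
        occupied = frozenset([sites[0].site_id, sites[1].site_id])
        g = build_single_species(
            SpeciesOccupancy("x", occupied), D, 30, full=True
        )
        assert g.nodes == D.site_ids
        assert len(g.edges) <= 1

    def test_unknown_site_rejected(self):
        D = dm(["a"], {})
        with pytest.raises(ValueError, match="unknown sites"):
            build_single_species(SpeciesOccupancy("x", frozenset({"z"})), D, 30)

    def test_edges_are_doubly_occupied_raw_edges(self, landscape_parts, full_bundle):
        sites, D, _ = landscape_parts
        raw = build_raw_distance(sites, D, 30.0)
        occs = species_occupancy(full_bundle.compositions)
        code, occ = next(iter(occs.items()))
        g = build_single_species(occ, D, 30.0, full=True)
        expected = {
            e for e in raw.edges
            if e[0] in occ.occupied and e[1] in occ.occupied
        }
        assert set(g.edges) == expected


class TestSimilarityGraph:
    def test_zero_threshold_equals_raw_minus_undefined(self, landscape_parts):
        sites, D, S = landscape_parts
        raw = build_raw_distance(sites, D, 30.0)
        g = build_similarity_graph(sites, D, S, 30.0, 0.0)
        index = {s: i for i, s in enumerate(S.site_ids)}
        expected = {
            (a, b) for a, b in raw.edges if S.defined[index[a], index[b]]
        }
        assert set(g.edges) == expected

    def test_min_sim_one_keeps_only_score_one(self, landscape_parts):
        sites, D, S = landscape_parts
        g = build_similarity_graph(sites, D, S, 30.0, 1.0)
        index = {s: i for i, s in enumerate(S.site_ids)}
        assert all(S.values[index[a], index[b]] == 1.0 for a, b in g.edges)

    def test_dual_construction_equivalence(self, landscape_parts):
        """Direct AND-construction equals raw-graph edge removal."""
        sites, D, S = landscape_parts
        direct = build_similarity_graph(sites, D, S, 30.0, 0.5)
        raw = build_raw_distance(sites, D, 30.0)
        index = {s: i for i, s in enumerate(S.site_ids)}
        removed = {
            (a, b)
            for a, b in raw.edges
            if S.defined[index[a], index[b]]
            and S.values[index[a], index[b]] >= 0.5
        }
        assert set(direct.edges) == removed

    def test_nestedness_and_subset_of_raw(self, landscape_parts):
        sites, D, S = landscape_parts
        raw = build_raw_distance(sites, D, 30.0)
        previous = None
        for level in (0.0, 0.3, 0.5, 0.7, 0.9):
            g = build_similarity_graph(sites, D, S, 30.0, level)
            assert g.edges <= raw.edges
            if previous is not None:
                assert g.edges <= previous
            previous = g.edges


class TestSweep:
    def test_degenerate_level_zero(self, landscape_parts):
        sites, D, S = landscape_parts
        raw = build_raw_distance(sites, D, 30.0)
        table = edge_count_sweep(sites, D, S, 30.0, [0.0])
        # all binary-jaccard similarities are defined, so level 0 = raw
        assert table["edges"].tolist() == [raw.n_edges]

    def test_counts_non_increasing_and_match_reconstruction(self, landscape_parts):
        sites, D, S = landscape_parts
        levels = [0.0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        table = edge_count_sweep(sites, D, S, 30.0, levels)
        counts = table["edges"].tolist()
        assert counts == sorted(counts, reverse=True)
        for level, count in zip(levels, counts):
            g = build_similarity_graph(sites, D, S, 30.0, level)
            assert g.n_edges == count
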