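"""Overlap graph, maximal-clique merged regions, families, event labels."""

import numpy as np
import pytest

from mirna_cnv import hotspot as hs
from mirna_cnv import simulate as sim
from mirna_cnv.annotate import reciprocal_overlap
from mirna_cnv.model import CnvCall, ConfigError


def c(start, end, cid, ind="I1", chrom="22"):
    return CnvCall(ind, chrom, start, end, 3, 20, cid)


class TestOverlapGraph:
    def test_identical_intervals_edge(self):
        g = hs.build_overlap_graph([c(1, 100, "a"), c(1, 100, "b", ind="I2")])
        assert g.has_edge("a", "b")

    def test_edge_exactly_at_threshold(self):
        # (1,100) and (61,160): shared 40 bp -> 40%/40%, kept at >= 0.40
        g = hs.build_overlap_graph([c(1, 100, "a"), c(61, 160, "b")], 0.40)
        assert g.has_edge("a", "b")
        g2 = hs.build_overlap_graph([c(1, 100, "a"), c(62, 160, "b")], 0.40)
        assert not g2.has_edge("a", "b")

    def test_no_cross_chromosome_edges(self):
        g = hs.build_overlap_graph([c(1, 100, "a"), c(1, 100, "b", chrom="15")])
        assert g.number_of_edges() == 0

    def test_threshold_domain(self):
        with pytest.raises(ConfigError):
            hs.build_overlap_graph([], min_fraction=0.0)
        with pytest.raises(ConfigError):
            hs.build_overlap_graph([], min_fraction=1.5)

    def test_single_sided_mode_is_more_permissive(self):
        a, b = c(1, 1000, "a"), c(1, 100, "b")  # 100/1000 = 0.1 vs 100/100 = 1.0
        assert not hs.build_overlap_graph([a, b], 0.4, "reciprocal").has_edge("a", "b")
        assert hs.build_overlap_graph([a, b], 0.4, "single").has_edge("a", "b")


class TestMergedRegions:
    def test_three_mutual_overlaps_one_region(self):
        calls = [c(1, 100, "a"), c(10, 110, "b"), c(20, 120, "c")]
        regions = hs.find_merged_regions(hs.build_overlap_graph(calls, 0.4))
        assert len(regions) == 1
        assert regions[0].member_call_ids == ("a", "b", "c")
        assert (regions[0].span_start, regions[0].span_end) == (1, 120)

    def test_chain_splits_into_two_cliques(self):
        # A-B and B-C overlap >= 40%, A-C do not: clique != connected component
        calls = [c(1, 100, "a"), c(55, 155, "b"), c(110, 210, "c")]
        g = hs.build_overlap_graph(calls, 0.40)
        assert g.has_edge("a", "b") and g.has_edge("b", "c") and not g.has_edge("a", "c")
        regions = hs.find_merged_regions(g)
        assert sorted(r.member_call_ids for r in regions) == [("a", "b"), ("b", "c")]

    def test_clique_property_on_every_region(self, small_cohort):
        _, individuals, calls, _, _ = small_cohort
        g = hs.build_overlap_graph(calls, 0.4)
        by_id = {x.call_id: x for x in calls}
        for r in hs.find_merged_regions(g):
            members = [by_id[m] for m in r.member_call_ids]
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert reciprocal_overlap(a, b) >= 0.4

    def test_matches_exhaustive_enumeration(self, clique_oracle):
        """Pivoted clique search equals brute-force subset enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(2, 16))
            calls = []
            for i in range(n):
                start = int(rng.integers(1, 500))
                calls.append(c(start, start + int(rng.integers(10, 400)), f"n{i}"))
            frac = float(rng.uniform(0.2, 0.9))
            g = hs.build_overlap_graph(calls, frac)
            idx = {f"n{i}": i for i in range(n)}
            edges = {(min(idx[u], idx[v]), max(idx[u], idx[v])) for u, v in g.edges}
            expected = {fs for fs in clique_oracle(n, edges) if len(fs) >= 2}
            got = {frozenset(idx[m] for m in r.member_call_ids)
                   for r in hs.find_merged_regions(g)}
            assert got == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        calls = []
        for i in range(40):
            start = int(rng.integers(1, 2000))
            calls.append(c(start, start + int(rng.integers(50, 800)), f"n{i}"))
        lo = hs.find_merged_regions(hs.build_overlap_graph(calls, 0.3))
        hi = hs.find_merged_regions(hs.build_overlap_graph(calls, 0.6))
        lo_sets = [set(r.member_call_ids) for r in lo]
        for r in hi:  # every stricter region is inside some looser region
            assert any(set(r.member_call_ids) <= s for s in lo_sets)


class TestFamilies:
    def test_breakpoint_identical_members_form_one_family(self):
        calls = [c(100, 10_000, f"a{i}", ind=f"I{i}") for i in range(5)]
        g = hs.build_overlap_graph(calls, 0.4)
        (region,) = hs.find_merged_regions(g)
        fams = hs.find_families(region, {x.call_id: x for x in calls})
        assert fams == [tuple(sorted(x.call_id for x in calls))]

    def test_half_overlap_yields_no_family(self):
        calls = [c(1, 1000, "a"), c(501, 1500, "b")]
        g = hs.build_overlap_graph(calls, 0.4)
        (region,) = hs.find_merged_regions(g)
        assert hs.find_families(region, {x.call_id: x for x in calls}) == []

    def test_family_threshold_must_dominate_merge(self):
        calls = [c(1, 100, "a"), c(1, 100, "b")]
        (region,) = hs.find_merged_regions(hs.build_overlap_graph(calls, 0.4))
        with pytest.raises(ConfigError):
            hs.find_families(region, {x.call_id: x for x in calls},
                             family_fraction=0.2, merge_fraction=0.4)

    def test_planted_hotspot_recovered_as_one_family(self):
        cfg = sim.SimConfig(
            populations=[sim.PopulationSpec("P", 100, 50)],
            hotspot_loci=[sim.HotspotLocus("22", 23_000_000, 23_200_000, 0.20)],
            background_rate=0.0, n_mirna_genes=5, seed=9,
        )
        _, calls, _, truth = sim.generate_cohort(cfg)
        assert len(truth.hotspot_carriers[0]) == 20
        g = hs.build_overlap_graph(calls, 0.4)
        regions = hs.attach_families(hs.find_merged_regions(g), calls)
        (region,) = regions
        assert len(region.families) == 1 and len(region.families[0]) == 20


class TestEventLabels:
    def test_partition_and_rules(self):
        calls = ([c(100, 10_000, f"h{i}", ind=f"I{i}") for i in range(6)]  # hotspot
                 + [c(50_000, 60_000, f"m{i}", ind=f"J{i}") for i in range(3)]  # mid
                 + [c(900_000, 910_000, "u0")])  # unique
        g = hs.build_overlap_graph(calls, 0.4)
        regions = hs.find_merged_regions(g)
        labels = hs.classify_events(regions, calls, min_events=5)
        assert all(labels[f"h{i}"] == "hotspot" for i in range(6))
        assert all(labels[f"m{i}"] == "intermediate" for i in range(3))
        assert labels["u0"] == "unique"
        assert set(labels) == {x.call_id for x in calls}

    def test_labels_partition_cohort(self, small_cohort):
        _, _, calls, _, _ = small_cohort
        g = hs.build_overlap_graph(calls, 0.4)
        labels = hs.classify_events(hs.find_merged_regions(g), calls)
        assert set(labels) == {x.call_id for x in calls}
        assert set(labels.values()) <= {"hotspot", "intermediate", "unique"}


def test_graphml_export_round_trips(tmp_path):
    import networkx as nx

    calls = [c(1, 100, "a"), c(10, 110, "b")]
    g = hs.build_overlap_graph(calls, 0.4)
    path = tmp_path / "g.graphml"
    hs.write_graphml(g, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == {"a", "b"} and back.has_edge("a", "b")
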