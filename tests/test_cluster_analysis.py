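"""Cluster enumeration rules, trimer motifs and dataset summaries."""

import itertools

import numpy as np
import pytest

from aroclust.cluster_analysis import (
    AromaticCluster,
    DatasetSummary,
    enumerate_clusters,
    summarize_dataset,
    trimer_motif,
)
from aroclust.config import Config
from aroclust.interaction_geometry import AromaticInteraction
from aroclust.ring_detection import AromaticRing


def fake_ring(ring_id, source="R", chain="A", res_name="PHE", seq=None):
    seq = seq if seq is not None else abs(hash(ring_id)) % 10000
    return AromaticRing(
        ring_id=ring_id, source_class=source, ring_type="benzene",
        parent=(chain, seq, res_name), atom_keys=((ring_id,),),
        center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
        chain_id=chain, parent_key=(chain, seq, "", res_name))


def edge(a, b, context):
    return AromaticInteraction(ring_a=a.ring_id, ring_b=b.ring_id, d=5.0,
                               alpha=0.0, theta=0.0, theta_a=0.0, theta_b=0.0,
                               conformation="face-to-face", context=context)


def rr_edge(a, b):
    ctx = "inter-chain" if a.chain_id != b.chain_id else "intra-chain"
    return edge(a, b, ctx)


class TestEnumerateClusters:
    def test_minimal_pd_dimer(self):
        d = fake_ring("d1", source="D", chain="A")
        r = fake_ring("r1", chain="A")
        clusters = enumerate_clusters([d, r], [edge(d, r, "drug-residue")], "PD")
        assert len(clusters) == 1
        assert clusters[0].size == 2
        assert len(clusters[0].counting_edges) == 1

    def test_pd_requires_d_ring(self):
        r1, r2 = fake_ring("r1"), fake_ring("r2")
        assert enumerate_clusters([r1, r2], [rr_edge(r1, r2)], "PD") == []

    def test_pp_detection_is_interchain_only(self):
        """A second A-chain ring near A1 but not B1 stays outside."""
        a1, a2 = fake_ring("a1", chain="A"), fake_ring("a2", chain="A")
        b1 = fake_ring("b1", chain="B")
        inters = [rr_edge(a1, b1), rr_edge(a1, a2)]
        clusters = enumerate_clusters([a1, a2, b1], inters, "PP")
        assert len(clusters) == 1
        assert clusters[0].ring_ids == {"a1", "b1"}
        assert len(clusters[0].detection_edges) == 1
        assert len(clusters[0].counting_edges) == 1    # no member intra edge

    def test_pp_counting_includes_member_intrachain(self):
        """A1-B1, A2-B1 inter-chain + A1-A2 intra-chain: one component,
        2 detection edges, 3 counting edges."""
        a1, a2 = fake_ring("a1", chain="A"), fake_ring("a2", chain="A")
        b1 = fake_ring("b1", chain="B")
        inters = [rr_edge(a1, b1), rr_edge(a2, b1), rr_edge(a1, a2)]
        clusters = enumerate_clusters([a1, a2, b1], inters, "PP")
        assert len(clusters) == 1
        assert clusters[0].ring_ids == {"a1", "a2", "b1"}
        assert len(clusters[0].detection_edges) == 2
        assert len(clusters[0].counting_edges) == 3

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            enumerate_clusters([], [], "XX")

    def test_matches_union_find_oracle(self):
        """Components equal an independent union-find on 200 random graphs."""

        class UnionFind:
            def __init__(self, items):
                self.p = {x: x for x in items}

            def find(self, x):
                while self.p[x] != x:
                    self.p[x] = self.p[self.p[x]]
                    x = self.p[x]
                return x

            def union(self, a, b):
                self.p[self.find(a)] = self.find(b)

        rng = np.random.default_rng(123)
        for trial in range(200):
            n = int(rng.integers(2, 51))
            rings = [fake_ring(f"t{trial}r{i}", chain="A", seq=i)
                     for i in range(n)]
            n_edges = int(rng.integers(0, n * 2))
            pairs = set()
            for _ in range(n_edges):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
            inters = [rr_edge(rings[i], rings[j]) for i, j in pairs]
            clusters = enumerate_clusters(rings, inters, "intra")

            uf = UnionFind(range(n))
            for i, j in pairs:
                uf.union(i, j)
            comps = {}
            for i in range(n):
                comps.setdefault(uf.find(i), set()).add(i)
            expected = {frozenset(f"t{trial}r{i}" for i in c)
                        for c in comps.values() if len(c) >= 2}
            got = {frozenset(c.ring_ids) for c in clusters}
            assert got == expected
            # every counting edge stays within one cluster
            for c in clusters:
                for e in c.counting_edges:
                    assert {e.ring_a, e.ring_b} <= c.ring_ids
            # sizes sum to number of non-singleton rings
            non_singleton = sum(len(c) for c in comps.values() if len(c) >= 2)
            assert sum(c.size for c in clusters) == non_singleton


class TestTrimerMotif:
    def _cluster(self, edges_idx):
        rings = [fake_ring(f"r{i}", seq=i) for i in range(3)]
        inters = [rr_edge(rings[i], rings[j]) for i, j in edges_idx]
        return AromaticCluster(rings=rings, detection_edges=inters,
                               counting_edges=inters, context="intra")

    def test_triangle_is_sym(self):
        assert trimer_motif(self._cluster([(0, 1), (1, 2), (0, 2)])) == "Sym"

    def test_path_is_lad(self):
        assert trimer_motif(self._cluster([(0, 1), (1, 2)])) == "Lad"

    def test_exhaustive_connected_3_graphs(self):
        """Every connected 3-node graph has 2 or 3 edges; the
        classification is total over them."""
        all_edges = [(0, 1), (1, 2), (0, 2)]
        for k in (1, 2, 3):
            for subset in itertools.combinations(all_edges, k):
                nodes = set(i for e in subset for i in e)
                connected = len(nodes) == 3 and k >= 2
                if not connected:
                    continue
                motif = trimer_motif(self._cluster(list(subset)))
                assert motif == ("Sym" if k == 3 else "Lad")

    def test_wrong_size_raises(self):
        rings = [fake_ring(f"r{i}", seq=i) for i in range(2)]
        c = AromaticCluster(rings=rings,
                            detection_edges=[rr_edge(rings[0], rings[1])],
                            counting_edges=[rr_edge(rings[0], rings[1])],
                            context="intra")
        with pytest.raises(ValueError):
            trimer_motif(c)


class TestSummarize:
    def test_printed_totals_reproduce_averages(self):
        """The summary-statistic definitions reproduce the published
        dataset table arithmetic."""
        pd_sum = DatasetSummary(n_complexes_total=10231,
                                n_complexes_with_cluster=5908,
                                n_clusters=7236, n_interactions=23303)
        pp_sum = DatasetSummary(n_complexes_total=4837,
                                n_complexes_with_cluster=3048,
                                n_clusters=7717, n_interactions=15309)
        intra = DatasetSummary(n_complexes_with_cluster=9760,
                               n_clusters=73312, n_interactions=277797)
        assert round(pd_sum.avg_clusters_per_complex, 2) == 1.22
        assert round(pp_sum.avg_clusters_per_complex, 2) == 2.53
        assert round(pd_sum.avg_interactions_per_cluster, 2) == 3.22
        assert round(pp_sum.avg_interactions_per_cluster, 2) == 1.98
        assert round(intra.avg_clusters_per_complex, 2) == 7.51
        assert round(pp_sum.pct_with_cluster) == 63

    def test_single_everything_gives_unit_averages(self):
        d = fake_ring("d1", source="D")
        r = fake_ring("r1")
        cluster = AromaticCluster(rings=[d, r],
                                  detection_edges=[edge(d, r, "drug-residue")],
                                  counting_edges=[edge(d, r, "drug-residue")],
                                  context="PD")
        s = summarize_dataset({"c1": [cluster]}, n_complexes_total=1)
        assert s.avg_clusters_per_complex == 1.0
        assert s.avg_interactions_per_cluster == 1.0
        assert s.pct_with_cluster == 100.0

    def test_zero_clusters_no_division_error(self):
        s = summarize_dataset({"c1": []}, n_complexes_total=1)
        assert s.n_clusters == 0
        assert s.avg_clusters_per_complex is None
        assert s.avg_interactions_per_cluster is None

    def test_composition_counts_residues_once(self):
        # a TRP contributes two rings but one residue instance
        t1 = fake_ring("t1", res_name="TRP", seq=5)
        t2 = fake_ring("t2", res_name="TRP", seq=5)
        f1 = fake_ring("f1", res_name="PHE", seq=6)
        edges = [rr_edge(t1, f1), rr_edge(t2, f1)]
        cluster = AromaticCluster(rings=[t1, t2, f1], detection_edges=edges,
                                  counting_edges=edges, context="intra")
        s = summarize_dataset({"c1": [cluster]})
        assert s.composition["TRP"] == pytest.approx(0.5)
        assert s.composition["PHE"] == pytest.approx(0.5)
        assert sum(s.composition.values()) == pytest.approx(1.0, abs=1e-9)

    def test_per_ring_counting_switch(self):
        t1 = fake_ring("t1", res_name="TRP", seq=5)
        t2 = fake_ring("t2", res_name="TRP", seq=5)
        f1 = fake_ring("f1", res_name="PHE", seq=6)
        edges = [rr_edge(t1, f1), rr_edge(t2, f1)]
        cluster = AromaticCluster(rings=[t1, t2, f1], detection_edges=edges,
                                  counting_edges=edges, context="intra")
        cfg = Config(composition_per_ring=True)
        s = summarize_dataset({"c1": [cluster]}, config=cfg)
        assert s.composition["TRP"] == pytest.approx(2 / 3)

    def test_exposure_and_ss_aggregation(self):
        r1 = fake_ring("r1", seq=1)
        r2 = fake_ring("r2", seq=2)
        e = rr_edge(r1, r2)
        cluster = AromaticCluster(rings=[r1, r2], detection_edges=[e],
                                  counting_edges=[e], context="intra")
        exposures = {("c1", r1.parent_key): 10.0, ("c1", r2.parent_key): 30.0}
        ss = {("c1", r1.parent_key): "Helix", ("c1", r2.parent_key): "Loop"}
        s = summarize_dataset({"c1": [cluster]}, exposures=exposures,
                              ss_assignments=ss)
        assert s.mean_pct_exposed == pytest.approx(20.0)
        assert s.ss_fractions["Helix"] == pytest.approx(0.5)
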