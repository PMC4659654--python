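"""Graph clustering, supercluster linking, filtering, contigs, graph export."""

import networkx as nx
import pytest

from repeatskim.align import find_similarity_hits
from repeatskim.iolayer import TaggedRead
from repeatskim.readcluster import (
    ClusterConsistencyError,
    ReadCluster,
    build_clusters,
    build_contigs,
    export_graph,
    filter_clusters,
    link_superclusters,
)

from conftest import random_seq, reads_from_template


class TestBuildClusters:
    def test_two_independent_families_two_clusters(self, rng):
        t1, t2 = random_seq(rng, 200), random_seq(rng, 200)
        reads = reads_from_template(rng, t1, 12, species="A", prefix="a")
        reads += reads_from_template(rng, t2, 8, species="B", prefix="b")
        hits = find_similarity_hits(reads)
        clusters, singles = build_clusters(hits, reads)
        assert len(clusters) == 2
        assert [c.size for c in clusters] == [12, 8]
        assert clusters[0].per_species_counts == {"A": 12}
        assert singles == []

    def test_chain_is_one_cluster(self, rng):
        s = random_seq(rng, 180)
        # a-b and b-c overlap by 60 bp, a-c only by 20 (below threshold)
        reads = [
            TaggedRead("X", "X_a", s[0:100]),
            TaggedRead("X", "X_b", s[40:140]),
            TaggedRead("X", "X_c", s[80:180]),
        ]
        hits = find_similarity_hits(reads)
        assert {frozenset((h.read_a, h.read_b)) for h in hits} == {
            frozenset(("X_a", "X_b")), frozenset(("X_b", "X_c")),
        }
        clusters, _ = build_clusters(hits, reads)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_partition_and_singletons(self, rng):
        t = random_seq(rng, 200)
        reads = reads_from_template(rng, t, 10, prefix="f")
        lone = [TaggedRead("X", f"X_lone{i}", random_seq(rng, 100)) for i in range(5)]
        clusters, singles = build_clusters(find_similarity_hits(reads + lone), reads + lone)
        clustered = set().union(*(c.member_reads for c in clusters))
        assert len(clustered) + len(singles) == 15
        assert clustered.isdisjoint(singles)
        total_counts = sum(sum(c.per_species_counts.values()) for c in clusters)
        assert total_counts + len(singles) == 15
        assert clusters[0].proportion == pytest.approx(10 / 15)

    def test_hit_naming_unknown_read_is_error(self, rng):
        reads = reads_from_template(rng, random_seq(rng, 150), 4)
        hits = find_similarity_hits(reads)
        with pytest.raises(ClusterConsistencyError):
            build_clusters(hits, reads[:2])


class TestFilterClusters:
    def _cluster(self, prop):
        return ReadCluster(1, frozenset({"a"}), {"X": 1}, prop)

    def test_genome_fraction_mode(self):
        # 150 of 1,000,000 reads = 0.015% >= 0.01% of the genome
        kept, tallies = filter_clusters([self._cluster(150 / 1_000_000)], "genome_fraction")
        assert len(kept) == 1 and tallies == {"retained": 1, "discarded": 0}

    def test_read_fraction_mode_discards_0004pct(self):
        # 40 of 1,000,000 reads = 0.004% < 0.005% of analysed reads
        kept, tallies = filter_clusters([self._cluster(40 / 1_000_000)], "read_fraction")
        assert kept == [] and tallies["discarded"] == 1

    def test_empty_input(self):
        assert filter_clusters([], "genome_fraction") == ([], {"retained": 0, "discarded": 0})

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            filter_clusters([], "banana")


class TestSuperclusters:
    def _mated(self, species, serial, seq1, seq2):
        n1, n2 = f"{species}_{serial}/1", f"{species}_{serial}/2"
        return [
            TaggedRead(species, n1, seq1, mate_id=n2),
            TaggedRead(species, n2, seq2, mate_id=n1),
        ]

    def _split_element(self, rng, n_pairs=8):
        """Two unrelated segments (as for an LTR and its internal domain)
        joined only by mate pairs."""
        left, right = random_seq(rng, 150), random_seq(rng, 150)
        reads = []
        for i in range(n_pairs):
            reads += self._mated("X", f"p{i:03d}", left[25:125], right[25:125])
        return reads

    def test_mate_pairs_merge_split_clusters(self, rng):
        reads = self._split_element(rng)
        hits = find_similarity_hits(reads)
        clusters, _ = build_clusters(hits, reads)
        assert len(clusters) == 2
        sup = link_superclusters(clusters, reads, min_shared_pairs=5)
        assert sup == [[1, 2]]

    def test_infinite_threshold_keeps_clusters_apart(self, rng):
        reads = self._split_element(rng)
        clusters, _ = build_clusters(find_similarity_hits(reads), reads)
        sup = link_superclusters(clusters, reads, min_shared_pairs=float("inf"))
        assert sup == [[1], [2]]

    def test_partition_independent_of_order(self, rng):
        reads = self._split_element(rng)
        clusters, _ = build_clusters(find_similarity_hits(reads), reads)
        a = link_superclusters(clusters, reads, 3)
        b = link_superclusters(list(reversed(clusters)), reads, 3)
        assert a == b


class TestContigs:
    def test_error_free_tiling_reconstructs_template(self, rng):
        template = random_seq(rng, 500)
        reads = [
            TaggedRead("X", f"X_t{i:02d}", template[s : s + 100])
            for i, s in enumerate(range(0, 401, 20))
        ]
        hits = find_similarity_hits(reads)
        clusters, _ = build_clusters(hits, reads)
        contigs = build_contigs(clusters[0], reads, hits)
        assert len(contigs) == 1
        assert contigs[0].consensus == template

    def test_two_templates_forced_into_one_cluster_give_two_contigs(self, rng):
        t1, t2 = random_seq(rng, 300), random_seq(rng, 300)
        reads = [
            TaggedRead("X", f"X_a{i}", t1[s : s + 100]) for i, s in enumerate(range(0, 201, 40))
        ] + [
            TaggedRead("X", f"X_b{i}", t2[s : s + 100]) for i, s in enumerate(range(0, 201, 40))
        ]
        hits = find_similarity_hits(reads)
        forced = ReadCluster(1, frozenset(r.read_id for r in reads), {"X": len(reads)}, 1.0)
        contigs = build_contigs(forced, reads, hits)
        assert len(contigs) == 2
        assert {c.consensus for c in contigs} == {t1, t2}

    def test_flank_beyond_shared_segment_is_masked(self, rng):
        """Reads continuing from a shared segment into private flanks keep
        only the shared part aligned (the flank is masked)."""
        core = random_seq(rng, 140)
        reads = [TaggedRead("X", f"X_c{i:02d}", core[s : s + 100])
                 for i, s in enumerate(range(0, 41, 5))]
        junction = core[40:140] [:60] + random_seq(rng, 40)  # 60 core + 40 private
        reads.append(TaggedRead("X", "X_jx", junction))
        hits = find_similarity_hits(reads)
        clusters, _ = build_clusters(hits, reads)
        contigs = build_contigs(clusters[0], reads, hits)
        (contig,) = contigs
        p = contig.placements["X_jx"]
        assert p.masked_suffix >= 35  # the 40-base private flank is masked

    def test_single_read_cluster_rejected(self, rng):
        c = ReadCluster(1, frozenset({"X_a"}), {"X": 1}, 1.0)
        with pytest.raises(ValueError):
            build_contigs(c, [TaggedRead("X", "X_a", random_seq(rng, 100))], [])


class TestExportGraph:
    def test_nodes_edges_and_attributes(self, rng, tmp_path):
        s = random_seq(rng, 160)
        reads = [
            TaggedRead("A", "A_x", s[0:100]),
            TaggedRead("B", "B_y", s[30:130]),
            TaggedRead("A", "A_z", s[60:160]),
        ]
        hits = find_similarity_hits(reads)
        clusters, _ = build_clusters(hits, reads)
        path = tmp_path / "cl.graphml"
        g = export_graph(clusters[0], hits, reads, path)
        assert g.number_of_nodes() == 3
        assert g.nodes["B_y"]["species"] == "B"
        assert all("identity" in d for _, _, d in g.edges(data=True))
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 3

    def test_empty_cluster_rejected(self, tmp_path):
        c = ReadCluster(1, frozenset(), {}, 0.0)
        with pytest.raises(ValueError):
            export_graph(c, [], [], tmp_path / "x.graphml")
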