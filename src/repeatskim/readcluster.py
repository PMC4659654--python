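"""Similarity-graph read clustering and per-cluster consensus layout.

Reads are nodes, similarity hits are edges; clusters are the connected
components, numbered 1..n by decreasing size.  Mate-pair links between
clusters join them into superclusters (repeats split between clusters,
e.g. the LTR and internal regions of one element).  Each cluster can be
laid out into greedy overlap consensus contigs whose per-read masked
segments drive the solo-LTR junction scan.
"""

from __future__ import annotations

import heapq
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from repeatskim.align import SimilarityHit, _best_window, encode_sequences, revcomp
from repeatskim.iolayer import TaggedRead


@dataclass
class ReadCluster:
    """A connected group of similar reads; the unit of repeat quantification."""

    cluster_id: int
    member_reads: frozenset[str]
    per_species_counts: dict[str, int]
    proportion: float
    annotation: str | None = None
    consensus_contigs: list["ContigLayout"] | None = None

    @property
    def size(self) -> int:
        return len(self.member_reads)

    def count_for(self, species_code: str) -> int:
        return self.per_species_counts.get(species_code, 0)


@dataclass
class ReadPlacement:
    """Placement of one read on a contig.

    ``offset`` is the contig column of the read's first placed-frame base;
    ``strand`` +1 places the read forward, -1 reverse-complemented.
    ``aligned`` is the placed-frame interval that agrees with the
    consensus; the rest of the read is masked.
    """

    offset: int
    strand: int
    read_length: int
    aligned: tuple[int, int]

    @property
    def masked_prefix(self) -> int:
        return self.aligned[0]

    @property
    def masked_suffix(self) -> int:
        return self.read_length - self.aligned[1]


@dataclass
class ContigLayout:
    consensus: str
    placements: dict[str, ReadPlacement]
    coverage: np.ndarray = field(repr=False, default=None)


class ClusterConsistencyError(ValueError):
    pass


def build_clusters(
    hits: Sequence[SimilarityHit],
    reads: Sequence[TaggedRead],
) -> tuple[list[ReadCluster], list[str]]:
    """Connected components of the similarity graph.

    Returns (clusters ordered by decreasing size, ids of singleton reads
    with no hits).  Cluster numbering ties are broken by the smallest
    member read id.  Per-species counts come from the read tags.
    """
    species_of = {r.read_id: r.species_code for r in reads}
    total = len(reads)
    g = nx.Graph()
    for h in hits:
        for rid in (h.read_a, h.read_b):
            if rid not in species_of:
                raise ClusterConsistencyError(f"hit names unknown read {rid!r}")
        g.add_edge(h.read_a, h.read_b)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    clusters = [
        ReadCluster(
            cluster_id=i + 1,
            member_reads=frozenset(comp),
            per_species_counts=dict(Counter(species_of[r] for r in comp)),
            proportion=len(comp) / total if total else 0.0,
        )
        for i, comp in enumerate(components)
    ]
    clustered = set(g.nodes)
    singletons = sorted(r.read_id for r in reads if r.read_id not in clustered)
    return clusters, singletons


def link_superclusters(
    clusters: Sequence[ReadCluster],
    reads: Sequence[TaggedRead],
    min_shared_pairs: float = 5,
) -> list[list[int]]:
    """Partition clusters into superclusters via mate-pair links.

    Two clusters are joined when at least ``min_shared_pairs`` read pairs
    span them; the partition is the union-find closure and is independent
    of cluster enumeration order.
    """
    cluster_of: dict[str, int] = {}
    for c in clusters:
        for rid in c.member_reads:
            cluster_of[rid] = c.cluster_id
    pair_counts: Counter[tuple[int, int]] = Counter()
    seen_pairs: set[tuple[str, str]] = set()
    for r in reads:
        if not r.mate_id:
            continue
        key = tuple(sorted((r.read_id, r.mate_id)))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        ca, cb = cluster_of.get(key[0]), cluster_of.get(key[1])
        if ca is None or cb is None or ca == cb:
            continue
        pair_counts[(min(ca, cb), max(ca, cb))] += 1
    g = nx.Graph()
    g.add_nodes_from(c.cluster_id for c in clusters)
    for (ca, cb), n in pair_counts.items():
        if n >= min_shared_pairs:
            g.add_edge(ca, cb)
    return sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda comp: (-len(comp), comp[0]),
    )


#: retain clusters making up at least 0.01% of the genome (per-species runs)
GENOME_FRACTION_THRESHOLD = 1e-4
#: retain clusters holding at least 0.005% of analysed reads (comparative run)
READ_FRACTION_THRESHOLD = 5e-5

_FILTER_THRESHOLDS = {
    "genome_fraction": GENOME_FRACTION_THRESHOLD,
    "read_fraction": READ_FRACTION_THRESHOLD,
}


def filter_clusters(
    clusters: Sequence[ReadCluster],
    mode: str = "genome_fraction",
    threshold: float | None = None,
) -> tuple[list[ReadCluster], dict[str, int]]:
    """Size-threshold cluster filtering.

    ``genome_fraction`` keeps clusters >= 0.01% of the genome (the cluster
    read proportion is the genome proportion under random sampling);
    ``read_fraction`` keeps clusters >= 0.005% of analysed reads.
    """
    if mode not in _FILTER_THRESHOLDS:
        raise ValueError(f"unknown filter mode {mode!r}; expected one of {sorted(_FILTER_THRESHOLDS)}")
    thr = _FILTER_THRESHOLDS[mode] if threshold is None else threshold
    retained = [c for c in clusters if c.proportion >= thr]
    tallies = {"retained": len(retained), "discarded": len(clusters) - len(retained)}
    return retained, tallies


# ---------------------------------------------------------------------------
# contig layout

def _hit_frame(h: SimilarityHit, len_b: int) -> tuple[int, int]:
    """(diagonal, hit length) of a hit in the a-forward/b-frame coordinates."""
    if h.orientation == "same":
        b_start = h.span_b[0]
    else:
        b_start = len_b - h.span_b[1]
    return h.span_a[0] - b_start, h.hit_length


def build_contigs(
    cluster: ReadCluster,
    reads: Mapping[str, TaggedRead] | Sequence[TaggedRead],
    hits: Sequence[SimilarityHit],
    mask_min_identity: float = 90.0,
    mask_min_length: int = 20,
) -> list[ContigLayout]:
    """Greedy overlap-layout consensus of a cluster.

    Seeds with the read having the most hits, extends by the longest
    remaining overlap to a placed read (first placement wins), builds a
    majority-vote consensus, then records for every read the maximal
    placed-frame window agreeing with the consensus at
    >= ``mask_min_identity``; the remainder is masked.  Deterministic:
    every tie is broken by read id.
    """
    if isinstance(reads, Mapping):
        read_map = dict(reads)
    else:
        read_map = {r.read_id: r for r in reads}
    members = sorted(cluster.member_reads)
    if len(members) < 2:
        raise ValueError("contig layout needs a cluster with >= 2 reads")
    member_set = set(members)
    adj: dict[str, list[tuple[str, SimilarityHit, bool]]] = defaultdict(list)
    degree: Counter[str] = Counter()
    for h in hits:
        if h.read_a in member_set and h.read_b in member_set:
            adj[h.read_a].append((h.read_b, h, False))
            adj[h.read_b].append((h.read_a, h, True))
            degree[h.read_a] += 1
            degree[h.read_b] += 1

    placed: dict[str, tuple[int, int]] = {}  # read -> (offset, strand)
    contigs: list[ContigLayout] = []
    remaining = set(members)
    while remaining:
        seed = max(remaining, key=lambda r: (degree[r], r))
        comp: dict[str, tuple[int, int]] = {seed: (0, +1)}
        heap: list[tuple[int, str, str]] = []
        tiebreak = 0

        def push_edges(rid: str):
            nonlocal tiebreak
            for other, h, mirrored in adj[rid]:
                if other in comp or other not in remaining:
                    continue
                heapq.heappush(heap, (-h.hit_length, rid, other, tiebreak, h, mirrored))
                tiebreak += 1

        push_edges(seed)
        while heap:
            _, rid, other, _, h, mirrored = heapq.heappop(heap)
            if other in comp:
                continue
            if mirrored:
                h = h.mirror()
            # h: read_a == rid (placed), read_b == other
            la = len(read_map[rid].sequence)
            lb = len(read_map[other].sequence)
            d, _hl = _hit_frame(h, lb)
            off_a, strand_a = comp[rid]
            rel = +1 if h.orientation == "same" else -1
            if strand_a == +1:
                off_b = off_a + d
            else:
                off_b = off_a + la - lb - d
            comp[other] = (off_b, strand_a * rel)
            push_edges(other)

        base = min(off for off, _ in comp.values())
        comp = {r: (off - base, s) for r, (off, s) in comp.items()}
        remaining -= set(comp)
        placed.update(comp)
        contigs.append(_consensus_layout(comp, read_map, mask_min_identity, mask_min_length))
    contigs.sort(key=lambda c: -len(c.consensus))
    return contigs


def _consensus_layout(
    comp: dict[str, tuple[int, int]],
    read_map: Mapping[str, TaggedRead],
    mask_min_identity: float,
    mask_min_length: int,
) -> ContigLayout:
    length = max(off + len(read_map[r].sequence) for r, (off, _) in comp.items())
    frames: dict[str, np.ndarray] = {}
    for rid, (off, strand) in comp.items():
        seq = read_map[rid].sequence
        if strand < 0:
            seq = revcomp(seq)
        arr, _ = encode_sequences([seq])
        frames[rid] = arr[0]

    def vote(aligned_spans: dict[str, tuple[int, int]] | None) -> np.ndarray:
        counts = np.zeros((length, 4), dtype=np.int32)
        for rid, (off, _strand) in comp.items():
            arr = frames[rid]
            lo, hi = (0, arr.size) if aligned_spans is None else aligned_spans[rid]
            if hi <= lo:
                continue
            seg = arr[lo:hi]
            valid = seg < 4
            counts[np.arange(off + lo, off + hi)[valid], seg[valid]] += 1
        return counts

    def masks(counts: np.ndarray, prev_spans) -> dict[str, tuple[int, int]]:
        spans: dict[str, tuple[int, int]] = {}
        for rid, (off, _strand) in comp.items():
            arr = frames[rid]
            # leave-one-out: a read only "aligns" where other reads support
            # the consensus, otherwise a lone read would trivially match
            # consensus its own bases created (e.g. its private flank)
            sub = counts[off : off + arr.size].copy()
            lo, hi = (0, arr.size) if prev_spans is None else prev_spans[rid]
            if hi > lo:
                seg = arr[lo:hi]
                valid = seg < 4
                sub[np.arange(lo, hi)[valid], seg[valid]] -= 1
            loo_cov = sub.sum(axis=1)
            loo_cons = np.argmax(sub, axis=1).astype(np.uint8)
            mism = (~((arr == loo_cons) & (arr < 4) & (loo_cov > 0))).astype(np.int64)
            best = _best_window(mism, mask_min_identity, min(mask_min_length, arr.size))
            if best is None:
                spans[rid] = (0, 0)
                continue
            s, e = best[0], best[0] + best[1]
            # an x%-identity window can ride a low-identity tail on a clean
            # body; require both ends to close with an exact 4-base run so
            # masked segments start right at the disagreement boundary
            k = 4
            while e - s >= max(k, mask_min_length) and mism[e - k : e].any():
                e -= 1
            while e - s >= max(k, mask_min_length) and mism[s : s + k].any():
                s += 1
            spans[rid] = (s, e) if e - s >= mask_min_length else (0, 0)
        return spans

    # two passes: masked flank bases pollute the first consensus around
    # insertion junctions, so rebuild it from aligned segments only
    counts = vote(None)
    spans = masks(counts, None)
    counts2 = vote(spans)
    # keep first-pass bases where aligned-only coverage vanishes
    cov2 = counts2.sum(axis=1)
    fallback = cov2 == 0
    counts2[fallback] = counts[fallback]
    spans = masks(counts2, spans)

    coverage = counts2.sum(axis=1)
    # majority vote; ties -> lexicographically smallest base; zero coverage -> N
    cons = np.argmax(counts2, axis=1).astype(np.uint8)
    cons[coverage == 0] = 4
    cons_str = "".join("ACGTN"[c] for c in cons)
    placements = {
        rid: ReadPlacement(
            offset=off, strand=strand, read_length=frames[rid].size, aligned=spans[rid]
        )
        for rid, (off, strand) in comp.items()
    }
    return ContigLayout(consensus=cons_str, placements=placements, coverage=coverage)


def flip_contig(contig: ContigLayout) -> ContigLayout:
    """The same layout read on the opposite strand (consensus
    reverse-complemented, placements mirrored)."""
    L = len(contig.consensus)
    placements = {}
    for rid, p in contig.placements.items():
        placements[rid] = ReadPlacement(
            offset=L - (p.offset + p.read_length),
            strand=-p.strand,
            read_length=p.read_length,
            aligned=(p.read_length - p.aligned[1], p.read_length - p.aligned[0]),
        )
    cov = contig.coverage[::-1].copy() if contig.coverage is not None else None
    return ContigLayout(consensus=revcomp(contig.consensus), placements=placements, coverage=cov)


def export_graph(
    cluster: ReadCluster,
    hits: Sequence[SimilarityHit],
    reads: Mapping[str, TaggedRead] | Sequence[TaggedRead],
    path,
) -> nx.Graph:
    """Write the cluster's similarity graph as GraphML (nodes carry the
    species attribute, edges the alignment identity); returns the graph."""
    if not cluster.member_reads:
        raise ValueError("cannot export an empty cluster")
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r for r in reads}
    g = nx.Graph()
    for rid in sorted(cluster.member_reads):
        g.add_node(rid, species=reads[rid].species_code)
    for h in hits:
        if h.read_a in cluster.member_reads and h.read_b in cluster.member_reads:
            g.add_edge(h.read_a, h.read_b, identity=float(h.identity),
                       length=int(h.hit_length), orientation=h.orientation)
    nx.write_graphml(g, path)
    return g
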