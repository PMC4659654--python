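"""Cross-species sequence conservation of repeats.

Two statistics: (i) per-species average pairwise read similarity within a
cluster, with overlap corrections for hits that stop short of the implied
read overlap; (ii) the per-read Hs/Ho ratio, where Hs is the frequency of
similarity hits to reads of the same species and Ho the frequency of hits
to reads of all other species, each normalized by the number of available
reads so the ratio is independent of copy-number differences between
species.  log10(Hs/Ho) is ~0 for repeats conserved across species and
increasingly positive for species-specific variants.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from repeatskim.align import SimilarityHit, find_similarity_hits
from repeatskim.iolayer import TaggedRead
from repeatskim.readcluster import ReadCluster

logger = logging.getLogger("repeatskim")

#: histogram of log10(Hs/Ho): bin width 0.1 over [-1, 4], out-of-range clamped
HISTOGRAM_RANGE = (-1.0, 4.0)
HISTOGRAM_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class HsHoRecord:
    """Intra- vs inter-specific hit frequencies of one read."""

    read_id: str
    species_code: str
    repeat_group: str
    Hs: float | None
    Ho: float | None

    @property
    def log10_ratio(self) -> float | None:
        if self.Hs and self.Ho:
            return float(np.log10(self.Hs / self.Ho))
        return None


@dataclass
class HsHoHistogram:
    repeat_group: str
    bin_edges: np.ndarray
    counts: np.ndarray
    n_records: int
    n_zero_hs: int
    n_zero_ho: int
    n_clamped: int
    single_species: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def implied_overlap(hit: SimilarityHit, len_a: int, len_b: int) -> int:
    """Maximum possible overlap implied by the hit's diagonal offsets."""
    if hit.orientation == "same":
        b_start = hit.span_b[0]
    else:
        b_start = len_b - hit.span_b[1]
    d = hit.span_a[0] - b_start
    return int(min(len_a, len_b + d) - max(0, d))


def adjusted_similarity(hit: SimilarityHit, len_a: int, len_b: int) -> float:
    """Identity rescaled by hit_length / implied overlap.

    When a hit ends before the read ends although the implied overlap
    continues, the unmatched overhang inside the overlap counts as
    mismatch: similarity = identity x hit_length / implied_overlap.
    """
    ov = implied_overlap(hit, len_a, len_b)
    return hit.identity * hit.hit_length / ov if ov > 0 else 0.0


def species_pairwise_similarity(
    cluster: ReadCluster,
    reads: Mapping[str, TaggedRead] | Sequence[TaggedRead],
    min_hit_length: int = 50,
    seed_length: int = 7,
    min_identity: float = 55.0,
) -> dict[str, float | None]:
    """Mean adjusted pairwise similarity per species within one cluster.

    Species with < 2 reads in the cluster are reported as None (undefined).
    Only hits of at least ``min_hit_length`` bp enter the mean; the search
    runs at word size ``seed_length`` for sensitivity well below the 90%
    clustering threshold (floor ``min_identity``).
    """
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r for r in reads}
    by_species: dict[str, list[TaggedRead]] = defaultdict(list)
    for rid in sorted(cluster.member_reads):
        r = reads[rid]
        by_species[r.species_code].append(r)
    out: dict[str, float | None] = {}
    for code, group in sorted(by_species.items()):
        if len(group) < 2:
            out[code] = None
            continue
        hits = find_similarity_hits(
            group, min_identity=min_identity, min_overlap=min_hit_length,
            seed_length=seed_length,
        )
        if not hits:
            out[code] = None
            continue
        lengths = {r.read_id: len(r.sequence) for r in group}
        values = [
            adjusted_similarity(h, lengths[h.read_a], lengths[h.read_b]) for h in hits
        ]
        out[code] = float(np.mean(values))
    return out


def _partner_sets(hits: Iterable[SimilarityHit]) -> dict[str, set[str]]:
    partners: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        partners[h.read_a].add(h.read_b)
        partners[h.read_b].add(h.read_a)
    return partners


def hs_ho(
    groups: Mapping[str, Sequence[TaggedRead]],
    hits: Mapping[str, Sequence[SimilarityHit]] | None = None,
    min_identity: float = 90.0,
    min_overlap: int = 55,
) -> tuple[list[HsHoRecord], dict[str, HsHoHistogram]]:
    """Hs/Ho records and log-ratio histograms per repeat group.

    ``groups`` maps a repeat-group label (reads pooled from clusters with
    the same annotation) to its species-tagged reads.  Hits may be supplied
    per group (computed at the comparative thresholds) or are computed
    here.  A hit counts as one distinct partner read regardless of how many
    local alignments the pair produced; self-hits never count.  Reads with
    Hs = 0 or Ho = 0 are excluded from the histogram and tallied.  A group
    with a single species is flagged (all Ho undefined).
    """
    records: list[HsHoRecord] = []
    histograms: dict[str, HsHoHistogram] = {}
    nbins = int(round((HISTOGRAM_RANGE[1] - HISTOGRAM_RANGE[0]) / HISTOGRAM_BIN_WIDTH))
    edges = np.linspace(*HISTOGRAM_RANGE, nbins + 1)
    for label, group_reads in sorted(groups.items()):
        species_of = {r.read_id: r.species_code for r in group_reads}
        n_by_species: dict[str, int] = defaultdict(int)
        for r in group_reads:
            n_by_species[r.species_code] += 1
        single_species = len(n_by_species) < 2
        if single_species:
            logger.warning("Hs/Ho group %r contains a single species; Ho undefined", label)
        group_hits = (
            hits[label]
            if hits is not None
            else find_similarity_hits(
                list(group_reads), min_identity=min_identity, min_overlap=min_overlap
            )
        )
        partners = _partner_sets(group_hits)
        total = sum(n_by_species.values())
        group_records: list[HsHoRecord] = []
        for r in group_reads:
            code = species_of[r.read_id]
            n_same = n_by_species[code] - 1  # excluding self
            n_other = total - n_by_species[code]
            mine = partners.get(r.read_id, set())
            same = sum(1 for p in mine if species_of[p] == code)
            other = len(mine) - same
            hs = same / n_same if n_same > 0 else None
            ho = other / n_other if n_other > 0 else None
            group_records.append(HsHoRecord(r.read_id, code, label, hs, ho))
        records.extend(group_records)
        ratios = [rec.log10_ratio for rec in group_records if rec.log10_ratio is not None]
        clamped = np.clip(ratios, *HISTOGRAM_RANGE) if ratios else np.zeros(0)
        n_clamped = int(np.sum((np.asarray(ratios) < HISTOGRAM_RANGE[0]) |
                               (np.asarray(ratios) > HISTOGRAM_RANGE[1]))) if ratios else 0
        if n_clamped:
            logger.info("Hs/Ho group %r: %d log-ratios clamped to histogram edges", label, n_clamped)
        counts, _ = np.histogram(clamped, bins=edges)
        histograms[label] = HsHoHistogram(
            repeat_group=label,
            bin_edges=edges,
            counts=counts,
            n_records=len(group_records),
            n_zero_hs=sum(1 for rec in group_records if rec.Hs == 0),
            n_zero_ho=sum(1 for rec in group_records if rec.Ho == 0),
            n_clamped=n_clamped,
            single_species=single_species,
        )
    return records, histograms


def hs_ho_restricted(
    groups: Mapping[str, Sequence[TaggedRead]],
    species_subset: Sequence[str],
    hits: Mapping[str, Sequence[SimilarityHit]] | None = None,
    min_identity: float = 90.0,
    min_overlap: int = 55,
) -> tuple[list[HsHoRecord], dict[str, HsHoHistogram]]:
    """Hs/Ho over a subset of species (e.g. one phylogenetic clade).

    Reads outside the subset are dropped before the computation, so Ho is
    restricted to the subset's other species.  Supplied hits are filtered
    to surviving read pairs.
    """
    subset = set(species_subset)
    if len(subset) < 2:
        raise ValueError("species_subset must contain at least 2 species")
    sub_groups = {
        label: [r for r in rs if r.species_code in subset]
        for label, rs in groups.items()
    }
    sub_groups = {label: rs for label, rs in sub_groups.items() if rs}
    sub_hits = None
    if hits is not None:
        sub_hits = {}
        for label, rs in sub_groups.items():
            keep = {r.read_id for r in rs}
            sub_hits[label] = [
                h for h in hits.get(label, []) if h.read_a in keep and h.read_b in keep
            ]
    return hs_ho(sub_groups, sub_hits, min_identity=min_identity, min_overlap=min_overlap)
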