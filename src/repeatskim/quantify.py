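"""Repeat abundance per species, class aggregation and replicate comparison.

The number of reads in a cluster is proportional to the genomic abundance
of the corresponding repeat, so a cluster's read proportion within one
species converts directly into a genome percentage and into Mbp per
monoploid genome (1Cx).  Repeat classes are hierarchical '/'-separated
paths (e.g. ``LTR/Ty3-gypsy/Ogre``, ``satellite/FabTR-2``); aggregation
sums abundances at any prefix depth and conserves totals.  All abundance
math uses 1Cx, so tetraploids are handled on the same scale as diploids.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from repeatskim.align import find_similarity_hits
from repeatskim.iolayer import SpeciesProfile, TaggedRead
from repeatskim.readcluster import ReadCluster

#: pg -> bp conversion for flow-cytometry genome sizes
BP_PER_PG = 0.978e9

#: pseudo-class for the non-repeat remainder, so per-species totals audit to 1
REMAINDER_CLASS = "singletons/low-copy"


@dataclass(frozen=True)
class AbundanceRecord:
    """Abundance of one repeat class in one species."""

    species_code: str
    repeat_class: str
    proportion: float

    @property
    def percent_genome(self) -> float:
        return 100.0 * self.proportion

    def mbp_per_1Cx(self, species: SpeciesProfile) -> float:
        return self.proportion * species.genome_size_1Cx / 1e6


def cluster_abundance(
    cluster: ReadCluster,
    species: SpeciesProfile,
    total_reads_analysed_for_species: int,
) -> AbundanceRecord:
    """Genome proportion of one cluster in one species.

    proportion = cluster reads of the species / total reads analysed for
    the species; Mbp/1Cx = proportion x 1Cx.
    """
    if total_reads_analysed_for_species <= 0:
        raise ValueError("total reads analysed must be positive")
    count = cluster.count_for(species.code)
    return AbundanceRecord(
        species_code=species.code,
        repeat_class=cluster.annotation or "unclassified",
        proportion=count / total_reads_analysed_for_species,
    )


def abundance_from_proportion(
    proportion: float, species: SpeciesProfile, repeat_class: str = "unclassified"
) -> AbundanceRecord:
    """AbundanceRecord straight from a known genome proportion."""
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    return AbundanceRecord(species.code, repeat_class, proportion)


def abundance_table(
    clusters: Sequence[ReadCluster],
    species_profiles: Mapping[str, SpeciesProfile],
    total_reads_by_species: Mapping[str, int],
    include_remainder: bool = True,
) -> list[AbundanceRecord]:
    """Per-(species, class) abundances from annotated clusters.

    Clusters sharing an annotation are summed.  The non-repeat remainder
    (1 - sum of cluster proportions) is emitted as the pseudo-class
    ``singletons/low-copy`` so that per-species proportions total 1.
    """
    acc: dict[tuple[str, str], float] = defaultdict(float)
    for c in clusters:
        for code, count in c.per_species_counts.items():
            if code not in species_profiles:
                raise KeyError(f"species {code!r} missing from the profile table")
            total = total_reads_by_species[code]
            acc[(code, c.annotation or "unclassified")] += count / total
    records = [
        AbundanceRecord(code, rclass, prop)
        for (code, rclass), prop in sorted(acc.items())
    ]
    if include_remainder:
        per_species = defaultdict(float)
        for r in records:
            per_species[r.species_code] += r.proportion
        for code in sorted(total_reads_by_species):
            if code in species_profiles:
                records.append(
                    AbundanceRecord(code, REMAINDER_CLASS, 1.0 - per_species[code])
                )
    return records


def class_at_level(repeat_class: str, level: int) -> str:
    return "/".join(repeat_class.split("/")[:level])


def aggregate_by_class(
    records: Sequence[AbundanceRecord], class_level: int
) -> list[AbundanceRecord]:
    """Sum abundances at a class-tree depth; conserves per-species totals."""
    if class_level < 1:
        raise ValueError("class_level must be >= 1")
    acc: dict[tuple[str, str], float] = defaultdict(float)
    for r in records:
        acc[(r.species_code, class_at_level(r.repeat_class, class_level))] += r.proportion
    return [
        AbundanceRecord(code, rclass, prop) for (code, rclass), prop in sorted(acc.items())
    ]


def records_frame(
    records: Sequence[AbundanceRecord],
    species_profiles: Mapping[str, SpeciesProfile] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "species_code": r.species_code,
            "repeat_class": r.repeat_class,
            "proportion": r.proportion,
            "percent_genome": r.percent_genome,
        }
        if species_profiles is not None:
            row["mbp_per_1Cx"] = r.mbp_per_1Cx(species_profiles[r.species_code])
        rows.append(row)
    return pd.DataFrame(rows)


def compare_replicates(
    records_run1: Sequence[AbundanceRecord],
    records_run2: Sequence[AbundanceRecord],
    group_level: int = 1,
) -> pd.DataFrame:
    """Per-class fold-differences between two runs of the same species.

    fold = max/min of the two abundances; classes present in only one run
    are flagged with fold = inf and excluded from the per-group means
    (column ``group`` truncates the class path at ``group_level``).
    """
    a = {(r.species_code, r.repeat_class): r.proportion for r in records_run1}
    b = {(r.species_code, r.repeat_class): r.proportion for r in records_run2}
    rows = []
    for key in sorted(set(a) | set(b)):
        p1, p2 = a.get(key), b.get(key)
        if p1 is None or p2 is None or min(p1, p2) == 0:
            fold = float("inf")
        else:
            fold = max(p1, p2) / min(p1, p2)
        rows.append(
            {
                "species_code": key[0],
                "repeat_class": key[1],
                "group": class_at_level(key[1], group_level),
                "proportion_run1": p1,
                "proportion_run2": p2,
                "fold": fold,
            }
        )
    return pd.DataFrame(rows)


def replicate_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Mean finite fold-difference per major repeat group."""
    finite = comparison[np.isfinite(comparison["fold"])]
    return (
        finite.groupby("group")["fold"]
        .agg(mean_fold="mean", max_fold="max", n="count")
        .reset_index()
    )


def genome_size_from_fcm(
    sample_g1_peak_mean: float,
    standard_g1_peak_mean: float,
    standard_2C_pg: float,
) -> tuple[float, float]:
    """Flow-cytometry genome size: (2C in pg, 2C in bp).

    2C pg = sample G1 peak mean x standard 2C pg / standard G1 peak mean;
    1 pg DNA = 0.978e9 bp.
    """
    if min(sample_g1_peak_mean, standard_g1_peak_mean, standard_2C_pg) <= 0:
        raise ValueError("peak means and standard 2C content must be positive")
    pg = sample_g1_peak_mean * standard_2C_pg / standard_g1_peak_mean
    return pg, pg * BP_PER_PG


def annotate_clusters(
    clusters: Sequence[ReadCluster],
    reads: Sequence[TaggedRead],
    reference_tiles: Sequence[TaggedRead],
    min_identity: float = 80.0,
    min_overlap: int = 55,
    label_map: Mapping[str, str] | None = None,
) -> list[ReadCluster]:
    """Label clusters by best cumulative similarity to a reference library.

    ``reference_tiles`` are pseudo-reads named ``REF:<family>:<i>`` (see
    :func:`repeatskim.simgenome.library_tiles`).  A cluster's score for a
    family is the summed identity x length over member-read/tile hits; the
    best family wins, ties (or no hits) give "unclassified".  ``label_map``
    optionally translates family ids into repeat-class paths.
    """
    id_to_read = {r.read_id: r for r in reads}
    member_of: dict[str, int] = {}
    for i, c in enumerate(clusters):
        for rid in c.member_reads:
            member_of[rid] = i
    pool = [id_to_read[rid] for rid in sorted(member_of)] + list(reference_tiles)
    hits = find_similarity_hits(pool, min_identity=min_identity, min_overlap=min_overlap)
    scores: list[dict[str, float]] = [defaultdict(float) for _ in clusters]
    for h in hits:
        ref, rid = None, None
        for x, y in ((h.read_a, h.read_b), (h.read_b, h.read_a)):
            if x.startswith("REF:"):
                ref, rid = x, y
        if ref is None or rid is None or rid.startswith("REF:"):
            continue
        ci = member_of.get(rid)
        if ci is None:
            continue
        family = ref.split(":", 2)[1]
        scores[ci][family] += h.identity * h.hit_length
    out = []
    for c, sc in zip(clusters, scores):
        if not sc:
            label = "unclassified"
        else:
            ranked = sorted(sc.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                label = "unclassified"
            else:
                fam = ranked[0][0]
                label = label_map.get(fam, fam) if label_map else fam
        out.append(_dc_replace(c, annotation=label))
    return out
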