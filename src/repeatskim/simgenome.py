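"""Multi-species repeatome simulator with exact ground truth.

Generates an ancestral repeat library (LTR retrotransposons with TG...CA
LTR termini and a PBS motif at the start of the internal region, satellite
monomers, dispersed repeats), evolves per-species copies under a
substitution-only model, assembles genomes by inserting copies into random
single-copy background, and samples tagged paired-end reads.  Every
insertion, junction and per-family bp total is recorded in a
:class:`TruthTable` so that downstream estimators (cluster abundance,
Hs/Ho, Rsf) can be scored against known values.

Evolution model: each species first applies a shared "lineage" substitution
pass to the ancestral sequence (making species variants diverge from each
other), then every copy is independently mutated at the per-copy divergence
rate.  Substitutions only; no indels, so alignment identities follow the
divergence rates analytically.  Solo-LTR formation is modeled as clean
intra-element recombination: the copy's 5' LTR is retained and the internal
region plus second LTR are excised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from repeatskim.align import revcomp
from repeatskim.iolayer import SpeciesProfile, TaggedRead, reads_for_coverage

#: genomic PBS sequence placed 3 bp downstream of the 5' LTR; reverse
#: complement of the 3' end of plant initiator-Met tRNA
DEFAULT_PBS_MOTIF = "TGGTATCAGAGC"
PBS_SPACER = 3

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _to_arr(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()

def _to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def random_sequence(n: int, rng: np.random.Generator, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _to_seq(rng.choice(4, size=n, p=p).astype(np.uint8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = _to_arr(seq)
    hit = np.nonzero((rng.random(arr.size) < rate) & (arr < 4))[0]
    if hit.size:
        # shift by 1-3 mod 4 guarantees a different base
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return _to_seq(arr)


VALID_KINDS = ("ltr_retrotransposon", "satellite", "dispersed_other")


@dataclass
class SimFamilySpec:
    """Specification of one simulated repeat family.

    ``divergence_per_species`` is the per-copy substitution rate (each copy
    mutated independently from the species template); ``lineage_divergence``
    is the shared per-species substitution pass applied once before copies
    are drawn, controlling how much species variants of the family differ
    from each other.  ``solo_fraction`` (LTR kind only) is the probability
    that a copy is reduced to a solo-LTR.  ``repeat_class`` is the
    hierarchical annotation label used for ground-truth cluster annotation.
    """

    family_id: str
    kind: str
    unit_length: int
    copies_per_species: Mapping[str, int]
    ltr_length: int = 0
    solo_fraction: Mapping[str, float] = field(default_factory=dict)
    divergence_per_species: Mapping[str, float] | float = 0.02
    lineage_divergence: Mapping[str, float] | float = 0.0
    repeat_class: str = ""
    satellite_array_size: int = 200
    pbs_motif: str = DEFAULT_PBS_MOTIF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"{self.family_id}: kind must be one of {VALID_KINDS}")
        if self.unit_length <= 0:
            raise ValueError(f"{self.family_id}: unit_length must be positive")
        if self.kind == "ltr_retrotransposon":
            if self.ltr_length < 34:
                raise ValueError(
                    f"{self.family_id}: ltr_length must be >= 34 (TG..CA termini plus a 30-nt tag)"
                )
            if self.unit_length <= 2 * self.ltr_length:
                raise ValueError(
                    f"{self.family_id}: unit_length must exceed 2 x ltr_length"
                )
            internal = self.unit_length - 2 * self.ltr_length
            if internal < PBS_SPACER + len(self.pbs_motif):
                raise ValueError(f"{self.family_id}: internal region too short for the PBS")
        elif self.solo_fraction:
            raise ValueError(f"{self.family_id}: solo_fraction is only meaningful for LTR kind")
        for code, f in dict(self.solo_fraction).items():
            if not 0 <= f <= 1:
                raise ValueError(f"{self.family_id}: solo_fraction[{code}] outside [0, 1]")
        for d in self._all_rates(self.divergence_per_species):
            if not 0 <= d <= 0.3:
                raise ValueError(f"{self.family_id}: divergence outside [0, 0.3]")
        if not self.repeat_class:
            self.repeat_class = {
                "ltr_retrotransposon": "LTR/unclassified",
                "satellite": "satellite",
                "dispersed_other": "dispersed",
            }[self.kind]

    @staticmethod
    def _all_rates(r) -> list[float]:
        return list(r.values()) if isinstance(r, Mapping) else [r]

    def rate_for(self, code: str, which: str = "copy") -> float:
        r = self.divergence_per_species if which == "copy" else self.lineage_divergence
        if isinstance(r, Mapping):
            return float(r.get(code, 0.0))
        return float(r)

    def copies_for(self, code: str) -> int:
        return int(self.copies_per_species.get(code, 0))

    def solo_fraction_for(self, code: str) -> float:
        return float(self.solo_fraction.get(code, 0.0))


@dataclass
class FamilySequences:
    """Ancestral sequences of one family."""

    family_id: str
    kind: str
    element: str = ""   # full element (LTR kinds / dispersed)
    ltr: str = ""
    internal: str = ""
    monomer: str = ""   # satellite

    @property
    def unit(self) -> str:
        return self.monomer if self.kind == "satellite" else self.element


@dataclass
class Insertion:
    family_id: str
    start: int
    end: int
    form: str      # full | solo | array | copy
    strand: str    # + | -


@dataclass
class FamilyTruth:
    family_id: str
    full_count: int = 0
    solo_count: int = 0
    bp: int = 0

    @property
    def solo_to_full(self) -> float:
        return self.solo_count / self.full_count if self.full_count else float("nan")


@dataclass
class TruthTable:
    """Exact ground truth for one simulated species genome."""

    species_code: str
    genome_length: int
    families: dict[str, FamilyTruth]
    insertions: list[Insertion]
    lu_junctions: dict[str, list[tuple[int, str]]]  # LTR_3'end/5'UTR boundaries

    def proportion(self, family_id: str) -> float:
        return self.families[family_id].bp / self.genome_length

    def background_bp(self) -> int:
        return self.genome_length - sum(f.bp for f in self.families.values())

    def to_frame(self):
        import pandas as pd
        rows = [
            {
                "species_code": self.species_code,
                "family_id": f.family_id,
                "full_count": f.full_count,
                "solo_count": f.solo_count,
                "bp": f.bp,
                "proportion": f.bp / self.genome_length,
            }
            for f in self.families.values()
        ]
        return pd.DataFrame(rows)


def _family_rng(seed: int, spec_seed: int, extra: Sequence[int] = ()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, spec_seed, *extra]))


def make_ancestral_library(
    specs: Sequence[SimFamilySpec], seed: int
) -> dict[str, FamilySequences]:
    """Deterministic ancestral sequence per family.

    LTR elements are ``LTR + internal + LTR`` with identical LTRs starting
    "TG" and ending "CA", and the PBS motif 3 bp into the internal region.
    """
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("family_ids must be unique")
    library: dict[str, FamilySequences] = {}
    for i, spec in enumerate(specs):
        rng = _family_rng(seed, spec.seed, (i,))
        if spec.kind == "ltr_retrotransposon":
            ltr = "TG" + random_sequence(spec.ltr_length - 4, rng) + "CA"
            internal_len = spec.unit_length - 2 * spec.ltr_length
            tail = internal_len - PBS_SPACER - len(spec.pbs_motif)
            internal = random_sequence(PBS_SPACER, rng) + spec.pbs_motif + random_sequence(tail, rng)
            library[spec.family_id] = FamilySequences(
                spec.family_id, spec.kind, element=ltr + internal + ltr,
                ltr=ltr, internal=internal,
            )
        elif spec.kind == "satellite":
            library[spec.family_id] = FamilySequences(
                spec.family_id, spec.kind, monomer=random_sequence(spec.unit_length, rng)
            )
        else:
            library[spec.family_id] = FamilySequences(
                spec.family_id, spec.kind, element=random_sequence(spec.unit_length, rng)
            )
    return library


def library_tiles(
    library: Mapping[str, FamilySequences], tile_length: int = 100, step: int = 50
) -> list[TaggedRead]:
    """Chop library sequences into overlapping tiles usable as annotation
    probes (pseudo-reads tagged with the reserved species code ``REF``)."""
    tiles: list[TaggedRead] = []
    for fam, seqs in library.items():
        seq = seqs.unit
        if seqs.kind == "satellite" and len(seq) < tile_length:
            reps = tile_length // len(seq) + 2
            seq = seq * reps
        for j, start in enumerate(range(0, max(1, len(seq) - tile_length + 1), step)):
            tiles.append(
                TaggedRead("REF", f"REF:{fam}:{j}", seq[start : start + tile_length])
            )
    return tiles


class GenomeSizingError(ValueError):
    pass


def build_species_genome(
    library: Mapping[str, FamilySequences],
    species: SpeciesProfile,
    specs: Sequence[SimFamilySpec],
    seed: int,
    target_length: int | None = None,
) -> tuple[str, TruthTable]:
    """Assemble one species genome and its exact truth table.

    Each inserted unit (full element, solo-LTR, satellite array or
    dispersed copy) lands at a distinct uniform position of the single-copy
    background so every element has flanking sequence; half the units go in
    on the minus strand.
    """
    target = int(target_length if target_length is not None else species.genome_size_1Cx)
    code = species.code
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, *(ord(c) for c in code)])
    )

    units: list[tuple[str, str, str]] = []  # (family_id, form, sequence)
    truth_fams: dict[str, FamilyTruth] = {}
    for spec in specs:
        n = spec.copies_for(code)
        if n <= 0:
            continue
        fam = library[spec.family_id]
        lin_rate = spec.rate_for(code, "lineage")
        copy_rate = spec.rate_for(code, "copy")
        template = mutate(fam.unit, lin_rate, rng)
        ft = FamilyTruth(spec.family_id)
        if spec.kind == "ltr_retrotransposon":
            solo_p = spec.solo_fraction_for(code)
            is_solo = rng.random(n) < solo_p
            for i in range(n):
                copy = mutate(template, copy_rate, rng)
                if is_solo[i]:
                    copy = copy[: spec.ltr_length]
                    units.append((spec.family_id, "solo", copy))
                    ft.solo_count += 1
                else:
                    units.append((spec.family_id, "full", copy))
                    ft.full_count += 1
                ft.bp += len(copy)
        elif spec.kind == "satellite":
            arrays = int(np.ceil(n / spec.satellite_array_size))
            per_array = [
                n // arrays + (1 if i < n % arrays else 0) for i in range(arrays)
            ]
            for cnt in per_array:
                arr_seq = "".join(mutate(template, copy_rate, rng) for _ in range(cnt))
                units.append((spec.family_id, "array", arr_seq))
                ft.full_count += cnt
                ft.bp += len(arr_seq)
        else:
            for _ in range(n):
                copy = mutate(template, copy_rate, rng)
                units.append((spec.family_id, "copy", copy))
                ft.full_count += 1
                ft.bp += len(copy)
        truth_fams[spec.family_id] = ft

    repeat_bp = sum(len(u[2]) for u in units)
    background_bp = target - repeat_bp
    if background_bp < max(1000, 10 * (len(units) + 1)):
        raise GenomeSizingError(
            f"{code}: requested repeat bp ({repeat_bp}) leaves too little background "
            f"in a {target} bp genome"
        )
    background = random_sequence(background_bp, rng)

    order = rng.permutation(len(units))
    positions = np.sort(rng.choice(background_bp - 1, size=len(units), replace=False) + 1)
    strands = np.where(rng.random(len(units)) < 0.5, "+", "-")

    parts: list[str] = []
    insertions: list[Insertion] = []
    lu_junctions: dict[str, list[tuple[int, str]]] = {}
    spec_by_id = {s.family_id: s for s in specs}
    prev = 0
    genome_pos = 0
    for idx, bg_pos in zip(order, positions):
        fam_id, form, seq = units[idx]
        strand = str(strands[idx])
        parts.append(background[prev:bg_pos])
        genome_pos += bg_pos - prev
        placed = seq if strand == "+" else revcomp(seq)
        start, end = genome_pos, genome_pos + len(placed)
        insertions.append(Insertion(fam_id, start, end, form, strand))
        if form == "full":
            ltr_len = spec_by_id[fam_id].ltr_length
            # LTR_3'end/5'UTR boundary of the 5' LTR, in genome coordinates
            if strand == "+":
                lu_junctions.setdefault(fam_id, []).append((start + ltr_len, "+"))
            else:
                lu_junctions.setdefault(fam_id, []).append((end - ltr_len, "-"))
        parts.append(placed)
        genome_pos += len(placed)
        prev = bg_pos
    parts.append(background[prev:])
    genome = "".join(parts)
    assert len(genome) == target

    truth = TruthTable(
        species_code=code,
        genome_length=len(genome),
        families=truth_fams,
        insertions=sorted(insertions, key=lambda x: x.start),
        lu_junctions=lu_junctions,
    )
    return genome, truth


def sample_reads(
    genome: str,
    species: SpeciesProfile | str,
    coverage: float,
    read_length: int = 100,
    insert_range: tuple[int, int] = (200, 400),
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[TaggedRead]:
    """Sample tagged paired-end reads at the requested fold coverage.

    Fragment starts are uniform; inserts uniform over ``insert_range``; the
    second mate is the reverse complement of the fragment end.  Read count
    is ``reads_for_coverage`` rounded up to an even number.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    imin, imax = insert_range
    if not (read_length <= imin <= imax < len(genome)):
        raise ValueError("need read_length <= min insert <= max insert < genome length")
    code = species.code if isinstance(species, SpeciesProfile) else str(species)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [seed & 0x7FFFFFFF, 0x5EAD, *(ord(c) for c in code)]
        )
    )
    n_reads = reads_for_coverage(len(genome), coverage, read_length)
    n_reads += n_reads % 2
    n_pairs = n_reads // 2
    garr = _to_arr(genome)
    inserts = rng.integers(imin, imax + 1, size=n_pairs)
    starts = rng.integers(0, len(genome) - inserts + 1)
    reads: list[TaggedRead] = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        fwd = _to_seq(garr[s : s + read_length])
        rev = revcomp(_to_seq(garr[s + ins - read_length : s + ins]))
        if error_rate > 0:
            fwd = mutate(fwd, error_rate, rng)
            rev = mutate(rev, error_rate, rng)
        serial = f"{i:07d}"
        n1 = f"{code}_{serial}/1"
        n2 = f"{code}_{serial}/2"
        reads.append(TaggedRead(code, n1, fwd, mate_id=n2))
        reads.append(TaggedRead(code, n2, rev, mate_id=n1))
    return reads
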