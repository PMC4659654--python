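"""Sequence and table I/O, species profiles, and the species-tag read codec.

Reads enter the pipeline as FASTA/FASTQ records whose names carry the
species of origin as a prefix tag (``<CODE>_<serial>/<mate>``), so that a
pooled multi-species read set remains attributable after clustering.
Genome sizes are handled internally in base pairs; Gbp/Mbp appear only at
presentation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("repeatskim")

TAG_SEPARATOR = "_"
MATE_SEPARATOR = "/"


class CodecError(ValueError):
    """Raised when a read name cannot be reconciled with the tag codec."""


@dataclass(frozen=True)
class SpeciesProfile:
    """A species entry: code, genome size and ploidy.

    ``genome_size_1C`` is the holoploid genome size in bp; the monoploid
    size (1Cx = 1C / (ploidy/2)) is the normalization constant for all
    abundance arithmetic and equals 1C exactly for diploids.
    """

    code: str
    genome_size_1C: int
    ploidy: int = 2
    chromosome_number: int | None = None

    def __post_init__(self) -> None:
        if not self.code or TAG_SEPARATOR in self.code or MATE_SEPARATOR in self.code:
            raise ValueError(
                f"species code {self.code!r} must be non-empty and must not "
                f"contain {TAG_SEPARATOR!r} or {MATE_SEPARATOR!r}"
            )
        if self.genome_size_1C <= 0:
            raise ValueError("genome_size_1C must be positive")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")

    @property
    def genome_size_1Cx(self) -> float:
        """Monoploid genome size in bp (1Cx = 1C for diploids)."""
        if self.ploidy == 2:
            return float(self.genome_size_1C)
        return self.genome_size_1C / (self.ploidy / 2)


@dataclass
class TaggedRead:
    """A read with its species of origin and optional mate linkage."""

    species_code: str
    read_id: str
    sequence: str
    mate_id: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def encode_read_name(species_code: str, serial: int | str, mate: int | None = None) -> str:
    """Serialize a read name carrying the species tag: ``CODE_serial[/mate]``."""
    if TAG_SEPARATOR in species_code:
        raise CodecError(f"species code {species_code!r} contains the tag separator")
    name = f"{species_code}{TAG_SEPARATOR}{serial}"
    if mate is not None:
        name += f"{MATE_SEPARATOR}{mate}"
    return name


def decode_read_name(name: str) -> tuple[str | None, str, int | None]:
    """Split a read name into (species_code, serial, mate).

    Returns ``species_code=None`` when the name carries no tag.  The codec
    round-trips: ``encode_read_name(*decode)`` reproduces the name.
    """
    body, mate = name, None
    if MATE_SEPARATOR in name:
        body, mate_str = name.rsplit(MATE_SEPARATOR, 1)
        if mate_str.isdigit():
            mate = int(mate_str)
        else:
            body = name
    if TAG_SEPARATOR in body:
        code, serial = body.split(TAG_SEPARATOR, 1)
        return code, serial, mate
    return None, body, mate


def mate_name(name: str) -> str | None:
    """Name of the mate of a paired read (1<->2), or None if unpaired."""
    code, serial, mate = decode_read_name(name)
    if mate not in (1, 2):
        return None
    other = 2 if mate == 1 else 1
    prefix = f"{code}{TAG_SEPARATOR}" if code is not None else ""
    return f"{prefix}{serial}{MATE_SEPARATOR}{other}"


_VALID_BASES = frozenset("ACGTN")


def read_sequences(
    path: str | Path,
    format: str = "fastq",
    known_codes: Sequence[str] | None = None,
    default_species: str | None = None,
) -> Iterator[TaggedRead]:
    """Stream TaggedReads from a FASTA/FASTQ file.

    The species tag is decoded from each read name; untagged reads get
    ``default_species``.  When ``known_codes`` is given, a tag outside it is
    an error.  Lowercase bases are upper-cased (logged once per file);
    characters outside {A,C,G,T,N} are a parse error.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}; expected 'fasta' or 'fastq'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    known = set(known_codes) if known_codes is not None else None
    warned_lowercase = False
    for i, record in enumerate(SeqIO.parse(str(path), format)):
        seq = str(record.seq)
        if seq != seq.upper():
            if not warned_lowercase:
                logger.warning("%s: lowercase bases found (record %s); upper-casing", path, record.id)
                warned_lowercase = True
            seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {i + 1} ({record.id}) contains invalid characters {sorted(bad)}"
            )
        code, _serial, mate = decode_read_name(record.id)
        if code is not None and known is not None and code not in known:
            raise CodecError(
                f"{path}: record {record.id} has unknown species tag {code!r}; "
                f"known codes: {sorted(known)}"
            )
        if code is None:
            code = default_species
            if code is None:
                raise CodecError(
                    f"{path}: record {record.id} carries no species tag and no "
                    "default species was configured"
                )
        yield TaggedRead(
            species_code=code,
            read_id=record.id,
            sequence=seq,
            mate_id=mate_name(record.id) if mate in (1, 2) else None,
        )


def write_reads_fastq(reads: Iterable[TaggedRead], path: str | Path, quality_char: str = "I") -> int:
    """Write reads as FASTQ with a constant quality string; returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> int:
    """Write (name, sequence) pairs as FASTA; returns count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def _to_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append(rec)
        elif hasattr(rec, "__dataclass_fields__"):
            rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
        else:
            raise TypeError(f"cannot tabulate record of type {type(rec)}")
    return pd.DataFrame(rows)


def write_table(records, path: str | Path, format: str = "tsv") -> None:
    """Write tabular results as TSV (tab-delimited, '.' decimal) or JSON.

    Values round-trip at full precision: floats are serialized with repr.
    An empty record list yields a header-only file (TSV) or ``[]`` (JSON).
    """
    df = _to_dataframe(records)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format=None)
    elif format == "json":
        payload = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
    else:
        raise ValueError(f"unsupported table format {format!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def reads_for_coverage(genome_size: float, coverage: float, read_length: int) -> int:
    """Number of reads of ``read_length`` nt giving ``coverage``-fold depth.

    count = round(genome_size * coverage / read_length); monotone
    non-decreasing in genome size and coverage.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    # round-half-away-from-zero, so 0.5 of a read counts as one
    return int(math.floor(genome_size * coverage / read_length + 0.5))


# ---------------------------------------------------------------------------
# species tables

SPECIES_TABLE_COLUMNS = ("code", "1C_bp", "ploidy")


def load_species_table(path: str | Path) -> dict[str, SpeciesProfile]:
    """Load a species table (TSV: code, 1C_bp, ploidy[, chromosomes])."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPECIES_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species table {path} lacks columns {missing}")
    profiles: dict[str, SpeciesProfile] = {}
    for _, row in df.iterrows():
        code = str(row["code"])
        if code in profiles:
            raise ValueError(f"duplicate species code {code!r} in {path}")
        chrom = None
        if "chromosomes" in df.columns and not pd.isna(row["chromosomes"]):
            chrom = int(row["chromosomes"])
        profiles[code] = SpeciesProfile(
            code=code,
            genome_size_1C=int(row["1C_bp"]),
            ploidy=int(row["ploidy"]),
            chromosome_number=chrom,
        )
    return profiles


def bundled_species_table() -> pd.DataFrame:
    """The bundled Fabeae panel: 23 legume species with flow-cytometry
    genome sizes and the read counts of their published sequencing runs."""
    ref = resources.files("repeatskim") / "data" / "fabeae_species.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def bundled_species_profiles() -> dict[str, SpeciesProfile]:
    df = bundled_species_table()
    return {
        str(r["code"]): SpeciesProfile(
            code=str(r["code"]), genome_size_1C=int(r["1C_bp"]), ploidy=int(r["ploidy"])
        )
        for _, r in df.iterrows()
    }
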