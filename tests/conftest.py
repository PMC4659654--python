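"""Shared fixtures: deterministic random sequences and small simulations."""

from __future__ import annotations

import numpy as np
import pytest

from repeatskim.iolayer import SpeciesProfile, TaggedRead
from repeatskim.simgenome import (
    SimFamilySpec,
    build_species_genome,
    make_ancestral_library,
    sample_reads,
)

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def mutate_seq(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    out = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        out[p] = BASES[(BASES.index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def reads_from_template(
    rng: np.random.Generator,
    template: str,
    n: int,
    read_length: int = 100,
    max_mut: int = 0,
    species: str = "X",
    prefix: str = "r",
    allow_reverse: bool = True,
) -> list[TaggedRead]:
    """Reads sampled from a template with optional mutations/orientation."""
    reads = []
    for i in range(n):
        s = int(rng.integers(0, len(template) - read_length + 1))
        seq = template[s : s + read_length]
        if max_mut:
            seq = mutate_seq(rng, seq, int(rng.integers(0, max_mut + 1)))
        if allow_reverse and rng.random() < 0.5:
            seq = rc(seq)
        reads.append(TaggedRead(species, f"{species}_{prefix}{i:04d}", seq))
    return reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ltr_sim():
    """One species with a solo-LTR-bearing family plus a satellite;
    genome, truth and two read sets (clustering subsample + deep set)."""
    code = "SIM"
    specs = [
        SimFamilySpec(
            "ltr1", "ltr_retrotransposon", 1200, {code: 1200}, ltr_length=250,
            solo_fraction={code: 0.5}, divergence_per_species=0.02,
            repeat_class="LTR/Ty3-gypsy/Ogre",
        ),
        SimFamilySpec(
            "satA", "satellite", 160, {code: 1200}, divergence_per_species=0.01,
            satellite_array_size=200, repeat_class="satellite",
        ),
    ]
    library = make_ancestral_library(specs, 77)
    profile = SpeciesProfile(code, 3_000_000)
    genome, truth = build_species_genome(library, profile, specs, 77)
    cluster_reads = sample_reads(genome, profile, 0.03, seed=78)
    deep_reads = sample_reads(genome, profile, 0.2, seed=79)
    return {
        "specs": specs, "library": library, "profile": profile,
        "genome": genome, "truth": truth,
        "cluster_reads": cluster_reads, "deep_reads": deep_reads,
    }
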