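"""Simulator: element anatomy, determinism, truth bookkeeping, read sampling."""

import numpy as np
import pytest

from repeatskim.align import revcomp
from repeatskim.iolayer import SpeciesProfile
from repeatskim.simgenome import (
    DEFAULT_PBS_MOTIF,
    GenomeSizingError,
    SimFamilySpec,
    build_species_genome,
    make_ancestral_library,
    sample_reads,
)


def _ltr_spec(code="SIM", copies=50, **kw):
    defaults = dict(
        family_id="fam", kind="ltr_retrotransposon", unit_length=1000,
        copies_per_species={code: copies}, ltr_length=200,
        divergence_per_species=0.0,
    )
    defaults.update(kw)
    return SimFamilySpec(**defaults)


class TestSpecValidation:
    def test_ltr_needs_room_for_two_ltrs(self):
        with pytest.raises(ValueError, match="unit_length"):
            _ltr_spec(unit_length=300, ltr_length=200)

    def test_solo_fraction_only_for_ltr_kind(self):
        with pytest.raises(ValueError, match="solo_fraction"):
            SimFamilySpec("s", "satellite", 30, {"SIM": 10}, solo_fraction={"SIM": 0.5})

    def test_divergence_range_checked(self):
        with pytest.raises(ValueError, match="divergence"):
            SimFamilySpec("d", "dispersed_other", 100, {"SIM": 1}, divergence_per_species=0.5)


class TestAncestralLibrary:
    def test_ltr_anatomy(self):
        lib = make_ancestral_library([_ltr_spec(unit_length=5000, ltr_length=400)], 1)
        fam = lib["fam"]
        el, ltr = fam.element, fam.ltr
        assert len(el) == 5000 and len(ltr) == 400
        # both LTR copies start TG and end CA
        assert el[:2] == "TG" and el[398:400] == "CA"
        assert el[4600:4602] == "TG" and el[-2:] == "CA"
        # PBS within 30 bp of the 5' LTR end
        pbs_at = el.find(DEFAULT_PBS_MOTIF, 400)
        assert 400 <= pbs_at <= 430

    def test_same_seed_identical_library(self):
        specs = [_ltr_spec(), SimFamilySpec("m", "satellite", 33, {"SIM": 5})]
        a = make_ancestral_library(specs, 9)
        b = make_ancestral_library(specs, 9)
        assert a["fam"].element == b["fam"].element
        assert a["m"].monomer == b["m"].monomer

    def test_satellite_monomer_length(self):
        lib = make_ancestral_library([SimFamilySpec("m", "satellite", 33, {"SIM": 5})], 2)
        assert len(lib["m"].monomer) == 33

    def test_duplicate_family_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_ancestral_library([_ltr_spec(), _ltr_spec()], 1)


class TestBuildGenome:
    def test_determinism_byte_identical(self):
        spec = _ltr_spec(divergence_per_species=0.03, solo_fraction={"SIM": 0.3})
        lib = make_ancestral_library([spec], 4)
        sp = SpeciesProfile("SIM", 400_000)
        g1, t1 = build_species_genome(lib, sp, [spec], 4)
        g2, t2 = build_species_genome(lib, sp, [spec], 4)
        assert g1 == g2
        assert t1.to_frame().equals(t2.to_frame())

    def test_zero_solo_fraction_gives_zero_solo_count(self):
        spec = _ltr_spec(solo_fraction={"SIM": 0.0})
        lib = make_ancestral_library([spec], 5)
        _, truth = build_species_genome(lib, SpeciesProfile("SIM", 300_000), [spec], 5)
        assert truth.families["fam"].solo_count == 0

    def test_zero_divergence_copies_identical_to_library(self):
        spec = _ltr_spec(copies=10)
        lib = make_ancestral_library([spec], 6)
        genome, truth = build_species_genome(lib, SpeciesProfile("SIM", 300_000), [spec], 6)
        el = lib["fam"].element
        for ins in truth.insertions:
            seg = genome[ins.start : ins.end]
            assert seg == el or seg == revcomp(el)

    def test_truth_bp_matches_genome_occupancy_exactly(self):
        specs = [
            _ltr_spec(divergence_per_species=0.05, solo_fraction={"SIM": 0.4}),
            SimFamilySpec("m", "satellite", 33, {"SIM": 500}, divergence_per_species=0.02),
        ]
        lib = make_ancestral_library(specs, 7)
        genome, truth = build_species_genome(lib, SpeciesProfile("SIM", 400_000), specs, 7)
        assert len(genome) == truth.genome_length == 400_000
        for fam, ft in truth.families.items():
            occupied = sum(
                i.end - i.start for i in truth.insertions if i.family_id == fam
            )
            assert occupied == ft.bp
        assert truth.background_bp() == 400_000 - sum(f.bp for f in truth.families.values())

    def test_divergence_005_pairwise_identity_90_to_91(self, rng):
        """Two lineages mutated independently at 5% per site leave ~90-91%
        pairwise identity (derived by aligning sampled copy pairs)."""
        spec = _ltr_spec(copies=40, divergence_per_species=0.05)
        lib = make_ancestral_library([spec], 8)
        genome, truth = build_species_genome(lib, SpeciesProfile("SIM", 300_000), [spec], 8)
        full = [i for i in truth.insertions if i.form == "full"][:12]
        idents = []
        for k in range(0, len(full) - 1, 2):
            a = genome[full[k].start : full[k].end]
            b = genome[full[k + 1].start : full[k + 1].end]
            if full[k].strand != full[k + 1].strand:
                b = revcomp(b)
            idents.append(np.mean([x == y for x, y in zip(a, b)]))
        assert 0.89 <= np.mean(idents) <= 0.92

    def test_oversized_repeat_request_raises(self):
        spec = _ltr_spec(copies=1000)  # 1000 x 1 kb in a 0.3 Mb genome
        lib = make_ancestral_library([spec], 9)
        with pytest.raises(GenomeSizingError):
            build_species_genome(lib, SpeciesProfile("SIM", 300_000), [spec], 9)


class TestSampleReads:
    def test_read_count_arithmetic(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 1_000_000))
        reads = sample_reads(genome, "SIM", 0.1, seed=1)
        assert len(reads) == 1000  # 1 Mbp x 0.1 / 100, already even
        assert len(reads) % 2 == 0

    def test_error_free_reads_match_genome(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        reads = sample_reads(genome, "SIM", 0.2, seed=2)
        for r in reads[:40]:
            assert r.sequence in genome or revcomp(r.sequence) in genome

    def test_mate_linkage_and_tags(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        reads = sample_reads(genome, "ABC", 0.1, seed=3)
        assert all(r.species_code == "ABC" for r in reads)
        by_id = {r.read_id: r for r in reads}
        for r in reads:
            assert by_id[r.mate_id].mate_id == r.read_id

    def test_mean_insert_near_300(self, rng):
        """Mates from one fragment imply the insert; the mean over >= 1000
        pairs should sit at the middle of the 200-400 range."""
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 600_000))
        reads = sample_reads(genome, "SIM", 0.4, seed=4)
        pairs = {}
        for r in reads:
            pairs.setdefault(r.read_id.rsplit("/", 1)[0], []).append(r)
        inserts = []
        for _, (r1, r2) in list(pairs.items())[:1200]:
            p1 = genome.find(r1.sequence)
            p2 = genome.find(revcomp(r2.sequence))
            if p1 >= 0 and p2 >= 0:
                inserts.append(p2 + 100 - p1)
        assert len(inserts) >= 1000
        assert abs(np.mean(inserts) - 300) <= 10

    def test_same_seed_identical_reads(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
        r1 = sample_reads(genome, "SIM", 0.1, seed=5)
        r2 = sample_reads(genome, "SIM", 0.1, seed=5)
        assert [(a.read_id, a.sequence) for a in r1] == [(b.read_id, b.sequence) for b in r2]

    def test_nonpositive_coverage_rejected(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        with pytest.raises(ValueError):
            sample_reads(genome, "SIM", 0.0)
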