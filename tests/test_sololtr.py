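"""Solo-LTR junction detection, validation, read counting and Rsf."""

import numpy as np
import pytest

from repeatskim.align import find_similarity_hits, revcomp
from repeatskim.iolayer import TaggedRead
from repeatskim.readcluster import ContigLayout, ReadPlacement, build_clusters, build_contigs
from repeatskim.simgenome import DEFAULT_PBS_MOTIF
from repeatskim.sololtr import (
    JunctionRejection,
    LTRJunctionModel,
    compute_rsf,
    count_junction_reads,
    detect_junction_candidates,
    estimate_rsf_for_cluster,
    validate_junction,
)

from conftest import random_seq


class TestComputeRsf:
    def test_all_full_length_means_zero(self):
        assert compute_rsf(100, 100).rsf == pytest.approx(0.0)

    def test_direct_formula(self):
        assert compute_rsf(100, 300).rsf == pytest.approx(2.0)

    def test_undefined_without_lu_reads(self):
        res = compute_rsf(0, 50)
        assert not res.defined
        assert res.formatted() == "-"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_rsf(-1, 5)


def _synthetic_contig(rng, ltr_len=120, utr_len=120, n_through=12, n_masked=12):
    """A consensus [LTR|5'UTR] layout: half the reads continue across the
    boundary, half stop there with masked (flank) tails."""
    ltr = random_seq(rng, ltr_len - 2) + "CA"
    # fixed spacer avoids a spurious CA right after the boundary
    utr = "GGT" + DEFAULT_PBS_MOTIF + random_seq(rng, utr_len - 15)
    cons = ltr + utr
    b = ltr_len
    placements = {}
    for i in range(n_through):
        off = b - 60 + (i % 7)
        placements[f"X_thru{i:02d}"] = ReadPlacement(off, +1, 100, (0, 100))
    for i in range(n_masked):
        off = b - 60 + (i % 7)
        aligned_end = b - off
        placements[f"X_mask{i:02d}"] = ReadPlacement(off, +1, 100, (0, aligned_end))
    for i in range(8):  # plain LTR-interior reads
        placements[f"X_ltr{i:02d}"] = ReadPlacement(i, +1, 100, (0, 100))
    cov = np.zeros(len(cons), dtype=int)
    for p in placements.values():
        cov[p.offset + p.aligned[0] : p.offset + p.aligned[1]] += 1
    return ContigLayout(consensus=cons, placements=placements, coverage=cov), b


class TestDetectCandidates:
    def test_hard_masking_boundary_detected_at_junction(self, rng):
        contig, b = _synthetic_contig(rng)
        cands = detect_junction_candidates(contig)
        assert len(cands) == 1
        assert abs(cands[0] - b) <= 2

    def test_uniform_contig_no_candidates(self, rng):
        cons = random_seq(rng, 300)
        placements = {
            f"X_{i:02d}": ReadPlacement(i * 20, +1, 100, (0, 100)) for i in range(11)
        }
        contig = ContigLayout(cons, placements, np.full(300, 5))
        assert detect_junction_candidates(contig) == []

    def test_low_coverage_columns_skipped(self, rng):
        contig, b = _synthetic_contig(rng)
        assert detect_junction_candidates(contig, min_coverage=100) == []


class TestValidateJunction:
    def test_ca_plus_pbs_accepted_with_tags(self, rng):
        contig, b = _synthetic_contig(rng)
        model = validate_junction(b, contig)
        assert isinstance(model, LTRJunctionModel)
        assert model.ltr3end_tag == contig.consensus[b - 30 : b]
        assert model.utr_tag == contig.consensus[b : b + 30]
        assert model.ltr3end_tag.endswith("CA")
        assert model.tg_ca_ok and model.pbs_ok

    def test_missing_ca_rejected(self, rng):
        contig, b = _synthetic_contig(rng)
        cons = contig.consensus[: b - 2] + "GG" + contig.consensus[b:]
        bad = ContigLayout(cons, contig.placements, contig.coverage)
        res = validate_junction(b, bad)
        assert isinstance(res, JunctionRejection) and res.reason == "tg_ca"

    def test_ca_without_pbs_rejected(self, rng):
        ltr = random_seq(rng, 118) + "CA"
        cons = ltr + random_seq(rng, 120)  # no PBS downstream
        contig = ContigLayout(cons, {}, np.zeros(len(cons), dtype=int))
        res = validate_junction(120, contig)
        assert isinstance(res, JunctionRejection) and res.reason == "pbs"

    def test_boundary_too_close_to_contig_end_untestable(self, rng):
        cons = random_seq(rng, 18) + "CA" + random_seq(rng, 200)
        contig = ContigLayout(cons, {}, np.zeros(len(cons), dtype=int))
        res = validate_junction(20, contig)
        assert isinstance(res, JunctionRejection) and res.reason == "tag-untestable"

    def test_boundary_snaps_to_nearby_ca(self, rng):
        contig, b = _synthetic_contig(rng)
        model = validate_junction(b + 2, contig)  # candidate off by 2 bp
        assert isinstance(model, LTRJunctionModel)
        assert model.boundary == b


class TestCountJunctionReads:
    def _model(self, rng):
        ltr_tag = random_seq(rng, 28) + "CA"
        utr_tag = random_seq(rng, 30)
        return LTRJunctionModel("fam", ltr_tag, utr_tag, 0, True, True), ltr_tag, utr_tag

    def test_adjacent_tags_count_lu_only(self, rng):
        model, ltr_tag, utr_tag = self._model(rng)
        read = TaggedRead("X", "X_0", random_seq(rng, 20) + ltr_tag + utr_tag + random_seq(rng, 20))
        assert count_junction_reads(model, [read]) == (1, 0)

    def test_ltr_tag_plus_flank_counts_lx_only(self, rng):
        model, ltr_tag, _ = self._model(rng)
        read = TaggedRead("X", "X_0", random_seq(rng, 30) + ltr_tag + random_seq(rng, 40))
        assert count_junction_reads(model, [read]) == (0, 1)

    def test_short_downstream_counts_neither(self, rng):
        # only 20 bp left after the tag: below the 30 bp requirement
        model, ltr_tag, _ = self._model(rng)
        read = TaggedRead("X", "X_0", random_seq(rng, 60) + ltr_tag + random_seq(rng, 20))
        assert count_junction_reads(model, [read]) == (0, 0)

    def test_reverse_complement_read_counted(self, rng):
        model, ltr_tag, utr_tag = self._model(rng)
        seq = random_seq(rng, 20) + ltr_tag + utr_tag + random_seq(rng, 20)
        read = TaggedRead("X", "X_0", revcomp(seq))
        assert count_junction_reads(model, [read]) == (1, 0)

    def test_three_tag_mismatches_tolerated_four_not(self, rng):
        model, ltr_tag, utr_tag = self._model(rng)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for n_mut, expected in ((3, 1), (4, 0)):
            tag = list(ltr_tag)
            for p in range(n_mut):
                tag[2 * p] = flip[tag[2 * p]]
            seq = random_seq(rng, 20) + "".join(tag) + utr_tag + random_seq(rng, 20)
            lu, _ = count_junction_reads(model, [TaggedRead("X", "X_0", seq)])
            assert lu == expected

    def test_species_filter(self, rng):
        model, ltr_tag, utr_tag = self._model(rng)
        seq = random_seq(rng, 20) + ltr_tag + utr_tag + random_seq(rng, 20)
        reads = [TaggedRead("A", "A_0", seq), TaggedRead("B", "B_0", seq)]
        assert count_junction_reads(model, reads, species_code="A") == (1, 0)


class TestEndToEndRecovery:
    def test_single_species_rsf_recovery(self, small_ltr_sim):
        """Full pipeline on one simulated genome (solo:full = 1): junction
        detected from cluster contigs, Rsf from deep reads near truth."""
        sim = small_ltr_sim
        reads = sim["cluster_reads"]
        hits = find_similarity_hits(reads)
        clusters, _ = build_clusters(hits, reads)
        # the LTR family is the largest cluster in this simulation
        contigs = build_contigs(clusters[0], reads, hits)
        res, models, _rej = estimate_rsf_for_cluster(
            contigs, sim["deep_reads"], "SIM", element_label="ltr1"
        )
        assert res is not None and res.defined
        ft = sim["truth"].families["ltr1"]
        truth = ft.solo_count / ft.full_count
        assert res.rsf == pytest.approx(truth, abs=0.5)
        assert models[0].ltr3end_tag.endswith("CA")
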