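"""Solo-LTR to full-length element ratio (Rsf) from junction-spanning reads.

Ectopic recombination between the two LTRs of a retrotransposon excises the
internal region and leaves a solo-LTR.  Short reads cannot span whole
elements, but they can span junctions: every full-length element carries
one LTR_3'end/5'UTR junction (the 3' end of its 5' LTR running into the
primer-binding site), while both full-length elements and solo-LTRs carry
an LTR_3'end/flank junction (an insertion site).  With LU = reads spanning
the LTR_3'end/5'UTR junction and Lx = reads with the LTR_3'end followed by
non-5'UTR sequence,

    E[LU] ~ N_full,   E[Lx] ~ N_full + N_solo,   Rsf = (Lx - LU)/LU ~ N_solo/N_full.

Rsf = 0 means all elements are full length; Rsf is coverage-invariant in
expectation because both counts scale linearly with coverage.

Junction models are found on cluster consensus contigs: an abrupt rise in
the fraction of reads whose alignment is masked downstream marks an
insertion-site boundary; candidates are accepted only with (i) the
conserved LTR terminal dinucleotide CA immediately 5' of the boundary and
(ii) a PBS (tRNA 3'-end complement) motif within the first 30 bp
downstream.  30-nt tags flanking the validated boundary are then matched
against raw reads (full tag placed in the read at >= 90% identity, i.e.
>= 27 of 30 positions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from repeatskim.align import encode_sequences, revcomp
from repeatskim.iolayer import TaggedRead
from repeatskim.readcluster import ContigLayout

logger = logging.getLogger("repeatskim")

TAG_LENGTH = 30
#: minimum matching positions of a placed 30-nt tag (90% of 30)
MIN_TAG_MATCHES = 27
#: minimum read bases downstream of the LTR_3'end tag for an Lx call
MIN_DOWNSTREAM = 30

#: 3'-terminal 12-mers of tRNAs usable as reverse-transcription primers;
#: the genomic PBS is the reverse complement of one of these
DEFAULT_TRNA_MOTIFS = (
    "GCTCTGATACCA",  # initiator-Met tRNA 3' end (plant consensus)
)
PBS_SEARCH_WINDOW = 30
PBS_MIN_MATCHES = 10  # of 12


@dataclass(frozen=True)
class LTRJunctionModel:
    """A validated LTR_3'end/5'UTR boundary with its two 30-nt tags."""

    element_label: str
    ltr3end_tag: str
    utr_tag: str
    boundary: int
    tg_ca_ok: bool
    pbs_ok: bool

    def __post_init__(self) -> None:
        if len(self.ltr3end_tag) != TAG_LENGTH or len(self.utr_tag) != TAG_LENGTH:
            raise ValueError("both junction tags must be exactly 30 nt")
        if self.tg_ca_ok and not self.ltr3end_tag.endswith("CA"):
            raise ValueError("tg_ca_ok requires the LTR_3'end tag to end in CA")


@dataclass(frozen=True)
class JunctionRejection:
    position: int
    reason: str  # tg_ca | pbs | tag-untestable | low-coverage


@dataclass(frozen=True)
class RsfResult:
    species_code: str
    element_label: str
    LU: int
    Lx: int

    @property
    def defined(self) -> bool:
        return self.LU > 0

    @property
    def rsf(self) -> float:
        return (self.Lx - self.LU) / self.LU if self.defined else float("nan")

    def formatted(self) -> str:
        return f"{self.rsf:.1f}" if self.defined else "-"


def detect_junction_candidates(
    contig: ContigLayout,
    low_threshold: float = 0.08,
    high_threshold: float = 0.15,
    window: int = 6,
    min_coverage: int = 5,
    min_masked_tail: int = 10,
) -> list[int]:
    """Candidate insertion-site boundaries on one contig.

    A read "terminates" at the last column of its aligned segment when at
    least ``min_masked_tail`` bases of the read continue masked beyond it
    (reads simply ending there do not count).  For a column c the masked
    fraction after is (terminations in [c, c+window)) / (reads covering c),
    and the fraction before uses the preceding window.  A candidate is
    called where the fraction after reaches ``high_threshold`` while the
    fraction before stays under ``low_threshold`` — an abrupt rise in
    masked read sequence, indicative of an insertion site; the boundary is
    placed just past the modal termination column inside the window.
    Columns with coverage below ``min_coverage`` are skipped.

    Operating point: at a genuine LTR-end boundary with no solo-LTRs at
    all, terminating (insertion-site) reads are roughly a quarter of the
    covering reads — continuing 5'-junction reads and internal-region
    reads make up the rest — while background columns terminate well under
    10% of covering reads; ``high_threshold = 0.15`` separates the two
    with margin, and solo-LTRs only raise the true signal.  The CA/PBS
    validation downstream removes false candidates this admits.
    """
    L = len(contig.consensus)
    cover = np.zeros(L + 1, dtype=np.int64)
    term = np.zeros(L + 1, dtype=np.int64)
    for p in contig.placements.values():
        a0, a1 = p.aligned
        if a1 <= a0:
            continue
        c0, c1 = p.offset + a0, p.offset + a1
        cover[c0] += 1
        cover[min(c1, L)] -= 1
        if p.masked_suffix >= min_masked_tail and c1 <= L:
            term[c1 - 1] += 1  # last aligned column before the masked tail
    coverage = np.cumsum(cover)[:L]
    term = term[:L]
    csum = np.concatenate([[0], np.cumsum(term)])

    def term_in(lo: int, hi: int) -> int:
        lo, hi = max(lo, 0), min(hi, L)
        return int(csum[hi] - csum[lo]) if hi > lo else 0

    candidates: list[int] = []
    c = window
    while c < L:
        cov = coverage[c]
        if cov < min_coverage:
            c += 1
            continue
        after = term_in(c, c + window) / cov
        before = term_in(c - window, c) / cov
        if after >= high_threshold and before < low_threshold:
            seg = term[c : c + window]
            peak = c + int(np.argmax(seg))
            # boundary = first masked column = one past the modal aligned end
            candidates.append(peak + 1)
            c = peak + window + 1
        else:
            c += 1
    return candidates


def validate_junction(
    candidate: int,
    contig: ContigLayout,
    trna_motifs: Sequence[str] = DEFAULT_TRNA_MOTIFS,
    element_label: str = "",
    snap: int = 5,
) -> LTRJunctionModel | JunctionRejection:
    """Validate a candidate boundary as an LTR_3'end/5'UTR junction.

    (i) the consensus must read "CA" immediately 5' of the boundary (the
    conserved LTR terminus; searched within ``snap`` bp of the candidate
    because the masked-fraction scan is only positionally accurate to a
    couple of bases), and (ii) the reverse complement of a tRNA 3'-end
    motif must match >= 10/12 positions within the first 30 bp downstream
    (the PBS).  Accepted models carry the two 30-nt tags adjacent to the
    boundary.
    """
    cons = contig.consensus
    boundary = None
    for delta in sorted(range(-snap, snap + 1), key=lambda x: (abs(x), x)):
        b = candidate + delta
        if 2 <= b <= len(cons) and cons[b - 2 : b] == "CA":
            boundary = b
            break
    if boundary is None:
        return JunctionRejection(candidate, "tg_ca")
    if boundary < TAG_LENGTH or boundary + TAG_LENGTH > len(cons):
        return JunctionRejection(candidate, "tag-untestable")
    downstream = cons[boundary : boundary + PBS_SEARCH_WINDOW]
    pbs_ok = any(
        _motif_matches(revcomp(m), downstream) for m in trna_motifs
    )
    if not pbs_ok:
        return JunctionRejection(candidate, "pbs")
    return LTRJunctionModel(
        element_label=element_label,
        ltr3end_tag=cons[boundary - TAG_LENGTH : boundary],
        utr_tag=cons[boundary : boundary + TAG_LENGTH],
        boundary=boundary,
        tg_ca_ok=True,
        pbs_ok=True,
    )


def _motif_matches(pbs: str, region: str, min_matches: int = PBS_MIN_MATCHES) -> bool:
    k = len(pbs)
    for off in range(0, len(region) - k + 1):
        window = region[off : off + k]
        if sum(a == b for a, b in zip(pbs, window)) >= min_matches:
            return True
    return False


def _tag_match_matrix(mat: np.ndarray, tag: str) -> np.ndarray:
    """Bool (n_reads x n_offsets): full tag placed at offset with >= 27/30
    matched positions."""
    tarr, _ = encode_sequences([tag])
    tarr = tarr[0]
    k = tarr.size
    if mat.shape[1] < k:
        return np.zeros((mat.shape[0], 0), dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)
    good = (win == tarr[None, None, :]) & (win < 4)
    return good.sum(axis=2) >= MIN_TAG_MATCHES


def count_junction_reads(
    model: LTRJunctionModel,
    reads: Sequence[TaggedRead],
    species_code: str | None = None,
) -> tuple[int, int]:
    """Count junction-spanning reads: (LU, Lx).

    LU: the read contains the LTR_3'end tag immediately followed by the
    5'UTR tag (proper order and orientation).  Lx: the read contains the
    LTR_3'end tag, at least 30 bp of read remain downstream, and that
    region has no 5'UTR-tag similarity.  Both strands are scanned (the
    reverse complement of a junction read shows the tags mirrored).  A read
    is counted once, with LU taking precedence.
    """
    if species_code is not None:
        reads = [r for r in reads if r.species_code == species_code]
    if not reads:
        return 0, 0
    seqs = [r.sequence for r in reads]
    mat, lengths = encode_sequences(seqs)
    matR, _ = encode_sequences([revcomp(s) for s in seqs])
    lu = np.zeros(len(reads), dtype=bool)
    lx = np.zeros(len(reads), dtype=bool)
    k = TAG_LENGTH
    for m in (mat, matR):
        ltr_hit = _tag_match_matrix(m, model.ltr3end_tag)
        utr_hit = _tag_match_matrix(m, model.utr_tag)
        n_off = ltr_hit.shape[1]
        for i in range(len(reads)):
            li = int(lengths[i])
            offs = np.nonzero(ltr_hit[i, : max(0, li - k + 1)])[0]
            for o in offs:
                end = o + k
                if end + k <= li and utr_hit[i, end]:
                    lu[i] = True
                elif li - end >= MIN_DOWNSTREAM:
                    # any 5'UTR-tag similarity downstream disqualifies Lx
                    down = utr_hit[i, end : max(end, min(n_off, li - k + 1))]
                    if not down.any():
                        lx[i] = True
    lx &= ~lu
    return int(lu.sum()), int(lx.sum())


def compute_rsf(LU: int, Lx: int, species_code: str = "", element_label: str = "") -> RsfResult:
    """Rsf = (Lx - LU)/LU; undefined (reported "-") when LU = 0."""
    if LU < 0 or Lx < 0:
        raise ValueError("junction read counts cannot be negative")
    if LU == 0:
        logger.info("Rsf undefined for %s/%s: no LTR_3'end/5'UTR reads", species_code, element_label)
    return RsfResult(species_code=species_code, element_label=element_label, LU=LU, Lx=Lx)


def estimate_rsf_for_cluster(
    contigs: Sequence[ContigLayout],
    reads: Sequence[TaggedRead],
    species_code: str,
    element_label: str = "",
    trna_motifs: Sequence[str] = DEFAULT_TRNA_MOTIFS,
    min_coverage: int = 5,
    **detect_kwargs,
) -> tuple[RsfResult | None, list[LTRJunctionModel], list[JunctionRejection]]:
    """End-to-end Rsf for one repeat cluster.

    Scans every contig for junction candidates, validates them, and counts
    junction reads for the best-supported accepted model (the one whose
    boundary has the highest contig coverage).  Returns (result or None if
    no model was accepted, accepted models, rejections).
    """
    from repeatskim.readcluster import flip_contig

    accepted: list[tuple[int, LTRJunctionModel]] = []
    rejections: list[JunctionRejection] = []
    for contig in contigs:
        # a junction is only visible with the LTR to the left of the
        # boundary, so scan the layout on both strands
        for oriented in (contig, flip_contig(contig)):
            for cand in detect_junction_candidates(oriented, min_coverage=min_coverage, **detect_kwargs):
                res = validate_junction(cand, oriented, trna_motifs, element_label=element_label)
                if isinstance(res, LTRJunctionModel):
                    cov = int(oriented.coverage[min(res.boundary, len(oriented.coverage) - 1)])
                    accepted.append((cov, res))
                else:
                    rejections.append(res)
    if not accepted:
        return None, [], rejections
    accepted.sort(key=lambda t: (-t[0], t[1].boundary))
    model = accepted[0][1]
    lu, lx = count_junction_reads(model, reads, species_code=species_code)
    return (
        compute_rsf(lu, lx, species_code=species_code, element_label=element_label),
        [m for _, m in accepted],
        rejections,
    )
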