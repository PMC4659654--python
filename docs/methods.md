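# Methods

`repeatskim` characterizes the repetitive fraction of unassembled genomes
from low-pass ("genome skimming") shotgun reads, compares repeat abundance
and sequence conservation across species, and estimates the ratio of
solo-LTRs to intact LTR retrotransposons. This note records the models,
the numerical choices, and what the bundled simulator does and does not
emulate.

## Similarity search and clustering

**Hit definition.** Two reads are similar when some ungapped local
alignment window between them (either orientation) is at least 55 bp long
with at least 90% identity — the operating point of mgblast-style read
comparison in graph-based repeat clustering. Identity is matches /
alignment columns; N never matches anything. The implementation works in
exact integer arithmetic (a window `[i, t)` qualifies iff
`100·mismatches ≤ (100 − pid)·(t − i)`), so threshold cases are decided
deterministically, not by float rounding.

**Seeding.** Candidate diagonals come from shared exact k-mers. A
qualifying window of length L at ≥ 90% identity contains at most
`floor(L/10)` mismatches and therefore an exact run of at least
`ceil((L − m)/(m + 1))` matching bases; minimizing over L ≥ 55 gives 8
(attained at L = 60, 70, 80). The default seed length is therefore **8**,
which makes the seeded search provably identical to exhaustive
all-diagonal evaluation at the default thresholds — verified against the
independent no-seeding reference (`align.exhaustive_hits`) in the test
suite. A longer seed would be faster but loses this guarantee.

**Canonical reporting.** Per (pair, orientation) one hit is reported:
among qualifying diagonals the one with the largest implied overlap
(ties: smaller absolute offset, then positive offset), and on it the
longest qualifying window (ties: leftmost). This makes outputs
byte-reproducible across runs and input orderings (up to the symmetric
mirror of each hit).

**Clusters** are connected components of the read-similarity graph,
numbered by decreasing size (ties: smallest member read id). Modularity
or other splitting is deliberately not applied by default. Mate pairs do
not create similarity edges; they join clusters into superclusters when
at least `min_shared_pairs` (default 5) pairs span two clusters. Cluster
size filters: ≥ 0.01% of the genome (per-species runs) or ≥ 0.005% of
analysed reads (comparative runs).

**Contig layout** is a greedy overlap-layout consensus: seed with the
highest-degree read, place neighbours by the longest remaining overlap
(first placement wins; all ties by read id), majority-vote consensus.
Two refinement details matter for junction work:

* *Leave-one-out masking.* A read's aligned segment is the longest window
  agreeing with the consensus at ≥ 90% where at least one *other* read
  supports the consensus base; otherwise a read that is the sole source of
  its own consensus columns (a private flank) would trivially "align".
* *Two-pass consensus with end trimming.* Masked flank bases are removed
  from the vote in a second pass, and aligned windows must open and close
  with an exact 4-base match run — a 90%-identity window can otherwise
  ride ~10 bp into a 25%-identity flank on the credit of a clean body,
  blurring junction positions.

## Repeat quantification

Cluster read counts are proportional to genomic abundance, so a cluster's
per-species read proportion converts directly to percent of the genome
and to Mbp per monoploid genome (`proportion × 1Cx`). All abundance math
uses 1Cx (equal to 1C for diploids), so a tetraploid enters the
genome-size statistics on the same scale as diploids; genome sizes are
held internally in bp and converted to Mbp/Gbp only for presentation.
Flow-cytometry sizes use `2C pg = sample G1 peak × standard 2C pg /
standard G1 peak` and 1 pg = 0.978 × 10⁹ bp. The non-repeat remainder is
always emitted as a `singletons/low-copy` pseudo-class so per-species
proportions audit to 1. Proportions are computed against reads entering
clustering (not reads surviving it); both denominators are logged.

Annotation assigns each cluster the repeat class of its best cumulative
similarity (summed identity × length over read-tile hits at ≥ 80%/55 bp)
against a reference library chopped into 100-nt tiles; ties give
`unclassified`. In validation runs the reference is the simulator's own
ancestral library.

## Cross-species conservation (Hs/Ho)

For each read within a pooled repeat group, `Hs` is the number of
distinct same-species reads it hits divided by the same-species group
size (excluding itself), and `Ho` the analogue over all other species.
Division by group sizes normalizes away copy-number differences between
species, so log10(Hs/Ho) ≈ 0 marks cross-species conserved repeats and
values ≫ 0 mark species-private variants. Choices the definition leaves
open: self-hits are excluded from numerator and denominator; a read pair
counts once however many local alignments it produced; reads with Hs = 0
or Ho = 0 are excluded from the histogram and tallied separately (a read
of a fully species-private family has no defined ratio); histograms use
0.1-wide bins on [−1, 4] with out-of-range values clamped to the edge
bins and counted.

Per-species average pairwise similarity inside a cluster uses a more
sensitive search (word size 7, hits ≥ 50 bp, identity floor 55% — well
below the 75–95% similarities the statistic is meant to resolve) and
rescales each hit by `hit_length / implied_overlap`, counting unmatched
overhang inside the implied read overlap as mismatch.

## Solo-LTR estimation (Rsf)

Ectopic recombination between an element's two LTRs excises the internal
region and leaves a solo-LTR. Junction accounting from short reads: every
full-length element carries one LTR_3'end→5'UTR junction (LU type) and
one LTR_3'end→flank junction (Lx type); a solo-LTR carries one Lx-type
junction only. Hence `E[LU] ∝ N_full`, `E[Lx] ∝ N_full + N_solo`, and

    Rsf = (Lx − LU) / LU  ≈  N_solo / N_full,

with Rsf = 0 exactly when all elements are intact. This double-counting
of full elements in Lx is the only accounting under which the Rsf = 0
anchor holds. Both counts scale linearly with coverage, so Rsf is
coverage-invariant in expectation.

Junction models are found on cluster contigs, where the two near-identical
LTR copies collapse onto one consensus whose downstream continuation is
mixed: internal sequence (from 5' LTRs) versus diverse flanks (from 3'
LTRs and solos). The masked-fraction scan (window 6 bp) calls a candidate
where ≥ 15% of covering reads terminate with masked tails while the
preceding window is below 8%; at a true boundary with *zero* solos the
terminating insertion-site reads are already ~a quarter of covering reads
while background columns stay below ~6%, so the operating point separates
the two with margin and any leakage is removed by validation. Candidates
are validated by (i) the conserved LTR terminal dinucleotide, "CA" on the
consensus immediately 5' of the boundary, searched within ±5 bp of the
candidate because the scan is positionally accurate only to a few bases,
and (ii) a PBS — the reverse complement of a tRNA 3'-end 12-mer (bundled
default: the plant initiator-Met motif whose genomic PBS reads
`TGGTATCAGAGC`) matching ≥ 10/12 within the first 30 bp downstream. Both
contig strands are scanned, since the junction is only visible with the
LTR left of the boundary; the mirror image at the LTR *start* is detected
too but always fails the PBS test, which is exactly the discrimination
the validation exists to provide.

Tag counting: the 30-nt tags flanking the boundary are matched against
raw reads as a full 30-mer placement with ≥ 27/30 positions matching
(= 90% of 30; both read strands scanned). A read is LU when both tags
match adjacently in order; Lx when the LTR_3'end tag matches, at least
30 bp of read remain downstream, and that region has no 5'UTR-tag match;
LU takes precedence. Keeping both window requirements symmetric (the full
tag inside the read, 30 bp needed on the far side in both cases — 41
eligible start positions each in a 100-nt read) is what makes the
estimator unbiased; admitting asymmetric 27-bp partial-tag overhangs
would bias Rsf by about −0.06·(1 + Rsf). LU = 0 yields an undefined
result, reported as "-".

## The simulator

`simgenome` generates the ground truth every estimator is scored against:
an ancestral library (LTR elements `LTR + internal + LTR` with TG…CA
termini and the PBS 3 bp into the internal region; satellite monomers;
dispersed repeats), per-species evolution, and genome assembly with every
insertion coordinate and junction recorded exactly.

Evolution is substitution-only in two tiers: a *lineage* pass applied
once per species (how far species variants drift apart — the knob behind
conserved-versus-private families) and an independent per-*copy* pass
(within-species family heterogeneity). No indels, so alignment identities
follow the rates analytically and the exact-window hit criterion stays
exact. Solo-LTR formation is clean intra-element recombination (the 5'
LTR retained, no target-site artifacts). Satellite copies are laid down
in tandem arrays; all units land at distinct uniform background positions
on random strands, so every element has flanking sequence. Background is
i.i.d. with 40% GC. Reads are 100-nt pairs from 200–400 bp fragments with
uniform starts, optional uniform per-base error, and species-tagged names
(`CODE_serial/mate`).

Not modeled, hence not probed by passing tests: indels and nested or
truncated insertions (available bias sources in real data), GC- and
fragmentation-bias of library preparation (the real driver of the
several-fold satellite quantification variance between replicate
libraries; here replicate variance is pure multinomial sampling, which
reproduces the satellite-versus-mobile ordering only because satellite
clusters are smaller), transposition dating, and phylogenetic structure
beyond star-shaped species divergence.

## Validation scenarios and problem sizes

The `validation` module pins the package's study conditions at desk
scale: three diploid species of ~10 Mbp rather than 23 species of
1.8–13.4 Gbp, sized so each estimator sees realistic per-repeat read
depths. The scenarios (used by both the test suite and
`scripts/acceptance.py`):

* *Panel arithmetic* — genome-size fold range, the 0.01x comparative read
  pool, run coverage, and %↔Mbp conversions over the bundled 23-species
  legume panel (flow-cytometry sizes and published run read counts).
* *Abundance recovery* — pooled comparative clustering at 0.05x over
  three 10-Mbp species carrying an LTR family (3%), a 33-bp satellite
  (2%) and a dispersed family (1.5%) at 2% copy divergence; per-family
  per-species proportions against truth, relative error averaged over 5
  simulations (single-draw sampling error at these depths is ~9–12%, so
  the 25% bound is assessed on the estimator mean, with the worst single
  draw also reported).
* *Oracle agreement* — 300 reads mixing family reads straddling the 90%
  boundary, tandem-repeat reads and random background; the seeded hit set
  must equal the exhaustive one exactly.
* *Rsf recovery* — one LTR family (6 000 insertion events, 1 200 bp unit,
  250 bp LTR, 2% divergence — a young, actively amplifying family, which
  is also the regime that dominates junction signal in real data) in a
  12-Mbp genome at solo:full ∈ {0, 0.5, 1, 2}; the junction model is
  built from a 0.015x skim and counted on a 0.2x read set; means over 5
  genomes per ratio (per-run σ ≈ 0.1–0.3, growing with the ratio).
* *Hs/Ho patterns* — a conserved element family (1% lineage divergence)
  against four satellite families at 9% lineage divergence with 160-bp
  monomers: within-species reads stay well above the 90% threshold while
  cross-species windows straddle it, giving the "mostly private with rare
  inter-specific hits" regime in which the ratio is large but defined;
  fully private families would have Ho = 0 and drop out entirely. The
  50:50 pooled mixture is tested for bimodality by comparing one- and
  two-component Gaussian mixture BICs on the log ratios.
* *Replicate variation* — two independent 0.05x samplings of one genome
  holding three large mobile families and six small satellite families;
  per-cluster fold differences versus class-level folds.

## Known limitations

Identity is ungapped; enabling indel evolution would require the gapped
alignment path and relaxes the seeding guarantee. Greedy layout is not a
string-graph assembler: long elements assemble as a single consensus only
at adequate depth, and tandem arrays produce phase-ambiguous layouts
(harmless for quantification, unusable for junctions — satellites carry
no LTR junctions). Junction detection needs the element cluster to reach
the coverage floor (default 5) at the boundary. Rsf inherits the
assumptions of the junction accounting: elements nested inside other
elements' internal regions blur Lx, and heavily truncated elements are
invisible to it.
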