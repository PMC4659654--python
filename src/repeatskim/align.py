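"""All-to-all read similarity search.

A similarity hit between two reads is an ungapped local alignment window of
length >= ``min_overlap`` with identity >= ``min_identity`` percent, in
either relative orientation.  The seeded search (:func:`find_similarity_hits`)
finds candidate diagonals through exact-match k-mer seeds and evaluates each
candidate diagonal exactly; :func:`exhaustive_hits` evaluates every diagonal
of every pair with no seeding and serves as the brute-force reference.

Seed-spacing guarantee: a qualifying window of length L >= 55 at >= 90%
identity contains at most floor(L/10) mismatches and therefore an exact-match
run of at least ceil((L - m)/(m + 1)) >= 8 consecutive bases (the minimum is
attained at L = 60, 70, 80).  With the default ``seed_length = 8`` every
qualifying diagonal is guaranteed to receive a seed, so the seeded search
returns exactly the hit set of the exhaustive scan.  N bases never match
anything, including other Ns.

Identity is computed as matches / alignment columns; with the default
substitution-only inputs there are no gap columns.  The reported hit for a
(pair, orientation) is canonical and deterministic: among qualifying
diagonals the one with the largest implied overlap (ties: smaller absolute
offset, then the positive offset), and on that diagonal the longest
qualifying window (ties: leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from repeatskim.iolayer import TaggedRead

# base encoding: A C G T N pad
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_PAD = 5
_COMP = np.array([3, 2, 1, 0, 4, _PAD], dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class SimilarityHit:
    """An ungapped local similarity between two reads.

    Spans are 0-based half-open intervals on each read in its own (input)
    orientation; ``orientation`` is "same" or "reverse".  One record is
    emitted per unordered pair and orientation; :meth:`mirror` gives the
    symmetric view.
    """

    read_a: str
    read_b: str
    identity: float
    hit_length: int
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    orientation: str

    def mirror(self) -> "SimilarityHit":
        return SimilarityHit(
            read_a=self.read_b, read_b=self.read_a, identity=self.identity,
            hit_length=self.hit_length, span_a=self.span_b, span_b=self.span_a,
            orientation=self.orientation,
        )


def encode_sequences(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a padded uint8 matrix plus a length vector."""
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int32, count=n)
    lmax = int(lengths.max()) if n else 0
    mat = np.full((n, lmax), _PAD, dtype=np.uint8)
    for i, s in enumerate(seqs):
        row = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
        mat[i, : lengths[i]] = row
    return mat, lengths


def _revcomp_matrix(mat: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    out = np.full_like(mat, _PAD)
    for i in range(mat.shape[0]):
        li = lengths[i]
        out[i, :li] = _COMP[mat[i, :li][::-1]]
    return out


def _kmer_table(mat: np.ndarray, lengths: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, read_index, position) for every N-free k-mer of every row."""
    n, lmax = mat.shape
    if lmax < k or n == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.astype(np.int32), z.astype(np.int32)
    win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)  # n x (lmax-k+1) x k
    valid = (win < 4).all(axis=2)
    npos = lmax - k + 1
    pos_ok = np.arange(npos)[None, :] <= (lengths[:, None] - k)
    valid &= pos_ok
    pow4 = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ pow4
    ridx, pidx = np.nonzero(valid)
    return codes[ridx, pidx], ridx.astype(np.int32), pidx.astype(np.int32)


def _pack(a, b, orient, diag, nreads: int, lmax: int) -> np.ndarray:
    span = 2 * lmax + 1
    return ((a.astype(np.int64) * nreads + b) * 2 + orient) * span + (diag + lmax)


def _unpack(key: np.ndarray, nreads: int, lmax: int):
    span = 2 * lmax + 1
    diag = (key % span) - lmax
    key //= span
    orient = key % 2
    key //= 2
    b = key % nreads
    a = key // nreads
    return a.astype(np.int32), b.astype(np.int32), orient.astype(np.int8), diag.astype(np.int32)


def _unique_int(arr: np.ndarray) -> np.ndarray:
    """Sorted unique values of an integer array (in-place sort based)."""
    if arr.size == 0:
        return arr
    arr = np.sort(arr)
    keep = np.empty(arr.size, dtype=bool)
    keep[0] = True
    np.not_equal(arr[1:], arr[:-1], out=keep[1:])
    return arr[keep]


def _group_slices(sorted_codes: np.ndarray):
    """Start/end boundaries of equal-value runs in a sorted array."""
    if sorted_codes.size == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64), sorted_codes[:0]
    change = np.nonzero(np.diff(sorted_codes))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [sorted_codes.size]])
    return starts, ends, sorted_codes[starts]


def _within_group_pairs(starts, ends, chunk_pairs: int):
    """Yield (i_idx, j_idx) entry-index arrays of all within-group pairs
    (i before j in the sorted table), vectorized and chunked."""
    sizes = ends - starts
    pair_counts = sizes * (sizes - 1) // 2
    order = np.arange(starts.size)
    total = 0
    batch: list[int] = []
    for gi in order:
        if pair_counts[gi] == 0:
            continue
        batch.append(gi)
        total += pair_counts[gi]
        if total >= chunk_pairs:
            yield _emit_group_pairs(starts[batch], ends[batch])
            batch, total = [], 0
    if batch:
        yield _emit_group_pairs(starts[batch], ends[batch])


def _emit_group_pairs(starts, ends):
    # per entry e (group g, rank r): pairs (e, e + 1 .. e + n_g - 1 - r)
    sizes = ends - starts
    entry_idx = np.concatenate([np.arange(s, e) for s, e in zip(starts, ends)])
    ranks = np.concatenate([np.arange(n) for n in sizes])
    counts = np.repeat(sizes, sizes) - ranks - 1
    total = int(counts.sum())
    i_idx = np.repeat(entry_idx, counts)
    block_start = np.cumsum(counts) - counts
    off = np.arange(total) - np.repeat(block_start, counts) + 1
    return i_idx, i_idx + off


def _cross_group_pairs(s1, e1, s2, e2, chunk_pairs: int):
    """Yield (i_idx in table1, j_idx in table2) for matched group pairs."""
    n2 = e2 - s2
    counts_per_group = (e1 - s1) * n2
    batch, total = [], 0
    for gi in range(s1.size):
        if counts_per_group[gi] == 0:
            continue
        batch.append(gi)
        total += counts_per_group[gi]
        if total >= chunk_pairs:
            yield _emit_cross_pairs(s1[batch], e1[batch], s2[batch], e2[batch])
            batch, total = [], 0
    if batch:
        yield _emit_cross_pairs(s1[batch], e1[batch], s2[batch], e2[batch])


def _emit_cross_pairs(s1, e1, s2, e2):
    sizes1 = e1 - s1
    sizes2 = e2 - s2
    entry1 = np.concatenate([np.arange(s, e) for s, e in zip(s1, e1)])
    counts = np.repeat(sizes2, sizes1)
    total = int(counts.sum())
    i_idx = np.repeat(entry1, counts)
    base2 = np.repeat(np.repeat(s2, sizes1), counts)
    block_start = np.cumsum(counts) - counts
    off = np.arange(total) - np.repeat(block_start, counts)
    return i_idx, base2 + off


def _seed_candidates(matF, matR, lengths, k: int, chunk_pairs: int = 6_000_000) -> np.ndarray:
    """Unique packed candidates (a < b, orientation, diagonal) from k-mer seeds.

    Same-orientation candidates come from forward-vs-forward seed matches;
    reverse-orientation candidates from forward-vs-reverse-complement
    matches, re-parameterized so the lower read index is always ``a`` in
    forward orientation.
    """
    nreads, lmax = matF.shape
    cf, rf, pf = _kmer_table(matF, lengths, k)
    cr, rr, pr = _kmer_table(matR, lengths, k)
    of = np.argsort(cf, kind="stable")
    cf, rf, pf = cf[of], rf[of], pf[of]
    orr = np.argsort(cr, kind="stable")
    cr, rr, pr = cr[orr], rr[orr], pr[orr]

    chunks: list[np.ndarray] = []

    def push(a, b, o, d):
        keep = a != b
        a, b, d = a[keep], b[keep], d[keep]
        if a.size:
            oarr = np.full(a.size, o, dtype=np.int64)
            chunks.append(_unique_int(_pack(a, b, oarr, d, nreads, lmax)))

    # forward vs forward: diagonal d = pos_a - pos_b with a < b
    fs, fe, fvals = _group_slices(cf)
    for ii, jj in _within_group_pairs(fs, fe, chunk_pairs):
        ra, rb, pa, pb = rf[ii], rf[jj], pf[ii], pf[jj]
        swap = ra > rb
        ra2 = np.where(swap, rb, ra)
        rb2 = np.where(swap, ra, rb)
        pa2 = np.where(swap, pb, pa)
        pb2 = np.where(swap, pa, pb)
        push(ra2, rb2, 0, (pa2 - pb2).astype(np.int64))
    # forward vs reverse-complement
    rs, re_, rvals = _group_slices(cr)
    common, fi, ri = np.intersect1d(fvals, rvals, return_indices=True)
    for ii, jj in _cross_group_pairs(fs[fi], fe[fi], rs[ri], re_[ri], chunk_pairs):
        r1, p1 = rf[ii], pf[ii]
        r2, p2 = rr[jj], pr[jj]
        # canonical frame: a = min index (forward), b = max index (revcomp'd)
        lo_first = r1 < r2
        a = np.where(lo_first, r1, r2)
        b = np.where(lo_first, r2, r1)
        # if r1 > r2 the alignment fwd(r1) vs rc(r2) is re-read as
        # fwd(r2) vs rc(r1):  pa = l2 - k - p2,  pb = l1 - k - p1
        d_direct = (p1 - p2).astype(np.int64)
        d_swapped = (lengths[r2] - p2) - (lengths[r1] - p1)
        d = np.where(lo_first, d_direct, d_swapped).astype(np.int64)
        push(a, b, 1, d)
    if not chunks:
        return np.zeros(0, dtype=np.int64)
    return _unique_int(np.concatenate(chunks))


def _overlap_bounds(d, la, lb):
    start = np.maximum(0, d)
    end = np.minimum(la, lb + d)
    return start, end


def _qualify(matF, matR, lengths, a, b, orient, d, pid: float, min_ov: int,
             chunk: int = 200_000) -> np.ndarray:
    """Exact qualification of candidate diagonals (vectorized, chunked)."""
    n = a.size
    out = np.zeros(n, dtype=bool)
    slack = 100.0 - pid
    need_matches = pid * min_ov  # 100*matches >= pid*min_ov
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        ca, cb, co, cd = a[lo:hi], b[lo:hi], orient[lo:hi], d[lo:hi]
        la, lb = lengths[ca], lengths[cb]
        s0, e0 = _overlap_bounds(cd, la, lb)
        lov = e0 - s0
        w = int(lov.max()) if lov.size else 0
        if w < min_ov:
            continue
        cols = np.arange(w, dtype=np.int32)
        apos = s0[:, None] + cols[None, :]
        valid = cols[None, :] < lov[:, None]
        aval = matF[ca[:, None], np.clip(apos, 0, matF.shape[1] - 1)]
        bpos = np.clip(apos - cd[:, None], 0, matF.shape[1] - 1)
        bval = np.empty_like(aval)
        same = co == 0
        if same.any():
            bval[same] = matF[cb[same][:, None], bpos[same]]
        if (~same).any():
            bval[~same] = matR[cb[~same][:, None], bpos[~same]]
        match = (aval == bval) & (aval < 4) & valid
        # prefilter: a qualifying window needs >= pid*min_ov/100 matches
        keep = np.nonzero(match.sum(axis=1) * 100 >= need_matches)[0]
        if keep.size == 0:
            continue
        mism_w = np.where(valid[keep], np.where(match[keep], 0, 100), 1_000_000).astype(np.int64)
        pm = np.cumsum(mism_w, axis=1)
        t = np.arange(1, w + 1, dtype=np.float64)
        c = np.concatenate(
            [np.zeros((keep.size, 1)), pm - slack * t[None, :]], axis=1
        )
        prefmax = np.maximum.accumulate(c, axis=1)
        qual = (c[:, min_ov:] <= prefmax[:, : w + 1 - min_ov] + 1e-9).any(axis=1)
        out[lo + keep] = qual
    return out


def _best_window(mism: np.ndarray, pid: float, min_ov: int):
    """Longest qualifying window on one diagonal (ties: leftmost).

    Returns (start, length, matches) relative to the overlap, or None.
    """
    L = mism.size
    if L < min_ov:
        return None
    slack = 100.0 - pid
    pm = np.concatenate([[0], np.cumsum(mism * 100)])
    c = pm - slack * np.arange(L + 1)
    m = np.maximum.accumulate(c)
    t = np.arange(min_ov, L + 1)
    # earliest i with prefix-max >= c[t]; window [i, t) qualifies if i <= t-min_ov
    i = np.searchsorted(m, c[t] - 1e-9, side="left")
    width = t - i
    ok = width >= min_ov
    if not ok.any():
        return None
    width = np.where(ok, width, -1)
    j = int(np.argmax(width))  # first maximal width -> leftmost end
    t_best, i_best = int(t[j]), int(i[j])
    length = t_best - i_best
    mm = int((pm[t_best] - pm[i_best]) // 100)
    return i_best, length, length - mm


def _canonical_order(lov, d):
    """np.lexsort keys preferring larger overlap, then smaller |d|, then d > 0.

    lexsort treats the LAST key as primary, so the keys run from least to
    most significant.
    """
    return (-np.sign(d), np.abs(d), -lov)


def _emit_hit(ids, matF, matR, lengths, a, b, orient, d, pid, min_ov):
    la, lb = int(lengths[a]), int(lengths[b])
    s0 = max(0, d)
    e0 = min(la, lb + d)
    av = matF[a, s0:e0]
    bcoords = (s0 - d, e0 - d)
    bm = matF if orient == 0 else matR
    bv = bm[b, bcoords[0]: bcoords[1]]
    mism = ~((av == bv) & (av < 4))
    best = _best_window(mism.astype(np.int64), pid, min_ov)
    if best is None:
        return None
    i, length, matches = best
    span_a = (s0 + i, s0 + i + length)
    bp0, bp1 = s0 + i - d, s0 + i + length - d  # in b' coordinates
    if orient == 0:
        span_b = (bp0, bp1)
        orientation = "same"
    else:
        span_b = (lb - bp1, lb - bp0)
        orientation = "reverse"
    return SimilarityHit(
        read_a=ids[a], read_b=ids[b],
        identity=100.0 * matches / length, hit_length=length,
        span_a=span_a, span_b=span_b, orientation=orientation,
    )


def find_similarity_hits(
    reads: Sequence[TaggedRead],
    min_identity: float = 90.0,
    min_overlap: int = 55,
    seed_length: int = 8,
) -> list[SimilarityHit]:
    """Every read pair (both orientations) with an ungapped local alignment
    of length >= ``min_overlap`` and identity >= ``min_identity`` percent.

    Self-hits are excluded.  One canonical hit is emitted per qualifying
    (unordered pair, orientation).  With ``seed_length <= 8`` the result is
    guaranteed identical to :func:`exhaustive_hits` at the default 90%/55 bp
    thresholds (see module docstring for the seed-spacing argument).
    """
    if not (0 < min_identity <= 100):
        raise ValueError("min_identity must be in (0, 100]")
    if min_overlap <= 0 or seed_length <= 0:
        raise ValueError("min_overlap and seed_length must be positive")
    if len(reads) == 0:
        return []
    ids = [r.read_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("read ids must be unique")
    matF, lengths = encode_sequences([r.sequence for r in reads])
    if matF.shape[1] < min_overlap:
        return []
    matR = _revcomp_matrix(matF, lengths)
    keys = _seed_candidates(matF, matR, lengths, seed_length)
    if keys.size == 0:
        return []
    a, b, orient, d = _unpack(keys.copy(), len(reads), matF.shape[1])
    s0, e0 = _overlap_bounds(d, lengths[a], lengths[b])
    lov = e0 - s0
    keep = lov >= min_overlap
    a, b, orient, d, lov = a[keep], b[keep], orient[keep], d[keep], lov[keep]
    if a.size == 0:
        return []
    qual = _qualify(matF, matR, lengths, a, b, orient, d, min_identity, min_overlap)
    a, b, orient, d, lov = a[qual], b[qual], orient[qual], d[qual], lov[qual]
    if a.size == 0:
        return []
    order = np.lexsort(_canonical_order(lov, d) + (orient, b, a))
    a, b, orient, d = a[order], b[order], orient[order], d[order]
    group = np.empty(a.size, dtype=bool)
    group[0] = True
    group[1:] = (np.diff(a) != 0) | (np.diff(b) != 0) | (np.diff(orient) != 0)
    hits: list[SimilarityHit] = []
    for idx in np.nonzero(group)[0]:
        h = _emit_hit(ids, matF, matR, lengths, int(a[idx]), int(b[idx]),
                      int(orient[idx]), int(d[idx]), min_identity, min_overlap)
        if h is not None:
            hits.append(h)
    return hits


# ---------------------------------------------------------------------------
# exhaustive reference (no seeding)

def exhaustive_hits(
    reads: Sequence[TaggedRead],
    min_identity: float = 90.0,
    min_overlap: int = 55,
) -> list[SimilarityHit]:
    """Brute-force reference: evaluate every diagonal of every read pair in
    both orientations, with no seeding.  Same hit definition and canonical
    reporting rule as :func:`find_similarity_hits`; intended for small read
    sets (hundreds) as the correctness oracle for the seeded search.
    """
    ids = [r.read_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("read ids must be unique")
    matF, lengths = encode_sequences([r.sequence for r in reads])
    if matF.size == 0 or matF.shape[1] < min_overlap:
        return []
    matR = _revcomp_matrix(matF, lengths)
    n = len(reads)
    lmax = matF.shape[1]
    slack = 100.0 - min_identity
    hits: list[SimilarityHit] = []
    for a in range(n):
        la = int(lengths[a])
        for b in range(a + 1, n):
            lb = int(lengths[b])
            # every diagonal whose implied overlap can reach min_overlap
            dall = np.arange(-(lb - min_overlap), la - min_overlap + 1, dtype=np.int64)
            s0, e0 = _overlap_bounds(dall, la, lb)
            lov = e0 - s0
            ok = lov >= min_overlap
            dall, s0, lov = dall[ok], s0[ok], lov[ok]
            if dall.size == 0:
                continue
            w = int(lov.max())
            cols = np.arange(w, dtype=np.int64)
            apos = s0[:, None] + cols[None, :]
            valid = cols[None, :] < lov[:, None]
            aval = matF[a, np.clip(apos, 0, lmax - 1)]
            bpos = np.clip(apos - dall[:, None], 0, lmax - 1)
            for orient, bmat in ((0, matF), (1, matR)):
                bval = bmat[b, bpos]
                match = (aval == bval) & (aval < 4) & valid
                wgt = np.where(valid, np.where(match, 0, 100), 1_000_000).astype(np.int64)
                pm = np.cumsum(wgt, axis=1)
                c = np.concatenate(
                    [np.zeros((dall.size, 1)),
                     pm - slack * np.arange(1, w + 1)[None, :]], axis=1)
                prefmax = np.maximum.accumulate(c, axis=1)
                qual = (c[:, min_overlap:] <= prefmax[:, : w + 1 - min_overlap] + 1e-9).any(axis=1)
                if not qual.any():
                    continue
                dq, lq = dall[qual], lov[qual]
                order = np.lexsort(_canonical_order(lq, dq))
                dbest = int(dq[order[0]])
                h = _emit_hit(ids, matF, matR, lengths, a, b, orient, dbest,
                              min_identity, min_overlap)
                if h is not None:
                    hits.append(h)
    return hits
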