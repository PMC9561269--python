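"""Internal seed-and-extend aligner and global identity scoring.

Stands in for an external long-read aligner at desk scale. Seeds are
minimizers (window minimum of hashed k-mer codes); candidate hits are
grouped by exact diagonal and verified by a vectorized gapless
extension (best-scoring contiguous segment under +match/-mismatch).
Indels therefore split an alignment into several diagonal segments --
exactly the representation downstream insertion placement consumes:
an insertion junction shows up as two chained segments whose contig
distance exceeds their reference distance.

:func:`global_identity` is the end-to-end identity used for sequence
content validation; it delegates the dynamic programming to
``Bio.Align.PairwiseAligner`` under this module's scoring scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import Align
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from ._dna import _mix64, encode, kmer_codes, revcomp

# scipy ndimage filters round-trip through float64; keep values <= 2**53
_SENTINEL = np.int64(2**53)


@dataclass
class AlignParams:
    seed_k: int = 15
    minimizer_window: int = 10
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    band_width: int = 200
    min_chain_seeds: int = 3
    min_alignment_length: int = 50
    min_identity: float = 0.70
    max_hits_per_seed: int = 100

    def __post_init__(self) -> None:
        if self.seed_k > 31:
            raise ValueError("seed_k must be <= 31")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")


@dataclass
class LocalAlignment:
    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str  # "+" or "-"
    score: int
    identity: float
    cigar: list[tuple[str, int]] = field(default_factory=list)
    proxy_mapq: int = 60

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


def _minimizer_positions(h: np.ndarray, w: int) -> np.ndarray:
    """Positions that are the minimum of at least one length-w window."""
    n = len(h)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if w <= 1 or n <= w:
        return np.nonzero(h < _SENTINEL)[0]
    # m[j] = min over the window starting at j (centered filter, shifted).
    mc = minimum_filter1d(h, size=w, mode="constant", cval=_SENTINEL)
    m = mc[w // 2 : w // 2 + n - w + 1]
    # i is a minimizer iff some window covering i attains h[i], i.e.
    # max_{j in [i-w+1, i]} m[j] == h[i] (since m[j] <= h[i] for i in W_j).
    bc = maximum_filter1d(m, size=w, mode="constant", cval=-_SENTINEL)
    idx = np.clip(np.arange(n) - (w - 1) // 2, 0, n - w)
    best = bc[idx]
    sel = (best == h) & (h < _SENTINEL)
    return np.nonzero(sel)[0]


def _hashed_codes(enc: np.ndarray, k: int) -> np.ndarray:
    codes, valid = kmer_codes(enc, k)
    # keep hashes strictly below the sentinel (52 usable bits)
    h = (_mix64(codes) >> np.uint64(12)).astype(np.int64)
    h[~valid] = _SENTINEL
    return h


class TargetIndex:
    """Minimizer index over a set of target sequences.

    Targets are concatenated with runs of N (which can never seed or
    extend a match) and indexed once; queries look seeds up via binary
    search on the sorted code array.
    """

    def __init__(self, targets: dict[str, str] | Iterable[tuple[str, str]], params: Optional[AlignParams] = None) -> None:
        self.params = params or AlignParams()
        items = list(targets.items()) if isinstance(targets, dict) else list(targets)
        self.names = [name for name, _ in items]
        sep = "N" * self.params.seed_k
        concat = sep.join(seq.upper() for _, seq in items)
        self.enc = encode(concat)
        self.offsets = np.zeros(len(items), dtype=np.int64)
        pos = 0
        for i, (_, seq) in enumerate(items):
            self.offsets[i] = pos
            pos += len(seq) + len(sep)
        self.lengths = np.array([len(seq) for _, seq in items], dtype=np.int64)
        h = _hashed_codes(self.enc, self.params.seed_k)
        mins = _minimizer_positions(h, self.params.minimizer_window)
        codes = h[mins]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = mins[order]

    def target_of(self, concat_pos: int) -> int:
        return int(np.searchsorted(self.offsets, concat_pos, side="right")) - 1


def _best_gapless_segment(
    mism: np.ndarray, match: int, mismatch: int
) -> tuple[int, int, int]:
    """Best-scoring contiguous segment of a +match/-mismatch profile.

    Returns (start, end, score) over the profile, end exclusive.
    """
    s = np.where(mism, mismatch, match).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(s)))
    mn = np.minimum.accumulate(cs)
    vals = cs[1:] - mn[:-1]
    end = int(np.argmax(vals))
    score = int(vals[end])
    target_min = mn[end]
    start = int(np.argmax(cs[: end + 1] == target_min))
    return start, end + 1, score


def seed_and_extend(
    query_id: str,
    query: str,
    index: TargetIndex,
    params: Optional[AlignParams] = None,
) -> list[LocalAlignment]:
    """Align a query against an indexed target set, both strands.

    Returns every diagonal segment passing the seed-count, length and
    identity thresholds, sorted by decreasing score. An exact substring
    of a target yields a full-length identity-1.0 alignment.
    """
    params = params or index.params
    k = params.seed_k
    nq = len(query)
    if nq < k:
        return []
    alignments: list[LocalAlignment] = []
    query = query.upper()
    for strand in "+-":
        qseq = query if strand == "+" else revcomp(query)
        qenc = encode(qseq)
        h = _hashed_codes(qenc, k)
        qmins = _minimizer_positions(h, params.minimizer_window)
        if len(qmins) == 0:
            continue
        qcodes = h[qmins]
        lo = np.searchsorted(index._codes, qcodes, side="left")
        hi = np.searchsorted(index._codes, qcodes, side="right")
        diags: list[np.ndarray] = []
        for qp, a, b in zip(qmins, lo, hi):
            if b - a == 0 or b - a > params.max_hits_per_seed:
                continue
            diags.append(index._pos[a:b] - qp)
        if not diags:
            continue
        alld = np.concatenate(diags)
        uniq, counts = np.unique(alld, return_counts=True)
        for d, cnt in zip(uniq, counts):
            if cnt < params.min_chain_seeds:
                continue
            i0 = int(max(0, -d))
            i1 = int(min(nq, len(index.enc) - d))
            if i1 - i0 < params.min_alignment_length:
                continue
            qwin = qenc[i0:i1]
            twin = index.enc[i0 + d : i1 + d]
            mism = (qwin != twin) | (qwin >= 4) | (twin >= 4)
            seg0, seg1, score = _best_gapless_segment(mism, params.match, params.mismatch)
            seglen = seg1 - seg0
            if seglen < params.min_alignment_length:
                continue
            matches = int(seglen - mism[seg0:seg1].sum())
            identity = matches / seglen
            if identity < params.min_identity:
                continue
            qs, qe = i0 + seg0, i0 + seg1
            ts, te = qs + int(d), qe + int(d)
            tix = index.target_of(ts)
            toff = int(index.offsets[tix])
            if te > toff + int(index.lengths[tix]):
                continue  # crosses a separator; mismatch run should prevent this
            if strand == "-":
                oqs, oqe = nq - qe, nq - qs
            else:
                oqs, oqe = qs, qe
            alignments.append(
                LocalAlignment(
                    query_id=query_id,
                    target_id=index.names[tix],
                    query_start=oqs,
                    query_end=oqe,
                    target_start=ts - toff,
                    target_end=te - toff,
                    strand=strand,
                    score=score,
                    identity=identity,
                    cigar=[("M", seglen)],
                )
            )
    alignments.sort(key=lambda a: (-a.score, a.target_id, a.target_start, a.strand))
    _assign_proxy_mapq(alignments)
    return alignments


def seed_and_extend_batch(
    queries: list[tuple[str, str]],
    index: TargetIndex,
    params: Optional[AlignParams] = None,
) -> dict[str, list[LocalAlignment]]:
    """Vectorized :func:`seed_and_extend` over many (id, sequence) queries.

    Semantically equivalent to aligning each query separately but all
    minimizer extraction and index lookups run as a handful of numpy
    operations over the whole batch -- the form used to recruit the
    hundreds of thousands of U reads onto orphan contigs.
    """
    params = params or index.params
    k = params.seed_k
    out: dict[str, list[LocalAlignment]] = {qid: [] for qid, _ in queries}
    usable = [(qid, q.upper()) for qid, q in queries if len(q) >= k]
    if not usable:
        return out
    sep = "N" * k
    for strand in "+-":
        seqs = [q if strand == "+" else revcomp(q) for _, q in usable]
        concat = sep.join(seqs)
        offsets = np.zeros(len(seqs), dtype=np.int64)
        pos = 0
        for i, s in enumerate(seqs):
            offsets[i] = pos
            pos += len(s) + k
        enc = encode(concat)
        h = _hashed_codes(enc, k)
        mins = _minimizer_positions(h, params.minimizer_window)
        codes = h[mins]
        lo = np.searchsorted(index._codes, codes, side="left")
        hi = np.searchsorted(index._codes, codes, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= params.max_hits_per_seed)
        mins, lo, counts = mins[keep], lo[keep], counts[keep]
        if len(mins) == 0:
            continue
        total = int(counts.sum())
        # ragged gather of index._pos[lo[i] : lo[i]+counts[i]]
        flat = (
            np.arange(total, dtype=np.int64)
            - np.repeat(np.cumsum(counts) - counts, counts)
            + np.repeat(lo, counts)
        )
        tpos = index._pos[flat]
        qpos_global = np.repeat(mins, counts)
        qidx = np.searchsorted(offsets, qpos_global, side="right") - 1
        qpos_local = qpos_global - offsets[qidx]
        diag = tpos - qpos_local
        # candidate = (query, diagonal) with enough supporting seeds
        key = qidx * np.int64(2**40) + (diag + np.int64(2**38))
        uniq, cnt = np.unique(key, return_counts=True)
        good = cnt >= params.min_chain_seeds
        nq_by_idx = [len(q) for _, q in usable]
        for u in uniq[good]:
            qi = int(u >> np.int64(40))
            d = int((u & np.int64(2**40 - 1)) - 2**38)
            qid = usable[qi][0]
            nq = nq_by_idx[qi]
            qoff = int(offsets[qi])
            aln = _verify_diagonal(
                enc[qoff : qoff + nq], nq, d, index, params, qid, strand
            )
            if aln is not None:
                out[qid].append(aln)
    for qid in out:
        out[qid].sort(key=lambda a: (-a.score, a.target_id, a.target_start, a.strand))
        _assign_proxy_mapq(out[qid])
    return out


def _verify_diagonal(
    qenc: np.ndarray,
    nq: int,
    d: int,
    index: TargetIndex,
    params: AlignParams,
    query_id: str,
    strand: str,
) -> Optional[LocalAlignment]:
    """Gapless verification of one (query, diagonal) candidate."""
    i0 = int(max(0, -d))
    i1 = int(min(nq, len(index.enc) - d))
    if i1 - i0 < params.min_alignment_length:
        return None
    qwin = qenc[i0:i1]
    twin = index.enc[i0 + d : i1 + d]
    mism = (qwin != twin) | (qwin >= 4) | (twin >= 4)
    seg0, seg1, score = _best_gapless_segment(mism, params.match, params.mismatch)
    seglen = seg1 - seg0
    if seglen < params.min_alignment_length:
        return None
    matches = int(seglen - mism[seg0:seg1].sum())
    identity = matches / seglen
    if identity < params.min_identity:
        return None
    qs, qe = i0 + seg0, i0 + seg1
    ts, te = qs + d, qe + d
    tix = index.target_of(ts)
    toff = int(index.offsets[tix])
    if te > toff + int(index.lengths[tix]):
        return None
    if strand == "-":
        oqs, oqe = nq - qe, nq - qs
    else:
        oqs, oqe = qs, qe
    return LocalAlignment(
        query_id=query_id,
        target_id=index.names[tix],
        query_start=oqs,
        query_end=oqe,
        target_start=ts - toff,
        target_end=te - toff,
        strand=strand,
        score=score,
        identity=identity,
        cigar=[("M", seglen)],
    )


def _assign_proxy_mapq(alignments: list[LocalAlignment]) -> None:
    """60 for a strictly unique best chain over its query span, 0 for ties."""
    for a in alignments:
        a.proxy_mapq = 60
        for b in alignments:
            if b is a or b.score < a.score:
                continue
            if b.score == a.score and b is not a:
                overlap = min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
                if overlap >= 0.5 * a.query_span:
                    a.proxy_mapq = 0
                    break
            elif b.score > a.score:
                overlap = min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
                if overlap >= 0.5 * a.query_span:
                    a.proxy_mapq = 0
                    break


def read_paf(path) -> list[LocalAlignment]:
    """Load alignments from a PAF file (external-aligner adapter).

    Lets an external long-read aligner stand in for the internal one:
    its PAF output feeds the same chaining/placement machinery.
    """
    out: list[LocalAlignment] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            matches, block = int(f[9]), int(f[10])
            out.append(
                LocalAlignment(
                    query_id=f[0],
                    target_id=f[5],
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    strand=f[4],
                    score=matches,
                    identity=matches / block if block else 0.0,
                    cigar=[("M", int(f[3]) - int(f[2]))],
                    proxy_mapq=int(f[11]),
                )
            )
    return out


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_identity(a: str, b: str, params: Optional[AlignParams] = None) -> float:
    """Identity (matches / alignment columns) of an end-to-end alignment.

    Strand is the caller's responsibility: reverse-complement one side
    first if orientations may differ.
    """
    if not a or not b:
        raise ValueError("global_identity requires two non-empty sequences")
    params = params or AlignParams()
    alignment = _aligner(params).align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns if columns else 0.0
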