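"""Lightweight local aligner (a blastn stand-in), hit filtering, and gapped
global alignment.

The local aligner is classic seed-and-extend: exact ``word_size`` seeds on
both strands, ungapped x-drop extension along the seed diagonal, then a
banded affine-gap (Gotoh) refinement around the extended segment.  Hits are
BLAST-tabular compatible, so externally computed blastn hits can substitute
the internal aligner anywhere downstream; the pipeline treats hit
provenance as opaque.

Scoring defaults mirror default blastn (+2/-3, gap open -5, extend -2,
word 11).  A gap of length L costs ``gap_open + L * gap_extend``.  N is
scored as a mismatch.  E-values use the ungapped Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with lambda = 1.33, K = 0.621 and
effective space ``|query| * db_length``; the length/identity filters
dominate in practice and the e-value scale is a documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp

import numpy as np
from numba import njit

from .seqio import AlignmentHit, InputError, Sequence, revcomp

KA_LAMBDA = 1.33
KA_K = 0.621

_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

NEG_INF = -(10 ** 9)


def encode(residues: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} to uint8 codes (N -> 4)."""
    return _CODE[np.frombuffer(residues.encode(), dtype=np.uint8)]


@dataclass
class AlignParams:
    """Scoring and search parameters for the blastn stand-in."""
    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: int = 20
    min_evalue: float = 10.0
    db_length: int = 0  # 0 -> subject length

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise InputError("word_size must be >= 4")
        if not (self.match > 0 and self.mismatch < 0):
            raise InputError("match must be positive, mismatch negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InputError("gap penalties must be <= 0")


@dataclass
class PairwiseAlignment:
    """A gapped global alignment as an ordered list of column pairs.

    Each column is ``(ref_pos | None, qry_pos | None)``; None marks a gap.
    Terminal columns with a gap on the query side are free end gaps
    (reference overhangs, i.e. truncations of the query).
    """
    ref_id: str
    qry_id: str
    columns: list[tuple[int | None, int | None]]
    score: float

    def identity(self) -> float:
        m = sum(1 for r, q in self.columns if r is not None and q is not None)
        return m / len(self.columns) if self.columns else 0.0


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _ungapped_extend(q, s, a0, a1, d, match, mismatch, xdrop):
    """Extend an exact anchor q[a0:a1] == s[a0+d:a1+d] along diagonal d.

    Returns (qa, qb, score, matches) for the best-scoring ungapped
    segment containing the anchor, with x-drop termination.
    """
    n = len(q)
    m = len(s)
    score = (a1 - a0) * match
    # right
    best = score
    qb = a1
    cur = score
    i = a1
    while i < n and i + d < m:
        if q[i] == s[i + d] and q[i] != 4:
            cur += match
        else:
            cur += mismatch
        i += 1
        if cur > best:
            best = cur
            qb = i
        if cur <= best - xdrop:
            break
    # left
    score = best
    best_l = score
    qa = a0
    cur = score
    i = a0
    while i > 0 and i + d > 0:
        i -= 1
        if q[i] == s[i + d] and q[i] != 4:
            cur += match
        else:
            cur += mismatch
        if cur > best_l:
            best_l = cur
            qa = i
        if cur <= best_l - xdrop:
            break
    matches = 0
    for i in range(qa, qb):
        if q[i] == s[i + d] and q[i] != 4:
            matches += 1
    return qa, qb, best_l, matches


@njit(cache=True)
def _banded_sw(a, b, dlo, dhi, match, mismatch, go, ge):
    """Smith-Waterman with affine gaps restricted to diagonals
    dlo <= j - i <= dhi (0-based sequence indices).

    Returns (score, ia, ib, ja, jb, path_a, path_b, path_len) where the
    path arrays hold 0-based positions or -1 for a gap, aligned columns
    in order, for the single best local alignment.
    """
    n = len(a)
    m = len(b)
    w = dhi - dlo + 3  # padded band width
    neg = -(10 ** 9)
    H = np.full((n + 1, w), neg, dtype=np.int64)
    E = np.full((n + 1, w), neg, dtype=np.int64)
    F = np.full((n + 1, w), neg, dtype=np.int64)
    # ptr: 0 stop, 1 diag, 2 fromE(left), 3 fromF(up); E/F openers tracked
    PH = np.zeros((n + 1, w), dtype=np.uint8)
    PE = np.zeros((n + 1, w), dtype=np.uint8)  # 1 = opened here
    PF = np.zeros((n + 1, w), dtype=np.uint8)

    best = 0
    bi = 0
    bj = 0
    for i in range(0, n + 1):
        jmin = i + dlo
        jmax = i + dhi
        if jmin < 0:
            jmin = 0
        if jmax > m:
            jmax = m
        for j in range(jmin, jmax + 1):
            k = j - (i + dlo) + 1  # band column
            if i == 0 or j == 0:
                H[i, k] = 0
                PH[i, k] = 0
                continue
            # E: gap in a (move left)
            e = neg
            if k - 1 >= 0:
                open_e = H[i, k - 1] + go + ge
                ext_e = E[i, k - 1] + ge
                if open_e >= ext_e:
                    e = open_e
                    PE[i, k] = 1
                else:
                    e = ext_e
                    PE[i, k] = 0
            E[i, k] = e
            # F: gap in b (move up); band shifts by one per row
            f = neg
            if k + 1 < w:
                open_f = H[i - 1, k + 1] + go + ge
                ext_f = F[i - 1, k + 1] + ge
                if open_f >= ext_f:
                    f = open_f
                    PF[i, k] = 1
                else:
                    f = ext_f
                    PF[i, k] = 0
            F[i, k] = f
            if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                sub = match
            else:
                sub = mismatch
            diag = H[i - 1, k] + sub  # (i-1, j-1) is same band column
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, k] = h
            PH[i, k] = p
            if h > best:
                best = h
                bi = i
                bj = j

    # traceback
    maxlen = n + m + 2
    pa = np.empty(maxlen, dtype=np.int64)
    pb = np.empty(maxlen, dtype=np.int64)
    L = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 2 in E, 3 in F
    while i > 0 and j > 0:
        k = j - (i + dlo) + 1
        if state == 0:
            p = PH[i, k]
            if p == 0:
                break
            if p == 1:
                pa[L] = i - 1
                pb[L] = j - 1
                L += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            pa[L] = -1
            pb[L] = j - 1
            L += 1
            opened = PE[i, k]
            j -= 1
            if opened == 1:
                state = 0
        else:
            pa[L] = i - 1
            pb[L] = -1
            L += 1
            opened = PF[i, k]
            i -= 1
            if opened == 1:
                state = 0
    # reverse
    ra = np.empty(L, dtype=np.int64)
    rb = np.empty(L, dtype=np.int64)
    for t in range(L):
        ra[t] = pa[L - 1 - t]
        rb[t] = pb[L - 1 - t]
    return best, i, bi, j, bj, ra, rb


@njit(cache=True)
def _gotoh_semiglobal(ref, qry, match, mismatch, go, ge):
    """Affine-gap global alignment with free end gaps on the query side.

    Rows index the reference, columns the query.  Terminal runs of
    reference positions aligned to nothing cost 0 (so query truncations
    surface as unaligned reference ends); all other gaps are affine.
    Returns (score, path_ref, path_qry) with -1 marking gaps; every
    reference and query position appears exactly once.
    """
    n = len(ref)
    m = len(qry)
    neg = -(10 ** 9)
    H = np.full((n + 1, m + 1), neg, dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in ref (left)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in qry (up)
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag 2 E 3 F 4 free-up
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    H[0, 0] = 0
    for i in range(1, n + 1):
        H[i, 0] = 0  # free leading gap in query
        PH[i, 0] = 4
    for j in range(1, m + 1):
        E[0, j] = go + j * ge
        H[0, j] = E[0, j]
        PH[0, j] = 2
        PE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_e = H[i, j - 1] + go + ge
            ext_e = E[i, j - 1] + ge
            if open_e >= ext_e:
                E[i, j] = open_e
                PE[i, j] = 1
            else:
                E[i, j] = ext_e
                PE[i, j] = 0
            open_f = H[i - 1, j] + go + ge
            ext_f = F[i - 1, j] + ge
            if open_f >= ext_f:
                F[i, j] = open_f
                PF[i, j] = 1
            else:
                F[i, j] = ext_f
                PF[i, j] = 0
            if ref[i - 1] == qry[j - 1] and ref[i - 1] != 4:
                sub = match
            else:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p

    # free trailing gap in query: best over last column
    best = H[n, m]
    bi = n
    for i in range(0, n + 1):
        if H[i, m] > best:
            best = H[i, m]
            bi = i

    maxlen = n + m + 2
    pa = np.empty(maxlen, dtype=np.int64)
    pb = np.empty(maxlen, dtype=np.int64)
    L = 0
    for i in range(n, bi, -1):  # unaligned reference tail
        pa[L] = i - 1
        pb[L] = -1
        L += 1
    i = bi
    j = m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 1:
                pa[L] = i - 1
                pb[L] = j - 1
                L += 1
                i -= 1
                j -= 1
            elif p == 4:  # free leading gap in query
                pa[L] = i - 1
                pb[L] = -1
                L += 1
                i -= 1
            elif p == 0:
                break
            else:
                state = p
        elif state == 2:
            pa[L] = -1
            pb[L] = j - 1
            L += 1
            opened = PE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            pa[L] = i - 1
            pb[L] = -1
            L += 1
            opened = PF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    ra = np.empty(L, dtype=np.int64)
    rb = np.empty(L, dtype=np.int64)
    for t in range(L):
        ra[t] = pa[L - 1 - t]
        rb[t] = pb[L - 1 - t]
    return best, ra, rb


# ---------------------------------------------------------------------------
# seeding

class SubjectIndex:
    """Exact k-mer index over both strands of a subject sequence."""

    def __init__(self, subject: Sequence, word_size: int):
        self.subject = subject
        self.word_size = word_size
        self.fwd = encode(subject.residues)
        self.rev = encode(revcomp(subject.residues))
        self.index = {"+": _kmer_index(self.fwd, word_size),
                      "-": _kmer_index(self.rev, word_size)}


def _kmer_index(codes: np.ndarray, k: int) -> dict[int, list[int]]:
    idx: dict[int, list[int]] = {}
    n = len(codes)
    if n < k:
        return idx
    key = 0
    valid = 0  # positions since last N
    mask = (1 << (2 * k)) - 1
    for i in range(n):
        c = codes[i]
        if c == 4:
            valid = 0
            key = 0
            continue
        key = ((key << 2) | int(c)) & mask
        valid += 1
        if valid >= k:
            idx.setdefault(key, []).append(i - k + 1)
    return idx


def _kmer_scan(codes: np.ndarray, k: int):
    """Yield (pos, key) for every N-free k-mer of a query."""
    n = len(codes)
    key = 0
    valid = 0
    mask = (1 << (2 * k)) - 1
    for i in range(n):
        c = codes[i]
        if c == 4:
            valid = 0
            key = 0
            continue
        key = ((key << 2) | int(c)) & mask
        valid += 1
        if valid >= k:
            yield i - k + 1, key


# ---------------------------------------------------------------------------
# public operations

def local_align(query: Sequence, subject: Sequence,
                params: AlignParams | None = None,
                index: SubjectIndex | None = None,
                exclude_self: bool = False) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of ``query`` against both strands
    of ``subject``.

    Returns hits sorted by descending score.  Sequences shorter than
    ``word_size`` produce an empty result.  With ``exclude_self`` the
    trivial self-diagonal of a self-comparison is skipped.
    """
    params = params or AlignParams()
    k = params.word_size
    if len(query) < k or len(subject) < k:
        return []
    if index is None:
        index = SubjectIndex(subject, k)
    elif index.word_size != k:
        raise InputError("index word_size differs from params.word_size")
    qcodes = encode(query.residues)
    m = len(subject)
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        scodes = index.fwd if strand == "+" else index.rev
        sidx = index.index[strand]
        # seed matches grouped by diagonal
        by_diag: dict[int, list[int]] = {}
        for qpos, key in _kmer_scan(qcodes, k):
            for spos in sidx.get(key, ()):
                d = spos - qpos
                if exclude_self and strand == "+" and d == 0:
                    continue
                by_diag.setdefault(d, []).append(qpos)
        # collapse overlapping/abutting seeds into exact anchors
        anchors: list[tuple[int, int, int]] = []  # (q0, q1, d)
        for d, positions in by_diag.items():
            positions.sort()
            run_s = positions[0]
            prev = positions[0]
            for p in positions[1:]:
                if p - prev <= k:
                    prev = p
                else:
                    anchors.append((run_s, prev + k, d))
                    run_s = p
                    prev = p
            anchors.append((run_s, prev + k, d))
        anchors.sort(key=lambda a: -(a[1] - a[0]))
        accepted: list[tuple[int, int, int, int]] = []  # q0,q1,s0,s1
        raw: list[tuple[int, float, int, int, int, int,
                        np.ndarray, np.ndarray]] = []
        for q0, q1, d in anchors:
            qm = (q0 + q1) // 2
            sm = qm + d
            covered = False
            for aq0, aq1, as0, as1 in accepted:
                if aq0 <= qm < aq1 and as0 <= sm < as1:
                    covered = True
                    break
            if covered:
                continue
            qa, qb, score, _ = _ungapped_extend(
                qcodes, scodes, q0, q1, d,
                params.match, params.mismatch, params.x_drop)
            # banded gapped refinement around the ungapped segment
            pad = max(params.x_drop, 2 * k)
            bw = params.x_drop // max(1, -params.gap_extend) + 2
            rq0 = max(0, qa - pad)
            rq1 = min(len(qcodes), qb + pad)
            rs0 = max(0, qa + d - pad)
            rs1 = min(m, qb + d + pad)
            A = qcodes[rq0:rq1]
            B = scodes[rs0:rs1]
            d_local = (rs0 - rq0)
            dlo = d - d_local - bw
            dhi = d - d_local + bw
            sc, _, _, _, _, pa, pb = _banded_sw(
                A, B, dlo, dhi, params.match, params.mismatch,
                params.gap_open, params.gap_extend)
            if len(pa) == 0:
                continue
            pa = np.where(pa >= 0, pa + rq0, -1)
            pb = np.where(pb >= 0, pb + rs0, -1)
            aligned_q = pa[pa >= 0]
            aligned_s = pb[pb >= 0]
            hq0 = int(aligned_q[0]) + rq0
            hq1 = int(aligned_q[-1]) + rq0 + 1
            hs0 = int(aligned_s[0]) + rs0
            hs1 = int(aligned_s[-1]) + rs0 + 1
            accepted.append((hq0, hq1, hs0, hs1))
            raw.append((sc, float(sc), hq0, hq1, hs0, hs1, pa, pb))

        # dedupe mutually overlapping refinements, best score first
        raw.sort(key=lambda r: (-r[0], r[2], r[4]))
        kept: list[tuple[int, int, int, int]] = []
        for sc, _, hq0, hq1, hs0, hs1, pa, pb in raw:
            dup = False
            for kq0, kq1, ks0, ks1 in kept:
                qov = min(hq1, kq1) - max(hq0, kq0)
                sov = min(hs1, ks1) - max(hs0, ks0)
                if (qov > 0.5 * (hq1 - hq0) and sov > 0.5 * (hs1 - hs0)):
                    dup = True
                    break
            if dup:
                continue
            kept.append((hq0, hq1, hs0, hs1))
            hit = _hit_from_path(query.id, subject.id, qcodes, scodes,
                                 strand, pa, pb, sc, params, m)
            if hit is not None:
                hits.append(hit)
    hits = [h for h in hits if h.evalue <= params.min_evalue]
    hits.sort(key=lambda h: (-h.score, h.q_start, h.s_start))
    return hits


def _hit_from_path(query_id, subject_id, qcodes, scodes, strand, pa, pb,
                   score, params, subject_len) -> AlignmentHit | None:
    matches = 0
    mism = 0
    gapo = 0
    in_gap = False
    for x, y in zip(pa, pb):
        if x < 0 or y < 0:
            if not in_gap:
                gapo += 1
                in_gap = True
            continue
        in_gap = False
        if qcodes[x] == scodes[y] and qcodes[x] != 4:
            matches += 1
        else:
            mism += 1
    ncols = len(pa)
    if ncols == 0:
        return None
    aligned_q = pa[pa >= 0]
    aligned_s = pb[pb >= 0]
    q0, q1 = int(aligned_q[0]), int(aligned_q[-1]) + 1
    s0, s1 = int(aligned_s[0]), int(aligned_s[-1]) + 1
    if strand == "-":  # map back to forward subject coordinates
        s0, s1 = subject_len - s1, subject_len - s0
    mlen = len(qcodes)
    nlen = params.db_length or subject_len
    evalue = KA_K * mlen * nlen * exp(-KA_LAMBDA * score)
    return AlignmentHit(query_id, subject_id, q0, q1, s0, s1, strand,
                        matches / ncols, ncols, float(score), evalue,
                        mism, gapo)


def filter_hits(hits: list[AlignmentHit], min_evalue: float = 1e-10,
                min_length: int = 90,
                min_identity: float = 0.90) -> list[AlignmentHit]:
    """Retain hits with evalue <= min_evalue, aln_length >= min_length and
    identity >= min_identity; boundaries inclusive, input order preserved.

    Defaults are the scaffolding/scoring thresholds used throughout:
    e-value 1e-10, 90 bp, 90% identity.
    """
    return [h for h in hits
            if h.evalue <= min_evalue
            and h.aln_length >= min_length
            and h.identity >= min_identity]


def global_align(ref: str, qry: str,
                 params: AlignParams | None = None,
                 ref_id: str = "ref", qry_id: str = "qry"
                 ) -> PairwiseAlignment:
    """Optimal affine-gap alignment of ``qry`` to the full ``ref``, with
    free end gaps on the query side (semi-global): a query shorter than
    the reference leaves unaligned reference ends rather than paying
    terminal gap penalties.
    """
    if not ref or not qry:
        raise InputError("global_align requires non-empty sequences")
    params = params or AlignParams()
    score, pa, pb = _gotoh_semiglobal(
        encode(ref), encode(qry), params.match, params.mismatch,
        params.gap_open, params.gap_extend)
    columns = [(int(x) if x >= 0 else None, int(y) if y >= 0 else None)
               for x, y in zip(pa, pb)]
    return PairwiseAlignment(ref_id, qry_id, columns, float(score))
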