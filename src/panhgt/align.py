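"""Pairwise alignment kernels.

All dynamic-programming cores used in the package live here: a global
affine-gap aligner with EMBOSS-style DNA defaults (used for the recent-HGT
similarity measure), a banded local aligner (used for fragment-based ANI),
a score-only local protein aligner (used for pan-genome edge weights) and a
profile-profile global aligner (used by the progressive MSA builder).

Conventions
-----------
* Gap penalties are positive numbers; a gap of length L costs
  ``gap_open + gap_ext * L`` (the opening charge is paid once, every gap
  column including the first pays the extension charge).
* DNA is encoded A=0 C=1 G=2 T=3, anything else (incl. N) = 4; code 4 never
  matches anything, so ambiguity characters score as mismatches.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DNA_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _DNA_LUT[ord(_c)] = _i
    _DNA_LUT[ord(_c.lower())] = _i

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_LUT = np.full(256, _AA_ALPHABET.index("X"), dtype=np.int8)
for _i, _c in enumerate(_AA_ALPHABET):
    _AA_LUT[ord(_c)] = _i
    _AA_LUT[ord(_c.lower())] = _i

NEG = -1e30


def encode_dna(seq: str) -> np.ndarray:
    return _DNA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_protein(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense array over the local residue encoding."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(_AA_ALPHABET), len(_AA_ALPHABET)), dtype=np.float64)
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            out[i, j] = m[a, b]
    return out


@njit(cache=False)
def _nw_affine(a, b, match, mismatch, gap_open, gap_ext):
    """Global affine-gap alignment (Gotoh) with traceback statistics.

    Returns (score, n_identical, n_aligned_pairs, alignment_length).
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    # pointers: 0 from M, 1 from X, 2 from Y
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_ext * i)
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_ext * j)
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] and a[i - 1] < 4 else mismatch
            best, ptr = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, ptr = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, ptr = Y[i - 1, j - 1], 2
            M[i, j] = best + s
            pM[i, j] = ptr
            o = M[i - 1, j] - gap_open - gap_ext
            e = X[i - 1, j] - gap_ext
            if o >= e:
                X[i, j] = o
                pX[i, j] = 0
            else:
                X[i, j] = e
                pX[i, j] = 1
            o = M[i, j - 1] - gap_open - gap_ext
            e = Y[i, j - 1] - gap_ext
            if o >= e:
                Y[i, j] = o
                pY[i, j] = 0
            else:
                Y[i, j] = e
                pY[i, j] = 2
    # traceback
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    i, j = n, m
    n_id = 0
    n_pairs = 0
    aln_len = 0
    while i > 0 or j > 0:
        aln_len += 1
        if state == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                n_id += 1
            n_pairs += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return score, n_id, n_pairs, aln_len


@njit(cache=False)
def _sw_banded(a, b, off, band, match, mismatch, gap_open, gap_ext):
    """Banded local affine alignment of a (query) against b (target).

    Cells are restricted to target positions j with |(j - i) - off| <= band.
    Returns (score, n_identical, n_aligned_pairs, alignment_length,
    query_span) for the best local alignment inside the band.
    """
    n, m = len(a), len(b)
    w = 2 * band + 1
    # rolling two-row score buffers; full pointer matrices for the traceback
    Hp = np.zeros(w + 2)
    Xp = np.full(w + 2, NEG)
    Yp = np.full(w + 2, NEG)
    Hc = np.zeros(w + 2)
    Xc = np.full(w + 2, NEG)
    Yc = np.full(w + 2, NEG)
    pH = np.zeros((n + 1, w + 2), dtype=np.int8)  # 0 stop,1 diag M,2 diag X,3 diag Y
    pX = np.zeros((n + 1, w + 2), dtype=np.int8)
    pY = np.zeros((n + 1, w + 2), dtype=np.int8)
    best = 0.0
    bi, bk = 0, 0
    # j = i + off + (k - band - 1), k in [1, w]
    for i in range(1, n + 1):
        Hc[0] = 0.0
        Xc[0] = NEG
        Yc[0] = NEG
        Hc[w + 1] = 0.0
        Xc[w + 1] = NEG
        Yc[w + 1] = NEG
        for k in range(1, w + 1):
            j = i + off + (k - band - 1)
            if j < 1 or j > m:
                # H = 0 keeps fresh local starts legal across the j = 0
                # boundary (and through the band edge); X/Y stay closed.
                Hc[k] = 0.0
                Xc[k] = NEG
                Yc[k] = NEG
                continue
            s = match if a[i - 1] == b[j - 1] and a[i - 1] < 4 else mismatch
            # diagonal predecessor is same k at i-1
            d = Hp[k]
            ptr = 1
            if Xp[k] > d:
                d, ptr = Xp[k], 2
            if Yp[k] > d:
                d, ptr = Yp[k], 3
            h = d + s
            if h < 0.0:
                h, ptr = 0.0, 0
            Hc[k] = h
            pH[i, k] = ptr
            # gap consuming a: (i-1, j) -> k+1 at row i-1
            o = Hp[k + 1] - gap_open - gap_ext
            e = Xp[k + 1] - gap_ext
            if o >= e:
                Xc[k] = o
                pX[i, k] = 0
            else:
                Xc[k] = e
                pX[i, k] = 1
            # gap consuming b: (i, j-1) -> k-1 at row i
            o = Hc[k - 1] - gap_open - gap_ext
            e = Yc[k - 1] - gap_ext
            if o >= e:
                Yc[k] = o
                pY[i, k] = 0
            else:
                Yc[k] = e
                pY[i, k] = 2
            if h > best:
                best = h
                bi, bk = i, k
        Hp, Hc = Hc, Hp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    # traceback from best H cell
    n_id = 0
    n_pairs = 0
    aln_len = 0
    i, k = bi, bk
    i_end = bi
    state = 0  # in H
    while i > 0:
        if state == 0:
            ptr = pH[i, k]
            if ptr == 0:
                break
            j = i + off + (k - band - 1)
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                n_id += 1
            n_pairs += 1
            aln_len += 1
            if ptr == 2:
                state = 1
            elif ptr == 3:
                state = 2
            i -= 1
        elif state == 1:  # X: gap in b, consumes a
            aln_len += 1
            nxt = pX[i, k]
            i -= 1
            k += 1
            state = 0 if nxt == 0 else 1
        else:  # Y: gap in a, consumes b
            aln_len += 1
            nxt = pY[i, k]
            k -= 1
            state = 0 if nxt == 0 else 2
    return best, n_id, n_pairs, aln_len, i_end - i


@njit(cache=False)
def _sw_protein_score(a, b, submat, gap_open, gap_ext):
    """Score-only local alignment with a substitution matrix (Gotoh)."""
    n, m = len(a), len(b)
    Hprev = np.zeros(m + 1)
    Xprev = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        H = np.zeros(m + 1)
        X = np.full(m + 1, NEG)
        y = NEG
        for j in range(1, m + 1):
            d = Hprev[j - 1] + submat[a[i - 1], b[j - 1]]
            x = max(Hprev[j] - gap_open - gap_ext, Xprev[j] - gap_ext)
            y = max(H[j - 1] - gap_open - gap_ext, y - gap_ext)
            h = max(0.0, d, x, y)
            H[j] = h
            X[j] = x
            if h > best:
                best = h
        Hprev = H
        Xprev = X
    return best


@njit(cache=False)
def _nw_profile(score, gap_open, gap_ext):
    """Global affine alignment over a precomputed column-score matrix.

    ``score[i, j]`` is the score of aligning column i of profile A with
    column j of profile B. Returns an int8 op array (0 = match columns,
    1 = gap in B / consume A column, 2 = gap in A / consume B column) in
    alignment order.
    """
    n, m = score.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_ext * i)
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_ext * j)
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, ptr = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, ptr = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, ptr = Y[i - 1, j - 1], 2
            M[i, j] = best + score[i - 1, j - 1]
            pM[i, j] = ptr
            o = M[i - 1, j] - gap_open - gap_ext
            e = X[i - 1, j] - gap_ext
            if o >= e:
                X[i, j], pX[i, j] = o, 0
            else:
                X[i, j], pX[i, j] = e, 1
            o = M[i, j - 1] - gap_open - gap_ext
            e = Y[i, j - 1] - gap_ext
            if o >= e:
                Y[i, j], pY[i, j] = o, 0
            else:
                Y[i, j], pY[i, j] = e, 2
    state = 0
    s = M[n, m]
    if X[n, m] > s:
        s, state = X[n, m], 1
    if Y[n, m] > s:
        s, state = Y[n, m], 2
    ops = np.empty(n + m, dtype=np.int8)
    t = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[t] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[t] = 1
            state = pX[i, j]
            i -= 1
        else:
            ops[t] = 2
            state = pY[i, j]
            j -= 1
        t += 1
    return ops[:t][::-1].copy()


# ---------------------------------------------------------------------------
# Python-level convenience wrappers
# ---------------------------------------------------------------------------

def global_dna_alignment_stats(
    seq_a: str,
    seq_b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_ext: float = 0.5,
) -> tuple[float, int, int, int]:
    """Global DNA alignment with EMBOSS needle DNA defaults.

    Returns (score, n_identical, n_aligned_pairs, alignment_length).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    return _nw_affine(encode_dna(seq_a), encode_dna(seq_b), match, mismatch, gap_open, gap_ext)


def global_protein_alignment_stats(
    seq_a: str,
    seq_b: str,
    submat: np.ndarray | None = None,
    gap_open: float = 10.0,
    gap_ext: float = 0.5,
) -> tuple[int, int, int]:
    """Global protein alignment; returns (n_identical, n_aligned_pairs, aln_len)."""
    a = encode_protein(seq_a)
    b = encode_protein(seq_b)
    if submat is None:
        submat = blosum62_matrix()
    score = submat[np.ix_(a, np.arange(submat.shape[1]))]
    ops = _nw_profile(np.ascontiguousarray(score[:, b]), gap_open, gap_ext)
    n_id = n_pairs = 0
    i = j = 0
    for op in ops:
        if op == 0:
            if seq_a[i] == seq_b[j]:
                n_id += 1
            n_pairs += 1
            i += 1
            j += 1
        elif op == 1:
            i += 1
        else:
            j += 1
    return n_id, n_pairs, len(ops)


def local_protein_score(seq_a: str, seq_b: str, submat: np.ndarray,
                        gap_open: float = 11.0, gap_ext: float = 1.0) -> float:
    """Smith–Waterman score with an affine gap model (BLOSUM62 by default)."""
    return float(_sw_protein_score(encode_protein(seq_a), encode_protein(seq_b),
                                   submat, gap_open, gap_ext))


def banded_local_dna_stats(
    frag: np.ndarray,
    target: np.ndarray,
    offset: int,
    band: int = 32,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 5.0,
    gap_ext: float = 2.0,
) -> tuple[float, int, int, int, int]:
    """Banded local alignment of an encoded fragment against an encoded target.

    ``offset`` is the expected diagonal (target position minus fragment
    position) around which a band of half-width ``band`` is explored.
    Returns (score, n_identical, n_aligned_pairs, alignment_length,
    fragment_span).
    """
    return _sw_banded(frag, target, offset, band, match, mismatch, gap_open, gap_ext)
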