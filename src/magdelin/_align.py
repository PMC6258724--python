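"""Affine-gap Smith-Waterman with a fully deterministic canonical alignment.

Identity and coverage of a local alignment depend on which co-optimal
alignment the traceback picks, so the canonical alignment is defined
traceback-free: among all local alignments, take the lexicographic
maximum of the additive statistics vector

    (score, matches, -columns, diagonal_columns, -gaps_in_a)

where `columns` counts all alignment columns including gaps,
`diagonal_columns` counts substitution columns and `gaps_in_a` counts
columns that consume a residue of the first sequence against a gap.
All five components are additive along an alignment path, so the
lexicographic maximum is computable by dynamic programming (Gotoh's
three-state recursion with vector-valued cells).  A gap of length k
costs ``gap_open + (k - 1) * gap_extend``.

Alignments that begin or end with a gap are never the lexicographic
maximum (trimming the gap strictly raises the score), so the recursion
starts fresh only in the substitution state and the final maximum is
taken over substitution-state cells.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: fixed residue order used for integer encoding
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

_NEG = np.int64(-(10**15))


def load_blosum62() -> np.ndarray:
    """BLOSUM62 as a 20x20 int64 array in :data:`AA_ORDER` order."""
    table = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = int(table[a, b])
    return mat


BLOSUM62 = load_blosum62()


def encode(seq: str) -> np.ndarray:
    """Encode a protein sequence as int8 codes; raises on illegal residues."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        bad = exc.args[0]
        raise ValueError(
            f"illegal residue {bad!r} at position {seq.index(bad) + 1}"
        ) from exc


@njit(cache=True)
def _lex_greater(s1, m1, c1, d1, u1, s2, m2, c2, d2, u2):  # pragma: no cover
    """(s, m, -c, d, -u) lexicographic comparison."""
    if s1 != s2:
        return s1 > s2
    if m1 != m2:
        return m1 > m2
    if c1 != c2:
        return c1 < c2
    if d1 != d2:
        return d1 > d2
    return u1 < u2


@njit(cache=True)
def gotoh_stats(a, b, sub, gap_open, gap_extend):  # pragma: no cover
    """Canonical local-alignment statistics of encoded sequences ``a``, ``b``.

    Returns (score, matches, columns, diagonal, gaps_in_a); score <= 0
    means no positive-scoring local alignment exists.
    """
    n = b.shape[0]
    neg = _NEG
    # rolling rows, 5 components per state: M (substitution), X (gap in b,
    # consuming a), Y (gap in a, consuming b)
    mS = np.full(n + 1, neg)
    mM = np.zeros(n + 1, np.int64)
    mC = np.zeros(n + 1, np.int64)
    mD = np.zeros(n + 1, np.int64)
    mU = np.zeros(n + 1, np.int64)
    xS = np.full(n + 1, neg)
    xM = np.zeros(n + 1, np.int64)
    xC = np.zeros(n + 1, np.int64)
    xD = np.zeros(n + 1, np.int64)
    xU = np.zeros(n + 1, np.int64)
    yS = np.full(n + 1, neg)
    yM = np.zeros(n + 1, np.int64)
    yC = np.zeros(n + 1, np.int64)
    yD = np.zeros(n + 1, np.int64)
    yU = np.zeros(n + 1, np.int64)

    best_s, best_m, best_c, best_d, best_u = np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0)

    for i in range(1, a.shape[0] + 1):
        # previous row snapshots
        pmS, pmM, pmC, pmD, pmU = mS.copy(), mM.copy(), mC.copy(), mD.copy(), mU.copy()
        pxS, pxM, pxC, pxD, pxU = xS.copy(), xM.copy(), xC.copy(), xD.copy(), xU.copy()
        pyS, pyM, pyC, pyD, pyU = yS.copy(), yM.copy(), yC.copy(), yD.copy(), yU.copy()
        mS[0] = neg
        xS[0] = neg
        yS[0] = neg
        ai = a[i - 1]
        for j in range(1, n + 1):
            bj = b[j - 1]
            # --- M state: best predecessor at (i-1, j-1) or a fresh start
            s, m, c, d, u = np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0)
            if pmS[j - 1] > neg and _lex_greater(
                pmS[j - 1], pmM[j - 1], pmC[j - 1], pmD[j - 1], pmU[j - 1], s, m, c, d, u
            ):
                s, m, c, d, u = pmS[j - 1], pmM[j - 1], pmC[j - 1], pmD[j - 1], pmU[j - 1]
            if pxS[j - 1] > neg and _lex_greater(
                pxS[j - 1], pxM[j - 1], pxC[j - 1], pxD[j - 1], pxU[j - 1], s, m, c, d, u
            ):
                s, m, c, d, u = pxS[j - 1], pxM[j - 1], pxC[j - 1], pxD[j - 1], pxU[j - 1]
            if pyS[j - 1] > neg and _lex_greater(
                pyS[j - 1], pyM[j - 1], pyC[j - 1], pyD[j - 1], pyU[j - 1], s, m, c, d, u
            ):
                s, m, c, d, u = pyS[j - 1], pyM[j - 1], pyC[j - 1], pyD[j - 1], pyU[j - 1]
            mS[j] = s + sub[ai, bj]
            mM[j] = m + (1 if ai == bj else 0)
            mC[j] = c + 1
            mD[j] = d + 1
            mU[j] = u
            if _lex_greater(mS[j], mM[j], mC[j], mD[j], mU[j], best_s, best_m, best_c, best_d, best_u):
                best_s, best_m, best_c, best_d, best_u = mS[j], mM[j], mC[j], mD[j], mU[j]

            # --- X state: gap column consuming a[i-1] (predecessors at (i-1, j))
            s = neg
            m = c = d = u = np.int64(0)
            if pmS[j] > neg:
                cand = pmS[j] - gap_open
                if s == neg or _lex_greater(cand, pmM[j], pmC[j], pmD[j], pmU[j], s, m, c, d, u):
                    s, m, c, d, u = cand, pmM[j], pmC[j], pmD[j], pmU[j]
            if pxS[j] > neg:
                cand = pxS[j] - gap_extend
                if s == neg or _lex_greater(cand, pxM[j], pxC[j], pxD[j], pxU[j], s, m, c, d, u):
                    s, m, c, d, u = cand, pxM[j], pxC[j], pxD[j], pxU[j]
            if pyS[j] > neg:
                cand = pyS[j] - gap_open
                if s == neg or _lex_greater(cand, pyM[j], pyC[j], pyD[j], pyU[j], s, m, c, d, u):
                    s, m, c, d, u = cand, pyM[j], pyC[j], pyD[j], pyU[j]
            if s == neg:
                xS[j] = neg
            else:
                xS[j] = s
                xM[j] = m
                xC[j] = c + 1
                xD[j] = d
                xU[j] = u + 1

            # --- Y state: gap column consuming b[j-1] (predecessors at (i, j-1))
            s = neg
            m = c = d = u = np.int64(0)
            if mS[j - 1] > neg:
                cand = mS[j - 1] - gap_open
                if s == neg or _lex_greater(cand, mM[j - 1], mC[j - 1], mD[j - 1], mU[j - 1], s, m, c, d, u):
                    s, m, c, d, u = cand, mM[j - 1], mC[j - 1], mD[j - 1], mU[j - 1]
            if xS[j - 1] > neg:
                cand = xS[j - 1] - gap_open
                if s == neg or _lex_greater(cand, xM[j - 1], xC[j - 1], xD[j - 1], xU[j - 1], s, m, c, d, u):
                    s, m, c, d, u = cand, xM[j - 1], xC[j - 1], xD[j - 1], xU[j - 1]
            if yS[j - 1] > neg:
                cand = yS[j - 1] - gap_extend
                if s == neg or _lex_greater(cand, yM[j - 1], yC[j - 1], yD[j - 1], yU[j - 1], s, m, c, d, u):
                    s, m, c, d, u = cand, yM[j - 1], yC[j - 1], yD[j - 1], yU[j - 1]
            if s == neg:
                yS[j] = neg
            else:
                yS[j] = s
                yM[j] = m
                yC[j] = c + 1
                yD[j] = d
                yU[j] = u

    return best_s, best_m, best_c, best_d, best_u
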