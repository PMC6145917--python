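"""Semi-global (glocal) pairwise identity kernel.

Identity is computed from an optimal alignment scored match = +1,
mismatch = -1, gap = -2, in which one of the two sequences (normally the
shorter) is aligned end to end while terminal gaps in the other are free
and their columns uncounted.  Both orientations are evaluated and the
better-scoring one used, which makes the measure symmetric.  Requiring one
sequence to be fully spanned is what keeps the measure meaningful: if both
ends of both sequences were free, the best-scoring alignment of two
unrelated sequences degenerates to a tiny exact overlap (a full alignment
of random DNA scores negative under this scheme) and identity saturates
at 1.

Among co-optimal alignments the one with the most match columns is used; a
residual tie on match count resolves toward the fewest alignment columns,
pinning the identity value deterministically.  Identity is then

    matches / alignment columns inside the aligned region,

where the aligned region runs from the first to the last column touching
the spanned sequence (internal gap columns count, free terminal gaps of
the other sequence do not).

`N` (and any non-ACGT letter) never matches anything, including itself.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i

_MATCH = 1
_MISMATCH = -1
_GAP = -2
_NEG = -(2**30)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 code array (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _glocal_stats(q, t):  # pragma: no cover - exercised via pairwise_identity
    """Align q end-to-end inside t (terminal gaps of t free).

    Returns (score, matches, columns) of the optimal path, lexicographically
    maximizing score, then matches, then fewest columns.
    """
    n = q.shape[0]
    m = t.shape[0]
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    C = np.zeros((n + 1, m + 1), dtype=np.int32)
    # row 0: skipping a prefix of t is free and spans no columns
    # column 0: q residues aligned to gaps are paid and counted
    for i in range(1, n + 1):
        S[i, 0] = S[i - 1, 0] + _GAP
        C[i, 0] = i
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            match = 1 if (qi == t[j - 1] and qi < 4) else 0
            bs = S[i - 1, j - 1] + (_MATCH if match == 1 else _MISMATCH)
            bm = M[i - 1, j - 1] + match
            bc = C[i - 1, j - 1] + 1
            s = S[i - 1, j] + _GAP
            mm = M[i - 1, j]
            c = C[i - 1, j] + 1
            if s > bs or (s == bs and (mm > bm or (mm == bm and c < bc))):
                bs, bm, bc = s, mm, c
            s = S[i, j - 1] + _GAP
            mm = M[i, j - 1]
            c = C[i, j - 1] + 1
            if s > bs or (s == bs and (mm > bm or (mm == bm and c < bc))):
                bs, bm, bc = s, mm, c
            S[i, j] = bs
            M[i, j] = bm
            C[i, j] = bc
    # free trailing gap in t: best endpoint anywhere on the last row
    bs, bm, bc = _NEG, 0, 0
    for j in range(m + 1):
        s, mm, c = S[n, j], M[n, j], C[n, j]
        if s > bs or (s == bs and (mm > bm or (mm == bm and c < bc))):
            bs, bm, bc = s, mm, c
    return bs, bm, bc


def identity_encoded(ea: np.ndarray, eb: np.ndarray) -> float:
    s1, m1, c1 = _glocal_stats(ea, eb)
    s2, m2, c2 = _glocal_stats(eb, ea)
    if s2 > s1 or (s2 == s1 and (m2 > m1 or (m2 == m1 and c2 < c1))):
        m1, c1 = m2, c2
    if c1 == 0:
        return 0.0
    return m1 / c1


@lru_cache(maxsize=1 << 20)
def _identity_cached(a: str, b: str) -> float:
    return identity_encoded(encode(a), encode(b))


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity of two DNA sequences under the glocal model.

    Symmetric; ``pairwise_identity(a, a) == 1.0``; a sequence contained
    verbatim in a longer one scores 1.0.  Results are memoized (the chained
    clustering ladder revisits the same representative pairs at every
    level).

    Raises ``ValueError`` on an empty sequence.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    if b < a:
        a, b = b, a
    return _identity_cached(a, b)
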