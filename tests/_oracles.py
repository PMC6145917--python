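"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package internals: the identity
oracle is a plain tuple-valued dynamic program, the clustering oracle a
straightforward quadratic loop.
"""

from __future__ import annotations

NEG = float("-inf")


def _glocal_oracle(q: str, t: str):
    """Best (score, matches, -columns) aligning q end-to-end within t.

    Scoring: match +1, mismatch -1, gap -2; leading/trailing gaps of t are
    free and span no columns.  Lexicographic maximization of the tuple
    implements "max score, then max matches, then fewest columns".
    """
    n, m = len(q), len(t)
    prev = [(0, 0, 0)] * (m + 1)
    for i in range(1, n + 1):
        cur = [(prev[0][0] - 2, prev[0][1], prev[0][2] - 1)]
        qi = q[i - 1]
        for j in range(1, m + 1):
            hit = 1 if (qi == t[j - 1] and qi in "ACGT") else 0
            diag = prev[j - 1]
            up = prev[j]
            left = cur[j - 1]
            cur.append(
                max(
                    (diag[0] + (1 if hit else -1), diag[1] + hit, diag[2] - 1),
                    (up[0] - 2, up[1], up[2] - 1),
                    (left[0] - 2, left[1], left[2] - 1),
                )
            )
        prev = cur
    return max(prev)


def identity_oracle(a: str, b: str) -> float:
    """Symmetric glocal identity: better-scoring of the two orientations."""
    score, matches, negcols = max(_glocal_oracle(a, b), _glocal_oracle(b, a))
    cols = -negcols
    return matches / cols if cols else 0.0


def greedy_cluster_oracle(items, threshold, identity):
    """Quadratic reference for greedy centroid clustering.

    ``items``: (id, seq, weight) triples; ``identity``: a callable.
    Returns (otu_assignments: dict id->otu index, representatives: list of
    (id, seq)) with the same ordering and tie rules as the real
    implementation: decreasing weight then ascending id; best centroid,
    earliest on identity ties; new OTU when best identity < threshold.
    """
    pool = sorted(items, key=lambda it: (-it[2], it[0]))
    reps: list[tuple[str, str]] = []
    assign: dict[str, int] = {}
    for item_id, seq, _w in pool:
        best_k, best_ident = None, -1.0
        for k, (_rid, rseq) in enumerate(reps):
            ident = identity(seq, rseq)
            if ident > best_ident:
                best_k, best_ident = k, ident
        if best_k is not None and best_ident >= threshold:
            assign[item_id] = best_k
        else:
            reps.append((item_id, seq))
            assign[item_id] = len(reps) - 1
    return assign, reps


def recount_presence(core_members: dict[str, set[str]], records) -> dict[str, set[str]]:
    """Brute-force recount: core id -> set of samples holding its members."""
    out = {cid: set() for cid in core_members}
    for rec in records:
        for cid, members in core_members.items():
            if rec.seq_id in members:
                out[cid].add(rec.sample_id)
    return out


def ecdf_oracle(values, x) -> float:
    """Sorted-scan ECDF: fraction of values <= x."""
    vs = sorted(values)
    k = 0
    for v in vs:
        if v <= x:
            k += 1
        else:
            break
    return k / len(vs)
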