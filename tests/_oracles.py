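"""Independent reference implementations ("oracles") used only by tests.

Nothing here shares code with the package's alignment or simulation
internals: the dynamic program below works on plain Python tuples with
native lexicographic comparison, the enumeration oracle walks every
local alignment explicitly, and the Monte-Carlo site oracle re-derives
expected sequence identity from the per-site substitution rule.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM = substitution_matrices.load("BLOSUM62")


def sub_score(x: str, y: str) -> int:
    return int(_BLOSUM[x, y])


def _key(score, matches, columns, diagonal, gaps_in_a):
    """Canonical ordering key: lexicographic max of this tuple defines the
    canonical local alignment."""
    return (score, matches, -columns, diagonal, -gaps_in_a)


def _unkey(key):
    s, m, negc, d, negu = key
    return (s, m, -negc, d, -negu)


def oracle_stats(a: str, b: str, gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND):
    """Tuple-valued Gotoh DP over plain Python tuples.

    Returns (score, matches, columns, diagonal, gaps_in_a) of the
    canonical local alignment, or the all-zero tuple when no alignment
    scores above 0 (the empty alignment).
    """
    la, lb = len(a), len(b)
    best = _key(0, 0, 0, 0, 0)
    prev_m: list[Optional[tuple]] = [None] * (lb + 1)
    prev_x: list[Optional[tuple]] = [None] * (lb + 1)
    prev_y: list[Optional[tuple]] = [None] * (lb + 1)
    for i in range(1, la + 1):
        cur_m: list[Optional[tuple]] = [None] * (lb + 1)
        cur_x: list[Optional[tuple]] = [None] * (lb + 1)
        cur_y: list[Optional[tuple]] = [None] * (lb + 1)
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cb = b[j - 1]
            # M state: diagonal predecessor or a fresh (empty) start
            preds = [p for p in (prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) if p is not None]
            s, m, negc, d, negu = max(preds + [_key(0, 0, 0, 0, 0)])
            cell = (s + sub_score(ca, cb), m + (1 if ca == cb else 0), negc - 1, d + 1, negu)
            cur_m[j] = cell
            if cell > best:
                best = cell
            # X state: gap column consuming a[i-1], predecessors at (i-1, j)
            cands = []
            if prev_m[j] is not None:
                p = prev_m[j]
                cands.append((p[0] - gap_open,) + p[1:])
            if prev_x[j] is not None:
                p = prev_x[j]
                cands.append((p[0] - gap_extend,) + p[1:])
            if prev_y[j] is not None:
                p = prev_y[j]
                cands.append((p[0] - gap_open,) + p[1:])
            if cands:
                s, m, negc, d, negu = max(cands)
                cur_x[j] = (s, m, negc - 1, d, negu - 1)
            # Y state: gap column consuming b[j-1], predecessors at (i, j-1)
            cands = []
            if cur_m[j - 1] is not None:
                p = cur_m[j - 1]
                cands.append((p[0] - gap_open,) + p[1:])
            if cur_x[j - 1] is not None:
                p = cur_x[j - 1]
                cands.append((p[0] - gap_open,) + p[1:])
            if cur_y[j - 1] is not None:
                p = cur_y[j - 1]
                cands.append((p[0] - gap_extend,) + p[1:])
            if cands:
                s, m, negc, d, negu = max(cands)
                cur_y[j] = (s, m, negc - 1, d, negu)
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return _unkey(best)


def enumerate_stats(a: str, b: str, gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND):
    """Exhaustively enumerate every local alignment (all start cells, all
    move sequences, including ones beginning or ending with gaps) and
    return the stats of the lexicographic maximum.  Exponential; only for
    tiny sequences."""
    la, lb = len(a), len(b)
    best = [_key(0, 0, 0, 0, 0)]

    def walk(i, j, s, m, c, d, u, last):
        key = _key(s, m, c, d, u)
        if key > best[0]:
            best[0] = key
        if i < la and j < lb:
            walk(i + 1, j + 1, s + sub_score(a[i], b[j]),
                 m + (1 if a[i] == b[j] else 0), c + 1, d + 1, u, "D")
        if i < la:
            cost = gap_extend if last == "X" else gap_open
            walk(i + 1, j, s - cost, m, c + 1, d, u + 1, "X")
        if j < lb:
            cost = gap_extend if last == "Y" else gap_open
            walk(i, j + 1, s - cost, m, c + 1, d, u, "Y")

    for i in range(la):
        for j in range(lb):
            walk(i, j, 0, 0, 0, 0, 0, None)
    return _unkey(best[0])


def oracle_hit(seq_a: str, seq_b: str):
    """(identity %, coverage %, score) of the canonical alignment, or None."""
    score, matches, columns, diag, gaps_in_a = oracle_stats(seq_a, seq_b)
    if score <= 0:
        return None
    consumed_a = diag + gaps_in_a
    consumed_b = columns - gaps_in_a
    consumed_short = consumed_a if len(seq_a) <= len(seq_b) else consumed_b
    identity = 100.0 * matches / columns
    coverage = 100.0 * consumed_short / min(len(seq_a), len(seq_b))
    return identity, coverage, score


def oracle_best_hits(proteome_a, proteome_b, min_identity=30.0, min_coverage=70.0):
    """Best filtered subject per query: max score, ties by identity then
    lexicographic subject id."""
    out = {}
    for pa, sa in proteome_a.items():
        candidates = []
        for pb, sb in proteome_b.items():
            hit = oracle_hit(sa, sb)
            if hit is None:
                continue
            identity, coverage, score = hit
            if identity >= min_identity and coverage >= min_coverage:
                candidates.append((-score, -identity, pb))
        if candidates:
            _, neg_ident, pb = min(candidates)
            out[pa] = (pb, -neg_ident)
    return out


def oracle_rbh(proteome_a, proteome_b, min_identity=30.0, min_coverage=70.0):
    forward = oracle_best_hits(proteome_a, proteome_b, min_identity, min_coverage)
    reverse = oracle_best_hits(proteome_b, proteome_a, min_identity, min_coverage)
    return {
        (pa, pb)
        for pa, (pb, _) in forward.items()
        if pb in reverse and reverse[pb][0] == pa
    }


def oracle_aai(proteome_a, proteome_b, min_identity=30.0, min_coverage=70.0):
    rbh = oracle_rbh(proteome_a, proteome_b, min_identity, min_coverage)
    if not rbh:
        return float("nan"), 0
    identities = [oracle_hit(proteome_a[pa], proteome_b[pb])[0] for pa, pb in rbh]
    return float(np.mean(identities)), len(rbh)


# ---------------------------------------------------------------------------
# Trees / sequence evolution


def path_edges(tree, tip_a: str, tip_b: str):
    """Edge lengths from the MRCA down to each of two tips (dendropy tree)."""
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    def chain(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    ca, cb = chain(leaves[tip_a]), chain(leaves[tip_b])
    ids_b = {id(n) for n in cb}
    mrca = next(n for n in ca if id(n) in ids_b)

    def down(ch):
        out = []
        for node in ch:
            if node is mrca:
                break
            out.append(float(node.edge.length))
        return out

    return down(ca), down(cb)


def mc_site_identity(edges_a, edges_b, n_sites: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo expected per-site identity between two tips.

    Simulates ``n_sites`` sites from a uniform 20-state ancestor down both
    edge paths: along an edge of length d each site substitutes with
    probability 1 - exp(-d), the replacement uniform over the other 19
    states."""
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 20, size=n_sites)

    def evolve(state, edges):
        for d in edges:
            hit = rng.random(n_sites) < 1.0 - np.exp(-d)
            repl = (state + rng.integers(1, 20, size=n_sites)) % 20
            state = np.where(hit, repl, state)
        return state

    a = evolve(anc.copy(), edges_a)
    b = evolve(anc.copy(), edges_b)
    return float(np.mean(a == b))


def random_proteome(rng: np.random.Generator, n_proteins: int, min_len: int,
                    max_len: int, prefix: str) -> dict[str, str]:
    """Random proteome with uniform residues, for oracle comparisons."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = {}
    for k in range(n_proteins):
        length = int(rng.integers(min_len, max_len + 1))
        out[f"{prefix}_p{k:03d}"] = "".join(
            aa[i] for i in rng.integers(0, 20, size=length)
        )
    return out


def mutate_sequence(seq: str, rng: np.random.Generator, p_sub: float) -> str:
    """Point-mutate a protein sequence with per-site probability ``p_sub``."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for c in seq:
        if rng.random() < p_sub:
            choices = [x for x in aa if x != c]
            out.append(choices[int(rng.integers(0, 19))])
        else:
            out.append(c)
    return "".join(out)
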