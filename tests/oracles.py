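"""Independent reference implementations used only to check stcmine.

These deliberately avoid the code paths they verify: tiny exhaustive
enumerators for alignments, HMM paths and motifs, plus Biopython's
PairwiseAligner as an externally-implemented alignment reference.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from stcmine.core import AA_INDEX, ALPHABET
from stcmine.similarity import blosum62


def _as_array(matrix: np.ndarray) -> substitution_matrices.Array:
    arr = substitution_matrices.Array(ALPHABET, dims=2)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            arr[a, b] = matrix[i, j]
    return arr


def biopython_local_score(q: str, s: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal Smith-Waterman score via Biopython (empty alignment -> 0)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _as_array(blosum62())
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return max(float(aligner.score(q, s)), 0.0)


def biopython_global_score(
    q: str, s: str, gap_open: float = 2.3, gap_extend: float = 0.63, scale: float = 0.25
) -> float:
    """Global affine-gap score with end gaps penalized, scaled BLOSUM62."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _as_array(blosum62() * scale)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.open_end_gap_score = -(gap_open + gap_extend)
    aligner.extend_end_gap_score = -gap_extend
    return float(aligner.score(q, s))


def brute_local_score(q: str, s: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Exhaustive enumeration of all gapped local alignments (tiny inputs)."""
    B = blosum62()
    qi = [AA_INDEX[c] for c in q]
    si = [AA_INDEX[c] for c in s]
    n, m = len(qi), len(si)
    best = 0.0

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + B[qi[i], si[j]], "M")
        if i < n:
            cost = gap_extend if last == "F" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "F")
        if j < m:
            cost = gap_extend if last == "E" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "E")

    for i in range(n):
        for j in range(m):
            rec(i, j, 0.0, None)
    return best


def enumerate_glocal_scores(hmm, seq: str) -> tuple[float, float]:
    """(viterbi_bits, forward_bits) by explicit path enumeration.

    Paths traverse the full model begin-to-end; flank residues before the
    entry point and after the exit point are free (0 bits). The forward
    value sums over all (entry point, path) combinations, matching the
    package's definition.
    """
    t = hmm.transitions
    L = hmm.L
    bg = hmm.background
    obs = [AA_INDEX[c] for c in seq]
    n = len(obs)
    results: list[float] = []

    def em_odds(probs: np.ndarray, x: int) -> float:
        return 1.0 if x == 20 else probs[x] / bg[x]

    def walk(state: str, node: int, pos: int, odds: float) -> None:
        if state in ("B", "M"):
            moves = [("M", node + 1, t[node, 0]), ("I", node, t[node, 1]), ("D", node + 1, t[node, 2])]
        elif state == "I":
            moves = [("M", node + 1, t[node, 3]), ("I", node, t[node, 4])]
        else:
            moves = [("M", node + 1, t[node, 5]), ("D", node + 1, t[node, 6])]
        for nstate, nnode, p in moves:
            if p == 0.0:
                continue
            if nnode > L:
                results.append(odds * p)  # exit to E, suffix flank is free
                continue
            if nstate == "M":
                if pos < n:
                    walk("M", nnode, pos + 1, odds * p * em_odds(hmm.match_emissions[nnode - 1], obs[pos]))
            elif nstate == "I":
                if pos < n:
                    walk("I", nnode, pos + 1, odds * p * em_odds(hmm.insert_emissions[nnode], obs[pos]))
            else:
                walk("D", nnode, pos, odds * p)

    for entry in range(n + 1):
        walk("B", 0, entry, 1.0)
    if not results:
        return float("-inf"), float("-inf")
    return float(np.log2(max(results))), float(np.log2(sum(results)))


def brute_discover_motifs(
    positives: list[str],
    negatives: list[str],
    kmin: int,
    kmax: int,
    min_freq: float,
) -> list[tuple[str, float]]:
    """Naive discriminative-motif enumeration (pattern, positive_freq)."""
    words = set()
    for seq in positives:
        for k in range(kmin, kmax + 1):
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if "X" not in w:
                    words.add(w)
    n = len(positives)
    surviving = {}
    for w in words:
        sup = frozenset(i for i, seq in enumerate(positives) if w in seq)
        if len(sup) / n < min_freq:
            continue
        if any(w in seq for seq in negatives):
            continue
        surviving[w] = sup
    kept = [
        w
        for w, sup in surviving.items()
        if not any(
            len(w2) > len(w) and w in w2 and surviving[w2] == sup for w2 in surviving
        )
    ]
    kept.sort(key=lambda w: (-len(surviving[w]) / n, -len(w), w))
    return [(w, len(surviving[w]) / n) for w in kept]
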