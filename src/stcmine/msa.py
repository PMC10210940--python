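"""Progressive multiple alignment, trimming, distances and dendrograms.

The aligner is a guide-tree progressive profile aligner: pairwise 3-mer
distances feed a UPGMA guide tree, and profiles are merged along it by
global affine-gap dynamic programming over BLOSUM62-derived column
scores. Distances between aligned sequences use the protdist
physicochemical categorisation: substitutions within a category
({C}, {M,V,L,I}, {G,A,S,T,P}, {F,Y,W}, {N,D,E,Q}, {H,K,R}) cost half a
difference, across categories a full one, with a -ln(1-D) correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import nw_affine_profile
from .core import (
    AA_INDEX,
    ALPHABET,
    CLADES,
    GAP,
    UNCLASSIFIED,
    Clade,
    CladeCall,
    PipelineConfig,
    ProteinRecord,
)
from .similarity import blosum62

log = logging.getLogger(__name__)

DISTANCE_CAP = 10.0
_GAPCODE = 21  # residues are 0..20 (20 = X); 21 encodes a gap

#: protdist physicochemical categories.
CATEGORIES = ("C", "MVLI", "GASTP", "FYW", "NDEQ", "HKR")
_CAT_INDEX = {aa: i for i, group in enumerate(CATEGORIES) for aa in group}
_CAT_INDEX["X"] = -1  # unknown: always a full difference


@dataclass
class Msa:
    """A gap-aligned block of named sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def column_gap_fractions(self) -> np.ndarray:
        block = _encode_block(self.rows)
        return (block == _GAPCODE).mean(axis=0)


def _encode_block(rows: list[str]) -> np.ndarray:
    lookup = np.zeros(128, dtype=np.uint8)
    for ch, idx in AA_INDEX.items():
        lookup[ord(ch)] = idx
    lookup[ord(GAP)] = _GAPCODE
    return np.vstack(
        [lookup[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows]
    )


def _decode_block(block: np.ndarray) -> list[str]:
    symbols = np.frombuffer((ALPHABET + GAP).encode(), dtype=np.uint8)
    return [bytes(symbols[row]).decode() for row in block]


# ---------------------------------------------------------------------------
# guide-tree distances

def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 minus the fraction of shared distinct k-mers.

    The denominator is the distinct k-mer count of the shorter sequence,
    so near-identical sequences get distances near 0.
    """
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    """All-pairs set-based k-mer distances, vectorized."""
    vocab: dict[str, int] = {}
    rows = []
    for s in seqs:
        idxs = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if w not in vocab:
                vocab[w] = len(vocab)
            idxs.add(vocab[w])
        rows.append(idxs)
    n = len(seqs)
    B = np.zeros((n, len(vocab) if vocab else 1), dtype=np.float32)
    for i, idxs in enumerate(rows):
        for j in idxs:
            B[i, j] = 1.0
    shared = B @ B.T
    sizes = B.sum(axis=1)
    mins = np.minimum.outer(sizes, sizes)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared / mins
    for i in range(n):  # sequences shorter than k
        if not rows[i]:
            for j in range(n):
                d[i, j] = d[j, i] = 0.0 if seqs[i] == seqs[j] else 1.0
    np.fill_diagonal(d, 0.0)
    return np.asarray(np.clip(d, 0.0, 1.0), dtype=float)


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class Dendrogram:
    """Rooted binary UPGMA merge tree; ``leaf_id`` set iff leaf."""

    height: float
    leaf_id: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_id]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) tree with deterministic tie-breaking.

    Ties in the minimum distance are broken by the lexicographically
    smallest pair of cluster representatives (each cluster represented by
    its smallest leaf id). Merge heights are half the cluster distance,
    so the tree is ultrametric.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 ids")
    D = dm.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    nodes = [Dendrogram(height=0.0, leaf_id=dm.ids[i]) for i in range(n)]
    sizes = np.ones(n)
    reps = list(dm.ids)
    for _ in range(n - 1):
        sub = np.where(active)[0]
        block = D[np.ix_(sub, sub)]
        m = block.min()
        ti, tj = np.where(block == m)
        pairs = [
            (sub[a], sub[b]) for a, b in zip(ti, tj) if sub[a] < sub[b]
        ]
        i, j = min(pairs, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))
        new = Dendrogram(height=m / 2.0, children=(nodes[i], nodes[j]))
        # merge j into i (weighted average of distances)
        wi, wj = sizes[i], sizes[j]
        merged = (wi * D[i] + wj * D[j]) / (wi + wj)
        D[i] = merged
        D[:, i] = merged
        D[i, i] = np.inf
        active[j] = False
        D[j] = np.inf
        D[:, j] = np.inf
        nodes[i] = new
        sizes[i] = wi + wj
        reps[i] = min(reps[i], reps[j])
    return nodes[int(np.where(active)[0][0])]


# ---------------------------------------------------------------------------
# progressive alignment

_B62_SCALED = None


def _b62_scaled() -> np.ndarray:
    """BLOSUM62 scaled into the GOP/GEP units of the progressive aligner."""
    global _B62_SCALED
    if _B62_SCALED is None:
        _B62_SCALED = blosum62() / 4.0
    return _B62_SCALED


def _profile_counts(block: np.ndarray) -> np.ndarray:
    """(columns, 21) residue frequencies; gaps contribute nothing."""
    counts = np.stack(
        [(block == c).sum(axis=0) for c in range(21)], axis=1
    ).astype(float)
    return counts / block.shape[0]


def _merge(
    block_a: np.ndarray, block_b: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[np.ndarray, np.ndarray]:
    """Profile-profile global alignment of two encoded row blocks."""
    S = _profile_counts(block_a) @ _b62_scaled() @ _profile_counts(block_b).T
    _, ops, nops = nw_affine_profile(S, gap_open, gap_extend)
    ncols = nops
    idx_a = np.full(ncols, -1, dtype=np.int64)
    idx_b = np.full(ncols, -1, dtype=np.int64)
    ia = ib = 0
    for c, t in enumerate(range(nops - 1, -1, -1)):
        op = ops[t]
        if op == 1 or op == 2:
            idx_a[c] = ia
            ia += 1
        if op == 1 or op == 3:
            idx_b[c] = ib
            ib += 1

    def expand(block, idx):
        out = np.full((block.shape[0], ncols), _GAPCODE, dtype=np.uint8)
        sel = idx >= 0
        out[:, sel] = block[:, idx[sel]]
        return out

    return expand(block_a, idx_a), expand(block_b, idx_b)


def progressive_align(
    seqs: list[ProteinRecord], gap_open: float = 2.3, gap_extend: float = 0.63
) -> Msa:
    """Guide-tree progressive alignment with affine gap penalties.

    Degapping any output row reproduces the corresponding input sequence.
    A single sequence yields a trivial one-row alignment. With exactly two
    sequences the result is the pairwise global alignment under the same
    scoring.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 1:
        return Msa(ids=[ids[0]], rows=[seqs[0].sequence])
    by_id = {s.id: s for s in seqs}
    values = _kmer_distance_matrix([s.sequence for s in seqs])
    tree = upgma(DistanceMatrix(ids=ids, values=values))

    def align_node(node: Dendrogram) -> tuple[list[str], np.ndarray]:
        if node.is_leaf:
            return [node.leaf_id], _encode_block([by_id[node.leaf_id].sequence])
        ids_a, block_a = align_node(node.children[0])
        ids_b, block_b = align_node(node.children[1])
        block_a, block_b = _merge(block_a, block_b, gap_open, gap_extend)
        return ids_a + ids_b, np.vstack([block_a, block_b])

    out_ids, block = align_node(tree)
    order = {pid: k for k, pid in enumerate(out_ids)}
    rows = _decode_block(block)
    return Msa(ids=list(ids), rows=[rows[order[pid]] for pid in ids])


def trim_msa(msa: Msa, gap_threshold: float = 0.5) -> Msa:
    """Keep exactly the columns whose gap fraction is <= gap_threshold."""
    fractions = msa.column_gap_fractions()
    keep = np.where(fractions <= gap_threshold)[0]
    if keep.size == 0:
        raise ValueError("alignment fully trimmed")
    block = _encode_block(msa.rows)[:, keep]
    return Msa(ids=list(msa.ids), rows=_decode_block(block))


# ---------------------------------------------------------------------------
# category distance

def category_distance(msa: Msa) -> DistanceMatrix:
    """Physicochemical-category distance between aligned rows.

    Over columns where both rows carry residues: 0 per identical pair,
    0.5 within a category, 1.0 across categories (X always 1.0). The raw
    mean difference D is corrected to -ln(1 - D) and capped at 10.
    """
    n = len(msa.rows)
    if n < 2:
        raise ValueError("need at least 2 rows")
    enc = _encode_block(msa.rows).astype(np.int16)
    catmap = np.full(22, -2, dtype=np.int16)
    for ch, idx in AA_INDEX.items():
        catmap[idx] = _CAT_INDEX[ch]
    cat = catmap[enc]
    x_idx = AA_INDEX["X"]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != _GAPCODE) & (enc[j] != _GAPCODE)
            m = int(both.sum())
            if m == 0:
                log.warning(
                    "rows %s and %s share no aligned residues; distance capped",
                    msa.ids[i],
                    msa.ids[j],
                )
                values[i, j] = values[j, i] = DISTANCE_CAP
                continue
            ei, ej = enc[i][both], enc[j][both]
            ci, cj = cat[i][both], cat[j][both]
            has_x = (ei == x_idx) | (ej == x_idx)
            score = np.where(
                has_x,
                1.0,
                np.where(ei == ej, 0.0, np.where(ci == cj, 0.5, 1.0)),
            )
            D = float(score.mean())
            if D >= 1.0 - np.exp(-DISTANCE_CAP):
                d = DISTANCE_CAP
            else:
                d = -np.log(1.0 - D)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(msa.ids), values=values)


# ---------------------------------------------------------------------------
# clade assignment by clustering

def assign_clades_by_clustering(
    candidates: list[ProteinRecord],
    references: list[ProteinRecord],
    ref_clades: dict[str, Clade],
    cfg: PipelineConfig | None = None,
) -> list[CladeCall]:
    """Classify candidates by their position in a UPGMA dendrogram.

    Candidates and clade-labelled references are aligned together, the
    alignment trimmed, category distances computed and a UPGMA tree built.
    Each candidate takes the clade of its smallest enclosing cluster that
    contains at least one reference — provided every reference inside
    agrees; otherwise it stays unclassified. A clade never present among
    the references can therefore never be called.
    """
    cfg = cfg or PipelineConfig()
    present = {ref_clades[r.id] for r in references if r.id in ref_clades}
    missing = [c for c in CLADES if c not in present]
    if missing:
        raise ValueError(f"no reference for clades {missing}")
    if not candidates:
        return []
    cand_ids = {c.id for c in candidates}
    seqs = list(candidates) + [r for r in references if r.id not in cand_ids]
    msa = progressive_align(seqs, gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)
    msa = trim_msa(msa, gap_threshold=cfg.trim_gap_threshold)
    dm = category_distance(msa)
    tree = upgma(dm)

    ref_ids = {r.id for r in references if r.id in ref_clades}
    parent: dict[int, Dendrogram] = {}
    leaf_nodes: dict[str, Dendrogram] = {}

    def index(node: Dendrogram) -> None:
        if node.is_leaf:
            leaf_nodes[node.leaf_id] = node
        for child in node.children:
            parent[id(child)] = node
            index(child)

    index(tree)

    calls = []
    for cand in candidates:
        node = leaf_nodes[cand.id]
        clade: Clade = UNCLASSIFIED
        while id(node) in parent:
            node = parent[id(node)]
            inside = set(node.leaves()) & ref_ids
            if inside:
                clades = {ref_clades[r] for r in inside}
                if len(clades) == 1:
                    clade = clades.pop()
                break
        calls.append(
            CladeCall(protein_id=cand.id, clade=clade, evidence="distance_cluster")
        )
    return calls
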