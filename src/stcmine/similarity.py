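"""Similarity screen against characterized seed enzymes (filter 1).

Each proteome sequence is aligned locally (Smith-Waterman, BLOSUM62,
affine gaps with BLAST-like defaults: open 11, extend 1) against every
seed. A candidate survives when some seed alignment exceeds both the
percent-identity and the query-coverage thresholds (strictly — the
published bounds are ">30 %" identity and ">60 %" coverage).

Percent identity uses the alignment-column denominator (gap columns
included, the blast ``pident`` convention); query coverage is the aligned
query span over the query length. X counts as a mismatch and scores 0
against every residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import sw_affine
from .core import AA_INDEX, ALPHABET, GAP, PipelineConfig, ProteinRecord


@lru_cache(maxsize=1)
def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 array in alphabet order; X rows/columns are 0."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate(ALPHABET[:20]):
        for j, b in enumerate(ALPHABET[:20]):
            out[i, j] = m[a, b]
    return out


@dataclass
class LocalAlignment:
    """An optimal local alignment with its filter-1 decision variables."""

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    identity_pct: float
    query_coverage_pct: float
    raw_score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")
        for qa, sa in zip(self.aligned_query, self.aligned_subject):
            if qa == GAP and sa == GAP:
                raise ValueError("column with gaps in both rows")


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)


def local_align(
    query: ProteinRecord,
    subject: ProteinRecord,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment under BLOSUM62.

    A gap of length k costs ``gap_open + k * gap_extend``. Traceback is
    deterministic (diagonal preferred over up over left). When the best
    local score is <= 0 the empty alignment is returned with identity and
    coverage 0.
    """
    if not query.sequence or not subject.sequence:
        raise ValueError("sequences must be non-empty")
    score, ops, nops, qend, send = sw_affine(
        _encode(query.sequence),
        _encode(subject.sequence),
        blosum62(),
        float(gap_open),
        float(gap_extend),
    )
    if nops == 0:
        return LocalAlignment(
            query_id=query.id,
            subject_id=subject.id,
            aligned_query="",
            aligned_subject="",
            identity_pct=0.0,
            query_coverage_pct=0.0,
            raw_score=0.0,
        )
    qa_parts: list[str] = []
    sa_parts: list[str] = []
    qi, sj = qend, send
    for t in range(nops):  # ops run from the end cell backwards
        op = ops[t]
        if op == 1:
            qi -= 1
            sj -= 1
            qa_parts.append(query.sequence[qi])
            sa_parts.append(subject.sequence[sj])
        elif op == 2:
            qi -= 1
            qa_parts.append(query.sequence[qi])
            sa_parts.append(GAP)
        else:
            sj -= 1
            qa_parts.append(GAP)
            sa_parts.append(subject.sequence[sj])
    aligned_q = "".join(reversed(qa_parts))
    aligned_s = "".join(reversed(sa_parts))
    columns = len(aligned_q)
    identical = sum(
        1
        for a, b in zip(aligned_q, aligned_s)
        if a == b and a != GAP and a != "X"
    )
    qspan = qend - qi  # aligned query residues span (end - start)
    return LocalAlignment(
        query_id=query.id,
        subject_id=subject.id,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        identity_pct=100.0 * identical / columns,
        query_coverage_pct=100.0 * qspan / len(query.sequence),
        raw_score=float(score),
    )


def screen(
    candidates: list[ProteinRecord],
    seeds: list[ProteinRecord],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[LocalAlignment]:
    """All candidate-vs-seed local alignments with positive score."""
    if not seeds:
        raise ValueError("seed set must be non-empty")
    hits = []
    for cand in candidates:
        for seed in seeds:
            aln = local_align(cand, seed, gap_open=gap_open, gap_extend=gap_extend)
            if aln.raw_score > 0:
                hits.append(aln)
    return hits


def similarity_filter(
    candidates: list[ProteinRecord],
    seeds: list[ProteinRecord],
    cfg: PipelineConfig | None = None,
    hits: list[LocalAlignment] | None = None,
) -> set[str]:
    """Ids of candidates with a seed hit above both filter-1 thresholds.

    Bounds are strict: identity must exceed ``min_identity_pct`` and
    coverage must exceed ``min_coverage_pct``. Precomputed ``hits`` from
    :func:`screen` may be passed to avoid re-aligning.
    """
    cfg = cfg or PipelineConfig()
    if hits is None:
        hits = screen(candidates, seeds)
    survivors = set()
    for aln in hits:
        if (
            aln.identity_pct > cfg.min_identity_pct
            and aln.query_coverage_pct > cfg.min_coverage_pct
        ):
            survivors.add(aln.query_id)
    return survivors
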