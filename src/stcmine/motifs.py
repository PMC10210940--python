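"""Metal-binding motif filter and discriminative motif discovery.

Filter 2 requires the class-I terpene-cyclase metal-binding signature:
an N-terminal (D/N)DxxD/E or DDxxxE aspartate-rich motif plus the
C-terminal NSE triad motif NxxxSxxxE. "N-terminal"/"C-terminal" are the
sequence halves split at floor(L/2).

Discriminative motifs are exact substrings (length kmin..kmax) present in
at least a minimum fraction of a positive set and entirely absent from a
negative set; maximal motifs only (a motif is dropped when an extension
has identical positive support). The published clade signatures are
DTSGC (clade 1), LRRENS (clade 2), DLMN (clade 3) and FYK (clade 4).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    AMINO_ACIDS,
    CLADES,
    UNCLASSIFIED,
    Clade,
    CladeCall,
    PipelineConfig,
    ProteinRecord,
)


@dataclass(frozen=True)
class MotifPattern:
    """A motif over the amino-acid alphabet plus the wildcard 'x'.

    Literal positions match exactly (the unknown residue X matches no
    literal); 'x' matches any residue including X.
    """

    pattern: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("pattern must have length >= 2")
        bad = set(self.pattern) - set(AMINO_ACIDS + "x")
        if bad:
            raise ValueError(f"invalid pattern symbols {sorted(bad)}")

    def matches_at(self, seq: str, start: int) -> bool:
        if start + len(self.pattern) > len(seq):
            return False
        for offset, p in enumerate(self.pattern):
            if p == "x":
                continue
            if seq[start + offset] != p:
                return False
        return True


#: N-terminal aspartate-rich metal-binding motif, (D/N)Dxx(D/E),
#: expanded into exact-literal alternatives.
NTERM_DDXXD = tuple(
    MotifPattern(a + "Dxx" + b, description="(D/N)Dxx(D/E)")
    for a in "DN"
    for b in "DE"
)
#: Alternative N-terminal variant DDxxxE.
NTERM_DDXXXE = (MotifPattern("DDxxxE", description="DDxxxE"),)
#: C-terminal NSE triad motif.
CTERM_NSE = MotifPattern("NxxxSxxxE", description="NxxxSxxxE")


def find_pattern(seq: str, pattern: MotifPattern, region: str = "anywhere") -> list[int]:
    """All (possibly overlapping) 0-based match starts of a motif.

    ``region="nterm"`` keeps starts in the first half of the sequence
    (before floor(L/2)); ``"cterm"`` keeps starts at or after floor(L/2).
    """
    if region not in ("nterm", "cterm", "anywhere"):
        raise ValueError(f"invalid region {region!r}")
    half = len(seq) // 2
    if region == "nterm":
        span = range(0, min(half, len(seq) - len(pattern.pattern) + 1))
    elif region == "cterm":
        span = range(half, len(seq) - len(pattern.pattern) + 1)
    else:
        span = range(0, len(seq) - len(pattern.pattern) + 1)
    return [i for i in span if pattern.matches_at(seq, i)]


def has_metal_binding_motifs(seq: str) -> bool:
    """N-terminal aspartate-rich motif AND C-terminal NSE motif present."""
    nterm = any(
        find_pattern(seq, p, region="nterm") for p in NTERM_DDXXD + NTERM_DDXXXE
    )
    return nterm and bool(find_pattern(seq, CTERM_NSE, region="cterm"))


def metal_binding_filter(seqs: list[ProteinRecord]) -> set[str]:
    """Ids of sequences carrying both conserved metal-binding motifs.

    This is the motif half of filter 2; it rejects the classic confounder,
    prenyltransferases that carry DDxxD but lack the C-terminal NSE motif.
    """
    return {rec.id for rec in seqs if has_metal_binding_motifs(rec.sequence)}


@dataclass
class DiscriminativeMotif:
    """An exact motif enriched in one clade and absent from the others."""

    motif: MotifPattern
    positive_freq: float
    clade: Clade = UNCLASSIFIED

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_freq <= 1.0):
            raise ValueError("positive_freq must be in (0, 1]")


def discover_motifs(
    positives: list[ProteinRecord],
    negatives: list[ProteinRecord],
    cfg: PipelineConfig | None = None,
    clade: Clade = UNCLASSIFIED,
) -> list[DiscriminativeMotif]:
    """Exact discriminative substring motifs of a positive set.

    Returns every substring of length kmin..kmax present in at least
    ``motif_min_freq`` of the positives and in none of the negatives,
    keeping maximal motifs only: a motif is dropped when some longer
    returned candidate contains it with an identical positive support
    set. Sorted by (frequency desc, length desc, lexicographic).
    """
    cfg = cfg or PipelineConfig()
    if not positives:
        raise ValueError("positive set must be non-empty")
    if not negatives:
        raise ValueError("negative set must be non-empty (discrimination undefined)")
    kmin, kmax = cfg.motif_kmin, cfg.motif_kmax

    support: dict[str, set[int]] = {}
    for idx, rec in enumerate(positives):
        seq = rec.sequence
        words = set()
        for k in range(kmin, kmax + 1):
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if "X" not in w:  # unknown residues cannot anchor a literal motif
                    words.add(w)
        for w in words:
            support.setdefault(w, set()).add(idx)

    n_pos = len(positives)
    min_count = cfg.motif_min_freq * n_pos
    frequent = {w: s for w, s in support.items() if len(s) >= min_count}

    neg_seqs = [rec.sequence for rec in negatives]

    def absent_from_negatives(word: str) -> bool:
        return not any(word in seq for seq in neg_seqs)

    candidates = {w: s for w, s in frequent.items() if absent_from_negatives(w)}

    # maximality: drop w if a longer candidate containing w has the same
    # positive support set (support of an extension is always a subset,
    # so equal size implies equal set)
    kept = []
    for w, sup in candidates.items():
        dominated = any(
            len(w2) > len(w) and w in w2 and candidates[w2] == sup
            for w2 in candidates
        )
        if not dominated:
            kept.append(w)

    kept.sort(key=lambda w: (-len(support[w]) / n_pos, -len(w), w))
    return [
        DiscriminativeMotif(
            motif=MotifPattern(w),
            positive_freq=len(support[w]) / n_pos,
            clade=clade,
        )
        for w in kept
    ]


def reassign_by_motif(
    unclassified: list[ProteinRecord],
    clade_motifs: dict[Clade, list[DiscriminativeMotif]],
) -> list[CladeCall]:
    """Reassign unclassified sequences that carry exactly one clade's motif.

    A sequence matching motifs of two or more clades, or none, stays
    unclassified. ``clade_motifs`` must have entries for all four clades.
    """
    missing = [c for c in CLADES if c not in clade_motifs]
    if missing:
        raise ValueError(f"clade_motifs missing clades {missing}")
    calls = []
    for rec in unclassified:
        matching = {
            clade
            for clade in CLADES
            for dm in clade_motifs[clade]
            if find_pattern(rec.sequence, dm.motif, region="anywhere")
        }
        clade = matching.pop() if len(matching) == 1 else UNCLASSIFIED
        calls.append(CladeCall(protein_id=rec.id, clade=clade, evidence="motif"))
    return calls
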