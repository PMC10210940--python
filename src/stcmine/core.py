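"""Domain types shared across the mining pipeline.

The pipeline screens predicted fungal proteomes for sesquiterpene cyclase
(STC) candidates and classifies them into four cyclization clades:

1. 1,10-cyclization of (2E,6E)-FPP
2. 1,10-cyclization of (3R)-NPP
3. 1,11-cyclization of (2E,6E)-FPP
4. 1,6/1,7-cyclization of (3R)-NPP

A fifth label, ``"unclassified"``, marks candidates without unambiguous
clade evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Union

#: The 20 canonical amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Unknown/ambiguous residue symbol. Maps to background in HMM scoring,
#: counts as a mismatch in identity, and matches nothing in motif literals.
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + UNKNOWN
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Ambiguity codes collapsed to X on input.
_AMBIGUOUS = set("BZJUO")

GAP = "-"

#: Clade label for candidates without unambiguous evidence.
UNCLASSIFIED = "unclassified"

#: A clade is an int in 1..4 or the string "unclassified".
Clade = Union[int, str]

CLADES = (1, 2, 3, 4)

#: Evidence sources for a clade call.
EVIDENCE_KINDS = ("distance_cluster", "motif", "hmm_best_score")

#: Division (taxonomic) labels carried by protein records.
DIVISIONS = ("basidiomycete", "ascomycete", "other")


def validate_clade(value: Clade, allow_unclassified: bool = True) -> Clade:
    """Check that *value* is 1-4 (or ``"unclassified"`` if allowed)."""
    if value in CLADES:
        return int(value)
    if allow_unclassified and value == UNCLASSIFIED:
        return UNCLASSIFIED
    raise ValueError(f"invalid clade label: {value!r}")


def normalize_sequence(raw: str) -> str:
    """Upper-case, strip ``*`` stops, map ambiguity codes B/Z/J/U/O to X.

    Raises ``ValueError`` on symbols outside the amino-acid alphabet.
    """
    seq = raw.upper().replace("*", "").replace(" ", "")
    out = []
    for ch in seq:
        if ch in _AMBIGUOUS:
            out.append(UNKNOWN)
        elif ch in AA_INDEX:
            out.append(ch)
        else:
            raise ValueError(f"invalid residue symbol {ch!r}")
    return "".join(out)


@dataclass
class ProteinRecord:
    """A named protein sequence with genome/division metadata."""

    id: str
    sequence: str
    genome_id: str = ""
    division: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of {self.id!r} must be non-empty")
        if self.division not in DIVISIONS:
            raise ValueError(f"invalid division {self.division!r}")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains invalid symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CladeCall:
    """Assignment of one protein to a cyclization clade.

    ``score`` is the bit score when evidence is ``hmm_best_score`` and must
    be absent otherwise.
    """

    protein_id: str
    clade: Clade
    evidence: str
    score: float | None = None

    def __post_init__(self) -> None:
        self.clade = validate_clade(self.clade)
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"invalid evidence {self.evidence!r}")
        if (self.score is not None) != (self.evidence == "hmm_best_score"):
            raise ValueError("score present iff evidence is hmm_best_score")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the published defaults.

    Filter 1 keeps candidates with a local-alignment hit above
    ``min_identity_pct`` percent identity and ``min_coverage_pct`` percent
    query coverage against a characterized seed (both strict bounds).
    Filter 3 keeps sequences with ``min_len_aa < length < max_len_aa``
    (exclusive bounds). ``gap_open``/``gap_extend`` are the affine penalties
    of the progressive aligner, in substitution-matrix units. HMM hits are
    retained at ``hmm_bit_threshold`` bits (the gathering threshold) and the
    second-generation models are trained on the ``refine_top_k`` top-scoring
    sequences per division. Two genes are tandem when at most
    ``tandem_window`` gene positions apart on one scaffold.
    """

    min_identity_pct: float = 30.0
    min_coverage_pct: float = 60.0
    min_len_aa: int = 250
    max_len_aa: int = 500
    gap_open: float = 2.3
    gap_extend: float = 0.63
    trim_gap_threshold: float = 0.5
    motif_min_freq: float = 0.75
    motif_kmin: int = 3
    motif_kmax: int = 6
    hmm_bit_threshold: float = 25.0
    refine_top_k: int = 100
    tandem_window: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity_pct <= 100.0):
            raise ValueError("min_identity_pct must be in [0, 100]")
        if not (0.0 <= self.min_coverage_pct <= 100.0):
            raise ValueError("min_coverage_pct must be in [0, 100]")
        if not self.min_len_aa < self.max_len_aa:
            raise ValueError("min_len_aa must be < max_len_aa")
        if not (0.0 < self.motif_min_freq <= 1.0):
            raise ValueError("motif_min_freq must be in (0, 1]")
        if self.motif_kmin > self.motif_kmax:
            raise ValueError("motif_kmin must be <= motif_kmax")
        if not (0.0 <= self.trim_gap_threshold <= 1.0):
            raise ValueError("trim_gap_threshold must be in [0, 1]")
        if self.tandem_window < 1:
            raise ValueError("tandem_window must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a plain ``key=value`` config file; unknown keys are errors."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                caster = int if "int" in str(known[key]) else float
                kwargs[key] = caster(value.strip())
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")


@dataclass
class FilterReport:
    """Per-genome survivor counts along the three-filter cascade."""

    genome_id: str
    n_input: int
    n_after_similarity: int
    n_after_motif: int
    n_after_length: int
    surviving_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_after_similarity,
            self.n_after_motif,
            self.n_after_length,
        )
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter counts must be non-increasing: {counts}")
        if self.n_after_length != len(self.surviving_ids):
            raise ValueError("n_after_length must equal len(surviving_ids)")
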