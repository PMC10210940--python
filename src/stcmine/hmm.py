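"""Profile hidden Markov models for STC clade families.

A model has L match states with per-state emission distributions over the
20 amino acids, insert states I0..IL, delete states D1..DL and per-node
transition bundles (Plan7-like, without I<->D transitions). Scoring is
*glocal*: the model must be traversed begin to end while the sequence may
have unaligned flanks, which are emitted at background frequencies and
therefore contribute 0 bits. The bit score is

    log2( P(sequence, path | model) / P(sequence | background) )

maximized over paths (Viterbi) or summed over paths and over flank splits
(forward). Unknown residues (X) emit background and contribute 0 bits.

Emission and transition probabilities are estimated from an alignment with
Laplace +1 pseudocounts; the background is uniform (0.05 per residue).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import hmm_glocal
from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    GAP,
    UNCLASSIFIED,
    Clade,
    CladeCall,
    ProteinRecord,
    validate_clade,
)

log = logging.getLogger(__name__)

# transition table columns
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

_PROB_TOL = 1e-9


@dataclass
class ProfileHmm:
    """A profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions``: (L, 20) rows for M1..ML. ``insert_emissions``:
    (L+1, 20) rows for I0..IL. ``transitions``: (L+1, 7) probability rows
    [MM, MI, MD, IM, II, DM, DD]; node 0 carries the begin wiring
    (B->M1, B->I0, B->D1) and node L the end wiring (M->E, I->E, D->E in
    the MM/IM/DM slots, with MD = DD = 0).
    """

    name: str
    clade: Clade
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clade = validate_clade(self.clade)
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        L = self.L
        if L < 1:
            raise ValueError("model must have at least one match state")
        if self.match_emissions.shape != (L, 20):
            raise ValueError("match_emissions must be (L, 20)")
        if self.insert_emissions.shape != (L + 1, 20):
            raise ValueError("insert_emissions must be (L+1, 20)")
        if self.transitions.shape != (L + 1, 7):
            raise ValueError("transitions must be (L+1, 7)")
        self._validate_probabilities()
        self._scoring_cache: tuple | None = None

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def _validate_probabilities(self) -> None:
        for name, rows in (
            ("match emission", self.match_emissions),
            ("insert emission", self.insert_emissions),
            ("background", self.background.reshape(1, -1)),
        ):
            sums = rows.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"{name} row {bad} sums to {sums[bad]:.6f}, expected 1"
                )
        t = self.transitions
        bundles = [
            ("M", t[:, [T_MM, T_MI, T_MD]].sum(axis=1)),
            ("I", t[:, [T_IM, T_II]].sum(axis=1)),
            ("D", t[:, [T_DM, T_DD]].sum(axis=1)),
        ]
        for name, sums in bundles:
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"{name} transition bundle at node {bad} sums to "
                    f"{sums[bad]:.6f}, expected 1"
                )
        if t[self.L, T_MD] != 0.0 or t[self.L, T_DD] != 0.0:
            raise ValueError("node L cannot transition to node L+1 deletes")

    def _scoring_tables(self):
        """Log2-odds tables for the kernels; X (index 20) scores 0."""
        if self._scoring_cache is None:
            L = self.L
            with np.errstate(divide="ignore"):
                mlo = np.zeros((L + 1, 21))
                mlo[1:, :20] = np.log2(self.match_emissions) - np.log2(
                    self.background
                )
                ilo = np.zeros((L + 1, 21))
                ilo[:, :20] = np.log2(self.insert_emissions) - np.log2(
                    self.background
                )
                tlog = np.log2(self.transitions)
            tlog[np.isneginf(tlog)] = -1.0e30
            self._scoring_cache = (mlo, ilo, tlog)
        return self._scoring_cache


def encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)


def score_sequence(hmm: ProfileHmm, seq: ProteinRecord | str, mode: str = "viterbi") -> float:
    """Glocal bit score of a sequence against a model."""
    if mode not in ("viterbi", "forward"):
        raise ValueError(f"unknown mode {mode!r}")
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq
    if not sequence:
        raise ValueError("sequence must be non-empty")
    mlo, ilo, tlog = hmm._scoring_tables()
    return float(hmm_glocal(encode(sequence), mlo, ilo, tlog, mode == "forward"))


def build_hmm(msa, name: str, clade: Clade) -> ProfileHmm:
    """Estimate a profile HMM from a (trimmed) alignment.

    Columns with gap fraction < 0.5 become match states; the remaining
    columns feed the flanking insert states. Emissions and transitions are
    count estimates with +1 pseudocount per residue / per outgoing edge.
    X residues are ignored in emission counts (they are not one of the 20).
    """
    rows = msa.rows
    n_rows = len(rows)
    if n_rows < 2:
        raise ValueError("need at least 2 aligned sequences")
    ncol = msa.column_count
    gap_frac = np.array(
        [sum(1 for r in rows if r[c] == GAP) / n_rows for c in range(ncol)]
    )
    is_match = gap_frac < 0.5
    L = int(is_match.sum())
    if L == 0:
        raise ValueError("no match states")
    # node index of each column: match columns get 1..L; insert columns
    # belong to the insert state of the preceding match node.
    node_of_col = np.zeros(ncol, dtype=int)
    k = 0
    for c in range(ncol):
        if is_match[c]:
            k += 1
        node_of_col[c] = k

    m_counts = np.zeros((L, 20))
    i_counts = np.zeros((L + 1, 20))
    t_counts = np.zeros((L + 1, 7))
    for row in rows:
        prev_state, prev_node = "B", 0
        for c in range(ncol):
            ch = row[c]
            if is_match[c]:
                node = node_of_col[c]
                state = "M" if ch != GAP else "D"
                if state == "M" and ch in AA_INDEX and ch != "X":
                    m_counts[node - 1, AA_INDEX[ch]] += 1
            else:
                if ch == GAP:
                    continue
                node = node_of_col[c]
                state = "I"
                if ch in AA_INDEX and ch != "X":
                    i_counts[node, AA_INDEX[ch]] += 1
            # D<->I adjacencies have no edge in the topology; skip them
            if (prev_state, state) not in (("D", "I"), ("I", "D")):
                t_counts[prev_node, _t_index(prev_state, state)] += 1
            prev_state, prev_node = state, node
        t_counts[prev_node, _t_index(prev_state, "M")] += 1  # exit to E

    match_em = (m_counts + 1.0) / (m_counts.sum(axis=1, keepdims=True) + 20.0)
    ins_em = (i_counts + 1.0) / (i_counts.sum(axis=1, keepdims=True) + 20.0)

    trans = np.zeros((L + 1, 7))
    for node in range(L + 1):
        m_edges = [T_MM, T_MI] if node == L else [T_MM, T_MI, T_MD]
        d_edges = [T_DM] if node == L else [T_DM, T_DD]
        for edges in (m_edges, [T_IM, T_II], d_edges):
            counts = t_counts[node, edges] + 1.0
            trans[node, edges] = counts / counts.sum()
    return ProfileHmm(
        name=name,
        clade=clade,
        match_emissions=match_em,
        insert_emissions=ins_em,
        transitions=trans,
    )


def _t_index(src: str, dst: str) -> int:
    if src in ("B", "M"):
        return {"M": T_MM, "I": T_MI, "D": T_MD}[dst]
    if src == "I":
        return {"M": T_IM, "I": T_II}[dst]
    if src == "D":
        return {"M": T_DM, "D": T_DD}[dst]
    raise ValueError(f"bad state {src}")


@dataclass
class HmmHit:
    """One retained model/sequence match (bit score above threshold)."""

    protein_id: str
    model_name: str
    clade: Clade
    bit_score: float

    def __post_init__(self) -> None:
        self.clade = validate_clade(self.clade)
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")


def hmm_search(
    hmms: list[ProfileHmm],
    proteome: list[ProteinRecord],
    threshold: float = 25.0,
) -> list[HmmHit]:
    """Score every sequence against every model; keep hits >= threshold."""
    if not hmms:
        raise ValueError("need at least one model")
    hits = []
    for rec in proteome:
        for hmm in hmms:
            score = score_sequence(hmm, rec, mode="viterbi")
            if score >= threshold:
                hits.append(
                    HmmHit(
                        protein_id=rec.id,
                        model_name=hmm.name,
                        clade=hmm.clade,
                        bit_score=score,
                    )
                )
    return hits


def assign_by_best_score(hits: list[HmmHit]) -> list[CladeCall]:
    """Assign each hit protein to the clade of its best-scoring model.

    An exact bit-score tie across different clades leaves the protein
    unclassified (with a warning). Output is sorted by protein id.
    """
    by_protein: dict[str, list[HmmHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    calls = []
    for pid in sorted(by_protein):
        group = by_protein[pid]
        best = max(h.bit_score for h in group)
        top_clades = {h.clade for h in group if h.bit_score == best}
        if len(top_clades) == 1:
            calls.append(
                CladeCall(
                    protein_id=pid,
                    clade=top_clades.pop(),
                    evidence="hmm_best_score",
                    score=best,
                )
            )
        else:
            log.warning(
                "protein %s: exact bit-score tie across clades %s; unclassified",
                pid,
                sorted(top_clades),
            )
            calls.append(
                CladeCall(
                    protein_id=pid,
                    clade=UNCLASSIFIED,
                    evidence="hmm_best_score",
                    score=best,
                )
            )
    return calls


def refine_generation2(
    gen1_hmms: list[ProfileHmm],
    all_hits: list[HmmHit],
    proteins: dict[str, ProteinRecord],
    top_k: int = 100,
    gap_open: float = 2.3,
    gap_extend: float = 0.63,
    trim_gap_threshold: float = 0.5,
) -> list[ProfileHmm]:
    """Rebuild one model per clade from the top-scoring hits.

    Per clade, the ``top_k`` best-scoring basidiomycete-derived and
    ``top_k`` best-scoring ascomycete-derived sequences (fewer if fewer
    exist; other divisions are pooled with basidiomycetes) are aligned,
    trimmed and used to re-estimate the model.
    """
    from .msa import progressive_align, trim_msa

    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    calls = assign_by_best_score(all_hits)
    clade_of = {c.protein_id: c.clade for c in calls}
    score_of = {c.protein_id: c.score for c in calls}
    models = []
    for hmm in sorted(gen1_hmms, key=lambda h: h.clade):
        clade = hmm.clade
        members = [pid for pid, cl in clade_of.items() if cl == clade]
        if not members:
            raise ValueError(f"no hits assigned to clade {clade}")
        train_ids: list[str] = []
        for division in ("basidiomycete", "ascomycete"):
            if division == "basidiomycete":
                pool = [p for p in members if proteins[p].division != "ascomycete"]
            else:
                pool = [p for p in members if proteins[p].division == "ascomycete"]
            pool.sort(key=lambda p: (-score_of[p], p))
            train_ids.extend(pool[:top_k])
        train = [proteins[p] for p in sorted(train_ids)]
        if len(train) < 2:
            raise ValueError(f"clade {clade}: fewer than 2 training sequences")
        msa = trim_msa(
            progressive_align(train, gap_open=gap_open, gap_extend=gap_extend),
            gap_threshold=trim_gap_threshold,
        )
        models.append(build_hmm(msa, name=f"gen2-clade{clade}", clade=clade))
    return models


# ---------------------------------------------------------------------------
# plain-text serialization (.shmm)

_FMT = "%.17g"


def _fmt_logs(probs: np.ndarray) -> str:
    with np.errstate(divide="ignore"):
        logs = np.log(probs)
    return " ".join(_FMT % v if np.isfinite(v) else "-inf" for v in logs)


def write_hmm(hmm: ProfileHmm, path) -> None:
    """Serialize a model as plain text (natural-log probabilities)."""
    with open(path, "w") as fh:
        fh.write("SHMM1\n")
        fh.write(f"name {hmm.name}\n")
        fh.write(f"clade {hmm.clade}\n")
        fh.write(f"L {hmm.L}\n")
        fh.write(f"background {_fmt_logs(hmm.background)}\n")
        for k in range(hmm.L):
            fh.write(f"match {k + 1} {_fmt_logs(hmm.match_emissions[k])}\n")
        for k in range(hmm.L + 1):
            fh.write(f"insert {k} {_fmt_logs(hmm.insert_emissions[k])}\n")
        for k in range(hmm.L + 1):
            fh.write(f"trans {k} {_fmt_logs(hmm.transitions[k])}\n")
        fh.write("END\n")


def read_hmm(path) -> ProfileHmm:
    """Parse a serialized model; malformed content raises with line number."""

    def parse_logs(tokens, lineno, expect):
        if len(tokens) != expect:
            raise ValueError(f"{path}:{lineno}: expected {expect} values")
        return np.exp([float(t) for t in tokens])

    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines or lines[0] != "SHMM1":
        raise ValueError(f"{path}:1: missing SHMM1 magic")
    header: dict[str, str] = {}
    idx = 1
    for key in ("name", "clade", "L"):
        parts = lines[idx].split(" ", 1)
        if parts[0] != key or len(parts) != 2:
            raise ValueError(f"{path}:{idx + 1}: expected '{key} <value>'")
        header[key] = parts[1]
        idx += 1
    L = int(header["L"])
    clade: Clade = header["clade"]
    if clade != UNCLASSIFIED:
        clade = int(clade)
    parts = lines[idx].split()
    if parts[0] != "background":
        raise ValueError(f"{path}:{idx + 1}: expected background line")
    background = parse_logs(parts[1:], idx + 1, 20)
    idx += 1
    match_em = np.zeros((L, 20))
    for k in range(L):
        parts = lines[idx].split()
        if parts[:2] != ["match", str(k + 1)]:
            raise ValueError(f"{path}:{idx + 1}: expected 'match {k + 1}'")
        match_em[k] = parse_logs(parts[2:], idx + 1, 20)
        idx += 1
    ins_em = np.zeros((L + 1, 20))
    for k in range(L + 1):
        parts = lines[idx].split()
        if parts[:2] != ["insert", str(k)]:
            raise ValueError(f"{path}:{idx + 1}: expected 'insert {k}'")
        ins_em[k] = parse_logs(parts[2:], idx + 1, 20)
        idx += 1
    trans = np.zeros((L + 1, 7))
    for k in range(L + 1):
        parts = lines[idx].split()
        if parts[:2] != ["trans", str(k)]:
            raise ValueError(f"{path}:{idx + 1}: expected 'trans {k}'")
        trans[k] = parse_logs(parts[2:], idx + 1, 7)
        idx += 1
    if idx >= len(lines) or lines[idx] != "END":
        raise ValueError(f"{path}:{idx + 1}: missing END")
    try:
        return ProfileHmm(
            name=header["name"],
            clade=clade,
            match_emissions=match_em,
            insert_emissions=ins_em,
            transitions=trans,
            background=background,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
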