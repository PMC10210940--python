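"""Seeded synthetic fixtures: planted clade models, families, decoys, genomes.

The generator emulates the study conditions end to end without external
data: four clade families are sampled from planted profile HMMs that carry
the conserved metal-binding motifs (N-terminal (D/N)DxxE-style and
C-terminal NxxxSxxxE, at protected model positions that admit no indels)
plus one clade-specific signature motif per family (defaults DTSGC,
LRRENS, DLMN, FYK). Decoys mirror the pipeline's real confounders:
prenyltransferase-like sequences (similar to a clade family and carrying
DDxxD, but with the C-terminal NSE motif destroyed), unrelated background
proteins, and wrong-length sequences that sail through the similarity and
motif filters but fall outside the 250-500 aa window. Gene layouts place
STC genes singly or in tandem clusters so that tandem statistics have a
known ground truth.

Everything is deterministic under the spec seed; the sampler uses the same
ProfileHmm machinery that scoring uses, so parameter-recovery experiments
are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, CLADES, Clade, ProteinRecord, validate_clade
from .genome import GeneLocus
from .hmm import (
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    ProfileHmm,
)
from .motifs import CTERM_NSE, MotifPattern, find_pattern

DEFAULT_CLADE_MOTIFS = {1: "DTSGC", 2: "LRRENS", 3: "DLMN", 4: "FYK"}

#: model-coordinate offsets of the planted metal motifs
_NTERM_START = 25  # N D x x E
_CTERM_OFFSET_FROM_END = 50  # N x x x S x x x E


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset."""

    family_size: int = 30
    divergence: float = 12.0
    planted_motifs: dict = field(default_factory=lambda: dict(DEFAULT_CLADE_MOTIFS))
    motif_penetrance: float = 0.9
    n_prenyltransferase_like: int = 20
    n_unrelated: int = 20
    n_wrong_length: int = 20
    refs_per_clade: int = 2
    n_scaffolds: int = 6
    tandem_cluster_prob: float = 0.4
    tandem_cluster_size: int = 2
    tandem_window: int = 4
    genome_id: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        if not (0.0 < self.motif_penetrance <= 1.0):
            raise ValueError("motif_penetrance must be in (0, 1]")
        if set(self.planted_motifs) != set(CLADES):
            raise ValueError("planted_motifs must cover clades 1-4")


def _model_length(clade: int) -> int:
    return 320 + 8 * clade


def make_clade_model(
    clade: Clade,
    length: int,
    divergence: float,
    seed: int,
    planted_motif: str | None = None,
) -> ProfileHmm:
    """A planted profile HMM for one cyclization clade.

    Match emissions are Dirichlet-like draws whose concentration on a
    random consensus residue is ``divergence`` (higher = more conserved).
    The metal-binding motif residues and the clade signature motif are
    hard-coded (one-hot) at fixed model positions, and the transition
    structure forbids indels inside or adjacent to the planted spans so
    every sampled sequence carries them intact.
    """
    clade = validate_clade(clade, allow_unclassified=False)
    if not (250 < length < 500):
        raise ValueError(f"model length must be in (250, 500), got {length}")
    motif = planted_motif if planted_motif is not None else DEFAULT_CLADE_MOTIFS[clade]
    rng = np.random.default_rng(seed)
    L = length

    alphas = np.full((L, 20), 0.25)
    consensus = rng.integers(0, 20, size=L)
    alphas[np.arange(L), consensus] += divergence
    match_em = rng.gamma(shape=alphas)
    match_em /= match_em.sum(axis=1, keepdims=True)

    aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def plant(start: int, letters: dict[int, str]) -> None:
        for off, letter in letters.items():
            row = np.zeros(20)
            row[aa_idx[letter]] = 1.0
            match_em[start + off] = row

    nterm = _NTERM_START
    plant(nterm, {0: "N", 1: "D", 4: "E"})  # (D/N)Dxx(D/E) instance
    cterm = L - _CTERM_OFFSET_FROM_END
    plant(cterm, {0: "N", 4: "S", 8: "E"})  # NxxxSxxxE
    motif_start = L // 2 + 15 + 12 * clade
    plant(motif_start, {i: ch for i, ch in enumerate(motif)})
    if motif_start + len(motif) >= cterm:
        raise ValueError("planted spans overlap; increase model length")

    trans = np.zeros((L + 1, 7))
    trans[:, [T_MM, T_MI, T_MD]] = (0.98, 0.01, 0.01)
    trans[:, [T_IM, T_II]] = (0.7, 0.3)
    trans[:, [T_DM, T_DD]] = (0.7, 0.3)
    # node L: exits to E
    trans[L, [T_MM, T_MI, T_MD]] = (0.99, 0.01, 0.0)
    trans[L, [T_DM, T_DD]] = (1.0, 0.0)

    # protect planted spans (match nodes are 1-based: column c -> node c+1)
    spans = [
        (nterm, nterm + 5),
        (cterm, cterm + 9),
        (motif_start, motif_start + len(motif)),
    ]
    for start, stop in spans:
        for node in range(start, stop + 1):  # node before span .. last span node
            trans[node, [T_MM, T_MI, T_MD]] = (1.0, 0.0, 0.0)
            trans[node, [T_DM, T_DD]] = (1.0, 0.0)

    insert_em = np.full((L + 1, 20), 0.05)
    return ProfileHmm(
        name=f"planted-clade{clade}",
        clade=clade,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        meta={
            "planted_motif": motif,
            "motif_nodes": (motif_start + 1, motif_start + len(motif)),
            "metal_nterm_nodes": (nterm + 1, nterm + 5),
            "metal_cterm_nodes": (cterm + 1, cterm + 9),
        },
    )


def _sample_path(model: ProfileHmm, rng) -> tuple[str, list[int]]:
    """Sample one sequence; returns (sequence, per-position match node or -1)."""
    t = model.transitions
    L = model.L
    cum = model.meta.get("_sampling_cumsums")
    if cum is None:
        cum = {
            "m_em": np.cumsum(model.match_emissions, axis=1),
            "i_em": np.cumsum(model.insert_emissions, axis=1),
            "M": np.cumsum(t[:, [T_MM, T_MI, T_MD]], axis=1),
            "I": np.cumsum(t[:, [T_IM, T_II]], axis=1),
            "D": np.cumsum(t[:, [T_DM, T_DD]], axis=1),
        }
        model.meta["_sampling_cumsums"] = cum
    seq: list[str] = []
    nodes: list[int] = []
    state, node = "M", 0  # begin occupies the M slot of node 0
    while True:
        nxt = int(np.searchsorted(cum[state][node], rng.random(), side="right"))
        if state == "I":
            if nxt == 0:
                state, node = "M", node + 1
            # else stay in I at the same node
        elif nxt == 0:
            state, node = "M", node + 1
        elif state == "M" and nxt == 1:
            state = "I"
        else:
            state, node = "D", node + 1
        if node > L:
            break
        if state == "M":
            aa_i = int(np.searchsorted(cum["m_em"][node - 1], rng.random(), side="right"))
            seq.append(AMINO_ACIDS[aa_i])
            nodes.append(node)
        elif state == "I":
            aa_i = int(np.searchsorted(cum["i_em"][node], rng.random(), side="right"))
            seq.append(AMINO_ACIDS[aa_i])
            nodes.append(-1)
    return "".join(seq), nodes


def _positions_of_nodes(nodes: list[int], span: tuple[int, int]) -> list[int]:
    lo, hi = span
    return [i for i, nd in enumerate(nodes) if lo <= nd <= hi]


def _scrub_forbidden(
    seq: list[str],
    forbidden: tuple[str, ...],
    protected: set[int],
    rng,
) -> None:
    """Mutate residues until no forbidden motif occurs; in place.

    Protected positions (planted metal/own-motif literals) are never
    touched; forbidden occurrences always contain an unprotected position
    with the default motif geometry.
    """
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for word in forbidden:
            idx = s.find(word)
            if idx < 0:
                continue
            free = [p for p in range(idx, idx + len(word)) if p not in protected]
            if not free:
                raise RuntimeError(f"cannot scrub {word!r}: all positions protected")
            p = int(rng.choice(np.array(free)))
            old = seq[p]
            choices = [a for a in AMINO_ACIDS if a != old]
            seq[p] = choices[int(rng.integers(0, len(choices)))]
            changed = True
            break


def sample_family(
    model: ProfileHmm,
    n: int,
    penetrance: float,
    seed: int,
    id_prefix: str = "stc",
    genome_id: str = "sim1",
    forbidden_motifs: tuple[str, ...] = (),
    return_truth: bool = False,
):
    """Sample n family members from a planted model.

    With probability ``1 - penetrance`` a sequence's clade-motif positions
    are resampled from background (motif knocked out). Divisions alternate
    basidiomycete/ascomycete. ``forbidden_motifs`` (the other clades'
    signatures) are scrubbed so they never occur in the family.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    motif = model.meta.get("planted_motif")
    motif_span = model.meta.get("motif_nodes")
    records = []
    truth = []
    for i in range(n):
        seq_str, nodes = _sample_path(model, rng)
        seq = list(seq_str)
        knocked_out = False
        if motif_span is not None and rng.random() > penetrance:
            for p in _positions_of_nodes(nodes, motif_span):
                seq[p] = AMINO_ACIDS[rng.integers(0, 20)]
            knocked_out = True
        protected = set()
        for key in ("metal_nterm_nodes", "metal_cterm_nodes"):
            if key in model.meta:
                protected.update(_positions_of_nodes(nodes, model.meta[key]))
        if motif_span is not None and not knocked_out:
            protected.update(_positions_of_nodes(nodes, motif_span))
        if forbidden_motifs:
            _scrub_forbidden(seq, tuple(forbidden_motifs), protected, rng)
        sequence = "".join(seq)
        records.append(
            ProteinRecord(
                id=f"{id_prefix}{i:03d}",
                sequence=sequence,
                genome_id=genome_id,
                division="basidiomycete" if i % 2 == 0 else "ascomycete",
            )
        )
        if return_truth:
            truth.append(
                {
                    "motif_knocked_out": knocked_out,
                    "motif_present": motif in sequence if motif else False,
                }
            )
    return (records, truth) if return_truth else records


def make_decoys(
    kind: str,
    n: int,
    seed: int,
    template_models: list[ProfileHmm] | None = None,
    forbidden_motifs: tuple[str, ...] = tuple(DEFAULT_CLADE_MOTIFS.values()),
    genome_id: str = "sim1",
) -> list[ProteinRecord]:
    """Decoy proteins of one kind.

    ``prenyltransferase_like``: sampled from a clade model (hence similar
    to the families), N-terminal motif rewritten to DDxxD, C-terminal NSE
    motif destroyed — passes filter 1, fails filter 2.
    ``unrelated``: background-random sequences — fail filter 1.
    ``wrong_length``: alternately model-derived sequences padded with
    background flanks to >= 500 aa (pass filters 1 and 2, fail the length
    filter) and short background sequences (~200 aa) carrying both metal
    motifs.
    """
    if kind not in ("prenyltransferase_like", "unrelated", "wrong_length"):
        raise ValueError(f"unknown decoy kind {kind!r}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        if kind == "unrelated":
            length = int(rng.integers(260, 480))
            seq = [AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length)]
            _scrub_forbidden(seq, forbidden_motifs, set(), rng)
            seq = _scrub_nse(seq, rng)  # keep them out of the motif filter too
            sequence = "".join(seq)
        elif kind == "prenyltransferase_like":
            if not template_models:
                raise ValueError("prenyltransferase_like decoys need template models")
            model = template_models[i % len(template_models)]
            seq_str, nodes = _sample_path(model, rng)
            seq = list(seq_str)
            npos = _positions_of_nodes(nodes, model.meta["metal_nterm_nodes"])
            seq[npos[0]] = "D"  # N -> D: the DDxxD prenyltransferase signature
            seq[npos[4]] = "D"
            for p in _positions_of_nodes(nodes, model.meta["metal_cterm_nodes"]):
                seq[p] = AMINO_ACIDS[rng.integers(0, 20)]
            protected = set(npos)
            _scrub_forbidden(seq, forbidden_motifs, protected, rng)
            seq = _scrub_nse(seq, rng, protected)
            sequence = "".join(seq)
        else:  # wrong_length
            if template_models and i % 2 == 0:
                model = template_models[(i // 2) % len(template_models)]
                seq_str, nodes = _sample_path(model, rng)
                seq = list(seq_str)
                protected = set()
                for key in ("metal_nterm_nodes", "metal_cterm_nodes"):
                    protected.update(_positions_of_nodes(nodes, model.meta[key]))
                _scrub_forbidden(seq, forbidden_motifs, protected, rng)
                prepad = [AMINO_ACIDS[j] for j in rng.integers(0, 20, size=150)]
                postlen = max(5, 520 - 150 - len(seq))
                postpad = [AMINO_ACIDS[j] for j in rng.integers(0, 20, size=postlen)]
                sequence = "".join(prepad + seq + postpad)
            else:
                length = int(rng.integers(120, 220))
                seq = [AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length)]
                for off, letter in ((0, "D"), (1, "D"), (4, "E")):
                    seq[15 + off] = letter
                cstart = length - 30
                for off, letter in ((0, "N"), (4, "S"), (8, "E")):
                    seq[cstart + off] = letter
                _scrub_forbidden(
                    seq,
                    forbidden_motifs,
                    {15, 16, 19, cstart, cstart + 4, cstart + 8},
                    rng,
                )
                sequence = "".join(seq)
        records.append(
            ProteinRecord(
                id=f"{kind[:6]}{i:03d}",
                sequence=sequence,
                genome_id=genome_id,
                division="other",
            )
        )
    return records


def _scrub_nse(seq: list[str], rng, protected: set[int] | None = None) -> list[str]:
    """Mutate until no C-terminal-half NxxxSxxxE occurrence remains."""
    protected = protected or set()
    while True:
        hits = find_pattern("".join(seq), CTERM_NSE, region="cterm")
        hits = [h for h in hits]
        if not hits:
            return seq
        h = hits[0]
        for p in (h + 4, h, h + 8):  # prefer mutating the S anchor
            if p not in protected:
                old = seq[p]
                choices = [a for a in AMINO_ACIDS if a != old and a not in "NSE"]
                seq[p] = choices[int(rng.integers(0, len(choices)))]
                break
        else:
            raise RuntimeError("cannot scrub NSE motif: all anchors protected")


@dataclass
class SimulatedDataset:
    """Everything one run of the pipeline needs, with ground truth."""

    spec: SimSpec
    proteome: list
    references: list
    ref_clades: dict
    loci: list
    truth: pd.DataFrame
    models: list


def make_genome(spec: SimSpec, seed: int | None = None) -> SimulatedDataset:
    """Generate the full fixture: proteome, references, layout, truth."""
    seed = spec.seed if seed is None else seed
    root = np.random.default_rng(seed)
    child = lambda: int(root.integers(0, 2**31 - 1))  # noqa: E731

    models = [
        make_clade_model(
            c,
            _model_length(c),
            spec.divergence,
            child(),
            planted_motif=spec.planted_motifs[c],
        )
        for c in CLADES
    ]
    all_motifs = tuple(spec.planted_motifs[c] for c in CLADES)

    truth_rows = []
    proteome: list[ProteinRecord] = []
    clade_of: dict[str, int] = {}
    for model in models:
        clade = model.clade
        forbidden = tuple(m for c, m in spec.planted_motifs.items() if c != clade)
        fam, fam_truth = sample_family(
            model,
            spec.family_size,
            spec.motif_penetrance,
            child(),
            id_prefix=f"stc_c{clade}_",
            genome_id=spec.genome_id,
            forbidden_motifs=forbidden,
            return_truth=True,
        )
        proteome.extend(fam)
        for rec, info in zip(fam, fam_truth):
            clade_of[rec.id] = clade
            truth_rows.append(
                {
                    "protein_id": rec.id,
                    "kind": "stc",
                    "clade": clade,
                    "division": rec.division,
                    **info,
                }
            )

    references = []
    ref_clades: dict[str, int] = {}
    for model in models:
        clade = model.clade
        forbidden = tuple(m for c, m in spec.planted_motifs.items() if c != clade)
        refs = sample_family(
            model,
            spec.refs_per_clade,
            1.0,
            child(),
            id_prefix=f"ref_c{clade}_",
            genome_id="reference",
            forbidden_motifs=forbidden,
        )
        references.extend(refs)
        for r in refs:
            ref_clades[r.id] = clade

    decoy_specs = [
        ("prenyltransferase_like", spec.n_prenyltransferase_like),
        ("unrelated", spec.n_unrelated),
        ("wrong_length", spec.n_wrong_length),
    ]
    for kind, n in decoy_specs:
        if n == 0:
            continue
        decoys = make_decoys(
            kind,
            n,
            child(),
            template_models=models,
            forbidden_motifs=all_motifs,
            genome_id=spec.genome_id,
        )
        proteome.extend(decoys)
        for rec in decoys:
            truth_rows.append(
                {
                    "protein_id": rec.id,
                    "kind": kind,
                    "clade": 0,
                    "division": rec.division,
                    "motif_knocked_out": False,
                    "motif_present": False,
                }
            )

    # --- genome layout ---------------------------------------------------
    groups: list[list[str]] = []
    for model in models:
        members = [r.id for r in proteome if clade_of.get(r.id) == model.clade]
        i = 0
        while i < len(members):
            size = 1
            if root.random() < spec.tandem_cluster_prob:
                size = min(spec.tandem_cluster_size, len(members) - i)
            groups.append(members[i : i + size])
            i += size
    for rec in proteome:
        if rec.id not in clade_of:
            groups.append([rec.id])
    order = root.permutation(len(groups))
    groups = [groups[k] for k in order]

    cursors = {f"scaffold_{s + 1}": 0 for s in range(spec.n_scaffolds)}
    loci = []
    cluster_of: dict[str, int] = {}
    n_clusters = 0
    for gi, group in enumerate(groups):
        scaffold = f"scaffold_{(gi % spec.n_scaffolds) + 1}"
        cursors[scaffold] += spec.tandem_window + 1 + int(root.integers(0, 3))
        cluster_id = -1
        if len(group) > 1:
            cluster_id = n_clusters
            n_clusters += 1
        for mi, pid in enumerate(group):
            if mi > 0:
                cursors[scaffold] += int(root.integers(1, spec.tandem_window + 1))
            strand = "+" if root.random() < 0.5 else "-"
            loci.append(
                GeneLocus(spec.genome_id, scaffold, cursors[scaffold], strand, pid)
            )
            if cluster_id >= 0:
                cluster_of[pid] = cluster_id
    perm = root.permutation(len(proteome))
    proteome = [proteome[k] for k in perm]

    truth = pd.DataFrame(truth_rows)
    truth["tandem_cluster"] = truth["protein_id"].map(
        lambda p: cluster_of.get(p, -1)
    )
    return SimulatedDataset(
        spec=spec,
        proteome=proteome,
        references=references,
        ref_clades=ref_clades,
        loci=loci,
        truth=truth,
        models=models,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the fixture as plain-text files (FASTA/TSV/.shmm)."""
    import os

    from .hmm import write_hmm
    from .io import write_fasta, write_gene_order

    os.makedirs(os.path.join(str(outdir), "models"), exist_ok=True)
    write_fasta(ds.proteome, os.path.join(str(outdir), "proteome.faa"))
    write_fasta(ds.references, os.path.join(str(outdir), "references.faa"))
    with open(os.path.join(str(outdir), "ref_clades.tsv"), "w") as fh:
        for pid, clade in ds.ref_clades.items():
            fh.write(f"{pid}\t{clade}\n")
    write_gene_order(ds.loci, os.path.join(str(outdir), "genes.tsv"))
    ds.truth.to_csv(os.path.join(str(outdir), "truth.tsv"), sep="\t", index=False)
    for model in ds.models:
        write_hmm(model, os.path.join(str(outdir), "models", f"{model.name}.shmm"))
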