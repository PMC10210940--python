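"""Readers and writers for the pipeline's plain-text formats.

FASTA in/out goes through Biopython. Tabular formats are TSV with fixed
column orders; floats are printed with 6 decimals so outputs diff cleanly.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import UNCLASSIFIED, Clade, CladeCall, ProteinRecord, normalize_sequence, validate_clade
from .genome import GeneLocus

log = logging.getLogger(__name__)


def read_fasta(path, genome_id: str = "", division: str = "other") -> list[ProteinRecord]:
    """Read a protein FASTA into normalized records.

    Sequences are upper-cased, ``*`` stops stripped and ambiguity codes
    mapped to X. Duplicate ids raise; an empty file logs a warning and
    returns an empty list.
    """
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=normalize_sequence(str(entry.seq)),
                genome_id=genome_id,
                division=division,
            )
        )
    if not records:
        log.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_clade_table(path) -> dict[str, Clade]:
    """Read a two-column TSV ``protein_id<TAB>clade`` with clade in 1-4."""
    table: dict[str, Clade] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pid, token = parts
            try:
                clade = validate_clade(int(token), allow_unclassified=False)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad clade {token!r}") from exc
            table[pid] = clade
    if not table:
        log.warning("no clade labels found in %s", path)
    return table


def read_gene_order(path) -> list[GeneLocus]:
    """Read a gene-order TSV: genome_id, scaffold, ordinal, strand, protein_id.

    Loci are returned grouped by (genome, scaffold) and sorted by ordinal;
    duplicate (genome, scaffold, ordinal) slots raise.
    """
    loci = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            genome_id, scaffold, ordinal, strand, protein_id = parts
            locus = GeneLocus(genome_id, scaffold, int(ordinal), strand, protein_id)
            slot = (genome_id, scaffold, locus.ordinal)
            if slot in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene slot {slot}")
            seen.add(slot)
            loci.append(locus)
    loci.sort(key=lambda l: (l.genome_id, l.scaffold, l.ordinal))
    return loci


def write_gene_order(loci: Iterable[GeneLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.genome_id}\t{l.scaffold}\t{l.ordinal}\t{l.strand}\t{l.protein_id}\n")


def write_calls(calls: Iterable[CladeCall], path) -> None:
    """Write clade calls as TSV: protein_id, clade, evidence, score."""
    with open(path, "w") as fh:
        fh.write("protein_id\tclade\tevidence\tscore\n")
        for c in calls:
            score = "" if c.score is None else f"{c.score:.6f}"
            fh.write(f"{c.protein_id}\t{c.clade}\t{c.evidence}\t{score}\n")


def read_calls(path) -> list[CladeCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id\t"):
            raise ValueError(f"{path}:1: missing header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            pid, clade, evidence, score = line.split("\t")
            calls.append(
                CladeCall(
                    protein_id=pid,
                    clade=clade if clade == UNCLASSIFIED else int(clade),
                    evidence=evidence,
                    score=float(score) if score else None,
                )
            )
    return calls


def write_hits_tsv(rows: Iterable[tuple], path, header: tuple[str, ...]) -> None:
    """Write a generic hits table; floats formatted with 6 decimals."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = [
                f"{v:.6f}" if isinstance(v, float) else str(v) for v in row
            ]
            fh.write("\t".join(cells) + "\n")
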