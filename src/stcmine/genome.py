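"""Tandem-duplication analysis of classified STC genes.

Two STC genes are in tandem when the second copy lies among the
``window`` genes upstream or downstream of the first on the same
scaffold (default window 4, counting all annotated genes in the
ordinal ranking, strand-agnostic). Tandem clusters are the connected
components of the resulting pair graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .core import CLADES, Clade, validate_clade


@dataclass(frozen=True)
class GeneLocus:
    """One gene's position in a genome: scaffold plus ordinal rank."""

    genome_id: str
    scaffold: str
    ordinal: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError(f"ordinal must be >= 1, got {self.ordinal}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class TandemReport:
    """Summary statistics of tandem organisation among STC genes.

    ``fraction_pairs_same_clade`` is computed over pairs whose both members
    carry a definite clade (1-4); pairs involving an unclassified member are
    counted separately in ``n_pairs_with_unclassified``. Because the
    published statistic is phrased per gene, ``fraction_genes_same_clade``
    (genes with at least one same-clade tandem partner, among clade-labelled
    tandem genes) is reported as well.
    """

    n_stc: int
    n_in_tandem: int
    fraction_in_tandem: float
    n_tandem_pairs: int
    fraction_pairs_same_clade: float
    fraction_genes_same_clade: float
    n_pairs_with_unclassified: int
    clusters: list = field(default_factory=list)


def detect_tandem(
    loci: Iterable[GeneLocus],
    stc_calls: Mapping[str, Clade],
    window: int = 4,
) -> TandemReport:
    """Find tandem STC pairs/clusters and the same-clade fractions.

    Parameters
    ----------
    loci
        Gene order for every annotated gene (not only STC); ordinals rank
        genes along their scaffold.
    stc_calls
        protein_id -> clade (1-4 or "unclassified") for the STC genes.
    window
        Maximum ordinal distance for a tandem pair. ``window=0`` is allowed
        for degenerate analyses and yields no pairs.
    """
    for pid, clade in stc_calls.items():
        validate_clade(clade)
    locus_by_id = {}
    seen_slots = set()
    for locus in loci:
        slot = (locus.genome_id, locus.scaffold, locus.ordinal)
        if slot in seen_slots:
            raise ValueError(f"duplicate gene slot {slot}")
        seen_slots.add(slot)
        locus_by_id[locus.protein_id] = locus

    missing = sorted(set(stc_calls) - set(locus_by_id))
    if missing:
        raise ValueError(f"STC ids missing from gene order: {missing}")

    stc_loci = sorted(
        (locus_by_id[pid] for pid in stc_calls),
        key=lambda l: (l.genome_id, l.scaffold, l.ordinal),
    )
    graph = nx.Graph()
    graph.add_nodes_from(l.protein_id for l in stc_loci)
    pairs = []
    for a, b in combinations(stc_loci, 2):
        if a.genome_id == b.genome_id and a.scaffold == b.scaffold:
            if abs(a.ordinal - b.ordinal) <= window:
                pairs.append((a.protein_id, b.protein_id))
                graph.add_edge(a.protein_id, b.protein_id)

    in_tandem = {pid for pair in pairs for pid in pair}
    clusters = [
        sorted(comp, key=lambda pid: locus_by_id[pid].ordinal)
        for comp in nx.connected_components(graph)
        if len(comp) > 1
    ]
    clusters.sort(key=lambda c: (
        locus_by_id[c[0]].genome_id,
        locus_by_id[c[0]].scaffold,
        locus_by_id[c[0]].ordinal,
    ))

    definite_pairs = [
        (a, b)
        for a, b in pairs
        if stc_calls[a] in CLADES and stc_calls[b] in CLADES
    ]
    same_clade_pairs = [
        (a, b) for a, b in definite_pairs if stc_calls[a] == stc_calls[b]
    ]
    n_unc_pairs = len(pairs) - len(definite_pairs)

    # Gene-phrased statistic: among clade-labelled tandem genes, the
    # fraction with >=1 same-clade partner.
    labelled_tandem = [p for p in in_tandem if stc_calls[p] in CLADES]
    genes_same = {pid for pair in same_clade_pairs for pid in pair}
    frac_genes_same = (
        len(genes_same & set(labelled_tandem)) / len(labelled_tandem)
        if labelled_tandem
        else 0.0
    )

    n_stc = len(stc_calls)
    return TandemReport(
        n_stc=n_stc,
        n_in_tandem=len(in_tandem),
        fraction_in_tandem=len(in_tandem) / n_stc if n_stc else 0.0,
        n_tandem_pairs=len(pairs),
        fraction_pairs_same_clade=(
            len(same_clade_pairs) / len(definite_pairs) if definite_pairs else 0.0
        ),
        fraction_genes_same_clade=frac_genes_same,
        n_pairs_with_unclassified=n_unc_pairs,
        clusters=clusters,
    )
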