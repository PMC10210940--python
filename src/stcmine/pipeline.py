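"""End-to-end orchestration of the STC mining method.

Stage order: similarity screen against characterized seeds (filter 1) →
metal-binding motif filter (filter 2) → length filter (filter 3) →
distance-based clade assignment against the seeds → discriminative motif
discovery and reassignment of unclassified candidates → generation-1
clade HMMs → glocal HMM search of the surviving candidates → best-score
clade assignment → generation-2 model refinement and re-search → tandem
duplication report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import motifs as motif_mod
from . import similarity
from .core import (
    CLADES,
    UNCLASSIFIED,
    Clade,
    CladeCall,
    FilterReport,
    PipelineConfig,
    ProteinRecord,
)
from .genome import GeneLocus, TandemReport, detect_tandem
from .hmm import (
    ProfileHmm,
    assign_by_best_score,
    build_hmm,
    hmm_search,
    refine_generation2,
)
from .msa import assign_clades_by_clustering, progressive_align, trim_msa

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    reports: dict[str, FilterReport]
    n_raw_hits: dict[str, int]
    calls_gen0: list[CladeCall]
    calls_gen1: list[CladeCall]
    calls_gen2: list[CladeCall]
    motifs: dict[Clade, list]
    models_gen1: list[ProfileHmm]
    models_gen2: list[ProfileHmm]
    tandem: TandemReport | None = None
    survivors: list[ProteinRecord] = field(default_factory=list)


def _length_ok(rec: ProteinRecord, cfg: PipelineConfig) -> bool:
    return cfg.min_len_aa < len(rec.sequence) < cfg.max_len_aa


def run_pipeline(
    proteomes: dict[str, list[ProteinRecord]],
    seeds: list[ProteinRecord],
    seed_clades: dict[str, Clade],
    gene_orders: list[GeneLocus] | None = None,
    cfg: PipelineConfig | None = None,
    train_with_motif_calls: bool = True,
    include_seeds_in_training: bool = True,
    use_motif_reassignment: bool = True,
    per_genome_classification: bool = False,
) -> PipelineResult:
    """Run every stage on one or more proteomes against labelled seeds.

    ``per_genome_classification`` runs the distance-dendrogram stage
    separately per genome (each genome's candidates aligned with the seeds)
    instead of pooling all survivors; classification defaults to pooled.
    ``use_motif_reassignment=False`` skips the signature-motif rescue of
    unclassified candidates (motifs are still discovered and reported).
    """
    cfg = cfg or PipelineConfig()
    if not proteomes:
        raise ValueError("need at least one proteome")
    missing = [c for c in CLADES if c not in set(seed_clades.values())]
    if missing:
        raise ValueError(f"seeds missing for clades {missing}")

    reports: dict[str, FilterReport] = {}
    n_raw_hits: dict[str, int] = {}
    survivors: list[ProteinRecord] = []
    for genome_id in sorted(proteomes):
        records = proteomes[genome_id]
        try:
            aligns = similarity.screen(records, seeds)
            pass1 = similarity.similarity_filter(records, seeds, cfg, hits=aligns)
        except Exception as exc:
            raise RuntimeError(f"similarity stage failed for {genome_id}") from exc
        stage1 = [r for r in records if r.id in pass1]
        pass2 = motif_mod.metal_binding_filter(stage1)
        stage2 = [r for r in stage1 if r.id in pass2]
        stage3 = [r for r in stage2 if _length_ok(r, cfg)]
        reports[genome_id] = FilterReport(
            genome_id=genome_id,
            n_input=len(records),
            n_after_similarity=len(stage1),
            n_after_motif=len(stage2),
            n_after_length=len(stage3),
            surviving_ids=[r.id for r in stage3],
        )
        n_raw_hits[genome_id] = len({a.query_id for a in aligns})
        survivors.extend(stage3)
        log.info(
            "%s: %d -> %d -> %d -> %d",
            genome_id,
            len(records),
            len(stage1),
            len(stage2),
            len(stage3),
        )

    if not survivors:
        return PipelineResult(
            reports=reports,
            n_raw_hits=n_raw_hits,
            calls_gen0=[],
            calls_gen1=[],
            calls_gen2=[],
            motifs={c: [] for c in CLADES},
            models_gen1=[],
            models_gen2=[],
            tandem=None,
        )

    # distance-based classification against the characterized seeds
    if per_genome_classification:
        dist_calls = []
        for genome_id in sorted(proteomes):
            group = [r for r in survivors if r.id in set(reports[genome_id].surviving_ids)]
            if group:
                dist_calls.extend(
                    assign_clades_by_clustering(group, seeds, seed_clades, cfg)
                )
    else:
        dist_calls = assign_clades_by_clustering(survivors, seeds, seed_clades, cfg)
    call_of = {c.protein_id: c for c in dist_calls}

    # discriminative motifs per clade from the classified sets
    by_id = {r.id: r for r in survivors}
    clade_sets = {
        c: [by_id[x.protein_id] for x in dist_calls if x.clade == c] for c in CLADES
    }
    clade_motifs: dict[Clade, list] = {}
    for c in CLADES:
        negatives = [r for c2 in CLADES if c2 != c for r in clade_sets[c2]]
        if clade_sets[c] and negatives:
            clade_motifs[c] = motif_mod.discover_motifs(
                clade_sets[c], negatives, cfg, clade=c
            )
        else:
            clade_motifs[c] = []

    if use_motif_reassignment:
        unclassified = [
            by_id[x.protein_id] for x in dist_calls if x.clade == UNCLASSIFIED
        ]
        for call in motif_mod.reassign_by_motif(unclassified, clade_motifs):
            if call.clade != UNCLASSIFIED:
                call_of[call.protein_id] = call
    calls_gen0 = [call_of[r.id] for r in survivors]

    # generation-1 models
    models_gen1 = []
    for c in CLADES:
        train = [
            by_id[x.protein_id]
            for x in calls_gen0
            if x.clade == c
            and (train_with_motif_calls or x.evidence != "motif")
        ]
        if include_seeds_in_training:
            train += [s for s in seeds if seed_clades.get(s.id) == c]
        if len(train) < 2:
            raise RuntimeError(
                f"generation-1 training failed: clade {c} has {len(train)} sequences"
            )
        msa = trim_msa(
            progressive_align(train, cfg.gap_open, cfg.gap_extend),
            cfg.trim_gap_threshold,
        )
        models_gen1.append(build_hmm(msa, name=f"gen1-clade{c}", clade=c))

    hits_gen1 = hmm_search(models_gen1, survivors, cfg.hmm_bit_threshold)
    calls_gen1 = assign_by_best_score(hits_gen1)

    proteins = dict(by_id)
    models_gen2 = refine_generation2(
        models_gen1,
        hits_gen1,
        proteins,
        top_k=cfg.refine_top_k,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
        trim_gap_threshold=cfg.trim_gap_threshold,
    )
    hits_gen2 = hmm_search(models_gen2, survivors, cfg.hmm_bit_threshold)
    calls_gen2 = assign_by_best_score(hits_gen2)

    tandem = None
    if gene_orders is not None:
        final_map = {c.protein_id: c.clade for c in calls_gen2}
        tandem = detect_tandem(gene_orders, final_map, window=cfg.tandem_window)

    return PipelineResult(
        reports=reports,
        n_raw_hits=n_raw_hits,
        calls_gen0=calls_gen0,
        calls_gen1=calls_gen1,
        calls_gen2=calls_gen2,
        motifs=clade_motifs,
        models_gen1=models_gen1,
        models_gen2=models_gen2,
        tandem=tandem,
        survivors=survivors,
    )


def report_table1(result: PipelineResult) -> str:
    """Per-genome filter-cascade counts as TSV, with a Total row."""
    lines = ["genome\tn_hits\tfilter1\tfilter2\tfilter3"]
    totals = [0, 0, 0, 0]
    for genome_id in sorted(result.reports):
        rep = result.reports[genome_id]
        row = [
            result.n_raw_hits.get(genome_id, 0),
            rep.n_after_similarity,
            rep.n_after_motif,
            rep.n_after_length,
        ]
        totals = [a + b for a, b in zip(totals, row)]
        lines.append(genome_id + "\t" + "\t".join(str(v) for v in row))
    lines.append("Total\t" + "\t".join(str(v) for v in totals))
    return "\n".join(lines) + "\n"
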