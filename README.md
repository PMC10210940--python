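# stcmine

Mining and cyclization-clade classification of fungal **sesquiterpene
cyclase (STC)** genes from predicted proteomes.

Sesquiterpene cyclases convert the linear C15 precursor farnesyl
diphosphate (FPP) into cyclic sesquiterpene skeletons. In fungi these
enzymes fall into four phylogenetic clades that track the initial
cyclization chemistry:

| clade | predicted mechanism |
|-------|---------------------|
| 1 | 1,10-cyclization of (2E,6E)-FPP |
| 2 | 1,10-cyclization of (3R)-NPP |
| 3 | 1,11-cyclization of (2E,6E)-FPP |
| 4 | 1,6/1,7-cyclization of (3R)-NPP |

Given predicted proteomes and a small set of biochemically characterized
reference STCs, `stcmine` finds candidate STC genes and predicts their
cyclization clade with a fully re-implemented, dependency-light pipeline:

1. **Similarity screen (filter 1)** — exact Smith–Waterman (BLOSUM62,
   affine gaps, open 11 / extend 1) of every proteome sequence against the
   references; survivors need > 30 % identity and > 60 % query coverage.
2. **Metal-binding motifs (filter 2)** — class-I terpene-cyclase signature:
   N-terminal `(D/N)DxxD/E` or `DDxxxE` **and** C-terminal `NxxxSxxxE`.
   This rejects the classic confounder, prenyltransferases that carry
   `DDxxD` but lack the NSE triad.
3. **Length filter (filter 3)** — 250 < length (aa) < 500.
4. **Distance classification** — progressive multiple alignment
   (guide-tree profile aligner, GOP 2.3 / GEP 0.63), gap-threshold column
   trimming, physicochemical-category distances
   (d = −ln(1 − D), categories {C} {MVLI} {GASTP} {FYW} {NDEQ} {HKR}),
   UPGMA dendrograms, and a smallest-enclosing-reference-cluster purity
   rule.
5. **Discriminative motifs** — exact MERCI-style substrings present in
   ≥ 75 % of one clade and absent from all others; candidates the
   dendrogram left unclassified are rescued when they carry exactly one
   clade's signature.
6. **Profile HMMs** — Plan7-style models built from the trimmed clade
   alignments (Laplace pseudocounts, uniform background), scored glocally
   in bits (log₂ likelihood ratio versus background; free flanks).
   Hits at a gathering threshold of 25 bits are assigned to the clade of
   the best-scoring model; second-generation models are rebuilt from the
   top-100 hits per taxonomic division and the search repeated.
7. **Tandem duplications** — two STC genes are tandem when at most four
   gene positions apart on one scaffold; the report gives the tandem
   fraction and the same-clade fraction of tandem pairs.

A seeded synthetic-data module (`stcmine.simulate`) generates complete
study fixtures — planted clade HMMs carrying the metal-binding and clade
motifs, decoy proteins, genome layouts with tandem clusters and a ground-
truth table — so every stage is testable without downloads.

## Worked example

Generate a synthetic study (4 clades × 12 members + 60 decoys) and run
the full pipeline:

```bash
stcmine simulate --seed 11 --family-size 12 --out fixture
stcmine pipeline \
    --proteome fixture/proteome.faa \
    --seeds fixture/references.faa \
    --seed-clades fixture/ref_clades.tsv \
    --genes fixture/genes.tsv \
    --out run
```

This prints the per-genome filter cascade:

```
genome    n_hits  filter1 filter2 filter3
proteome  108     78      58      48
Total     108     78      58      48
```

108 proteins enter; filter 1 removes the 30 background-random decoys,
filter 2 the 20 prenyltransferase-like decoys (DDxxD without the
C-terminal NSE motif), filter 3 the 10 over-length decoys — the 48
surviving candidates are exactly the planted STCs. `run/calls_gen2.tsv`
holds the final clade calls with bit scores:

```
protein_id   clade  evidence        score
stc_c1_000   1      hmm_best_score  562.476257
stc_c1_001   1      hmm_best_score  566.149679
```

`run/motifs.tsv` lists the discriminative motifs per clade; the four
planted signatures dominate their clades
(`DTSGC` 92 %, `LRRENS` 92 %, `DLMN`-containing 92 %, `FYK` 100 % here).
`run/tandem.json` reports the tandem statistics — in this run 26 of 48
STC genes (54 %) lie in tandem clusters and 100 % of tandem pairs share a
clade, matching the planted layout.

Every subcommand (`screen`, `motifs`, `classify`, `hmm build/search`,
`tandem`, `simulate`, `pipeline`) is a thin wrapper over the library API
(`stcmine.run_pipeline`, `stcmine.local_align`, `stcmine.build_hmm`, …).

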