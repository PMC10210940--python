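# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stcmine`. Everything stated here is implemented and
exercised by the test suite; no empirical claim is made beyond what the
tests and `scripts/acceptance.py` themselves compute.

## Problem setting

Fungal sesquiterpene cyclases (STC) are class-I terpene cyclases that
cyclize farnesyl diphosphate. Family members can be recognised by
sequence similarity to characterized enzymes, by two conserved
Mg²⁺-coordinating motifs — an N-terminal aspartate-rich motif
((D/N)DxxD/E or DDxxxE) and a C-terminal NSE triad (NxxxSxxxE) — and by a
typical length of 250–500 aa. Within the family, four clades predict the
initial carbocation chemistry. The pipeline first *finds* family members
(three-filter cascade) and then *classifies* them (distances → motifs →
profile HMMs, iteratively refined).

## Similarity screen

The screen is exact Smith–Waterman with BLOSUM62 and affine penalties
(gap of length k costs open + k·extend; defaults open 11, extend 1, the
common protein-BLAST setting). There is no E-value model and no heuristic
seeding: the survival criterion is exactly the two reported decision
variables, percent identity (identical columns over all alignment
columns, gaps included) strictly above 30 and query coverage (aligned
query span over query length) strictly above 60. The unknown residue X
scores 0 against everything and never counts as identical. Traceback
tie-breaks are fixed (diagonal over up over left; first-best end cell),
so alignments are deterministic. The DP core is checked against an
independently implemented aligner (Biopython's `PairwiseAligner`) and
against explicit enumeration of all gapped local alignments on small
inputs.

## Motif semantics

Motif patterns are literal residues plus the wildcard `x`. A literal
matches only itself — X (unknown) matches no literal but does match `x`.
"N-terminal" and "C-terminal" regions are the sequence halves split at
⌊L/2⌋: a simple, deterministic reading consistent with the two-domain
layout of class-I terpene synthases. Filter 2 requires an N-terminal
aspartate-rich match AND a C-terminal NSE match. (A structural
domain-database lookup is not part of this implementation; the motif
conjunction plus the decoy-bearing fixtures exercise the same
discrimination.)

Discriminative motifs are exact substrings of length 3–6 present in at
least `motif_min_freq` of a clade's sequences and in zero sequences of
the other clades ("absent" is strict). The default frequency 0.75 admits
the weakest of the four published clade signatures (DLMN at 77 %). Only
maximal motifs are reported: a motif is dropped when an extension has an
identical supporting set, which collapses nested repeats of one signal
into its longest form. Wildcard/physicochemical-class motif discovery is
an extension point, not implemented — the known clade signatures are all
exact strings.

## Alignment, distances, dendrograms

The progressive aligner builds a guide tree from all-pairs distinct-3-mer
distances (1 − shared/min) via UPGMA, then merges profiles along the tree
with global affine-gap DP over expected BLOSUM62 column scores (profile
columns scored as frequency-weighted averages; gaps contribute nothing to
the substitution term). BLOSUM62 is scaled by 1/4 so the published
GOP 2.3 / GEP 0.63 penalties are on the scale of a good match. End gaps
are penalized like internal ones. With two sequences the procedure *is*
pairwise global DP (verified against Biopython). No claim is made of
MAFFT-identical alignments; the alignment is deterministic and lossless
(degapping reproduces the inputs).

Column trimming keeps exactly the columns with gap fraction ≤ 0.5; this
is a pure gap-threshold rule standing in for an alignment-quality
trimmer.

Distances between aligned rows follow the protdist categories model in
spirit: over columns where both rows have residues, an identical pair
costs 0, a within-category substitution ({C}, {M,V,L,I}, {G,A,S,T,P},
{F,Y,W}, {N,D,E,Q}, {H,K,R}) costs 0.5, anything else (including any X)
costs 1; the mean difference D is corrected with d = −ln(1 − D) and
capped at 10. The full rate-matrix machinery of the original categories
model is intentionally replaced by this hand-checkable form that
preserves the key property — same-category substitutions cost less.

UPGMA is standard average linkage with merge height d/2 (ultrametric);
ties in the minimum are broken by the lexicographically smallest pair of
cluster representatives, making trees independent of input order. The
implementation is cross-checked against SciPy's average-linkage
cophenetic distances.

Clade assignment reads the dendrogram deterministically: each candidate
takes the clade of its smallest enclosing cluster that contains a
reference, provided all references inside agree; mixed or absent
references leave it unclassified. This replaces by-eye reading of
dendrograms with a purity rule, and by construction can never call a
clade that has no reference. Classification is pooled across genomes by
default; a `per_genome_classification` flag aligns each genome's
candidates with the references separately.

## Profile HMMs

Models are Plan7-like: match states M1..ML with 20-residue emissions,
insert states I0..IL, delete states D1..DL, no I↔D edges. Alignment
columns with gap fraction < 0.5 become match states. Emissions are count
estimates with Laplace +1 pseudocounts; transitions likewise, +1 per
outgoing edge (observed D↔I adjacencies, which have no edge in the
topology, are skipped). The background is uniform 0.05. These choices
replace Dirichlet mixtures, entropy weighting and sequence weighting so
that every number in a model is hand-checkable; sequence weighting is a
noted extension point.

Scoring is **glocal**: the model must be traversed begin to end, while
sequence flanks are emitted at background frequencies and contribute
0 bits; entry (after any prefix) and exit (before any suffix) points are
free. The bit score is log₂ P(seq, path | model) − log₂ P(seq | bg)
maximized over paths (Viterbi) or summed over paths *and* flank splits
(forward). X emits background (0 bits). Both recursions are verified to
1e−9 bits against explicit path enumeration for small models. The
"gathering threshold" of 25 is interpreted as this bit score; it is
configurable. A sequence hit by several clade models takes the clade of
the highest score; an exact cross-clade tie is left unclassified with a
warning.

Second-generation refinement pools, per clade, the `refine_top_k` (=100)
best-scoring basidiomycete-derived and ascomycete-derived hits (all if
fewer; other divisions are pooled with basidiomycetes), re-aligns, trims
and rebuilds. Generation-1 training sets include the reference seeds and
motif-rescued members by default; both are flag-controlled.

Serialization is a plain-text format with natural-log probabilities at
17 significant digits. Writing is byte-stable (write∘read∘write is
byte-identical) and probabilities survive a round trip to ~1e−15
relative — exact bit equality is impossible through a log/exp
representation and is not claimed.

## Tandem duplications

Two STC genes are tandem when on the same scaffold at ordinal distance
≤ window (default 4), counting all annotated genes in the ranking and
ignoring strand. Clusters are connected components of the pair graph.
Because the published same-clade statistic is phrased per gene while
pairs are the natural unit, both are reported:
`fraction_pairs_same_clade` (over pairs whose both members have a
definite clade; pairs involving unclassified members are counted
separately) and `fraction_genes_same_clade` (clade-labelled tandem genes
with ≥ 1 same-clade partner).

## Synthetic study conditions

The generator emulates the study at desk scale. Defaults: four families
of 30 sequences sampled from planted profile HMMs (model lengths
328/336/344/352 aa), two labelled references per clade, and 60 decoys
(20 prenyltransferase-like, 20 unrelated, 20 wrong-length).

* **Emission divergence.** Match emissions are Dirichlet-like draws with
  concentration `divergence` (default 12) on a random consensus residue —
  calibrated once so that within-family pairwise identity falls in the
  40–70 % band typical of within-clade STC comparisons (asserted by a
  test); across clades, models are independent, so similarity is at
  background.
* **Planted motifs.** The metal-binding motifs sit at fixed model
  positions (N-terminal at node 26, C-terminal 50 nodes from the end) and
  the clade signature (DTSGC/LRRENS/DLMN/FYK) at a clade-specific
  position; their residues are one-hot and the transition structure
  forbids indels in and adjacent to the spans, so every sampled sequence
  carries the motifs intact. Signature penetrance is 0.9: with
  probability 0.1 a family member's signature positions are resampled
  from background. Other clades' signatures are scrubbed from each
  family, mirroring the strict absence that discriminative discovery
  requires.
* **Indels.** Per-node M→I and M→D probabilities are 0.01 outside
  protected spans, keeping sampled lengths well inside (250, 500).
* **Decoys.** Prenyltransferase-like decoys are samples from a clade
  model with the N-terminal motif rewritten to DDxxD and the C-terminal
  NSE motif destroyed — they pass filter 1 and fail filter 2, like their
  real counterparts. Unrelated decoys are background-random and die at
  filter 1. Wrong-length decoys alternate between model-derived sequences
  padded to ≥ 500 aa (they pass filters 1–2 and fail filter 3) and short
  motif-bearing background sequences.
* **Layout.** STC genes are placed singly or in tandem clusters
  (within-cluster ordinal gaps 1–4, between-group gaps > 4), so the
  ground-truth tandem statistics are exact. Tandem clusters are drawn
  within a clade, so the fixture's same-clade fraction is 1 by
  construction — the mixed-clade case is exercised by direct unit tests
  of the detector, not by the generator.
* The sampler uses the same ProfileHmm machinery as scoring, so
  parameter-recovery experiments compare like with like. All outputs are
  byte-deterministic under the spec seed.

What passing tests on these fixtures do **not** show: performance on real
proteomes with domain architectures, fragmented gene models, compositional
bias, or clades whose true divergence differs from the planted setting;
the generator makes no attempt to imitate real STC residue composition
beyond motif and length structure.

## Problem sizes and numerical choices

The default validation study uses 4 × 30 families + 60 decoys
(pipeline end-to-end in seconds) and 500 samples for parameter recovery;
oracle comparisons use models with L ≤ 5 and sequences ≤ 8 residues,
where exhaustive enumeration is exact. Tolerances: 1e−9 bits for
DP-vs-enumeration, exact float equality only where algorithms are
identical by construction. Degenerate inputs are defined rather than
undefined: empty alignment when the best local score is ≤ 0 (identity
and coverage 0), distance cap 10 for saturated or disjoint row pairs,
error (not silence) for fully-trimmed alignments, clade-less references,
missing loci, or models without match states.

## Known limitations

* No E-value calibration, domain-level parsing or HMMER file
  compatibility; glocal (not local) model alignment, adequate because
  candidates are near-full-length after the cascade.
* The identity/coverage screen is quadratic-time exact DP — fine for
  proteome-vs-seed screens, not tuned for all-vs-all genomics.
* Motif discovery is exact-substring only.
* The distance model is a category-penalized p-distance, not a
  maximum-likelihood substitution model; no bootstrap support values.
* Gene ranks are taken from the provided gene-order table as ground
  truth; no synteny or duplication dating.
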