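# Methods

This note documents the models, algorithms and numerical choices behind
`rpb1kit`, and what the synthetic-data experiments do and do not show.

## Distances and the barcode gap

All sequence distances are Kimura two-parameter (K2P):

    d = -1/2 · ln[(1 − 2P − Q) · √(1 − 2Q)]

with `P` the proportion of transitions and `Q` of transversions over
*comparable* sites. Columns where either sequence carries a gap or an N
are removed pairwise (pairwise deletion), not listwise: the reference set
mixes full-length and shorter fragments, and complete deletion would
discard most of the alignment. Whether the original barcode-gap analyses
used pairwise or complete deletion is not documented; we fix pairwise and
state it here. When the logarithm's argument is non-positive (saturated
pairs) or no comparable sites remain, the distance is *undefined* and is
propagated as NaN — never as infinity; all downstream minima, maxima and
means skip undefined values, and sliding windows additionally treat a
pair as undefined inside a window with fewer than 10 comparable columns.

The barcode gap of a sequence is its minimum K2P distance to any
heterospecific sequence minus its maximum distance to any conspecific
(zero for single-sequence species). The OTU threshold is derived from the
minimum gap over non-excluded sequences by flooring to a resolution of
0.1 percentage points and stepping down one unit — a 0.9 % minimum gap
yields a 0.8 % threshold. This mirrors the published rule and makes the
threshold conservative: strictly below the smallest observed
between-species separation. If the result falls below the largest
intraspecific distance, a warning object is returned rather than silently
accepting an over-splitting threshold. Named taxa can be excluded from
the derivation (the field's unresolved *Gigaspora* species complex is the
motivating case).

A column is *diagnostic* for a species if all its members share one
unambiguous base there and no other sequence carries that base; window
profiles report the sum over species, alongside mean pairwise K2P, in
50-bp windows at step 1 (the window size is the published choice; the
step is ours, chosen for maximal resolution).

## Read processing

The cascade is order-fixed: demultiplex → length/ambiguity →
alignment screen → pre-cluster → chimera removal → frame correction.
Each stage's input count equals the previous stage's output count and the
funnel table records the accounting.

* **Demultiplexing.** Barcodes are 9 bp with pairwise Hamming distance
  ≥ 4 (validated on load), so one observed mismatch still identifies a
  unique barcode; reads at two or more mismatches go to an unassigned
  bin. Barcode and primer are trimmed.
* **Length/ambiguity.** Reads shorter than 200 bp *including* barcode and
  primer, or containing any N, are removed. The length convention follows
  the published accounting ("shorter than 200 bp including primers,
  barcode and adapters"); a flag switches to trimmed-length filtering.
* **Alignment screen.** Each read is aligned (edlib, free end gaps on the
  longer sequence) against every ungapped reference; identity is matched
  columns over the aligned span, excluding terminal gaps — reads are
  partial-length fragments and terminal overhang says nothing about
  homology. Reads under 60 % identity to every reference are discarded;
  random DNA scores ≈ 0.55 under this definition and never passes. The
  best-scoring reference is stored for frame correction.
* **Pre-clustering** at 99.7 % similarity and **OTU picking** at the
  derived K2P threshold use the same deterministic greedy engine:
  sequences are visited in descending abundance (ties: longer first, then
  lexicographic id) and join the first centroid within threshold, found
  via a 4-mer cosine prescreen whose ties are broken by insertion order.
  Determinism was preferred over re-implementing the stochastic Bayesian
  clustering used in the original pipeline; the decision structure
  (greedy, abundance-sorted, centroid-based) is the same as USEARCH's.
  Each cluster additionally tracks its longest member sequence: greedy
  order visits abundant-but-short sequences first, so the centroid alone
  would truncate information that longer members carry.
* **Chimera detection** is a two-parent single-crossover scorer in the
  spirit of UCHIME. Queries are visited in ascending abundance; candidate
  parents must be ≥ 2× as abundant. For each parent pair the score is
  restricted to the query span covered by both parents (pyrosequencing
  reads vary from ~145 to ~515 bp, and an uncovered tail is evidence of
  nothing); the best crossover must reach 99 % model identity over that
  span, beat the better single parent by a margin of 1 % *and* by at
  least 3 absolute bases (UCHIME's `mindiffs` default), with each parent
  contributing ≥ 30 bases. The absolute-difference floor prevents single
  coincidental matches on short spans from flagging clean reads.
* **Frame correction** exploits the marker's coding exons. The read is
  aligned to its best screened reference, whose per-position exon/intron
  labels and codon phases come from the region annotation (0-based
  half-open intervals; `frame` is the phase of the first exon column).
  A single-base read indel inside a reference homopolymer run of length
  ≥ 3, in an exon, is repaired (the dominant pyrosequencing error mode);
  intron columns are never edited, and multi-base or non-homopolymer
  discrepancies are left alone. After correction the exon portion must
  align without net frameshift and translate without stop codons from
  the first complete codon, else the sequence is discarded with a named
  status (`frameshift` / `stop-codon`). Reads overlapping fewer than 30
  exon positions pass through flagged `no-exon`.

## Taxonomy and molecular taxa

Three independent assignments are computed per (non-singleton) OTU
representative:

1. **Naive-Bayes k-mer classifier** (k = 8): per-species smoothed k-mer
   presence probabilities, scored by summed log-likelihood; confidence
   per rank is the fraction of 100 bootstrap subsamples (1/8 of the query
   k-mers each) agreeing with the full-data winner at that rank, and the
   lineage is truncated at the deepest rank with confidence ≥ 0.80.
2. **Parsimony placement**: the query is threaded onto the reference
   alignment via its closest reference, then every edge of the reference
   tree is scored by full Fitch parsimony with the query attached there.
   The minimal-cost edge set is narrowed by smallest query-to-subtree
   p-distance, then smallest subtree; the assignment is the shared
   lineage of the remaining subtree(s), and confidence is
   1 − (ties − 1)/edges. Parsimony insertion is deterministic and has the
   same decision structure as likelihood-based evolutionary placement,
   which it stands in for.
3. **Bootstrapped neighbour joining** on K2P distances of query plus
   references (100 replicates by default; the original analysis used
   1000, and the count is configurable). The assignment is the shared
   lineage of the smallest clade containing the query with bootstrap
   support ≥ 0.70. Undefined distances within a bootstrap replicate are
   imputed at twice the largest defined distance; a query with no defined
   distance to any reference is unassigned.

The consensus prefers tree methods over the classifier and placement over
NJ, but never reports a rank at which any non-empty assignment disagrees:
compatible assignments (one a prefix of the other) take the deeper
lineage ("could be refined"), and any genuine disagreement truncates to
the deepest commonly agreed rank. Taking "prefer placement" literally on
tree-method disagreement would let the result contradict the NJ lineage;
we resolved that tension in favour of the no-contradiction invariant,
which also matches the fallback "common taxonomic sublevel" rule.

OTUs with total count 1 are removed as singletons (their taxonomy is
never consulted, so it is not computed); OTUs whose consensus phylum is
not the target phylum are removed as off-target, and specificity is
reported as `100 · (1 − off-target reads / reads passing the length
filter)`, rounded to two decimals. Retained OTUs sharing their
deepest-named consensus lineage merge into one molecular taxon (MT),
named by the species or as "*Taxon* sp." at shallower ranks; an alias
table can merge sibling species indistinguishable on short fragments
into a single MT.

## Community statistics

Samples are rarefied to equal depth (default 1400 reads) by seeded
multivariate-hypergeometric subsampling; samples below the depth are
dropped with a warning. UniFrac (unweighted; weighted, normalized by
default so values live in [0, 1]) is computed with scikit-bio on the
neighbour-joining K2P tree of OTU representatives, midpoint-rooted with
negative NJ branch lengths clamped to zero. PCoA is classical scaling
(Gower double-centring + symmetric eigendecomposition) implemented
in-package because the library routine zeroes negative eigenvalues,
which we are contractually required to report; coordinates are scaled by
√λ on non-negative axes and proportions explained are relative to the
positive eigenvalue sum. ANOSIM uses mid-ranks for tied distances,
R = (mean between-group rank − mean within-group rank)/(M/2) with
M = n(n−1)/2, and a seeded label-permutation p-value
(hits + 1)/(permutations + 1), which makes the test valid (p ≥ 1/(m+1))
and slightly conservative; under a true null its rejection rate at
α = 0.05 stays below 8 % in the calibration check.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes,
with full ground truth:

* **Reference evolution.** A random coalescent-style ultrametric topology
  over `n_species` (default 8) is scaled so the realised mean pairwise
  *exon* K2P distance matches `target_inter_species_divergence` (default
  5 %), with a floor of `min_inter_species_divergence` (default 2 %) on
  the shallowest split — without the floor a random tree can place two
  species closer than the within-species spread, which would destroy the
  barcode gap the whole analysis rests on. Sequences evolve by a K2P
  substitution process (κ = 2) along the tree; introns evolve at
  `intron_rate_multiplier` (default 4) times the exon rate, reproducing
  the intron/exon variability contrast by construction; the terminal
  primer sites (20 bp each end) are invariant so the primers locate in
  every species. Codons that mutate into stops revert to the parental
  codon, keeping every exon translation stop-free. The default marker is
  756 bp: exon 150 / intron 81 / exon 210 / intron 75 / exon 240, frame 0.
  Isolates (default 2 per species) differ from the species sequence at
  exactly ⌊intra/2 · L⌋ sites (default intra-species divergence 0.2 %),
  bounding pairwise isolate divergence by the configured value. An
  off-target outgroup (different phylum, 35 % divergent) is included at a
  read fraction of 0.06 % to exercise the specificity accounting.
* **Communities.** Per treatment (three levels, four plots each), a
  Dirichlet mean composition enriches one third of the species four-fold
  over a flat baseline; each plot draws its composition from a Dirichlet
  with concentration 50 and each read's species from that draw. Reads
  are `barcode + forward primer + amplicon prefix`, the prefix length
  triangular over (145, 254, 515) bp to mimic the published length
  summary, 1800 reads per sample by default (the published samples
  ranged from 1425 to 2770).
* **Errors and chimeras.** Substitutions are i.i.d. per base (default
  0.002); homopolymer indels occur per run of length r ≥ 2 with
  probability `rate · (r − 1)` capped at 0.5 (default rate 0.002),
  always changing the run length by exactly one. No quantitative error
  rate was published for the original sequencing run; these defaults are
  this package's choice of a plausible pyrosequencing error load and are
  the single most uncertain part of the emulation. Chimeras replace a
  read with probability `chimera_rate` (default 5 %) by a single
  crossover between the templates of two earlier reads of the same
  sample (distinct species by default), the breakpoint uniform over
  positions leaving at least 50 bp from each parent — template switching
  requires a primed homologous stretch, and shorter contributions are
  operationally part of one parent. Every read has exactly one
  ground-truth row (sample, species, isolate, chimera parents and
  breakpoint, injected error counts), and identical seed + configuration
  reproduce byte-identical output.

**Chimera benchmark definition.** Detection sensitivity is reported over
*detectable* chimeras: those whose parents differ at ≥ 3 sites on each
side of the breakpoint within the read. Below that bound a chimera is
within sequencing-error distance of a pure parent read; no de novo
detector can flag it, and it merges harmlessly into the parent's OTU.
This mirrors how chimera-detection benchmarks stratify sensitivity by
number of differences. The evaluation reports recall over all chimeras
alongside (about 0.72 at the defaults, versus about 0.87–0.92 over
detectable ones, at a false-positive rate ≤ 10⁻⁴).

**What passing tests do and do not show.** The generator has no indel
process outside homopolymers, no flowgram-level noise, no PCR abundance
bias, no length-dependent quality decay, and its taxonomy is rank-
complete and consistent with the species tree by construction. Passing
the recovery tests therefore shows the pipeline's logic is correct under
the stated error model, not that real 454 data meet that model;
in particular the three-way taxonomy consensus is exercised mostly in
its agreeing regime on clean synthetic data.

## Problem sizes and runtime choices

The default end-to-end scenario is 8 species × 2 isolates, 12 samples ×
1800 reads (21,600 reads), which one CPU processes in a few minutes; unit
tests use 4–6 species and 80–600 reads per sample. NJ bootstraps default
to 100 (the original 1000 is configurable), ANOSIM to 2000 permutations,
and the null-calibration check uses 200 simulations of 12 samples at 199
permutations. These sizes are the package's choices for a thorough yet
convenient default experiment; all are configurable upward.

## Known limitations

* Placement is parsimony-based; it does not produce likelihood weights,
  and ties are resolved by a fixed deterministic rule.
* The chimera detector assumes exactly two parents and one crossover;
  multi-parent or multi-breakpoint artefacts are out of scope (as they
  are for the two-parent model it follows).
* Frame correction repairs only single-base discrepancies in reference
  homopolymer runs of length ≥ 3; rarer error modes lead to discards,
  which slightly deflates per-sample depths.
* The greedy clusterer's 4-mer prescreen examines the top 16 candidates;
  pathological centroid landscapes could in principle hide a
  within-threshold centroid, though the OTU-level clustering absorbs
  stragglers in practice.
* Undefined (NaN) K2P distances are imputed inside NJ bootstrap
  replicates (twice the maximum defined distance); with very short or
  saturated queries the reported supports inherit that heuristic.
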