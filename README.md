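# rpb1kit

Tools for evaluating a single-copy, protein-coding marker gene — the
largest subunit of RNA polymerase II (RPB1) — as a DNA barcode for
arbuscular mycorrhizal fungi (AMF, phylum *Glomeromycota*), and for
analysing amplicon-sequencing community data with it.

Ribosomal markers in AMF are highly polymorphic *within* a single
organism, which confounds species-level community analysis. RPB1 is
single-copy and monomorphic within an isolate, so between-sequence
distance reflects between-organism divergence. `rpb1kit` implements the
full computational workflow that evaluation and its field application
require:

* **Marker evaluation** — pairwise Kimura two-parameter (K2P) distances
  with pairwise deletion,
  `d = -½·ln[(1−2P−Q)·√(1−2Q)]` for transition proportion `P` and
  transversion proportion `Q`; 50-bp sliding-window variability and
  diagnostic-nucleotide profiles; barcode-gap analysis (per sequence, the
  difference between its minimum interspecific and maximum intraspecific
  distance); and derivation of an OTU distance threshold as the floored
  minimum gap minus one resolution step (a 0.9 % minimum gap gives a
  0.8 % threshold).
* **Read processing** — a fixed filter cascade for barcoded pyrosequencing
  amplicons: demultiplexing (9-bp barcodes, ≥4 mismatches apart), a
  200-bp length / ambiguity filter, a 60 %-identity alignment screen
  against the reference alignment, greedy pre-clustering at 99.7 %
  similarity, de novo two-parent-crossover chimera detection, and
  homopolymer frame-shift correction validated by stop-codon-free exon
  translation.
* **OTU picking and taxonomy** — greedy abundance-sorted centroid
  clustering at the derived K2P threshold; three independent taxonomic
  assignments per OTU (naive-Bayes k-mer classifier with bootstrap
  confidence, parsimony placement on the reference tree, bootstrapped
  neighbour joining on K2P distances) merged by a fixed consensus
  precedence; aggregation of OTUs into species-level molecular taxa (MTs).
* **Community statistics** — rarefaction to equal depth, unweighted and
  weighted UniFrac on the OTU tree, principal coordinates analysis, and
  ANOSIM (`R ∈ [−1,1]`, permutation p-value) for treatment effects.
* **Synthetic data with ground truth** — a generator that evolves a
  reference set under a K2P substitution process on a random species tree
  (introns faster than exons, stop-free coding exons, conserved primer
  sites), then emits barcoded community reads with 454-style homopolymer
  errors, substitution errors, and single-crossover chimeras, together
  with a per-read ground-truth table. Every downstream stage is testable
  without any external data.

## Worked example

```python
from rpb1kit.simulate import SimulationConfig, simulate_reference_set, simulate_community_reads
from rpb1kit.pipeline import PipelineParams, run_pipeline

cfg = SimulationConfig(n_species=6, reads_per_sample=400, plots_per_treatment=2, seed=7)
ref, tree = simulate_reference_set(cfg)
reads, sample_map, truth = simulate_community_reads(cfg, ref)
primer = ref.records[0].ungapped[:cfg.primer_length]

params = PipelineParams(rarefaction_depth=250, anosim_permutations=999, seed=7)
result = run_pipeline(reads, sample_map, ref, tree, primer, params)

r = result.report
for stage, n_in, n_out in r.funnel:
    print(f"{stage:>20}: {n_in:>6} -> {n_out}")
print(f"OTU threshold: {r.otu_threshold:.3f} (K2P distance)")
print(f"OTUs retained: {r.otu_count_retained}   molecular taxa: {r.mt_count}")
print(f"specificity: {r.specificity_percent}%")
a = r.anosim["weighted"]
print(f"ANOSIM (weighted UniFrac): R={a['R']:.2f}, p={a['p']:.4f}")
```

prints

```
               demux:   2400 -> 2400
    length-ambiguity:   2400 -> 2299
        align-screen:   2299 -> 2299
          precluster:   2299 -> 2299
             chimera:   2299 -> 2209
               frame:   2209 -> 1956
                 otu:   1956 -> 1956
 singleton-offtarget:   1956 -> 1953
OTU threshold: 0.028 (K2P distance)
OTUs retained: 6   molecular taxa: 6
specificity: 99.91%
ANOSIM (weighted UniFrac): R=1.00, p=0.0740
```

The funnel shows each filter's read accounting: 101 reads fail the 200-bp
length filter, 90 reads sit in chimera-flagged clusters, 253 carry
uncorrectable frameshifts or stop codons. All six simulated species are
recovered as exactly six molecular taxa, and the off-target outgroup reads
are removed with 99.91 % specificity. The treatments are perfectly
separated (R = 1.00), but with only two plots per treatment the
permutation test cannot reach p < 0.05; the full 3 × 4 design can and
does.

The same workflow is available from a shell:

```bash
rpb1kit simulate --seed 7 --outdir sim/
rpb1kit run --reads sim/reads.fasta --sample-map sim/sample_map.tsv \
    --reference sim/reference.fasta --taxonomy sim/taxonomy.tsv \
    --annotation sim/annotation.tsv --tree sim/reference_tree.nwk \
    --primer sim/primer.txt --seed 7 --outdir run/
```

with `eval-marker`, `process-reads`, `cluster-assign`, `community` and
`report` subcommands for the individual stages.

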