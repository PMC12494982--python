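# tnseqmap

Quantitative essentiality analysis for transposon-insertion sequencing
(Tn-seq) of serially passaged mutant libraries. The package covers the full
pipeline from IR-tagged reads to quantitative essentiality calls:

- **`tnseqmap.simulate`** — synthetic Tn-seq library generator: random
  genomes with planted 21-mer repeats, tiled gene annotations with four
  essentiality classes (E / F1 / F2 / NE), serial-passage P (promoter) and T
  (terminator) libraries with per-class insertion densities and decay rates,
  overdispersed read counts (floor of 2 reads), replicate thinning from a
  shared passage-1 pool, and a P-library retention bias upstream of
  essential genes.
- **`tnseqmap.genome`** — genome/annotation data model (1-based closed
  coordinates), 21-bp sliding-window repeat masking over the forward and
  reverse-complement sequence, regulatory element derivation (UTR5/UTR3 from
  TSS/TTS, inter-genic-intra-operon gaps), FASTA/GFF3/BED I/O.
- **`tnseqmap.insertions`** — insertion tables (`position<TAB>reads` TSV),
  insertion calling from IR-tagged FASTQ reads (tag `TACGGACTTTATC`, one
  mismatch allowed, ambiguous placements discarded), single-read filtering,
  and merging of samples with per-sample top/bottom 5% read-count trimming.
- **`tnseqmap.metrics`** — linear density (distinct inserted positions per
  effective bp, repeat-aware), RPKM, and normalization against a gold set of
  known non-essential genes.
- **`tnseqmap.gmm`** — unsupervised essentiality calling by 1-D Gaussian
  mixtures with AIC/BIC model selection; 4-class (E/F1/F2/NE) and binary
  (E/NE) modes; eligibility filtering for regulatory elements.
- **`tnseqmap.decay`** — NE-normalized LD trajectories across passages,
  k-means clustering with distortion-elbow selection and a minimum cluster
  size, trapezoidal AUC over the passage grid (1,2,3,4,6,8,10 for genes),
  P-vs-T AUC comparisons (one-tailed t-tests), and N-/C-termini analysis.
- **`tnseqmap.windows`** — annotation-independent E/NE genome segmentation
  with a calibrated sliding window (default 31 bp; calibration scans sizes
  3–150 bp for <5% E-to-NE misclassification), segment filtering (≥5 bp,
  <10% repeated), and segment-to-annotation mapping.
- **`tnseqmap.enrichment`** — positively selected insertions between first
  and last passage (TMM normalization, one-tailed t-tests, Bonferroni),
  position categorization against the annotation, whole-gene enrichment with
  top-3 hot-insertion subtraction, COG hypergeometric enrichment with BH
  adjustment, and binding-site accessibility tests.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria; the remaining
modules carry unit and property tests (hypothesis).

## Command line

```sh
# simulate a synthetic experiment (genome, annotation, P/T sample tables)
tnseqmap simulate --genome-length 100000 --n-genes 100 --seed 1 --out run/

# call insertions from IR-tagged reads
tnseqmap call reads.fastq --genome run/genome.fasta --out run/called.tsv

# per-feature LD/RPKM metrics from merged passage-1 samples
tnseqmap metrics --manifest run/manifest.tsv --genome run/genome.fasta \
    --annotation run/annotation.gff3 --sidecar run/annotation_classes.tsv \
    --out run/metrics.tsv

# GMM essentiality calls
tnseqmap classify --metrics run/metrics.tsv --out run/calls.tsv

# decay trajectories, k-means clusters, AUC
tnseqmap decay --manifest run/manifest.tsv --genome run/genome.fasta \
    --annotation run/annotation.gff3 --sidecar run/annotation_classes.tsv \
    --out run/decay.tsv

# sliding-window segmentation
tnseqmap segment --manifest run/manifest.tsv --genome run/genome.fasta \
    --annotation run/annotation.gff3 --out run/segments.bed

# insertion enrichment between first and last passage
tnseqmap enrich --manifest run/manifest.tsv --out run/enriched.tsv

# summary report over a run directory
tnseqmap report run/
```

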