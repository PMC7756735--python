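# Methods

## Model

`smncopy` treats SMN1 copy-number estimation as two nearly independent
measurements that only become interpretable jointly:

1. **Allele fraction.** At three paralog-discriminating positions
   (chr5:70247724, 70247773, 70247921 in SMN1 and their homologs 875,420 bp
   upstream in SMN2) the base a read carries identifies its gene of origin
   regardless of where the aligner placed it. D1/(D1+D2) therefore estimates
   the fraction of SMN1-derived chromatids among all SMN chromatids — but a
   1:1 and a 2:2 genotype both give ½.
2. **Total dosage.** The combined SMN1+SMN2 depth, normalized against 20
   control genes and then against the batch, gives the scale factor θ̂ —
   proportional to total SMN copy number, but blind to how copies split
   between the paralogs.

Their product π = θ̂·D1/(D1+D2) is a copy-number-aware SMN1 dose: ≈ 0.5 for
2:2, < ⅓ whenever only one SMN1 copy is present among three or more total
copies. The batch enters only through the column means Z̄ₖ; the method
assumes the batch-average total SMN copy number is ≈ 4 (true of unselected
cohorts), and `run_batch` warns when >20% of a batch is flagged, since the
normalization is then biased.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| carrier threshold on π | ⅓ | midpoint between the 1-of-4 (0.25) and 2-of-4 (0.5) expectations, as published |
| genotype centroids (θ̂, D1/D2) | 1:3→(1,⅓), 1:2→(0.75,½), 1:1→(0.5,1) | expectations under a batch mean of 4 copies |
| centroid match tolerance | 0.15 on each axis | the published rule says only "∼"; 0.15 is half the smallest centroid spacing on θ̂, and it reproduces every validated worked-example call including the documented inconclusive |
| silent-carrier tolerances | θ̂ within 0.12 of {0.75, 0.5}, every π within 0.12 of ½ | tighter than genotype matching because the 2+0 call triggers follow-up in a sample that looks depth-normal |
| variant presence | ≥3 supporting reads and ≥8% of covering reads | guards against sequencing error at 30–60× without suppressing a genuine heterozygous tag (~25–50% of SMN1-locus reads) |
| min base quality | 13 | applied only at discriminating/variant positions; depth counts every aligned base |
| mapping-quality filter | none | the paralogs produce legitimate MAPQ-0 multi-mappers; filtering them destroys the allele signal |

All thresholds are overridable via a `key = value` config file
(`--config`).

## Counting conventions

* D1/D2 pool reads from **both** paralog coordinates. Mapping position is
  uninformative between near-identical paralogs; only the carried base
  discriminates. The practical consequence is that site depth is the full
  SMN-locus depth, roughly doubling the signal available at each site.
* Overlapping mates are counted once per fragment (higher-quality mate
  wins), so D1/D2 approximates molecule support.
* Mean gene depth is the arithmetic mean of per-base aligned depth over the
  closed interval, zero-depth positions included; deleted/skipped bases do
  not contribute.
* The 2-bp deletion g.27706_27707delAT is supported only by alignments whose
  CIGAR deletes both bases; partial overlap is not the HGVS event.
* A site with zero covering reads yields an undefined π (NaN), and the
  sample is reported *inconclusive* — never silently classified.

## Genotype matching

A carrier genotype is a candidate when θ̂ is within 0.15 of its expected
scale factor **and** the median per-site D1/D2 ratio is within 0.15 of its
expected ratio; among several candidates the closest (Euclidean) wins, and
zero candidates — including the case where θ̂ and the ratios pull toward
different genotypes — yields *inconclusive*. The median (not the mean) of
the three ratios feeds the match so one noisy site cannot flip a call.

## Registry

Coordinates ship as a plain TSV inside the package (GRCh37 only; any other
build tag is an explicit error). Discriminating-site alleles are the GRCh37
reference bases at the paired coordinates (site b is exon-7 c.840: C in
SMN1, T in SMN2). Gene intervals are RefSeq transcript spans resolved once
by the package authors; the exact interval boundaries used by other
implementations are unpublished, so mean-depth values need not match other
tools digit-for-digit — the normalization is interval-agnostic as long as
one fixed set is used across a batch.

## Synthetic fixtures

The generator writes pre-aligned, coordinate-sorted, indexed BAMs — no
aligner in the loop — with full-length GRCh37 contigs in the header so all
coordinates are authentic. It emulates:

* per-copy read tiling: each SMN copy contributes `mean_depth_per_copy`
  (default 15×, i.e. 30× per diploid gene, a standard WGS depth) of evenly
  spaced reads; control genes are tiled at `control_depth` (30×);
* paralog mismapping: each SMN read is placed at the SMN1 or SMN2 locus
  with probability ½ (configurable), at MAPQ 0;
* allele painting: SMN1-origin reads carry the SMN1 base at all three
  sites, and with `silent_carrier_haplotype` also the g.27134T>G base and
  the 2-bp deletion in their CIGAR;
* uniform per-base substitution errors at `base_error_rate` (0 by default;
  recovery studies use 0.001, a NovaSeq-like post-filter rate).

The truth record tallies the reads actually written (after error
injection), so on error-free fixtures extraction must agree **exactly**.

What the generator does *not* emulate: Poisson depth fluctuation (tiling is
quasi-deterministic), GC and mappability bias, insert-size structure,
paired-end mates, soft-clipping, and real aligner behaviour at the locus.
Passing recovery tests therefore demonstrate the correctness of the
counting, normalization and classification machinery under the method's own
coverage model — not the field error rate of the thresholds on real
sequencing data, which the original validation cohorts addressed.

Tests and recovery studies use a desk-scale registry
(`simulate.fixture_registry()`): the real sites, variants and chromosomes,
with each control gene shrunk to a 1 kb window inside its real span and the
SMN intervals to ~1.5 kb around the sites and variants. Because Z and θ̂
depend on mean depths, not interval lengths, this changes nothing
statistically and keeps a 20-replicate, 50-genome study in the minutes
range. The recovery study uses N = 50 batches with 10% carriers (two 1:2,
one 1:3, one 1:1, one silent 2+0) across 20 seeds.

## Numerical choices

* All statistics in double precision; rounding only at report formatting.
  Reports print π and θ̂ to 3 decimals (published reports used 2, which is
  ambiguous between rounding and truncation at the 0.01 level).
* mean(θ̂) = 1 holds algebraically; tests assert it to 1e-9.
* Batch computation is order-equivariant; reports are byte-identical for
  any worker count (extraction is parallel, normalization joint and
  serial).
* Per-sample seeds for batch generation derive from one base seed via a
  seed sequence; identical seeds give byte-identical BAMs.

## Known limitations

* Absolute genotypes are only meaningful for carriers; 0-copy (affected)
  patterns are surfaced as a note, not a validated call.
* SMN1/SMN2 hybrid alleles (extra exon-1–6 copies) can shift θ̂ upward and
  push a true 1:1 toward the 1:2 centroid, exactly as in the bundled
  validated panel's first sample; MLPA itself cannot resolve the hybrid's
  origin.
* The silent-carrier rule is necessary-condition screening: the two tag
  polymorphisms are population-linked to duplications, not diagnostic.
* CRAM input requires the reference FASTA; the full CRAM decode path is
  exercised only on real references since a genome-scale FASTA cannot ship
  with the package.
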