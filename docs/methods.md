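# Methods

## Scoring model

A binding-site collection of N aligned, equal-length (L ≥ 4) ACGT
sequences yields per-position frequencies
`f(b, l) = (n(b, l) + α) / (N + 4α)` and individual-information weights
`riw(b, l) = 2 + log₂ f(b, l)` bits, assuming a uniform genomic
background. The score of a width-L sequence is the sum of its
per-position weights. Two identities anchor the scale: a perfectly
conserved position contributes 2 bits, and the expected score of a site
drawn position-wise from `f` equals the model information content
`Rsequence = Σ_l Σ_b f·riw` (checked as a property test and by the
acceptance script).

**Pseudocount.** Default α = 0, reproducing the literal frequency
matrix of the collection. A base never observed at a position then has
weight −∞ (IEEE negative infinity), so any sequence using it is
rejected by every finite threshold; this sentinel is deliberate and
tested. Simulation studies that *sample* a finite collection from a
generating matrix use α = 0.5: with 60 sampled sites, bases of
frequency ~0.003 are frequently unobserved, and an unsmoothed model
would spuriously assign −∞ to genuine sites. The package default stays
at 0; the smoothing is a per-run configuration.

**Collection statistics.** The model's mean μ and standard deviation σ
come from scoring every collection member; the operating threshold is
`T = μ − 1.5σ`. σ is the population SD (divide by N) because the
collection is treated as the complete reference set; a `sd_mode`
switch selects the sample convention. An optional small-sample
correction subtracts the first-order sampling-bias term
`e(N) = 3 / (2 ln 2 · N)` bits from every weight; it is off by default
since the uncorrected weights are the common convention for
individual-information scanning, and the corrected mode shifts every
width-L score rigidly by `L·e(N)` (asserted in tests).

**Ambiguity codes.** Scores are undefined for non-ACGT bases; scanned
windows containing them are skipped and counted, never scored.

## Scanner

Windows of width L on both strands are scored vectorised (the
reverse-strand score of a window is its forward score under the
reverse-complemented weight matrix). "Above threshold" is strict (>).
When both strands pass at the same coordinates — routine for
near-palindromic operators — only the higher-scoring strand is
reported, ties to '+': a physical operator occupies one locus and
double-counting would inflate every downstream per-COG count.
Coordinates are 0-based half-open internally and 1-based inclusive in
exported TSV/GFF3. Equivalence with exhaustive per-window enumeration
is asserted on 10-kb contigs in the test suite and re-checked by the
acceptance script.

## Gene context

The promoter window spans −300/+50 bp around the translational start,
strand-aware and clipped to the contig. The upstream extent is a
configuration value: reported window conventions vary between −300 and
−350 upstream, and the package default follows the narrower one. Each hit is
associated with exactly one gene — the one minimising the distance
between the site midpoint and the translational start, compared
exactly in half-bp units. Exact ties prefer the gene whose promoter
window fully contains the site, then the lower start coordinate, then
the lexicographically smaller gene id. Operons are maximal runs of
same-contig, same-strand adjacent genes with intergenic gap strictly
below 100 bp. By default a site is credited only to its nearest gene;
`propagate_links_to_operons` optionally extends the credit to
downstream operon members, since a promoter site regulates the whole
transcription unit, but this expansion changes per-COG counts and is
therefore opt-in.

## Taxonomic filter and COG decoration

Homology-based taxonomic typing is deliberately replaced by a
declarative per-gene annotation table (gene id → best-hit protein, COG
id, one-letter COG category, phylum). Only links to genes in the
allowed phyla (default Firmicutes + Actinobacteria, where the LexA-type
operator is conserved) survive; unannotated genes are counted
separately, and the three-way partition kept/dropped/unannotated always
sums to the input size. Genes without a COG are excluded from COG-level
statistics but retained in site counts.

## Prototypical-COG classification

For each COG, `C(t) = |{s : s > t}|` is computed for integer t from 12
to 20 bits. Scores of genuinely regulated promoters are approximately
normal around `Rsequence`; within ±1.3σ of the mean, the normal CDF is
close to linear, so `C(t)` over the central range is well fit by a
line. The fit is ordinary least squares (scipy's `linregress` behind
`fit_cumulative`); zero-variance counts define R² := 0, never NaN. The
prototypical call is the conjunction R² > 0.85 AND max score > 16 bits
(strict, "above the mean") AND ≥ 10 sites with score in the closed
interval [12, 20]. Cumulative counts use strict >, the in-range
membership count is inclusive; both comparisons are configuration
switches because either convention is defensible. A diagnostic,
`r2_cutoff_diagnostic`, ranks eligible COGs by R² and tabulates how
many known-reference regulon members versus novel COGs enter as the
cutoff is relaxed — the procedure used to justify a conservative
cutoff — but requires the reference COG list as input and makes no call
by itself. No enrichment test or multiple-testing correction is
computed: the category distribution versus threshold is reported
side-by-side with an optional reference ensemble distribution,
descriptively.

## Synthetic metagenome generator

The generator emulates the statistical structure the analysis assumes,
and defines the standard study conditions used by the tests:

- **Motif.** A 16-bp near-palindromic matrix (CGAAC-n₄-GTTCG consensus,
  AT-rich spacer; eight 0.99-conserved positions, two moderately
  conserved, six weak). Information content 16.30 bits; sampled-site
  scores are ≈ N(16.3, 2.9), emulating the observed score spectrum of
  regulated promoters. It is a synthetic stand-in with the qualitative
  shape of the Gram-positive LexA operator, not a published matrix.
- **Validated-site collection.** 60 sites, 75% sampled from the sharp
  matrix and 25% from a temperature-softened version (`f^0.5`,
  renormalised). A multispecies collection of experimentally validated
  sites is more heterogeneous than any single regulon's sites; the weak
  tail reproduces the empirically observed relationship in which the
  collection-derived μ − 1.5σ threshold (here typically 8–10.5 bits)
  falls well below the 12–20 bit profiling range while regulated-site
  scores still centre near 16 bits. Without it, the threshold would cut
  into the profiling range and truncate every cumulative distribution.
- **Layout.** 40 contigs × 50 kb (~2 Mb). Genes of 500–1500 bp are laid
  out in operons (Poisson size, mean 2, max 5) with 20–95 bp gaps
  inside operons and 320–470 bp between them, so every operon head has
  a full promoter. One phylum per contig (a contig is one species, so
  the phylum filter has block structure), gut-like mix: Firmicutes
  0.45, Bacteroidetes 0.30, Actinobacteria 0.15, Proteobacteria 0.10.
  10% of genes stay unannotated; the rest draw from 50 background COGs
  with random categories.
- **Planting.** Five regulon COGs (named after canonical SOS families:
  lexA/umuD, recA, uvrB, dinB, uvrD homolog clusters, categories L/T/K)
  are each assigned to 15 distinct operon-head genes on allowed-phylum
  contigs — the simulated regulator is phylum-restricted, mirroring the
  biology the taxonomic filter assumes — and one matrix-sampled site is
  written into each promoter, ending 20–140 bp upstream of the
  translational start. The proximity bound guarantees the site is
  nearest its own gene even for divergent promoters facing each other
  across an intergenic gap, and makes overlap between planted sites
  geometrically impossible.
- **Determinism.** All randomness flows through one
  `numpy.random.Generator`; identical configuration and seed give
  byte-identical FASTA/TSV/manifest output (tested). The truth manifest
  records every planted site's coordinates, strand, sequence and score,
  and is verified against the emitted sequences.

What the generator does **not** emulate: sequencing error, assembly
artifacts and chimeras, uneven coverage, codon structure or realistic
gene content, horizontal transfer, and within-phylum motif divergence
beyond the softened-collection tail. Passing the recovery test
therefore shows the inference machinery is correct under the assumed
statistical structure, not that the biological assumptions hold in any
particular real community.

## Problem sizes and numerical choices

The standard recovery study uses ~2 Mb of sequence — enough for ~1500
genes and ~36 profiled COGs — which the vectorised scanner processes in
well under a second; tests and the acceptance script complete in a few
seconds. With 15 sites per regulon COG the R² criterion operates close
to its design point: typical recovery is 5/5 with occasional 4/5 at
some seeds (step-function noise in a 9-bin cumulative distribution of
15 scores), with false positives essentially absent because a
background COG would need ten chance promoter hits above 12 bits.
Score comparisons in tests use exact tolerances (1e-9) against frozen
brute-force oracle values; midpoint distance ties are compared in
integer half-bp units to avoid float equality.

## Known limitations

- Gapped or variable-length motifs and motif discovery are out of
  scope; the collection arrives aligned.
- No FDR control on scan hits and no significance test on category
  distributions; the classifier is a deterministic rule, not a model
  with calibrated error rates.
- The annotation table is trusted as given; no homology search or
  taxonomy resolution is performed.
- Site-to-gene association uses the midpoint-to-start distance only;
  it does not model divergent promoters regulating both flanking genes
  (a site is credited to exactly one gene unless operon propagation is
  enabled, which only extends credit downstream).
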