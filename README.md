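# metaregulon

Inference of transcription-factor **meta-regulons** — the composite,
multi-species regulon of a bacterial community — directly from
metagenomic contigs.

Metagenome assemblies sample a regulatory network in its natural
habitat: every promoter carrying a conserved operator motif is evidence
that the gene behind it belongs to the regulon, whichever (possibly
uncultured) species contributed the contig. `metaregulon` implements
that inference for motifs conserved at the phylum level, with the SOS
response repressor LexA in Gram-positive gut bacteria as the motivating
case, and ships a synthetic-metagenome generator with a ground-truth
manifest so the whole pipeline can be validated end to end without any
external download.

## Method

1. **Ri scoring model.** From an aligned collection of experimentally
   validated binding sites, per-position base frequencies
   `f(b, l)` give individual-information weights
   `riw(b, l) = 2 + log₂ f(b, l)` bits (uniform background). A
   sequence's score is `Ri(s) = Σ_l riw(s_l, l)`; the expected score of
   a true site equals the motif information content
   `Rsequence = Σ_l Σ_b f·riw`. Scoring the collection itself fixes the
   operating threshold at `μ − 1.5σ`.
2. **Both-strand scanning.** Every window of the motif width on both
   strands of every contig is scored; windows above the threshold are
   reported once (the better strand wins at palindromic positions),
   windows containing ambiguous bases are skipped and counted.
3. **Gene context.** Each hit is associated with the gene whose
   translational start is closest to the site midpoint; sites fully
   inside the −300/+50 bp promoter window are flagged. Same-strand
   genes separated by < 100 bp are grouped into operons.
4. **Taxonomic filtering.** Only sites whose gene maps to a phylum
   where the motif is conserved (default Firmicutes + Actinobacteria)
   are retained, using a declarative per-gene annotation table
   (COG id, COG functional category, phylum).
5. **Prototypical regulon COGs.** For each COG, the cumulative count
   `C(t)` of promoter sites scoring above `t` is computed in 1-bit
   steps over 12–20 bits. Because true-site scores are approximately
   normal around `Rsequence` (~16 bits), `C(t)` is nearly linear in its
   central range; a COG is called *prototypical* when an OLS fit gives
   `R² > 0.85`, at least one site exceeds 16 bits, and at least 10
   sites fall in the 12–20 bit range.

## Worked example

```python
from metaregulon import SiteCollection, build_scoring_model, rsequence, score_sequence

sites = SiteCollection.from_sequences(
    ["GAACGTTC", "GTACGTTC", "GAACGTAC", "CAACGTTC", "GAACGATC", "TAACGTTG"]
)
model = build_scoring_model(sites, pseudocount=0.25)
print(f"information {rsequence(model):.3f} bits, threshold {model.threshold:.3f} bits")
print(f"score(GAACGTTC) = {score_sequence(model, 'GAACGTTC'):.3f} bits")
```

prints

```
information 8.126 bits, threshold 9.491 bits
score(GAACGTTC) = 13.129 bits
```

i.e. this small motif carries ~8.1 bits of information, the
consensus-like probe scores 13.1 bits, and any window scoring at most
9.49 bits would be discarded by the collection-derived threshold.

The full pipeline on a synthetic community (`examples/05_full_recovery.py`)
generates ~2 Mb of annotated contigs in which 5 designated regulon COGs
received 15 promoter-planted sites each over a background of 50
unrelated COGs, then recovers them:

```
scan threshold: 8.6340 bits
                   raw_sites: 598
              promoter_sites: 193
       phylum_filtered_sites: 124
               cogs_profiled: 36
           prototypical_cogs: 5
prototypical COGs: COG0210, COG0389, COG0468, COG0556, COG1974
planted regulon COGs : ['COG0210', 'COG0389', 'COG0468', 'COG0556', 'COG1974']
false positives      : []
```

All five planted COGs are recovered and no background COG passes the
three-clause rule. Each `examples/0*.py` script demonstrates one
capability (model building, scanning, gene context, classification,
recovery) and prints what the numbers mean.

A thin CLI mirrors the library (`metaregulon build-model | scan | link |
filter | profile | simulate | run`); `metaregulon run config.yaml`
executes all stages and writes a stage-count report.

## Layout

```
src/metaregulon/
  motif.py       Ri scoring models (frequencies, weights, thresholds)
  scan.py        both-strand sliding-window scanner
  genes.py       operons, promoter windows, site–gene linking
  annotation.py  phylum filtering and COG decoration
  regulon.py     cumulative-score regression and prototypical calls
  simulate.py    synthetic metagenomes with planted ground truth
  pipeline.py    stage orchestration and run reports
  cli.py         thin command-line layer
```
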