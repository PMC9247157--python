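# chirplex

Where, and how, does a chromatin-associated lncRNA touch the genome?
`chirplex` implements the computational arm of that question for
ChIRP-seq-style occupancy data, as asked of *MIR205HG/LEADR* in prostate
basal cells: consensus binding peaks from replicate pulldowns, strand-aware
TSS-proximal annotation against a random-region permutation null,
Hoogsteen-rule RNA:DNA triplex prediction with RNA-accessibility masking,
triplex-stratified region-set enrichment (Alu, histone marks), and
triplex/Alu co-occurrence statistics with a monotone-trend test.  A seeded
synthetic-data generator with planted ground truth makes every stage
testable end-to-end with no downloads.

It is written for computational biologists who want either the individual
statistical pieces (a consensus-peak builder, a triplex scanner that is
provably equivalent to an exhaustive scan, a calibrated region-set
enrichment test, a tie-corrected Jonckheere-Terpstra test) or the whole
pipeline as a template for their own lncRNA occupancy analysis.

## The models in brief

**Consensus peaks.** Each replicate peak is anchored at its MACS2 summit
(midpoint fallback) and extended ±500 bp; overlapping extended regions
pooled across replicates form connected components, and a component
supported by ≥2 of 3 distinct replicates becomes a consensus peak, shrunk
to the span of its members' narrow regions when those fit inside.

**Proximal annotation.** The proximal window is −1,500/+500 bp around the
TSS in transcript orientation, split into region 1 (−1,500/−500) and
region 2 (−500/+500).  The proximal excess over random expectation is
tested with a Pearson 2×2 chi-square (df = 1, no continuity correction)
against the averaged random list, and with permutation p-values over lists
of random length-matched regions.

**Triplex search.** A hit pairs an RNA window (triplex-forming
oligonucleotide, TFO) with the purine strand of a duplex DNA tract
(triplex target site, TTS) under one of four Hoogsteen motif tables
(pyrimidine U·A/C·G parallel; purine A·A/G·G antiparallel; G·G/U·A in both
orientations), mismatch-only, with minimum length 15 nt (20 nt optional),
mismatch rate ≤20%, and a TFO guanine-content filter.  Hits are *maximal*
windows — extending one step violates the rate or a boundary — and the
scanner is tested to agree exactly with an exhaustive all-offsets scan.
Bases of the lncRNA with <10% probability of being single-stranded can be
masked out first.  RNA-side footprints merge into DNA-binding domains
(DBDs); the genomic region test compares the number of target regions
carrying a DNA-binding site (DBS) against length-matched random regions.

**Enrichment and co-occurrence.** Region-set enrichment follows the LOLA
construction (restricted universe from the query sets; odds ratio
(a·d)/(b·c); one-sided exact test), with a triplex-stratified ratio of
odds ratios.  DBS–Alu distances are edge-to-edge within peaks, and the
fraction of genes carrying both a triplex and an Alu is tested for a
monotone trend across fold-change-ranked bins with the tie-corrected
Jonckheere-Terpstra statistic.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic bundle (seeded, deterministic):

```sh
python analysis/01_simulate.py
python analysis/02_consensus.py
python analysis/03_annotate.py
python analysis/04_triplex.py
python analysis/05_enrichment.py
python analysis/06_cooccurrence.py
```

The run prints, among other things:

```
300 consensus peaks (mean length 903 bp) from 1050 replicate peaks
manifest recovery: 300/300 true peaks, support>=2 in all, 0 from private noise
proximal: 10.33% of 300 peaks vs 8.08% random (1.28-fold)
  chi-square p = 0.193; empirical p = 0.00498 (200 lists of 2000)
DBD 47-70: 107 hits, 24 regions
DBD 119-196: 619 hits, 23 regions
region test [any]: observed 24/30, null 0.23+-0.45, p = 0.01
Alu: OR(triplex) 52.5, OR(triplex-less) 0.019, ratio 2756.25 -> tracks with the triplex
H3K27me3: OR(triplex) 0.219, OR(triplex-less) 4.57, ratio 0.05 -> tracks against the triplex
24 triplex-forming peaks; 100% have their Alu within 300 bp of the DBS (median gap 150 bp)
JT = 240.0, p = 1.07e-09 for a decreasing triplex+Alu trend across 3 fold-change bins
```

Reading this: all 300 planted peaks survive consensus with no
replicate-private noise; the planted 10.23%-proximal placement is
recovered (the chi-square is underpowered at n = 300 — the permutation
test is not); the two planted DNA-binding domains are recovered at their
exact coordinates (1-based 47–70 and 119–196) under masking; the region
test puts the triplex excess at its p-value floor of 1/100; Alu and
H3K4me1 track the triplex-forming peaks while H3K27me3 tracks the
triplex-less ones; and the triplex+Alu share decays with fold-change rank.

The same stages are available as a CLI (`chirplex simulate | consensus |
annotate | triplex | enrich | cooccur | all`) for use on real peak files.

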