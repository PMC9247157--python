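# Methods

This note documents the models implemented in `chirplex`, the choices made
where the design was genuinely open, what the synthetic data emulate (and
do not), and the numerical conventions.  Problem sizes quoted here are the
package's defaults; everything scales through configuration objects.

## Coordinates and formats

All genomic intervals are 0-based half-open (the BED convention); two
intervals touching at a shared endpoint do not overlap.  RNA-side domain
coordinates are reported 1-based inclusive on the transcript, the usual
convention for naming RNA regions.  Chromosome names are taken verbatim —
no `chr` normalization — and a name absent from the genome raises instead
of producing a silent empty join, which is the classic failure mode of
interval pipelines.  BED6 and 10-column ENCODE narrowPeak are parsed and
written natively with per-line error reporting; FASTA goes through
Biopython; the RNA accessibility profile is a 2-column TSV of 1-based
position and probability of being single-stranded.

## Consensus peaks

Replicate peaks are anchored at their summit (narrowPeak column 10) or, if
the summit is unknown, the interval midpoint, and extended by
`extend_size` (default 500 bp) on both sides.  Extended regions pooled
across replicates are swept into connected components of pairwise overlap;
chained overlaps (A–B, B–C, but not A–C) therefore resolve into a *single*
component.  A component counts *distinct replicates*, not peaks; with
`min_support` (default 2 of 3) it becomes a consensus peak.  When every
member's narrow region lies within the component's extended span, the
consensus interval shrinks to the minimal interval covering the narrow
regions, so identical replicates reproduce their input intervals exactly.
Raising `min_support` can only remove peaks, and replicate file order does
not matter; both are property-tested.

## TSS-relative annotation

The proximal window is −1,500/+500 bp around the TSS in transcript
orientation (for a minus-strand gene with TSS *t*, genomic
[*t*−500, *t*+1500)), split exactly into region 1 (−1,500/−500) and
region 2 (−500/+500).  Annotation priority is Proximal > 5′UTR > 3′UTR >
Exon > Intron > Downstream (≤3,000 bp past the gene end) > Distal
Intergenic, with nearest-TSS tie-breaking; UTR/exon categories are only
reachable when sub-gene annotation tracks are supplied.  Cutpeaks are the
non-empty intersections of proximal peaks with the strand-projected
region 1/region 2 windows; by construction the two cutpeak sets partition
the peak∩proximal bases with no double coverage (property-tested).  The
region-2 overlap classes (`includeFeature`, `overlapStart`, `inside`,
`overlapEnd`) are computed in TSS-relative coordinates so the strand case
analysis disappears; peaks confined to region 1 form the remainder class.

The proximal excess is tested two ways.  (1) A Pearson 2×2 chi-square
(df = 1, no continuity correction) of the observed proximal count against
the *averaged* random list, a reconstruction that reproduces the published
worked example (10.23% of 5,064 vs 8.02% of 5,000 → p ≈ 1.2 × 10⁻⁴) from
its printed percentages; per-list comparison is retained as an option.
(2) Permutation p-values over lists of random fixed-length regions:
the standard estimator p = (1 + #{lists ≥ observed})/(N + 1), and a second
variant defined as 1/k where k counts lists whose own chi-square against
the observed counts is Benjamini–Hochberg-significant across the N lists
(the correction method was an open choice; BH is the default).  The two
variants answer slightly different questions and are both exposed.

Random regions are sampled uniformly over chromosome coordinates with
full containment, chromosomes weighted by placeable positions; no
gap/blacklist masking is applied (synthetic genomes have none; a blacklist
can be emulated by restricting the chromosome table).  The
`proximal_only` mode confines every region to a proximal window (the
500-random-proximal-peak control).

## Triplex model

A triplex hit aligns an RNA window (TFO) against the purine strand of a
DNA tract (TTS) under a per-position Hoogsteen triplet table:

| motif | triplets | RNA orientation vs purine strand |
|---|---|---|
| pyrimidine_parallel | U·A, C·G | parallel |
| purine_antiparallel | A·A, G·G | antiparallel |
| GT_parallel | G·G, U·A | parallel |
| GT_antiparallel | G·G, U·A | antiparallel |

The error model is mismatch-only — triplex geometry disallows bulges at
this level of description — with mismatch rate ≤ `max_error_rate` (0.20)
over the aligned window and length ≥ `min_length` (15; the stricter
analysis uses 20).  Since the published analysis states only the length
thresholds, the error rate and the TFO guanine-content floor
(`min_guanine_rate`, 0.10) are pinned at the defaults of the
Triplexator/TDF family and exposed in configuration.  The guanine filter
as specified applies to the TFO, which a pure poly-U TFO cannot pass;
tests of the textbook poly-U·poly-A case therefore set the filter to 0
explicitly.

**Hit definition.** A hit is a *maximal* window: one-step extension in
either direction violates the mismatch rate or runs off a sequence
boundary (transcript end, region end, or a masked base).  The guanine
filter applies after maximality, so a maximal window failing it yields no
hit even if a sub-window would pass.  Rate comparisons use exact rational
arithmetic (`Fraction` of the decimal string) — with floats, 0.8 × 15
exceeds 12 and misclassifies boundary windows.

**Masking.** Bases with accessibility below `ss_prob_threshold` (0.10)
are replaced by `N` and act as hard breaks: no hit may contain one, and
extension stops there.  Masking therefore never creates new RNA:DNA
pairings; it can truncate a hit at a mask edge, so the invariant tested is
containment (every masked hit lies within an unmasked hit), not set
inclusion of identical windows.

**Search architecture and exactness.** Every triplet in every motif puts a
purine on the purine strand, so a window with mismatch rate ≤ e has purine
fraction ≥ 1 − e and lies inside a maximal purine tract.  The scanner
first finds all maximal tracts on both strands (`find_tts`), merges
overlapping tracts into per-strand candidate zones, and aligns the RNA
only against those zones, enumerating diagonals whose total match count
reaches ⌈rate × min_length⌉ (a necessary condition) and re-checking each
candidate's maximality against the full sequences.  The result is exactly
the exhaustive all-offsets/all-windows scan, and the test suite asserts
set equality with an independently written brute-force oracle on 100
seeded instances.  Windows identical under several motifs (U·A is shared
by the pyrimidine and GT tables) are reported once, keeping the first
motif in the priority order pyrimidine > purine > GT.

**DBDs and the region test.** RNA-side hit footprints closer than
`merge_gap` (10 nt) merge into DNA-binding domains, annotated with their
supporting hit and region counts.  The genomic region test counts target
regions with ≥1 DBS (overall and per DBD) against `n_randomizations`
(≥19; default 99) draws of length-matched regions sampled uniformly from
the genome or from a supplied background pool — the elaborate background
matching of the original TDF tool is deliberately not reproduced in favor
of a simpler null whose calibration is verified by simulation.  The
p-value is (1 + #{null ≥ observed})/(n + 1) with z = (obs − mean)/sd
(undefined when sd = 0).  Because the count statistic is discrete, the
standard p is conservative under heavy ties; a `randomized_p` option
implements the classical uniform tie-broken (randomized) p-value, which
is exactly uniform under exchangeability and is what the calibration test
uses.  The promoter test applies the same machinery to strand-aware
−1,500/+500 promoter windows of a target gene list vs all other genes and
reports the 2×2 chi-square.

## Enrichment

`build_restricted_universe` merges the query sets into the background
universe (the LOLA construction); sampling units are universe *elements*,
not base pairs.  An element supports a database at ≥1 bp overlap
(`min_overlap` generalizes).  The odds ratio is (a·d)/(b·c) — ∞ when
b·c = 0 with a·d > 0, NaN when both vanish — with a one-sided (greater)
exact hypergeometric p-value, two-sided available by flag.  The
triplex-stratified ratio of odds ratios contrasts triplex-containing and
triplex-less peaks against the same universe and database.  When the two
strata partition the universe their ORs are exact reciprocals, so perfect
association in one stratum drives the pair to (∞, 0); such coherent
degenerate pairs map to a directional ratio (∞ or 0), while incoherent
ones (both 0, both ∞, NaN) are reported as undefined.

## Co-occurrence and trend

DBS–Alu distances are edge-to-edge (0 when overlapping) to the nearest
Alu within the peak span ± 1 kb (configurable); peaks with no Alu in the
window are flagged and excluded from the summary denominator by default.
The ranked-bin analysis sorts genes by |fold change| descending (ties by
gene id, for determinism), cuts consecutive bins of `bin_size` (default
20; the last bin may be short — equal bins beyond the top bin were an
open choice), and classifies each gene as triplex+Alu / triplex only /
Alu only / neither.

The Jonckheere–Terpstra statistic is Σ over ordered group pairs i < j of
#{x < y} + ½·#{x = y}.  The p-value uses the normal approximation with the
standard tie-corrected variance (Hollander–Wolfe), or a seeded permutation
of the pooled values for small samples; the two agree within 0.02 at
n = 60 (tested with 4,999 permutations).  The trend applied to the figure
construction uses the per-gene 0/1 triplex+Alu indicator within ordered
bins, i.e. a trend of percentages of a binary trait.

## Synthetic data: what it emulates, and what it does not

The generator produces, from one seed, a byte-reproducible bundle:
genome FASTA, gene BED (+ exon/UTR tracks), Alu BED, three replicate
narrowPeak sets, lncRNA FASTA, accessibility TSV, histone-mark BEDs, a
fold-change table, and a JSON manifest of everything planted.  Defaults
encode the study conditions: 3 replicates; 10.23% of the 300 true peaks
proximal against an ~8% random background rate (the gene density — 60
genes on 2 × 1.04 Mb — is chosen so that a random 775-bp region touches a
proximal window with ~8% probability); peak lengths ~N(775, 100²); two
planted GT-motif domains at 1-based 119–196 and 47–70 of a 2,000-nt
lncRNA; planted target sites in region-1 windows of 40% of genes; an
Alu-like element 150 bp from each target site; H3K4me1 at odds 5 and
H3K27me3 at odds 0.2 for triplex vs non-triplex peaks over a 30% base
rate.

Design details that make ground truth exact rather than approximate:

* **Null control.**  The genome background is i.i.d. uniform ACGT scrubbed
  of every window that would qualify as a triplex target site on either
  strand.  The scrub screens 15-bp windows for ≥11 same-class bases plus
  25–29-bp windows for ≥⌈0.8·w⌉ — a counting argument shows these screens
  are jointly complete for tracts of any length at the 15-nt/20% setting —
  and rewrites flagged spans with a parity-alternating purine/pyrimidine
  pattern until no screen fires.  Every recovered site is therefore a
  planted one; the only residual purine tracts sit at planted-site flanks
  and Alu boundaries on the opposite strand, where the chance of an RNA
  match is negligible.
* **Crisp hit boundaries.**  Planted tracts carry 10 cytosines on each
  side of the purine strand, so alignment extensions beyond the planted
  core are always mismatches, and the accessibility profile pins the
  planted domains ≥0.9 while masking their 12-nt RNA flanks below 0.1.
  Under the masked search this makes the recovered domain span *exactly*
  the planted interval (extensions beyond the domain are blocked by the
  mask), with the first two target sites per domain anchored at the
  domain's two ends.  An optional decoy tract plants a domain whose
  profile sits below the masking threshold, to demonstrate that masking
  removes it.
* **Private noise.**  Noise peaks are placed on 3-kb stripes assigned
  exclusively to one replicate, with 600-bp margins, so extended noise
  regions can never overlap across replicates; true-peak centers keep
  ≥2.6 kb spacing so no two true peaks merge into one consensus region.
  Consensus recovery is consequently exact (all true, zero private).
* **Alu-like element.**  A fixed 300-bp synthetic consensus (generated
  once from a pinned seed and scrubbed like the genome), not a real
  repeat-database sequence; repeat identity is irrelevant to the
  statistics.

What passing these tests does *not* show about real data: real genomes
are full of genuine purine tracts, repeats and blacklist artifacts, so
real triplex calls carry a background the clean null removes; real peak
callers produce correlated, coverage-dependent boundaries rather than
symmetric jitter; real secondary-structure profiles are smooth
equilibrium estimates, not block masks; and real domain boundaries are
soft.  The synthetic results validate the *machinery* (recovery,
calibration, directionality), not effect sizes on biological data.

## Problem sizes and runtime conventions

The analysis scripts and the acceptance run use the default bundle
(2 × 1.04 Mb, 300 peaks), 200 random lists of 2,000 regions for the
permutation null, and 99 randomizations for the region test; calibration
simulations use 200 replicates with 39 randomizations on small uniform
genomes, sizes chosen to give the discrete statistics enough spread for a
meaningful calibration check.  With 300 peaks the synthetic chi-square for
a 10.3%-vs-8% proximal excess is underpowered (p ≈ 0.2) while the
permutation test detects it — the published contrast at n = 5,064 is
significant for both, and the worked example reproduces its printed
p-value from the printed counts.

## Known limitations

* Thermodynamic triplex stability, pH and modified bases are out of
  scope; the model is purely combinatorial.
* The region-test null is length-matched uniform sampling; it does not
  match GC content or chromatin context.
* The published empirical p-value definition ("1 divided by the number of
  significantly different lists") has a floor of 1/N and cannot reach the
  smallest values the publication prints; both it and the standard
  estimator are implemented without forcing agreement.
* `region1Only`-style overlap percentages depend on peak-length geometry
  and will differ between the synthetic bundle and any real dataset.
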