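#!/usr/bin/env python
"""Triplex-stratified region-set enrichment of consensus peaks.

Splits consensus peaks into triplex-containing and triplex-less strata
(masked search over the whole peak set), builds the restricted universe
from the peaks themselves, and reports the odds ratio of each stratum
against the Alu track and each histone-mark track, plus their ratio.  A
ratio above 1 means the feature tracks the triplex.

Writes results/enrichment.tsv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from chirplex.enrichment import (RegionDatabase, build_restricted_universe,
                                 stratified_or_ratio)
from chirplex.io import (read_accessibility_profile, read_fasta,
                         read_region_file)
from chirplex.triplex import TriplexParams, find_triplex_hits, mask_rna


def main() -> None:
    res = ROOT / "results"
    bdir = res / "bundle"
    params = TriplexParams()
    cs = read_region_file(str(res / "consensus.bed"))
    rna_rec = list(read_fasta(str(bdir / "lncrna.fa"), "RNA").values())[0]
    prof = read_accessibility_profile(str(bdir / "accessibility.tsv"),
                                      len(rna_rec))
    rna = mask_rna(rna_rec, prof, params.ss_prob_threshold)
    genome = {c: r.sequence
              for c, r in read_fasta(str(bdir / "genome.fa")).items()}
    hits = find_triplex_hits(rna, cs, genome, params)
    tri = {h.region_name for h in hits}
    flags = [iv.name in tri for iv in cs]
    print(f"{sum(flags)} triplex-containing vs {len(cs) - sum(flags)} "
          f"triplex-less consensus peaks")
    universe = build_restricted_universe([cs])

    tracks = {"Alu": bdir / "alu.bed",
              "H3K4me1": bdir / "marks" / "H3K4me1.bed",
              "H3K27me3": bdir / "marks" / "H3K27me3.bed"}
    with open(res / "enrichment.tsv", "w") as fh:
        fh.write("database\tor_triplex\tor_triplexless\tratio\n")
        for name, path in tracks.items():
            db = RegionDatabase.from_regions(name, read_region_file(str(path)))
            r = stratified_or_ratio(cs, flags, universe, db)
            fh.write(f"{name}\t{r.or_triplex}\t{r.or_triplexless}\t"
                     f"{r.ratio}\n")
            side = "with" if (r.ratio or 0) > 1 else "against"
            print(f"{name}: OR(triplex) {r.or_triplex:.3g}, "
                  f"OR(triplex-less) {r.or_triplexless:.3g}, "
                  f"ratio {r.ratio if r.ratio is None else round(r.ratio, 2)}"
                  f" -> tracks {side} the triplex")


if __name__ == "__main__":
    main()
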