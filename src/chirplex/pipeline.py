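"""End-to-end pipeline orchestration with deterministic seeding.

Stages run in the order simulate? -> consensus -> annotate -> triplex ->
enrich -> cooccur, each writing its outputs before the next starts.  One
global seed derives per-stage seeds by fixed offsets so any stage can be
rerun in isolation reproducibly.  Every output file carries a provenance
header (tool version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .annotate import (PeakAnnotator, RandomizationParams, RegionScheme,
                       chisq_2x2, cut_peaks, classify_overlap,
                       empirical_pvalue, feature_distribution, fold_enrichment,
                       sample_random_regions, tss_profile)
from .consensus import ConsensusParams, consensus_region_set, find_consensus_peaks
from .cooccurrence import (dbs_alu_distance, jonckheere_terpstra,
                           triplex_alu_table)
from .enrichment import (RegionDatabase, build_restricted_universe,
                         region_set_enrichment, stratified_or_ratio)
from .intervals import GenomicInterval, RegionSet, overlap_flags
from .io import (read_accessibility_profile, read_fasta, read_genes,
                 read_region_file, write_region_file)
from .triplex import (TriplexParams, find_triplex_hits, mask_rna, merge_dbds,
                      region_test)

log = logging.getLogger("chirplex")

STAGE_OFFSETS = {"simulate": 0, "annotate": 1, "triplex": 2, "cooccur": 3}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    # inputs; when simulate is set these are generated into outdir/bundle
    simulate: Optional[dict] = None
    replicates: List[str] = field(default_factory=list)
    genome: str = ""
    genes: str = ""
    lncrna: str = ""
    accessibility: str = ""
    alu: str = ""
    marks: Dict[str, str] = field(default_factory=dict)
    fold_changes: str = ""
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    scheme: RegionScheme = field(default_factory=RegionScheme)
    randomization: RandomizationParams = field(default_factory=RandomizationParams)
    triplex: TriplexParams = field(default_factory=TriplexParams)
    n_region_test_randomizations: int = 99
    bin_size: int = 20

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "consensus" in kwargs:
            kwargs["consensus"] = ConsensusParams(**kwargs["consensus"])
        if "scheme" in kwargs:
            sc = kwargs["scheme"]
            sc = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in sc.items()}
            kwargs["scheme"] = RegionScheme(**sc)
        if "randomization" in kwargs:
            kwargs["randomization"] = RandomizationParams(**kwargs["randomization"])
        if "triplex" in kwargs:
            tp = kwargs["triplex"]
            if "motifs" in tp:
                tp["motifs"] = tuple(tp["motifs"])
            kwargs["triplex"] = TriplexParams(**tp)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        path_fields = {"outdir", "simulate", "replicates", "genome", "genes",
                       "lncrna", "accessibility", "alu", "marks",
                       "fold_changes"}
        blob = json.dumps(
            {k: str(v) for k, v in sorted(vars(self).items())
             if k not in path_fields},
            sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (f"chirplex {__version__} seed={config.seed} "
            f"config={config.config_hash()}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the aggregated report (also written to disk).

    A stage failure raises after logging which stage failed; outputs of the
    completed stages remain on disk.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": config.config_hash()}
    stage = "setup"
    try:
        # ------------------------------------------------------ simulate
        if config.simulate is not None:
            stage = "simulate"
            log.info("stage %s", stage)
            from .synth import SyntheticConfig, generate_bundle

            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed + STAGE_OFFSETS["simulate"])
            bundle = generate_bundle(SyntheticConfig(**sim_kwargs))
            bdir = os.path.join(config.outdir, "bundle")
            bundle.write(bdir)
            config.replicates = [
                os.path.join(bdir, f"rep{i + 1}.narrowPeak")
                for i in range(bundle.config.n_replicates)]
            config.genome = os.path.join(bdir, "genome.fa")
            config.genes = os.path.join(bdir, "genes.bed")
            config.lncrna = os.path.join(bdir, "lncrna.fa")
            config.accessibility = os.path.join(bdir, "accessibility.tsv")
            config.alu = os.path.join(bdir, "alu.bed")
            config.marks = {m: os.path.join(bdir, "marks", f"{m}.bed")
                            for m in bundle.marks}
            config.fold_changes = os.path.join(bdir, "fold_changes.tsv")

        for path in ([config.genome, config.genes, config.lncrna]
                     + config.replicates):
            if path and not os.path.exists(path):
                raise FileNotFoundError(f"missing input file: {path}")

        # ------------------------------------------------------ consensus
        stage = "consensus"
        log.info("stage %s", stage)
        replicate_sets = [read_region_file(p, "narrowPeak")
                          for p in config.replicates]
        peaks = find_consensus_peaks(replicate_sets, config.consensus)
        consensus_set = consensus_region_set(peaks)
        write_region_file(consensus_set,
                          os.path.join(config.outdir, "consensus.bed"),
                          header=_header(config))
        report["n_consensus_peaks"] = len(peaks)
        mean_len = (float(np.mean([len(p.interval) for p in peaks]))
                    if peaks else 0.0)
        report["mean_consensus_length"] = round(mean_len, 1)

        # ------------------------------------------------------ annotate
        stage = "annotate"
        log.info("stage %s", stage)
        genome = read_fasta(config.genome)
        chrom_sizes = {c: len(r) for c, r in genome.items()}
        genes = read_genes(config.genes)
        ann = PeakAnnotator(genes, config.scheme)
        dist = feature_distribution(consensus_set.intervals, genes,
                                    config.scheme, annotator=ann)
        dist.to_csv(os.path.join(config.outdir, "feature_distribution.tsv"),
                    sep="\t", index=False)
        rparams = RandomizationParams(
            n_lists=config.randomization.n_lists,
            list_size=config.randomization.list_size,
            peak_length=config.randomization.peak_length,
            seed=config.seed + STAGE_OFFSETS["annotate"])
        rand_lists = sample_random_regions(rparams, chrom_sizes, genes,
                                           config.scheme)
        rand_fracs = []
        for rl in rand_lists:
            d = feature_distribution(rl.intervals, genes, config.scheme,
                                     annotator=ann)
            rand_fracs.append(
                d.loc[d.category == "Proximal Region", "percent"].item() / 100)
        obs_prox = dist.loc[dist.category == "Proximal Region"]
        obs_frac = obs_prox["percent"].item() / 100
        n_obs = len(consensus_set)
        mean_rand = float(np.mean(rand_fracs))
        a = int(obs_prox["count"].item())
        c = int(round(mean_rand * rparams.list_size))
        chi, chi_p = chisq_2x2(a, n_obs - a, c, rparams.list_size - c)
        report["proximal_percent"] = round(100 * obs_frac, 2)
        report["random_proximal_percent"] = round(100 * mean_rand, 2)
        report["proximal_fold_enrichment"] = round(
            fold_enrichment(obs_frac, mean_rand), 2) if mean_rand else None
        report["proximal_chisq_p"] = chi_p
        report["proximal_empirical_p"] = empirical_pvalue(
            obs_frac, rand_fracs, "standard")

        assigned = []
        for pk in consensus_set:
            cat, gene = ann.assign(pk)
            if cat == "Proximal Region":
                assigned.append((pk, gene))
        report["n_proximal_peaks"] = len(assigned)
        profile = tss_profile(
            [pk for pk, _ in assigned], genes,
            window=-config.scheme.proximal[0], binsize=100, annotator=ann)
        profile.to_csv(os.path.join(config.outdir, "tss_profile.tsv"),
                       sep="\t", header=["peak_count"])
        cp1 = cut_peaks(assigned, "region1", config.scheme)
        cp2 = cut_peaks(assigned, "region2", config.scheme)
        for label, cps in (("region1", cp1), ("region2", cp2)):
            write_region_file(
                RegionSet(label, [c.interval for c in cps]),
                os.path.join(config.outdir, f"cutpeaks_{label}.bed"),
                header=_header(config))
        report["n_region1_cutpeaks"] = len(cp1)
        report["n_region2_cutpeaks"] = len(cp2)
        ov = classify_overlap(assigned, config.scheme)
        ov.to_csv(os.path.join(config.outdir, "overlap_classes.tsv"),
                  sep="\t", index=False)
        report["overlap_classes"] = {
            r["class"]: round(r["percent"], 1) for _, r in ov.iterrows()}

        # ------------------------------------------------------ triplex
        stage = "triplex"
        log.info("stage %s", stage)
        lnc = list(read_fasta(config.lncrna, moltype="RNA").values())[0]
        rna_seq = lnc.sequence
        if config.accessibility:
            prof = read_accessibility_profile(config.accessibility, len(lnc))
            rna_seq = mask_rna(lnc, prof, config.triplex.ss_prob_threshold)
        genome_seqs = {c: r.sequence for c, r in genome.items()}
        region1_set = RegionSet(
            "region1_cutpeaks",
            [GenomicInterval(c.interval.chrom, c.interval.start,
                             c.interval.end, name=c.parent)
             for c in cp1])
        rt = region_test(rna_seq, region1_set, genome_seqs,
                         config.n_region_test_randomizations, config.triplex,
                         seed=config.seed + STAGE_OFFSETS["triplex"])
        hits = find_triplex_hits(rna_seq, region1_set, genome_seqs,
                                 config.triplex)
        dbds = merge_dbds(hits, config.triplex.merge_gap)
        with open(os.path.join(config.outdir, "dbd_table.tsv"), "w") as fh:
            fh.write(f"# {_header(config)}\n")
            fh.write("rna_start\trna_end\tn_hits\tn_supporting_regions\n")
            for d in dbds:
                fh.write(f"{d.rna_start}\t{d.rna_end}\t{d.n_hits}\t"
                         f"{d.n_supporting_regions}\n")
        dbs_set = RegionSet("dbs", [h.dna for h in hits])
        write_region_file(dbs_set, os.path.join(config.outdir, "dbs.bed"),
                          header=_header(config))
        with open(os.path.join(config.outdir, "region_test.tsv"), "w") as fh:
            fh.write(f"# {_header(config)}\n")
            fh.write("dbd\tobserved\tn_regions\tnull_mean\tnull_sd\tz\tp\n")
            for r in rt:
                label = (f"{r.dbd.rna_start}-{r.dbd.rna_end}" if r.dbd
                         else "any")
                fh.write(f"{label}\t{r.observed}\t{r.n_regions}\t"
                         f"{r.null_mean:.3f}\t{r.null_sd:.3f}\t"
                         f"{'NA' if r.z is None else round(r.z, 3)}\t"
                         f"{r.p:.6g}\n")
        report["region_test"] = {
            (f"{r.dbd.rna_start}-{r.dbd.rna_end}" if r.dbd else "any"): {
                "observed": r.observed, "p": r.p}
            for r in rt}
        report["dbds"] = [[d.rna_start, d.rna_end] for d in dbds]

        # ------------------------------------------------------ enrich
        stage = "enrich"
        log.info("stage %s", stage)
        report["enrichment"] = {}
        if config.alu or config.marks:
            tri_regions = {h.region_name for h in hits}
            full_hits = find_triplex_hits(
                rna_seq,
                RegionSet("peaks", consensus_set.intervals), genome_seqs,
                config.triplex)
            tri_peaks = {h.region_name for h in full_hits}
            flags = [iv.name in tri_peaks for iv in consensus_set]
            universe = build_restricted_universe([consensus_set])
            dbs = {}
            if config.alu:
                dbs["Alu"] = RegionDatabase.from_regions(
                    "Alu", read_region_file(config.alu))
            for mname, mpath in config.marks.items():
                dbs[mname] = RegionDatabase.from_regions(
                    mname, read_region_file(mpath))
            rows = []
            for name, db in dbs.items():
                entry = {}
                if any(flags) and not all(flags):
                    res = stratified_or_ratio(consensus_set, flags, universe, db)
                    entry = {
                        "or_triplex": res.or_triplex,
                        "or_triplexless": res.or_triplexless,
                        "ratio": res.ratio,
                    }
                else:
                    r = region_set_enrichment(consensus_set, universe, db)
                    entry = {"or": r.odds_ratio, "p": r.p_value}
                report["enrichment"][name] = entry
                rows.append((name, entry))
            with open(os.path.join(config.outdir, "enrichment.tsv"), "w") as fh:
                fh.write(f"# {_header(config)}\n")
                fh.write("database\tmetric\tvalue\n")
                for name, entry in rows:
                    for k, v in entry.items():
                        fh.write(f"{name}\t{k}\t{v}\n")
            report["n_triplex_peaks"] = int(sum(flags))

        # ------------------------------------------------------ cooccur
        stage = "cooccur"
        log.info("stage %s", stage)
        if config.alu and config.fold_changes:
            alu_set = read_region_file(config.alu)
            pk_by_name = {iv.name: iv for iv in consensus_set}
            pairs = []
            seen_pk = set()
            for h in hits:
                if h.region_name in pk_by_name and h.region_name not in seen_pk:
                    seen_pk.add(h.region_name)
                    pairs.append((pk_by_name[h.region_name], h.dna))
            records, summary = dbs_alu_distance(pairs, alu_set)
            report["dbs_alu"] = summary
            fc = {}
            with open(config.fold_changes) as fh:
                for line in fh:
                    if line.strip():
                        g, v = line.split("\t")
                        fc[g] = float(v)
            hit_regions = {h.region_name for h in hits}
            dbs_genes = {c.gene_id for c in cp1 if c.parent in hit_regions}
            prox_alu = []
            for g in genes:
                lo, hi = config.scheme.proximal_window(g)
                prox_alu.append(GenomicInterval(g.chrom, lo, hi, g.strand,
                                                g.gene_id))
            alu_gene_flags = overlap_flags(prox_alu, alu_set)
            alu_genes = {g.gene_id for g, f in zip(genes, alu_gene_flags) if f}
            table = triplex_alu_table([g.gene_id for g in genes], dbs_genes,
                                      alu_genes, fc, config.bin_size)
            table.to_csv(os.path.join(config.outdir, "triplex_alu_bins.tsv"),
                         sep="\t", index=False)
            if len(table) >= 3:
                flags01 = []
                ranked = sorted(fc, key=lambda g: (-abs(fc[g]), g))
                for bi in range(0, len(ranked), config.bin_size):
                    chunk = ranked[bi:bi + config.bin_size]
                    flags01.append([
                        1.0 if (g in dbs_genes and g in alu_genes) else 0.0
                        for g in chunk])
                jt, jt_p = jonckheere_terpstra(flags01, "decreasing")
                report["triplex_alu_trend"] = {"jt": jt, "p": jt_p}

        report_path = os.path.join(config.outdir, "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")
        return report
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
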