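"""End-to-end orchestration: simulate -> telomere -> centromere -> partition
-> rdna -> popgen -> sv -> regions, with a consolidated report and manifest.

Each stage writes its outputs before the next starts, so a downstream
failure preserves everything upstream; the manifest records the package
version, seed, every stage parameter and the input checksums, which is
sufficient to reproduce a run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io_formats import (Interval, write_bed, write_fasta,
                         write_methylation_tsv, write_vcf_genotypes)
from .popgen import filter_sites, stratify_regions, window_stats
from .rdna import locate_5s_clusters, te_colocalization
from .regionstats import (build_partition, methylation_enrichment,
                          te_region_fraction)
from .satellite import (call_centromeres, classify_morphology, decompose_hor,
                        discover_monomer, quantify_copies)
from .svtools import merge_callsets, population_specific, write_sv_vcf
from .synthetic import (CohortSpec, GenomeSpec, generate_cohort,
                        generate_genome, generate_methylation,
                        generate_sv_callsets, generate_truth_svs)
from .telomere import classify_t2t, scan_telomeres

log = logging.getLogger("satkit")


@dataclass
class RunConfig:
    outdir: str = "satkit_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {
        "telomere": True, "satellite": True, "rdna": True,
        "popgen": True, "sv": True, "regions": True,
    })
    # stage parameters (defaults mirror the module defaults)
    telomere_window: int = 10_000
    telomere_min_copies: int = 10
    satellite_window: int = 10_000
    satellite_min_identity: float = 0.96
    rdna_min_identity: float = 0.9
    rdna_max_gap: int = 5000
    rdna_flank: int = 10_000
    rdna_n_perm: int = 1000
    popgen_window: int = 10_000
    popgen_maf: float = 0.05
    popgen_max_missing: float = 0.2
    popgen_hwe: float = 1e-5
    sv_max_dist: int = 1000
    sv_min_support: int = 2
    sv_min_size: int = 30
    sv_n_callers: int = 3
    sv_n_truth: int = 40
    sv_jitter_sd: float = 100.0
    meth_base_mean: float = 0.6
    meth_delta: float = 0.15
    meth_sites: int = 2000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full synthetic-data pipeline; returns the summary dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    summary: dict = {"seed": config.seed, "warnings": []}
    manifest: dict = {
        "satkit_version": __version__,
        "config": dataclasses.asdict(config),
        "checksums": {},
        "stages_run": [],
        "stages_skipped": [],
    }

    try:
        # --- simulate -----------------------------------------------------
        gspec = GenomeSpec.default(seed=config.seed)
        genome, truth = generate_genome(gspec)
        lengths = {r.id: len(r.seq) for r in genome}
        write_fasta(genome, out / "genome.fa")
        write_bed(truth.intervals(), out / "truth.bed")
        manifest["stages_run"].append("simulate")

        # --- telomere -----------------------------------------------------
        if config.stages.get("telomere", True):
            rows = []
            for rec in genome:
                rep = scan_telomeres(rec, terminal_window=config.telomere_window)
                status = classify_t2t(rep, config.telomere_min_copies)
                rows.append((rec.id, rep.p.copies, rep.q.copies, status.value))
            with open(out / "telomere.tsv", "w") as f:
                f.write("chrom\tp_copies\tq_copies\tstatus\n")
                for r in rows:
                    f.write("\t".join(map(str, r)) + "\n")
            summary["telomere"] = {c: {"p": p, "q": q, "status": s}
                                   for c, p, q, s in rows}
            manifest["stages_run"].append("telomere")
        else:
            manifest["stages_skipped"].append("telomere")

        # --- satellite / centromere ---------------------------------------
        partition = None
        calls = None
        if config.stages.get("satellite", True):
            monomers = discover_monomer(genome)
            if not monomers:
                raise RuntimeError("satellite stage found no monomer candidate")
            top = monomers[0]
            array_iv = max(top.arrays, key=len)
            array_seq = next(r.seq for r in genome if r.id == array_iv.chrom)
            hor = decompose_hor(
                array_seq[array_iv.start:array_iv.end], top)
            hits = quantify_copies(genome, top,
                                   min_identity=config.satellite_min_identity)
            calls = call_centromeres(genome, hits, top.length,
                                     window=config.satellite_window)
            bed = [c.interval for c in calls.values() if c.called]
            write_bed(bed, out / "centromeres.bed")
            with open(out / "satellite.tsv", "w") as f:
                f.write("monomer_length\tcopy_count\tmean_identity\thor_period\t"
                        "hor_consensus_length\tvariant_units\tconsensus\n")
                f.write(f"{top.length}\t{top.copy_count}\t{top.mean_identity:.4f}\t"
                        f"{hor.hor_period}\t{hor.hor_consensus_length}\t"
                        f"{len(hor.variant_unit_indices)}\t{top.consensus}\n")
            summary["satellite"] = {
                "monomer_length": top.length,
                "hor_period": hor.hor_period,
                "hor_consensus_length": hor.hor_consensus_length,
                "variant_unit_indices": list(hor.variant_unit_indices),
                "per_chrom_copies": {c: hits[c].count for c in hits},
                "morphology": {c: classify_morphology(call)
                               for c, call in calls.items() if call.called},
            }
            for call in calls.values():
                for blk in call.secondary_blocks:
                    summary["warnings"].append(f"secondary satellite block {blk}")
                if not call.called:
                    summary["warnings"].append(f"{call.chrom}: centromere uncalled")
            partition = build_partition(calls, lengths)
            manifest["stages_run"].append("satellite")
        else:
            manifest["stages_skipped"].append("satellite")

        # --- rdna ---------------------------------------------------------
        if config.stages.get("rdna", True) and partition is not None:
            probe = truth.probe_5s
            if probe:
                clusters = locate_5s_clusters(genome, probe,
                                              min_identity=config.rdna_min_identity,
                                              max_gap=config.rdna_max_gap,
                                              partition=partition)
                te_ivs = [iv for t in truth.chromosomes.values()
                          for iv in t.te_intervals]
                coloc = te_colocalization(clusters, te_ivs, "LINE/L2", lengths,
                                          flank=config.rdna_flank,
                                          n_perm=config.rdna_n_perm,
                                          seed=config.seed)
                with open(out / "rdna.tsv", "w") as f:
                    f.write("chrom\tstart\tend\tcopies\tmodal_spacer\tarm\n")
                    for c in clusters:
                        f.write(f"{c.interval.chrom}\t{c.interval.start}\t"
                                f"{c.interval.end}\t{c.copy_count}\t"
                                f"{c.modal_spacer}\t{c.arm}\n")
                summary["rdna"] = {
                    "n_clusters": len(clusters),
                    "modal_spacers": [c.modal_spacer for c in clusters],
                    "te_colocalization_fraction": coloc.observed_fraction,
                    "te_colocalization_p": coloc.p_value,
                }
            manifest["stages_run"].append("rdna")
        else:
            manifest["stages_skipped"].append("rdna")

        # --- popgen ---------------------------------------------------------
        if config.stages.get("popgen", True) and partition is not None:
            cohort_spec = CohortSpec(seed=config.seed)
            gm, ctruth = generate_cohort(partition, cohort_spec)
            write_vcf_genotypes(gm, out / "cohort.vcf", contigs=lengths)
            gm_f, tally = filter_sites(gm, config.popgen_maf,
                                       config.popgen_max_missing,
                                       config.popgen_hwe)
            stats = window_stats(gm_f, *cohort_spec.pop_labels,
                                 window=config.popgen_window,
                                 chrom_lengths=lengths)
            summaries = stratify_regions(stats, partition)
            with open(out / "popgen_regions.tsv", "w") as f:
                f.write("region\tstatistic\tmean\tsd\tn_windows\n")
                for s in summaries:
                    f.write(f"{s.region}\t{s.statistic}\t{s.mean}\t{s.sd}\t{s.count}\n")
            summary["popgen"] = {
                "sites_kept": tally.kept,
                "excluded": {"missing": tally.missing, "maf": tally.maf,
                             "hwe": tally.hwe},
                "region_fst": {s.region: s.mean for s in summaries
                               if s.statistic == "fst"},
            }
            manifest["stages_run"].append("popgen")
        else:
            manifest["stages_skipped"].append("popgen")

        # --- sv -------------------------------------------------------------
        if config.stages.get("sv", True):
            pop_a = [f"A{i}" for i in range(3)]
            pop_b = [f"B{i}" for i in range(2)]
            truth_svs = generate_truth_svs(lengths, config.sv_n_truth,
                                           pop_a, pop_b, seed=config.seed)
            truth.sv_records = truth_svs
            callsets = generate_sv_callsets(truth_svs, config.sv_n_callers,
                                            config.sv_jitter_sd, fn_rate=0.05,
                                            seed=config.seed)
            merged = merge_callsets(callsets, max_dist=config.sv_max_dist,
                                    min_support=config.sv_min_support,
                                    min_size=config.sv_min_size)
            specific = population_specific(merged, pop_a, pop_b)
            samples = pop_a + pop_b
            write_sv_vcf(merged, samples, out / "sv_merged.vcf", contigs=lengths)
            write_sv_vcf(specific, samples, out / "sv_popA_specific.vcf",
                         contigs=lengths)
            summary["sv"] = {"n_truth": len(truth_svs), "n_merged": len(merged),
                             "n_popA_specific": len(specific)}
            manifest["stages_run"].append("sv")
        else:
            manifest["stages_skipped"].append("sv")

        # --- regions --------------------------------------------------------
        if config.stages.get("regions", True) and partition is not None:
            # region statistics are defined on the generator's centromere
            # (satellite array plus pericentromeric margins), not the
            # satellite-only call, so TE/methylation use the truth partition
            truth_part = truth.partition()
            te_ivs = [iv for t in truth.chromosomes.values()
                      for iv in t.te_intervals]
            erv = te_region_fraction(te_ivs, truth_part, "LTR/ERV1")
            meth, _mtruth = generate_methylation(
                truth_part, config.meth_base_mean, config.meth_delta,
                config.meth_sites, seed=config.seed)
            write_methylation_tsv(meth, out / "methylation.tsv")
            enr = methylation_enrichment(meth, truth_part)
            summary["regions"] = {
                "erv1_centromere_fraction": erv["fractions"]["centromere"],
                "methylation_region_means": enr.region_means,
                "methylation_anova_p": enr.anova_p,
                "methylation_lsd_p": {f"{a}|{b}": p
                                      for (a, b), p in enr.lsd_p.items()},
            }
            manifest["stages_run"].append("regions")
        else:
            manifest["stages_skipped"].append("regions")

        for p in sorted(out.iterdir()):
            if p.is_file() and p.name not in ("manifest.json", "summary.json",
                                              "run.log"):
                manifest["checksums"][p.name] = _sha256(p)
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True, default=str)
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    finally:
        log.removeHandler(fh)
        fh.close()
    return summary
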