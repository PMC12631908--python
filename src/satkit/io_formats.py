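"""Readers and writers for the standard formats the pipeline exchanges.

All coordinates crossing module boundaries are 0-based half-open; conversion
from 1-based closed conventions (GFF3, VCF POS) happens here and only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("satkit")

_VALID_BASES = set("ACGTN")

#: byte codes for A, C, G, T used by the numeric sequence routines
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 array of ASCII codes (vector-comparison substrate)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class GenomeRecord:
    """One chromosome: identifier plus upper-case ACGTN sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with an optional class label."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Sequences are upper-cased (a note is logged when lowercase input is seen);
    duplicate identifiers and characters outside ACGTN are rejected.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        seen.add(rec.id)
        raw = str(rec.seq)
        seq = raw.upper()
        if seq != raw:
            log.info("FASTA record %s: lowercase bases upper-cased", rec.id)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"FASTA record {rec.id}: invalid characters {sorted(bad)}"
            )
        records.append(GenomeRecord(rec.id, seq))
    return records


def write_fasta(records: list[GenomeRecord], path, width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Interval]:
    """Read BED (0-based half-open) into Intervals; name column preserved."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start in BED line")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            out.append(Interval(chrom, start, end, name, strand))
    return out


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            if iv.strand:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


@dataclass(frozen=True)
class GffFeature:
    interval: Interval
    type: str
    attributes: dict[str, str] = field(default_factory=dict, hash=False)


def read_gff3(path) -> list[GffFeature]:
    """Read GFF3 (1-based closed) and convert to 0-based half-open Intervals."""
    out: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns, expected 9")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer GFF3 coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start in GFF3 line")
            attrs = _parse_gff3_attributes(attr_s)
            name = attrs.get("family", attrs.get("ID", ftype))
            iv = Interval(chrom, start1 - 1, end1, name, strand if strand in "+-" else None)
            out.append(GffFeature(iv, ftype, attrs))
    return out


def write_gff3(features: list[GffFeature], path, source: str = "satkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attr = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        source,
                        f.type,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand or ".",
                        ".",
                        attr,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genotype matrices (VCF)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for a two-population cohort.

    ``geno`` holds alt-allele dosage per (site, sample): 0, 1, 2, or -1 for
    missing. ``pops`` maps a population label to the member sample names.
    Positions are 1-based as in VCF.
    """

    chrom: np.ndarray          # (n_sites,) object/str
    pos: np.ndarray            # (n_sites,) int, 1-based
    ref: np.ndarray            # (n_sites,) str
    alt: np.ndarray            # (n_sites,) str
    samples: list[str]
    pops: dict[str, list[str]]
    geno: np.ndarray           # (n_sites, n_samples) int8

    def __post_init__(self):
        labelled = [s for pop in self.pops.values() for s in pop]
        if sorted(labelled) != sorted(self.samples):
            raise ValueError("population labels must partition the sample list")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[s] for s in self.pops[pop]], dtype=int)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[mask_or_index],
            self.pos[mask_or_index],
            self.ref[mask_or_index],
            self.alt[mask_or_index],
            list(self.samples),
            {k: list(v) for k, v in self.pops.items()},
            self.geno[mask_or_index],
        )


def read_vcf_genotypes(path, sample_map: dict[str, str]) -> tuple[GenotypeMatrix, int]:
    """Read biallelic GT fields from a VCF into a GenotypeMatrix.

    ``sample_map`` maps sample name -> population label. Multi-allelic sites
    are skipped; the returned counter reports how many. Phased and unphased
    genotypes are treated identically for dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    missing = [s for s in sample_map if s not in vcf.samples]
    if missing:
        raise ValueError(f"samples absent from VCF: {missing}")
    keep_idx = [i for i, s in enumerate(vcf.samples) if s in sample_map]
    samples = [vcf.samples[i] for i in keep_idx]

    chroms, poss, refs, alts, rows = [], [], [], [], []
    skipped_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped_multiallelic += 1
            continue
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=missing
        g = var.gt_types[keep_idx].astype(np.int8)
        g[g == 3] = -1
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(g)
    vcf.close()

    pops: dict[str, list[str]] = {}
    for s in samples:
        pops.setdefault(sample_map[s], []).append(s)
    geno = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    gm = GenotypeMatrix(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=int),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        samples,
        pops,
        geno,
    )
    return gm, skipped_multiallelic


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf_genotypes(gm: GenotypeMatrix, path, contigs: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=satkit\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.geno[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Methylation tables
# ---------------------------------------------------------------------------

def read_methylation_tsv(path):
    """Read a methylation table (chrom, pos0, frequency) into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "frequency"], comment="#")
    if len(df) and not ((df.frequency >= 0) & (df.frequency <= 1)).all():
        raise ValueError("methylation frequencies outside [0, 1]")
    return df


def write_methylation_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
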