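"""Structural-variant merging across callers and population-specific filtering.

Merging follows the SURVIVOR positional-parameter semantics
(max_dist, min_support, type agreement, strand agreement, distance
estimation, min_size): records from *different* inputs cluster when their
breakpoints lie within max_dist (single-linkage, so merging is symmetric in
input order); clusters supported by at least min_support inputs emit one
record at the member-median position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SV_TYPES = ("DEL", "INS", "INV", "DUP", "TRA", "CPX")


def normalize_gt(gt: str | None) -> tuple[int, ...] | None:
    """Parse a GT string; phased and unphased compare equal ('0|1' == '0/1')."""
    if gt is None:
        return None
    sep = "|" if "|" in gt else "/"
    alleles = gt.split(sep)
    if any(a == "." for a in alleles):
        return None
    return tuple(sorted(int(a) for a in alleles))


@dataclass
class SVRecord:
    """One structural variant call.

    ``pos`` is 1-based as in VCF; ``genotypes`` maps sample/input label to a
    GT string. ``support`` is filled in by merging.
    """

    chrom: str
    pos: int
    svtype: str
    length: int
    end: int | None = None
    strand: str = "+"
    genotypes: dict[str, str] = field(default_factory=dict)
    source: str = ""
    support: int = 1
    id: str = "."

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype}")
        if self.length < 0:
            raise ValueError("SV length must be >= 0 (store |SVLEN|)")
        if self.end is None:
            if self.svtype in ("DEL", "INV", "DUP"):
                self.end = self.pos + self.length
            else:
                self.end = self.pos


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller root wins
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def _median_low(values: list[int]) -> int:
    """Median with even-count ties broken toward the smaller value."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def merge_callsets(callsets: dict[str, list[SVRecord]],
                   max_dist: int = 1000,
                   min_support: int = 2,
                   require_type: bool = True,
                   require_strand: bool = True,
                   use_est_dist: bool = False,
                   min_size: int = 30,
                   contigs: dict[str, set[str]] | None = None) -> list[SVRecord]:
    """Merge SV call sets from multiple callers/samples.

    ``callsets`` maps an input label to its (position-sorted) records.
    Records shorter than ``min_size`` (except translocations, which have no
    length) are discarded before clustering. ``contigs`` optionally gives the
    reference contig names declared by each input; disagreement is rejected.
    Returns merged records carrying per-input genotypes and support counts.
    """
    if contigs:
        names = list(contigs.values())
        if any(n != names[0] for n in names[1:]):
            raise ValueError("inconsistent reference contig names across inputs")
    if use_est_dist:
        raise NotImplementedError("distance estimation from SV size is not supported")

    pool: list[tuple[str, SVRecord]] = []
    for label, records in callsets.items():
        for rec in records:
            if rec.svtype != "TRA" and rec.length < min_size:
                continue
            pool.append((label, rec))

    # sort by (chrom, pos) so neighbour scanning is linear-ish
    order = sorted(range(len(pool)), key=lambda i: (pool[i][1].chrom, pool[i][1].pos))
    uf = _UnionFind(len(pool))
    for oi, i in enumerate(order):
        li, ri = pool[i]
        for j in order[oi + 1:]:
            lj, rj = pool[j]
            if rj.chrom != ri.chrom or rj.pos - ri.pos > max_dist:
                break
            if li == lj:
                continue
            if require_type and ri.svtype != rj.svtype:
                continue
            if require_strand and ri.strand != rj.strand:
                continue
            uf.union(i, j)

    clusters: dict[int, list[tuple[str, SVRecord]]] = {}
    for i in range(len(pool)):
        clusters.setdefault(uf.find(i), []).append(pool[i])

    merged: list[SVRecord] = []
    for members in clusters.values():
        support = len({label for label, _ in members})
        if support < min_support:
            continue
        recs = [r for _, r in members]
        pos = _median_low([r.pos for r in recs])
        end = _median_low([r.end for r in recs])
        length = _median_low([r.length for r in recs])
        # per-sample genotypes: first non-missing value in deterministic
        # (input label, position) member order
        genotypes: dict[str, str] = {}
        for _label, rec in sorted(members, key=lambda m: (m[0], m[1].pos)):
            for sample, gt in rec.genotypes.items():
                genotypes.setdefault(sample, gt)
        merged.append(SVRecord(
            chrom=recs[0].chrom, pos=pos, svtype=recs[0].svtype,
            length=length, end=end, strand=recs[0].strand,
            genotypes=genotypes,
            source=",".join(sorted({label for label, _ in members})),
            support=support,
        ))
    merged.sort(key=lambda r: (r.chrom, r.pos, r.svtype))
    return merged


def population_specific(merged: list[SVRecord],
                        pop_a: list[str],
                        pop_b: list[str],
                        known_samples: list[str] | None = None) -> list[SVRecord]:
    """Select SVs private to population A with fully consistent genotypes.

    A record is retained when every population-B sample is homozygous
    reference or absent, at least one population-A sample carries the
    variant, and every population-A sample carries the *same* non-reference
    genotype (e.g. 0/1 in all of them — an absent or hom-ref A sample breaks
    consistency). Population ids are validated against ``known_samples`` when
    given, otherwise against the union of samples seen in the records.
    """
    known = (set(known_samples) if known_samples is not None
             else {s for rec in merged for s in rec.genotypes})
    unknown = [s for s in pop_a + pop_b if s not in known]
    if unknown and merged:
        raise ValueError(f"sample ids absent from merged records: {unknown}")

    hom_ref = (0, 0)
    out: list[SVRecord] = []
    for rec in merged:
        b_gts = [normalize_gt(rec.genotypes.get(s)) for s in pop_b]
        if any(g is not None and g != hom_ref for g in b_gts):
            continue
        a_gts = [normalize_gt(rec.genotypes.get(s)) for s in pop_a]
        non_ref = {g for g in a_gts if g is not None and g != hom_ref}
        if len(non_ref) != 1:
            continue
        if any(g is None or g == hom_ref for g in a_gts):
            continue  # consistency requires every A sample to share the genotype
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# VCF I/O for SVs
# ---------------------------------------------------------------------------

def write_sv_vcf(records: list[SVRecord], samples: list[str], path,
                 contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=satkit\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Supporting inputs">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, rec in enumerate(records):
            svlen = -rec.length if rec.svtype == "DEL" else rec.length
            info = f"SVTYPE={rec.svtype};SVLEN={svlen};END={rec.end};SUPP={rec.support}"
            gts = "\t".join(rec.genotypes.get(s, "./.") for s in samples)
            fh.write(f"{rec.chrom}\t{rec.pos}\tsv{i}\tN\t<{rec.svtype}>\t.\tPASS\t"
                     f"{info}\tGT\t{gts}\n")


def read_sv_vcf(path, source: str = "") -> list[SVRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[SVRecord] = []
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        if svtype is None:
            continue
        svlen = var.INFO.get("SVLEN", 0)
        end = var.INFO.get("END", var.POS)
        genotypes = {}
        # cyvcf2 genotypes: [a0, a1, phased]
        for s, g in zip(samples, var.genotypes):
            a = ["." if x < 0 else str(x) for x in g[:-1]]
            genotypes[s] = ("|" if g[-1] else "/").join(a)
        out.append(SVRecord(
            chrom=var.CHROM, pos=var.POS, svtype=svtype,
            length=abs(int(svlen)), end=int(end),
            genotypes=genotypes, source=source,
            support=int(var.INFO.get("SUPP", 1)), id=var.ID or ".",
        ))
    vcf.close()
    return out


def match_to_truth(merged: list[SVRecord], truth: list[SVRecord],
                   max_dist: int = 1000) -> dict[int, int | None]:
    """Greedy nearest-position matching of merged calls to truth records.

    Used by recovery tests: each merged record is paired with the closest
    unclaimed truth record of the same type and chromosome within max_dist.
    """
    claimed: set[int] = set()
    assignment: dict[int, int | None] = {}
    for mi, rec in enumerate(merged):
        best, best_d = None, max_dist + 1
        for ti, t in enumerate(truth):
            if ti in claimed or t.chrom != rec.chrom or t.svtype != rec.svtype:
                continue
            d = abs(t.pos - rec.pos)
            if d < best_d:
                best, best_d = ti, d
        assignment[mi] = best
        if best is not None:
            claimed.add(best)
    return assignment
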