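"""Synthetic genomes, cohorts, methylation tables and SV call sets.

The generator emulates the architecture of a croaker-like telomere-to-telomere
assembly: chromosomes carry terminal telomeric hexamer arrays (CCCTAA-type on
the p end of the forward strand, TTAGGG-type on the q end), one centromeric
satellite array built from a 42 bp monomer arranged in a 168 bp higher-order
repeat of four units (two of them carrying fixed substitutions), interspersed
TE families with a configurable centromeric placement fraction (an ERV1-like
family concentrated pericentromerically, an L2-like family linked to 5S
clusters), and 5S rDNA tandem clusters on the short arm with a conserved
98 bp inter-copy spacer. Every output is paired with a machine-readable truth
set, and all randomness flows from one top-level seed through named
substreams so adding one feature class never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BASE_BYTES, GenomeRecord, Interval, decode_seq, encode_seq
from .regionstats import REGIONS, RegionPartition, partition_chromosome
from .svtools import SVRecord

TELOMERE_Q = "TTAGGG"   # G-strand motif at the q terminus
TELOMERE_P = "CCCTAA"   # C-strand motif at the p terminus


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream named after a feature class."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.415) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASE_BYTES, size=length, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a new base)."""
    if rate <= 0:
        return arr
    arr = arr.copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = BASE_BYTES[BASE_BYTES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SatelliteSpec:
    """Centromeric satellite architecture (42 bp monomer, 168 bp HOR)."""

    monomer_length: int = 42
    hor_units: int = 4
    variant_units: int = 2
    variant_subs_per_unit: int = 2
    array_copies: int = 300          # HOR copies in the array
    per_copy_mutation_rate: float = 0.02

    def __post_init__(self):
        if self.variant_units > self.hor_units:
            raise ValueError("variant_units must be <= hor_units")

    @property
    def hor_length(self) -> int:
        return self.monomer_length * self.hor_units

    @property
    def array_length(self) -> int:
        return self.hor_length * self.array_copies


@dataclass
class RdnaSpec:
    """5S rDNA tandem cluster: gene body plus conserved inter-copy spacer."""

    unit_length: int = 120
    spacer_length: int = 98
    copies: int = 200
    linked_te_family: str | None = "LINE/L2"

    def __post_init__(self):
        if self.copies < 1 or self.spacer_length < 0:
            raise ValueError("need copies >= 1 and spacer_length >= 0")

    @property
    def cluster_length(self) -> int:
        return self.copies * self.unit_length + (self.copies - 1) * self.spacer_length


@dataclass
class TEFamily:
    label: str
    element_length: int
    genome_copies: int
    centromere_fraction: float = 0.0

    def __post_init__(self):
        if not 0 <= self.centromere_fraction <= 1:
            raise ValueError("centromere_fraction must be in [0, 1]")


@dataclass
class TESpec:
    families: list[TEFamily] = field(default_factory=lambda: [
        TEFamily("LTR/ERV1", 200, 60, 0.85),
        TEFamily("LINE/L2", 150, 40, 0.0),
    ])


@dataclass
class ChromosomeSpec:
    name: str
    length: int
    centromere_position_fraction: float = 0.3
    telomere_copies_p: int = 30
    telomere_copies_q: int = 30
    satellite: SatelliteSpec | None = field(default_factory=SatelliteSpec)
    te: TESpec | None = field(default_factory=TESpec)
    rdna: RdnaSpec | None = None

    def __post_init__(self):
        if not 0 < self.centromere_position_fraction < 1:
            raise ValueError("centromere_position_fraction must be in (0, 1)")


@dataclass
class GenomeSpec:
    """Whole-genome generator spec; ``seed`` fully determines the output."""

    chromosomes: list[ChromosomeSpec]
    seed: int = 0
    gc: float = 0.415
    centromere_margin: int = 15_000  # pericentromere flank on each array side

    @classmethod
    def default(cls, seed: int = 0) -> "GenomeSpec":
        return cls(
            chromosomes=[
                ChromosomeSpec("chr1", 500_000, 0.3, rdna=RdnaSpec()),
                ChromosomeSpec("chr2", 400_000, 0.2),
            ],
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class RdnaClusterTruth:
    interval: Interval
    copies: int
    spacer_length: int          # end-to-start distance between adjacent genes
    start_to_start: int         # full repeat-unit period


@dataclass
class ChromosomeTruth:
    chrom: str
    length: int
    telomere_p: Interval | None = None
    telomere_q: Interval | None = None
    telomere_copies_p: int = 0
    telomere_copies_q: int = 0
    centromere: Interval | None = None       # satellite array plus margins
    satellite_array: Interval | None = None  # the array exactly
    satellite_spec: SatelliteSpec | None = None
    rdna_clusters: list[RdnaClusterTruth] = field(default_factory=list)
    te_intervals: list[Interval] = field(default_factory=list)


@dataclass
class TruthAnnotation:
    chromosomes: dict[str, ChromosomeTruth] = field(default_factory=dict)
    monomer: str | None = None
    hor_consensus: str | None = None
    variant_unit_indices: tuple[int, ...] = ()
    probe_5s: str | None = None
    sv_records: list[SVRecord] = field(default_factory=list)
    region_params: dict[str, dict[str, float]] = field(default_factory=dict)
    methylation_means: dict[str, float] = field(default_factory=dict)

    def partition(self) -> RegionPartition:
        """RegionPartition derived from the truth centromere intervals."""
        part = RegionPartition()
        for chrom, t in self.chromosomes.items():
            if t.centromere is not None:
                part.add(partition_chromosome(chrom, t.length, t.centromere))
        return part

    def intervals(self) -> list[Interval]:
        """All truth intervals as BED-ready records."""
        out: list[Interval] = []
        for t in self.chromosomes.values():
            for iv, label in [
                (t.telomere_p, "telomere_p"), (t.telomere_q, "telomere_q"),
                (t.centromere, "centromere"), (t.satellite_array, "satellite_array"),
            ]:
                if iv is not None:
                    out.append(Interval(iv.chrom, iv.start, iv.end, label))
            for cl in t.rdna_clusters:
                out.append(Interval(cl.interval.chrom, cl.interval.start,
                                    cl.interval.end, "5S_cluster"))
            out.extend(t.te_intervals)
        return out


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _build_hor(spec: SatelliteSpec, seed: int) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Monomer consensus, HOR consensus and the variant unit positions.

    Variant units carry fixed substitutions (identical in every HOR copy, and
    distinct between variant units) so the higher-order signal is periodic.
    """
    rng_m = substream(seed, "satellite-monomer")
    monomer = _random_seq(rng_m, spec.monomer_length, gc=0.5)
    rng_v = substream(seed, "satellite-hor-variants")
    units = [monomer.copy() for _ in range(spec.hor_units)]
    # spread variant units across the HOR (indices 1, 3, ... by default)
    step = max(1, spec.hor_units // max(1, spec.variant_units))
    variant_idx = tuple(sorted((1 + step * k) % spec.hor_units
                               for k in range(spec.variant_units)))
    used_positions: set[int] = set()
    for vi in variant_idx:
        for _ in range(spec.variant_subs_per_unit):
            while True:
                pos = int(rng_v.integers(spec.monomer_length))
                if pos not in used_positions:
                    used_positions.add(pos)
                    break
            base = units[vi][pos]
            units[vi][pos] = rng_v.choice(BASE_BYTES[BASE_BYTES != base])
    return monomer, np.concatenate(units), variant_idx


def _place_nonoverlapping(rng: np.random.Generator, lo: int, hi: int, length: int,
                          reserved: list[tuple[int, int]], tries: int = 500) -> int | None:
    """Uniform start in [lo, hi - length] avoiding reserved intervals."""
    if hi - lo < length:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in reserved):
            return start
    return None


def generate_genome(spec: GenomeSpec) -> tuple[list[GenomeRecord], TruthAnnotation]:
    """Generate chromosomes per spec plus an exact truth annotation."""
    truth = TruthAnnotation()
    records: list[GenomeRecord] = []

    sat_specs = [c.satellite for c in spec.chromosomes if c.satellite]
    if sat_specs:
        monomer, hor, variant_idx = _build_hor(sat_specs[0], spec.seed)
        truth.monomer = decode_seq(monomer)
        truth.hor_consensus = decode_seq(hor)
        truth.variant_unit_indices = variant_idx

    rdna_specs = [c.rdna for c in spec.chromosomes if c.rdna]
    if rdna_specs:
        rng5 = substream(spec.seed, "5s-unit")
        unit_5s = _random_seq(rng5, rdna_specs[0].unit_length, gc=0.52)
        spacer_5s = _random_seq(substream(spec.seed, "5s-spacer"),
                                rdna_specs[0].spacer_length, gc=0.45)
        truth.probe_5s = decode_seq(unit_5s)

    te_templates: dict[str, np.ndarray] = {}
    for c in spec.chromosomes:
        if c.te:
            for fam in c.te.families:
                if fam.label not in te_templates:
                    te_templates[fam.label] = _random_seq(
                        substream(spec.seed, f"te-template:{fam.label}"),
                        fam.element_length, gc=0.45)

    for cspec in spec.chromosomes:
        L = cspec.length
        ct = ChromosomeTruth(cspec.name, L)
        feature_total = (6 * (cspec.telomere_copies_p + cspec.telomere_copies_q)
                         + (cspec.satellite.array_length if cspec.satellite else 0)
                         + (cspec.rdna.cluster_length if cspec.rdna else 0))
        if feature_total > L:
            raise ValueError(
                f"{cspec.name}: implanted features ({feature_total} bp) exceed "
                f"chromosome length ({L} bp)")

        arr = _random_seq(substream(spec.seed, f"background:{cspec.name}"), L, spec.gc)
        reserved: list[tuple[int, int]] = []

        # --- telomeres ---------------------------------------------------
        if cspec.telomere_copies_p > 0:
            p_len = 6 * cspec.telomere_copies_p
            arr[:p_len] = np.tile(encode_seq(TELOMERE_P), cspec.telomere_copies_p)
            ct.telomere_p = Interval(cspec.name, 0, p_len, "telomere_p")
            reserved.append((0, p_len))
        if cspec.telomere_copies_q > 0:
            q_len = 6 * cspec.telomere_copies_q
            arr[L - q_len:] = np.tile(encode_seq(TELOMERE_Q), cspec.telomere_copies_q)
            ct.telomere_q = Interval(cspec.name, L - q_len, L, "telomere_q")
            reserved.append((L - q_len, L))
        ct.telomere_copies_p = cspec.telomere_copies_p
        ct.telomere_copies_q = cspec.telomere_copies_q

        # --- centromeric satellite array ---------------------------------
        cen_zone: tuple[int, int] | None = None
        if cspec.satellite:
            sat = cspec.satellite
            center = int(L * cspec.centromere_position_fraction)
            a_start = max(0, center - sat.array_length // 2)
            a_end = a_start + sat.array_length
            if a_end > L:
                raise ValueError(f"{cspec.name}: satellite array overflows chromosome")
            array_seq = np.tile(hor, sat.array_copies)
            array_seq = _mutate(substream(spec.seed, f"satellite-mut:{cspec.name}"),
                                array_seq, sat.per_copy_mutation_rate)
            arr[a_start:a_end] = array_seq
            reserved.append((a_start, a_end))
            ct.satellite_array = Interval(cspec.name, a_start, a_end, "satellite_array")
            ct.satellite_spec = sat
            cen_lo = max(0, a_start - spec.centromere_margin)
            cen_hi = min(L, a_end + spec.centromere_margin)
            ct.centromere = Interval(cspec.name, cen_lo, cen_hi, "centromere")
            cen_zone = (a_start, a_end)

        # --- 5S rDNA cluster on the short arm ----------------------------
        if cspec.rdna:
            rd = cspec.rdna
            pieces = []
            for k in range(rd.copies):
                pieces.append(unit_5s)
                if k < rd.copies - 1:
                    pieces.append(spacer_5s)
            cluster = np.concatenate(pieces)
            # short arm is the smaller flank of the centromere
            if ct.centromere is not None:
                if ct.centromere.start <= L - ct.centromere.end:
                    arm_lo, arm_hi = 0, ct.centromere.start
                else:
                    arm_lo, arm_hi = ct.centromere.end, L
            else:
                arm_lo, arm_hi = 0, L
            rng_r = substream(spec.seed, f"rdna:{cspec.name}")
            start = _place_nonoverlapping(rng_r, arm_lo + 500, arm_hi - 500,
                                          len(cluster), reserved)
            if start is None:
                raise ValueError(f"{cspec.name}: no room for the 5S cluster on the short arm")
            arr[start:start + len(cluster)] = cluster
            reserved.append((start, start + len(cluster)))
            ct.rdna_clusters.append(RdnaClusterTruth(
                Interval(cspec.name, start, start + len(cluster), "5S_cluster"),
                rd.copies, rd.spacer_length, rd.unit_length + rd.spacer_length))
            if rd.linked_te_family:
                tmpl = te_templates.get(rd.linked_te_family)
                if tmpl is None:
                    tmpl = _random_seq(substream(spec.seed, f"te-template:{rd.linked_te_family}"),
                                       150, gc=0.45)
                gap = int(rng_r.integers(200, 1500))
                te_start = start + len(cluster) + gap
                if te_start + len(tmpl) <= arm_hi:
                    arr[te_start:te_start + len(tmpl)] = tmpl
                    reserved.append((te_start, te_start + len(tmpl)))
                    ct.te_intervals.append(Interval(cspec.name, te_start,
                                                    te_start + len(tmpl),
                                                    rd.linked_te_family))

        # --- interspersed TEs --------------------------------------------
        if cspec.te:
            rng_t = substream(spec.seed, f"te-place:{cspec.name}")
            for fam in cspec.te.families:
                tmpl = te_templates[fam.label]
                n_cen = round(fam.genome_copies * fam.centromere_fraction)
                n_arm = fam.genome_copies - n_cen
                placed_cen = 0
                if n_cen and ct.centromere is not None and cen_zone is not None:
                    # pericentromeric margins flank the satellite array so TE
                    # copies are centromeric without interrupting the array
                    margins = [(lo, hi) for lo, hi in
                               [(ct.centromere.start, cen_zone[0]),
                                (cen_zone[1], ct.centromere.end)]
                               if hi - lo >= fam.element_length]
                    for _ in range(n_cen):
                        lo, hi = margins[int(rng_t.integers(len(margins)))] if margins else (0, 0)
                        start = _place_nonoverlapping(rng_t, lo, hi,
                                                      fam.element_length, reserved)
                        if start is None:
                            continue
                        arr[start:start + fam.element_length] = tmpl
                        reserved.append((start, start + fam.element_length))
                        ct.te_intervals.append(Interval(cspec.name, start,
                                                        start + fam.element_length,
                                                        fam.label))
                        placed_cen += 1
                for _ in range(n_arm):
                    for _attempt in range(50):
                        start = _place_nonoverlapping(rng_t, 0, L,
                                                      fam.element_length, reserved,
                                                      tries=50)
                        if start is None:
                            break
                        mid = start + fam.element_length / 2
                        if ct.centromere is not None and \
                                ct.centromere.start <= mid < ct.centromere.end:
                            continue  # arm copy landed pericentromeric; resample
                        arr[start:start + fam.element_length] = tmpl
                        reserved.append((start, start + fam.element_length))
                        ct.te_intervals.append(Interval(cspec.name, start,
                                                        start + fam.element_length,
                                                        fam.label))
                        break

        records.append(GenomeRecord(cspec.name, decode_seq(arr)))
        truth.chromosomes[cspec.name] = ct

    return records, truth


# ---------------------------------------------------------------------------
# Cohort generation (Balding-Nichols differentiation model)
# ---------------------------------------------------------------------------

@dataclass
class RegionCohortParams:
    theta: float        # expected per-site heterozygosity of the ancestral pool
    fst: float          # Balding-Nichols F (expected Weir-Cockerham FST)
    n_sites: int | None = None   # None: region span times the cohort site_density

    def __post_init__(self):
        if not 0 <= self.fst < 1:
            raise ValueError("target fst must be in [0, 1)")
        if not 0 < self.theta <= 0.375:
            raise ValueError("theta must be in (0, 0.375] (uniform-MAF model bound)")


@dataclass
class CohortSpec:
    """Two-population cohort with region-dependent diversity/differentiation.

    Defaults mirror the study design: 20 + 21 diploids, differentiation
    highest in the centromere (F = 0.33), then the short arm (0.19), then the
    long arm (0.13), and diversity lowest in the centromere.
    """

    n_pop_a: int = 20
    n_pop_b: int = 21
    regions: dict[str, RegionCohortParams] = field(default_factory=lambda: {
        "short_arm": RegionCohortParams(theta=0.22, fst=0.19),
        "centromere": RegionCohortParams(theta=0.08, fst=0.33),
        "long_arm": RegionCohortParams(theta=0.30, fst=0.13),
    })
    pop_labels: tuple[str, str] = ("popA", "popB")
    site_density: float = 0.01   # variant sites per bp when n_sites is derived
    seed: int = 0


@dataclass
class CohortTruth:
    site_regions: np.ndarray          # region label per site
    region_params: dict[str, RegionCohortParams]
    spec: CohortSpec


def _maf_upper(theta: float) -> float:
    """m with E[2q(1-q)] = theta for q ~ Uniform(0, m): m - (2/3) m^2 = theta."""
    return 0.75 * (1.0 - np.sqrt(1.0 - 8.0 * theta / 3.0))


def generate_cohort(partition: RegionPartition,
                    spec: CohortSpec) -> tuple["GenotypeMatrix", CohortTruth]:
    """Draw two-population diploid genotypes under a Balding-Nichols model.

    Per site: an ancestral minor-allele frequency is drawn uniformly on
    (0, m(theta)); each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F)
    around it (a point mass at p when F = 0); diploid genotypes are
    Binomial(2, p_pop). Sites carry their region label in the truth.
    """
    from .io_formats import GenotypeMatrix

    rng = substream(spec.seed, "cohort")
    samples_a = [f"{spec.pop_labels[0]}_{i:02d}" for i in range(spec.n_pop_a)]
    samples_b = [f"{spec.pop_labels[1]}_{i:02d}" for i in range(spec.n_pop_b)]

    chroms_l, pos_l, geno_l, region_l = [], [], [], []
    for region, params in spec.regions.items():
        spans = []
        for chrom, cp in partition.chroms.items():
            iv = getattr(cp, region)
            if iv is not None:
                spans.append((chrom, iv.start, iv.end))
        if not spans:
            continue
        total_span = sum(e - s for _, s, e in spans)
        n_region = (params.n_sites if params.n_sites is not None
                    else round(spec.site_density * total_span))
        if n_region == 0:
            continue
        alloc = [round(n_region * (e - s) / total_span) for _, s, e in spans]
        alloc[-1] = n_region - sum(alloc[:-1])
        m = _maf_upper(params.theta)
        for (chrom, s, e), n in zip(spans, alloc):
            if n <= 0:
                continue
            n = min(n, e - s)
            pos0 = np.sort(rng.choice(np.arange(s, e), size=n, replace=False))
            p_anc = rng.uniform(0.0, m, size=n)
            if params.fst > 0:
                F = params.fst
                shape = (1 - F) / F
                pa = rng.beta(np.maximum(p_anc * shape, 1e-9),
                              np.maximum((1 - p_anc) * shape, 1e-9))
                pb = rng.beta(np.maximum(p_anc * shape, 1e-9),
                              np.maximum((1 - p_anc) * shape, 1e-9))
            else:
                pa = pb = p_anc
            ga = rng.binomial(2, pa[:, None], size=(n, spec.n_pop_a))
            gb = rng.binomial(2, pb[:, None], size=(n, spec.n_pop_b))
            chroms_l.append(np.full(n, chrom, dtype=object))
            pos_l.append(pos0 + 1)  # 1-based VCF positions
            geno_l.append(np.concatenate([ga, gb], axis=1).astype(np.int8))
            region_l.append(np.full(n, region, dtype=object))

    if chroms_l:
        chrom_arr = np.concatenate(chroms_l)
        pos_arr = np.concatenate(pos_l)
        geno = np.concatenate(geno_l, axis=0)
        regions_arr = np.concatenate(region_l)
        order = np.lexsort((pos_arr, chrom_arr.astype(str)))
        chrom_arr, pos_arr = chrom_arr[order], pos_arr[order]
        geno, regions_arr = geno[order], regions_arr[order]
    else:
        chrom_arr = np.array([], dtype=object)
        pos_arr = np.array([], dtype=int)
        geno = np.empty((0, spec.n_pop_a + spec.n_pop_b), dtype=np.int8)
        regions_arr = np.array([], dtype=object)

    n_sites = len(pos_arr)
    gm = GenotypeMatrix(
        chrom_arr, pos_arr,
        np.full(n_sites, "A", dtype=object), np.full(n_sites, "G", dtype=object),
        samples_a + samples_b,
        {spec.pop_labels[0]: samples_a, spec.pop_labels[1]: samples_b},
        geno,
    )
    return gm, CohortTruth(regions_arr, dict(spec.regions), spec)


# ---------------------------------------------------------------------------
# Methylation tables
# ---------------------------------------------------------------------------

def generate_methylation(partition: RegionPartition, base_mean: float = 0.6,
                         centromere_delta: float = 0.15, n_sites: int = 2000,
                         seed: int = 0, sd: float = 0.1) -> tuple[pd.DataFrame, dict]:
    """Per-site methylation frequencies, elevated inside the centromere.

    Frequencies are Normal(mean, sd) clipped to [0, 1], with mean
    ``base_mean`` on the arms and ``base_mean + centromere_delta`` in the
    centromere. Site positions are uniform over the partitioned chromosomes.
    """
    if not (0 <= base_mean <= 1 and 0 <= base_mean + centromere_delta <= 1):
        raise ValueError("base_mean and base_mean + centromere_delta must be in [0, 1]")
    rng = substream(seed, "methylation")
    rows = []
    chroms = list(partition.chroms)
    if chroms and n_sites > 0:
        lengths = np.array([partition[c].length for c in chroms], dtype=float)
        probs = lengths / lengths.sum()
        counts = rng.multinomial(n_sites, probs)
        for chrom, n in zip(chroms, counts):
            if n == 0:
                continue
            pos = np.sort(rng.choice(partition[chrom].length, size=n, replace=False))
            for p in pos:
                region = partition.region_of(chrom, p)
                mean = base_mean + (centromere_delta if region == "centromere" else 0.0)
                rows.append((chrom, int(p), float(np.clip(rng.normal(mean, sd), 0, 1))))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "frequency"])
    truth = {"base_mean": base_mean,
             "centromere_mean": base_mean + centromere_delta, "sd": sd}
    return df, truth


# ---------------------------------------------------------------------------
# SV truth sets and noisy multi-caller call sets
# ---------------------------------------------------------------------------

def generate_truth_svs(chrom_lengths: dict[str, int], n_svs: int,
                       pop_a: list[str], pop_b: list[str], seed: int = 0,
                       a_specific_fraction: float = 0.2,
                       size_range: tuple[int, int] = (50, 500),
                       min_separation: int = 5000) -> list[SVRecord]:
    """Random DEL/INS truth records with per-sample genotypes.

    A fraction of records is made population-A specific with a uniform 0|1
    genotype in every A sample (the pattern the consistency filter selects).
    Truth breakpoints are kept at least ``min_separation`` bp apart so that
    distinct events remain distinguishable after caller jitter.
    """
    rng = substream(seed, "sv-truth")
    chroms = list(chrom_lengths)
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    out: list[SVRecord] = []
    for i in range(n_svs):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(size_range[0], size_range[1] + 1))
        pos = None
        for _ in range(200):
            cand = int(rng.integers(1000, chrom_lengths[chrom] - length - 1000))
            if all(abs(cand - p) >= min_separation for p in placed[chrom]):
                pos = cand
                break
        if pos is None:
            raise ValueError("could not place truth SVs with the requested separation")
        placed[chrom].append(pos)
        svtype = "DEL" if rng.random() < 0.5 else "INS"
        genotypes: dict[str, str] = {}
        if rng.random() < a_specific_fraction:
            for s in pop_a:
                genotypes[s] = "0|1"
            for s in pop_b:
                genotypes[s] = "0|0"
        else:
            for s in pop_a + pop_b:
                g = int(rng.integers(0, 3))
                genotypes[s] = ("0/0", "0/1", "1/1")[g]
        out.append(SVRecord(chrom, pos, svtype, length, genotypes=genotypes,
                            source="truth", id=f"truth{i}"))
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


def generate_sv_callsets(truth_svs: list[SVRecord], n_callers: int = 3,
                         pos_jitter_sd: float = 100.0, fn_rate: float = 0.0,
                         genotype_scheme: str = "keep", seed: int = 0,
                         pop_a: list[str] | None = None,
                         pop_b: list[str] | None = None) -> dict[str, list[SVRecord]]:
    """Noisy per-caller call sets over a truth set.

    Each caller reports each truth SV with probability 1 - fn_rate, its
    position perturbed by seeded Gaussian jitter; type and length are
    preserved. ``genotype_scheme='uniform_a'`` overwrites genotypes with a
    uniform 0|1 in population A and 0|0 in population B.
    """
    if pos_jitter_sd < 0:
        raise ValueError("pos_jitter_sd must be non-negative")
    callsets: dict[str, list[SVRecord]] = {}
    for c in range(n_callers):
        label = f"caller{c + 1}"
        rng = substream(seed, f"sv-caller:{label}")
        records: list[SVRecord] = []
        for t in truth_svs:
            if rng.random() < fn_rate:
                continue
            jitter = int(round(rng.normal(0, pos_jitter_sd))) if pos_jitter_sd > 0 else 0
            genotypes = dict(t.genotypes)
            if genotype_scheme == "uniform_a":
                for s in (pop_a or []):
                    genotypes[s] = "0|1"
                for s in (pop_b or []):
                    genotypes[s] = "0|0"
            records.append(SVRecord(t.chrom, max(1, t.pos + jitter), t.svtype,
                                    t.length, genotypes=genotypes, source=label,
                                    id=f"{label}_{t.id}"))
        records.sort(key=lambda r: (r.chrom, r.pos))
        callsets[label] = records
    return callsets
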