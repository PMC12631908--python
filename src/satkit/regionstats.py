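"""Chromosome partitioning into short-arm / centromere / long-arm, and
per-region transposable-element, methylation and gene-content statistics.

The methylation enrichment test follows the classical one-way ANOVA with
Fisher's LSD (least significant difference) pairwise comparisons: pairwise
t statistics use the pooled within-group mean square from the ANOVA and its
error degrees of freedom, with no multiplicity adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import Interval

log = logging.getLogger("satkit")

REGIONS = ("short_arm", "centromere", "long_arm")


@dataclass(frozen=True)
class ChromosomePartition:
    """The three regions tiling one chromosome exactly (no gap, no overlap).

    Degenerate arms (centromere abutting a chromosome end) are represented
    as None and flagged.
    """

    chrom: str
    length: int
    short_arm: Interval | None
    centromere: Interval
    long_arm: Interval | None

    def __post_init__(self):
        ivs = [iv for iv in (self.short_arm, self.centromere, self.long_arm) if iv]
        # arms may be listed in either genomic order; sort before tiling check
        ivs = sorted(ivs, key=lambda iv: iv.start)
        if ivs[0].start != 0 or ivs[-1].end != self.length:
            raise ValueError(f"{self.chrom}: partition does not span the chromosome")
        for a, b in zip(ivs, ivs[1:]):
            if a.end != b.start:
                raise ValueError(f"{self.chrom}: partition has a gap or overlap at {a.end}")

    def region_of(self, position: float) -> str | None:
        """Region label containing a (midpoint) coordinate, else None."""
        for label in REGIONS:
            iv = getattr(self, label)
            if iv is not None and iv.start <= position < iv.end:
                return label
        return None


@dataclass
class RegionPartition:
    """short_arm/centromere/long_arm partitions keyed by chromosome."""

    chroms: dict[str, ChromosomePartition] = field(default_factory=dict)

    def add(self, entry: ChromosomePartition) -> None:
        self.chroms[entry.chrom] = entry

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def __getitem__(self, chrom: str) -> ChromosomePartition:
        return self.chroms[chrom]

    def region_of(self, chrom: str, position: float) -> str | None:
        if chrom not in self.chroms:
            return None
        return self.chroms[chrom].region_of(position)


def partition_chromosome(chrom: str, chrom_length: int,
                         centromere: Interval) -> ChromosomePartition:
    """Partition a chromosome around its centromere call.

    The shorter flank becomes the short arm; an exact tie assigns the p
    (left) flank as short. A centromere abutting an end yields a None arm,
    logged as degenerate.
    """
    left_len = centromere.start
    right_len = chrom_length - centromere.end
    left = Interval(chrom, 0, centromere.start, "arm") if left_len > 0 else None
    right = (Interval(chrom, centromere.end, chrom_length, "arm")
             if right_len > 0 else None)
    if left is None or right is None:
        log.warning("%s: centromere abuts a chromosome end; empty arm", chrom)
    if left_len <= right_len:
        short, long_ = left, right
    else:
        short, long_ = right, left
    cen = Interval(chrom, centromere.start, centromere.end, "centromere")
    return ChromosomePartition(chrom, chrom_length, short, cen, long_)


def build_partition(calls: dict[str, "object"], lengths: dict[str, int]) -> RegionPartition:
    """Partition every chromosome with a successful centromere call."""
    part = RegionPartition()
    for chrom, call in calls.items():
        if getattr(call, "called", True) and getattr(call, "interval", None):
            part.add(partition_chromosome(chrom, lengths[chrom], call.interval))
        else:
            log.info("%s: no centromere call; excluded from partition", chrom)
    return part


# ---------------------------------------------------------------------------
# TE content per region
# ---------------------------------------------------------------------------

def te_region_fraction(te_intervals: list[Interval], partition: RegionPartition,
                       family: str) -> dict[str, dict[str, float]]:
    """Per-region copy counts and fractions for one TE family.

    Copies are assigned to the region containing their midpoint; copies on
    chromosomes absent from the partition are ignored. Fractions sum to 1
    over the three regions (all zero when the family has no assigned copy).
    """
    counts = {r: 0 for r in REGIONS}
    for iv in te_intervals:
        if iv.name != family:
            continue
        region = partition.region_of(iv.chrom, iv.midpoint)
        if region is not None:
            counts[region] += 1
    total = sum(counts.values())
    fractions = {r: (counts[r] / total if total else 0.0) for r in REGIONS}
    return {"counts": counts, "fractions": fractions, "total": total}


# ---------------------------------------------------------------------------
# Methylation enrichment
# ---------------------------------------------------------------------------

@dataclass
class AnovaLsdResult:
    region_means: dict[str, float]
    region_counts: dict[str, int]
    chromosome_mean: float            # all regions pooled (centromere included)
    arms_mean: float | None           # arms-only baseline
    f_statistic: float
    anova_p: float
    lsd_p: dict[tuple[str, str], float]
    lsd_t: dict[tuple[str, str], float]
    mse: float
    df_error: int
    defined: bool = True


def anova_lsd(groups: dict[str, np.ndarray]) -> AnovaLsdResult:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    LSD t for groups i, j: (mean_i - mean_j) / sqrt(MSE (1/n_i + 1/n_j)),
    referred to a t distribution on N - k degrees of freedom (two-sided),
    unadjusted for multiplicity.
    """
    labels = [k for k, v in groups.items() if len(v) >= 2]
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    means = {k: float(np.mean(a)) for k, a in zip(labels, arrays)}
    counts = {k: len(a) for k, a in zip(labels, arrays)}
    pooled = np.concatenate(arrays) if arrays else np.array([])
    chrom_mean = float(np.mean(pooled)) if len(pooled) else float("nan")

    if len(labels) < 2:
        return AnovaLsdResult(means, counts, chrom_mean, None, float("nan"),
                              float("nan"), {}, {}, float("nan"), 0, defined=False)

    f_stat, p = stats.f_oneway(*arrays)
    n_total = sum(counts.values())
    k = len(labels)
    mse = sum((len(a) - 1) * np.var(a, ddof=1) for a in arrays) / (n_total - k)
    df_err = n_total - k

    lsd_p: dict[tuple[str, str], float] = {}
    lsd_t: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            se = np.sqrt(mse * (1 / counts[a] + 1 / counts[b]))
            t = (means[a] - means[b]) / se if se > 0 else float("inf")
            lsd_t[(a, b)] = float(t)
            lsd_p[(a, b)] = float(2 * stats.t.sf(abs(t), df_err))
    return AnovaLsdResult(means, counts, chrom_mean, None, float(f_stat),
                          float(p), lsd_p, lsd_t, float(mse), df_err)


def methylation_enrichment(meth, partition: RegionPartition) -> AnovaLsdResult:
    """Test centromeric methylation enrichment across the three regions.

    ``meth`` is a DataFrame with columns chrom, pos (0-based), frequency.
    Returns region means, the whole-chromosome mean (centromere included),
    the arms-only mean, and ANOVA + LSD p-values. Regions with fewer than
    two sites are dropped; with fewer than two populated regions the test
    is flagged undefined.
    """
    groups: dict[str, list[float]] = {r: [] for r in REGIONS}
    for chrom, pos, freq in zip(meth["chrom"], meth["pos"], meth["frequency"]):
        region = partition.region_of(chrom, pos)
        if region is not None:
            groups[region].append(float(freq))
    arrays = {r: np.asarray(v) for r, v in groups.items() if len(v) >= 2}
    result = anova_lsd(arrays)
    arm_vals = np.concatenate([arrays[r] for r in ("short_arm", "long_arm") if r in arrays]) \
        if any(r in arrays for r in ("short_arm", "long_arm")) else np.array([])
    result.arms_mean = float(np.mean(arm_vals)) if len(arm_vals) else None
    return result


# ---------------------------------------------------------------------------
# Gene content per region
# ---------------------------------------------------------------------------

def gene_region_counts(genes: list[Interval], expression: dict[str, float],
                       partition: RegionPartition,
                       active_min: float = 1.0) -> dict[str, dict[str, int]]:
    """Total and transcriptionally active gene counts per region.

    Genes are assigned by midpoint; genes absent from the expression table
    count as abundance 0. Duplicate gene ids are rejected.
    """
    seen: set[str] = set()
    out = {r: {"total": 0, "active": 0} for r in REGIONS}
    for g in genes:
        if g.name in seen:
            raise ValueError(f"duplicate gene id: {g.name}")
        seen.add(g.name)
        region = partition.region_of(g.chrom, g.midpoint)
        if region is None:
            continue
        out[region]["total"] += 1
        if expression.get(g.name, 0.0) >= active_min:
            out[region]["active"] += 1
    return out
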