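"""Site QC and windowed population-genetic statistics.

Per-site filters follow the common resequencing QC recipe: missingness
< 0.2, minor allele frequency >= 0.05, and an exact Hardy-Weinberg test
p >= 1e-5 on pooled genotype counts. Windowed statistics follow the
VCFtools conventions: nucleotide diversity is per-site unbiased expected
heterozygosity summed over the window and divided by the window span;
Tajima's D uses the 1989 coefficients at the window's haplotype count;
between-population differentiation is the Weir-Cockerham (1984) weighted
(ratio-of-sums) FST over the window's per-site variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_formats import GenotypeMatrix, Interval
from .regionstats import REGIONS, RegionPartition


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value on diploid genotype counts.

    Sums the probabilities of all heterozygote configurations (same rare
    allele count and parity) no more likely than the observed one,
    conditional on the allele counts.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    if rare == 0:
        return 1.0
    # log probability of k hets given rare allele count under HWE
    lf = [math.lgamma(i + 1) for i in range(2 * n + 1)]

    def logprob(k: int) -> float:
        hom_rare = (rare - k) // 2
        hom_common = n - k - hom_rare
        common = 2 * n - rare
        return (k * math.log(2) + lf[n] - lf[k] - lf[hom_rare] - lf[hom_common]
                + lf[rare] + lf[common] - lf[2 * n])

    ks = range(rare % 2, rare + 1, 2)
    ks = [k for k in ks if (rare - k) // 2 + k <= n]
    logs = {k: logprob(k) for k in ks}
    mx = max(logs.values())
    probs = {k: math.exp(v - mx) for k, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)) / total)


@dataclass
class FilterTally:
    missing: int = 0
    maf: int = 0
    hwe: int = 0
    kept: int = 0


def filter_sites(gm: GenotypeMatrix, maf_min: float = 0.05,
                 max_missing: float = 0.2,
                 hwe_p_min: float = 1e-5) -> tuple[GenotypeMatrix, FilterTally]:
    """Apply the missingness / MAF / exact-HWE site filters.

    A site is kept when its missing fraction is below ``max_missing``, its
    minor allele frequency (over non-missing alleles) is at least
    ``maf_min``, and the exact HWE p-value on genotype counts pooled across
    all samples is at least ``hwe_p_min``. Reasons are tallied in filter
    order (a site excluded for missingness is not also counted under MAF).
    """
    tally = FilterTally()
    keep = np.zeros(gm.n_sites, dtype=bool)
    for i in range(gm.n_sites):
        g = gm.geno[i]
        called = g >= 0
        n = int(called.sum())
        if gm.n_samples and (gm.n_samples - n) / gm.n_samples >= max_missing:
            tally.missing += 1
            continue
        if n == 0:
            tally.missing += 1
            continue
        alt = int(g[called].sum())
        maf = min(alt, 2 * n - alt) / (2 * n)
        if maf < maf_min:
            tally.maf += 1
            continue
        n_het = int((g[called] == 1).sum())
        n_ref = int((g[called] == 0).sum())
        n_alt = int((g[called] == 2).sum())
        if hwe_exact_p(n_het, n_ref, n_alt) < hwe_p_min:
            tally.hwe += 1
            continue
        keep[i] = True
    tally.kept = int(keep.sum())
    return gm.take_sites(keep), tally


# ---------------------------------------------------------------------------
# Tajima coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaCoefficients:
    """Tajima (1989) normalization constants for n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaCoefficients":
        if n < 4:
            raise ValueError("Tajima's D requires at least 4 haplotypes")
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1 = c1 / a1
        e2 = c2 / (a1 ** 2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


# ---------------------------------------------------------------------------
# Per-site building blocks
# ---------------------------------------------------------------------------

def _site_counts(g: np.ndarray) -> tuple[int, int, int]:
    """(non-missing diploids, alt allele count, het count) for one pop/site."""
    called = g >= 0
    n = int(called.sum())
    alt = int(g[called].sum())
    het = int((g[called] == 1).sum())
    return n, alt, het


def site_pi(g: np.ndarray) -> float:
    """Unbiased per-site expected heterozygosity, 2n/(2n-1) * 2 p (1-p)."""
    n, alt, _ = _site_counts(g)
    if n < 1 or 2 * n < 2:
        return 0.0
    p = alt / (2 * n)
    return (2 * n) / (2 * n - 1) * 2 * p * (1 - p)


def wc_fst_components(g_a: np.ndarray, g_b: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) per-site variance components (a, b, c).

    Two populations, diploid data, using observed heterozygote frequencies.
    Returns (0, 0, 0) when either population has no called genotype.
    """
    n1, alt1, het1 = _site_counts(g_a)
    n2, alt2, het2 = _site_counts(g_b)
    if n1 == 0 or n2 == 0:
        return 0.0, 0.0, 0.0
    r = 2
    p1, p2 = alt1 / (2 * n1), alt2 / (2 * n2)
    h1, h2 = het1 / n1, het2 / n2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a), float(b), float(c)


def weighted_fst(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Weir-Cockerham weighted (ratio-of-sums) FST over a site block.

    ``g_a``/``g_b`` are (n_sites, n_samples) dosage matrices. NaN when the
    summed denominator is zero. Negative estimates are retained.
    """
    num = den = 0.0
    for i in range(g_a.shape[0]):
        a, b, c = wc_fst_components(g_a[i], g_b[i])
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

@dataclass
class PopWindowStat:
    n_sites: int
    s: int
    pi: float
    tajima_d: float | None


@dataclass
class WindowStat:
    interval: Interval
    n_sites: int
    pops: dict[str, PopWindowStat]
    fst: float                      # NaN when undefined


def tajima_d_from_window(pi_sum: float, s: int, n_hap: int) -> float | None:
    """Tajima's D from summed pairwise diversity, S, and haplotype count."""
    if s == 0 or n_hap < 4:
        return None
    c = TajimaCoefficients.for_n(n_hap)
    var = c.e1 * s + c.e2 * s * (s - 1)
    if var <= 0:
        return None
    return (pi_sum - s / c.a1) / math.sqrt(var)


def window_stats(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                 window: int = 10_000,
                 chrom_lengths: dict[str, int] | None = None,
                 min_hap_for_d: int = 4) -> list[WindowStat]:
    """Per-window pi, S, Tajima's D (per population) and WC FST.

    Windows tile each chromosome in non-overlapping ``window``-bp blocks.
    Windows with zero genotyped sites are retained with undefined statistics.
    Tajima's D uses sites with at least ``min_hap_for_d`` non-missing
    haplotypes in the population and the median haplotype count over them.
    """
    idx_a = gm.sample_indices(pop_a)
    idx_b = gm.sample_indices(pop_b)
    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom in set(gm.chrom.tolist()):
            sel = gm.chrom == chrom
            chrom_lengths[str(chrom)] = int(gm.pos[sel].max()) if sel.any() else window

    out: list[WindowStat] = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        sel = np.flatnonzero(gm.chrom == chrom)
        pos0 = gm.pos[sel] - 1
        for w_start in range(0, L, window):
            w_end = min(w_start + window, L)
            span = w_end - w_start
            in_w = sel[(pos0 >= w_start) & (pos0 < w_end)]
            pops: dict[str, PopWindowStat] = {}
            for label, idx in ((pop_a, idx_a), (pop_b, idx_b)):
                pi_sum = 0.0
                s = 0
                haps = []
                for i in in_w:
                    g = gm.geno[i][idx]
                    n, alt, _ = _site_counts(g)
                    if n == 0:
                        continue
                    pi_sum += site_pi(g)
                    if 0 < alt < 2 * n:
                        s += 1
                    if 2 * n >= min_hap_for_d:
                        haps.append(2 * n)
                d = None
                if haps:
                    # D over sites with enough haplotypes, at their median n
                    pi_d = 0.0
                    s_d = 0
                    n_hap = int(np.median(haps))
                    for i in in_w:
                        g = gm.geno[i][idx]
                        n, alt, _ = _site_counts(g)
                        if 2 * n >= min_hap_for_d:
                            pi_d += site_pi(g)
                            if 0 < alt < 2 * n:
                                s_d += 1
                    d = tajima_d_from_window(pi_d, s_d, n_hap)
                pops[label] = PopWindowStat(len(in_w), s, pi_sum / span, d)
            fst = weighted_fst(gm.geno[in_w][:, idx_a], gm.geno[in_w][:, idx_b]) \
                if len(in_w) else float("nan")
            out.append(WindowStat(Interval(chrom, w_start, w_end, "window"),
                                  len(in_w), pops, fst))
    return out


# ---------------------------------------------------------------------------
# Region stratification
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    region: str
    statistic: str
    mean: float | None
    sd: float | None
    count: int


def stratify_regions(stats: list[WindowStat],
                     partition: RegionPartition) -> list[RegionSummary]:
    """Mean +/- SD (n-1 denominator) per region for every statistic.

    Windows are assigned by midpoint; undefined values (NaN FST, undefined
    Tajima's D) are excluded from that statistic's mean but the window still
    counts for the others.
    """
    values: dict[tuple[str, str], list[float]] = {}
    pops: set[str] = set()
    for ws in stats:
        pops.update(ws.pops)
    stat_names = ["fst"] + [f"{s}:{p}" for p in sorted(pops) for s in ("pi", "tajima_d")]

    for ws in stats:
        region = partition.region_of(ws.interval.chrom, ws.interval.midpoint)
        if region is None:
            continue
        if not math.isnan(ws.fst):
            values.setdefault((region, "fst"), []).append(ws.fst)
        for pop, ps in ws.pops.items():
            values.setdefault((region, f"pi:{pop}"), []).append(ps.pi)
            if ps.tajima_d is not None:
                values.setdefault((region, f"tajima_d:{pop}"), []).append(ps.tajima_d)

    out: list[RegionSummary] = []
    for region in REGIONS:
        for stat in stat_names:
            vals = values.get((region, stat), [])
            if vals:
                mean = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                out.append(RegionSummary(region, stat, mean, sd, len(vals)))
            else:
                out.append(RegionSummary(region, stat, None, None, 0))
    return out
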