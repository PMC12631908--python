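"""5S rDNA tandem-cluster detection, spacer estimation, and TE co-localization.

Clusters are chains of probe matches; the inter-copy spacer is the modal
end-to-start distance between adjacent gene copies (equivalently, the modal
start-to-start distance minus the probe length), with the mode chosen over
the mean for robustness to occasionally deleted copies. Co-localization with
a TE family is assessed by a permutation test that uniformly re-places each
cluster on its own chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeRecord, Interval
from .satellite import SatelliteMonomer, quantify_copies


@dataclass
class RdnaCluster:
    interval: Interval
    copy_count: int
    modal_spacer: int | None      # None for single-copy clusters
    spacer_sd: float | None
    spacers: list[int] = field(default_factory=list)
    arm: str | None = None


def locate_5s_clusters(genome: list[GenomeRecord], probe: str,
                       min_identity: float = 0.9, max_gap: int = 5000,
                       partition=None) -> list[RdnaCluster]:
    """Locate tandem 5S clusters by genome-wide probe matching.

    The probe is matched with the same tiled identity scanner used for
    satellite quantification; hits whose start-to-start gap is at most
    ``max_gap`` chain into one cluster. The modal spacer is the mode of
    (next start - previous start - probe length) within the cluster.
    """
    if len(probe) < 50:
        raise ValueError("probe must be at least 50 bp")
    plen = len(probe)
    pseudo = SatelliteMonomer(probe, plen, 0, 1.0)
    hits = quantify_copies(genome, pseudo, min_identity=min_identity)

    clusters: list[RdnaCluster] = []
    for chrom, h in hits.items():
        if h.count == 0:
            continue
        starts = np.sort(h.starts)
        chains: list[list[int]] = [[int(starts[0])]]
        for s in starts[1:]:
            if s - chains[-1][-1] <= max_gap + plen:
                chains[-1].append(int(s))
            else:
                chains.append([int(s)])
        for chain in chains:
            spacers = [b - a - plen for a, b in zip(chain, chain[1:])]
            modal = None
            sd = None
            if spacers:
                modal = Counter(spacers).most_common(1)[0][0]
                sd = float(np.std(spacers, ddof=1)) if len(spacers) > 1 else 0.0
            iv = Interval(chrom, chain[0], chain[-1] + plen, "5S_cluster")
            arm = None
            if partition is not None:
                region = partition.region_of(chrom, iv.midpoint)
                arm = {"short_arm": "short", "long_arm": "long"}.get(region, region)
            clusters.append(RdnaCluster(iv, len(chain), modal, sd, spacers, arm))
    return clusters


# ---------------------------------------------------------------------------
# Co-localization permutation test
# ---------------------------------------------------------------------------

@dataclass
class ColocalizationResult:
    observed_fraction: float
    p_value: float
    n_perm: int
    defined: bool = True


def te_colocalization(clusters: list[RdnaCluster], te_intervals: list[Interval],
                      family: str, chrom_lengths: dict[str, int],
                      flank: int = 10_000, n_perm: int = 1000,
                      seed: int = 0) -> ColocalizationResult:
    """Permutation test for cluster/TE-family co-localization.

    Statistic: fraction of clusters with at least one family member within
    ``flank`` bp. Null: each cluster is re-placed uniformly on its own
    chromosome ``n_perm`` times; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if not clusters:
        return ColocalizationResult(float("nan"), float("nan"), n_perm, defined=False)
    rng = np.random.default_rng(seed)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c.interval.chrom for c in clusters}:
        fam = sorted(
            (iv for iv in te_intervals if iv.chrom == chrom and iv.name == family),
            key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in fam], dtype=float)
        ends = np.array([iv.end for iv in fam], dtype=float)
        running_max_end = np.maximum.accumulate(ends) if len(ends) else ends
        by_chrom[chrom] = (starts, running_max_end)

    def hit(chrom: str, start: float, length: int) -> bool:
        starts, max_end = by_chrom[chrom]
        if len(starts) == 0:
            return False
        k = int(np.searchsorted(starts, start + length + flank, side="right"))
        return k > 0 and max_end[k - 1] >= start - flank

    observed = float(np.mean([
        hit(c.interval.chrom, c.interval.start, len(c.interval)) for c in clusters
    ]))

    null_hits = np.zeros(n_perm)
    for c in clusters:
        chrom = c.interval.chrom
        L = chrom_lengths[chrom]
        clen = len(c.interval)
        hi = max(1, L - clen)
        rand_starts = rng.integers(0, hi, size=n_perm)
        starts, max_end = by_chrom[chrom]
        if len(starts):
            k = np.searchsorted(starts, rand_starts + clen + flank, side="right")
            ok = (k > 0) & (np.where(k > 0, max_end[np.maximum(k - 1, 0)], -np.inf)
                            >= rand_starts - flank)
            null_hits += ok
    null_frac = null_hits / len(clusters)
    p = (1 + int(np.sum(null_frac >= observed - 1e-12))) / (1 + n_perm)
    return ColocalizationResult(observed, p, n_perm)
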