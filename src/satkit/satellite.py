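"""Centromeric satellite discovery, HOR decomposition, copy quantification,
centromere delineation and chromosome morphology.

Monomer discovery is self-contained: tandem periodicity is detected by k-mer
offset autocorrelation (the fraction of positions matching themselves at lag
p), candidate arrays are localized where the lag-p match signal is dense, and
the consensus is the column-majority vote over consecutive monomer-length
units. Harmonic lags (2p, 3p, ...) of a detected fundamental are folded into
one family and reported at the smallest period whose consensus passes the
identity threshold — the higher-order multiple is the business of
``decompose_hor``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (BASE_BYTES, GenomeRecord, Interval, decode_seq,
                         encode_seq, revcomp)

log = logging.getLogger("satkit")


# ---------------------------------------------------------------------------
# Monomer discovery
# ---------------------------------------------------------------------------

@dataclass
class SatelliteMonomer:
    consensus: str
    length: int
    copy_count: int
    mean_identity: float
    arrays: list[Interval] = field(default_factory=list)
    score: float = 0.0


def _autocorrelation(a: np.ndarray, min_period: int, max_period: int) -> np.ndarray:
    """Match fraction a[i] == a[i+p] for each lag p in [min_period, max_period]."""
    scores = np.zeros(max_period - min_period + 1)
    for k, p in enumerate(range(min_period, max_period + 1)):
        if p >= len(a):
            break
        scores[k] = float(np.mean(a[:-p] == a[p:]))
    return scores


def _consensus_entropy(consensus: np.ndarray) -> float:
    """Shannon entropy (bits) of the consensus base composition."""
    counts = np.array([np.sum(consensus == b) for b in BASE_BYTES], dtype=float)
    freq = counts[counts > 0] / counts.sum()
    return float(-np.sum(freq * np.log2(freq)))


def _localize_array(a: np.ndarray, period: int,
                    min_run: int) -> tuple[int, int] | None:
    """Longest region where the lag-``period`` match signal is dense (>0.6)."""
    match = (a[:-period] == a[period:]).astype(np.float32)
    win = max(3 * period, 64)
    kernel = np.ones(win) / win
    smooth = np.convolve(match, kernel, mode="same")
    dense = smooth > 0.6
    if not dense.any():
        return None
    # longest True run
    edges = np.flatnonzero(np.diff(np.concatenate(([0], dense.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    best = int(np.argmax(lengths))
    s, e = int(starts[best]), int(ends[best]) + period
    if e - s < min_run:
        return None
    return s, min(e, len(a))


def _units_consensus(region: np.ndarray, period: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Chop a region into period-length units; column-majority consensus.

    Ties in the majority vote break alphabetically (A < C < G < T). Returns
    (units matrix, consensus, mean unit identity).
    """
    n = len(region) // period
    units = region[: n * period].reshape(n, period)
    counts = np.stack([(units == b).sum(axis=0) for b in BASE_BYTES])
    consensus = BASE_BYTES[np.argmax(counts, axis=0)]  # argmax -> first max = alphabetical
    ident = float(np.mean(units == consensus[None, :]))
    return units, consensus, ident


def discover_monomer(seqs: list[GenomeRecord], min_period: int = 20,
                     max_period: int = 500, min_copies: int = 50,
                     min_consensus_identity: float = 0.8,
                     min_entropy: float = 1.0,
                     peak_delta: float = 0.02) -> list[SatelliteMonomer]:
    """Rank candidate satellite monomers by total genome copy count.

    Peaks of the k-mer offset autocorrelation above the baseline by
    ``peak_delta`` propose candidate periods; each is localized and given a
    phase-aligned column-majority consensus. Low-complexity consensi
    (entropy < ``min_entropy`` bits) are rejected, harmonic periods of an
    accepted fundamental are folded into it, and candidates below
    ``min_copies`` supporting units are dropped.
    """
    arrays = [encode_seq(r.seq) for r in seqs]
    total_scores = None
    weights = 0
    for a in arrays:
        if len(a) <= max_period:
            continue
        s = _autocorrelation(a, min_period, max_period)
        total_scores = s * len(a) if total_scores is None else total_scores + s * len(a)
        weights += len(a)
    if total_scores is None:
        return []
    scores = total_scores / weights
    baseline = float(np.median(scores))

    periods = np.arange(min_period, max_period + 1)
    elevated = scores > baseline + peak_delta
    peak_periods = [
        int(periods[i]) for i in range(len(periods))
        if elevated[i]
        and (i == 0 or scores[i] >= scores[i - 1])
        and (i == len(periods) - 1 or scores[i] >= scores[i + 1])
    ]

    accepted: list[SatelliteMonomer] = []
    accepted_periods: list[int] = []
    for p in sorted(peak_periods):
        tol = max(1, round(0.02 * p))
        if any(
            abs(p - m * q) <= tol
            for q in accepted_periods
            for m in range(2, p // q + 2)
        ):
            continue  # harmonic of an already-accepted fundamental
        copy_count = 0
        ident_sum = 0.0
        best_consensus = None
        hits: list[Interval] = []
        for rec, a in zip(seqs, arrays):
            if len(a) <= p * 2:
                continue
            loc = _localize_array(a, p, min_run=2 * p)
            if loc is None:
                continue
            s_, e_ = loc
            units, consensus, ident = _units_consensus(a[s_:e_], p)
            if len(units) == 0:
                continue
            if best_consensus is None or len(units) > copy_count:
                best_consensus = consensus
            copy_count += len(units)
            ident_sum += ident * len(units)
            hits.append(Interval(rec.id, s_, e_, f"period{p}"))
        if best_consensus is None or copy_count < min_copies:
            continue
        mean_ident = ident_sum / copy_count
        if mean_ident < min_consensus_identity:
            continue
        if _consensus_entropy(best_consensus) < min_entropy:
            log.info("period %d rejected as low-complexity", p)
            continue
        accepted.append(SatelliteMonomer(decode_seq(best_consensus), p,
                                         copy_count, mean_ident, hits,
                                         score=float(scores[p - min_period])))
        accepted_periods.append(p)

    accepted.sort(key=lambda m: (-m.copy_count, m.length))
    return accepted


# ---------------------------------------------------------------------------
# HOR decomposition
# ---------------------------------------------------------------------------

@dataclass
class HORStructure:
    unit_classes: np.ndarray            # cluster index per unit along the array
    hor_period: int
    hor_consensus_length: int
    variant_unit_indices: tuple[int, ...]
    conforming_fraction: float
    monomer_length: int
    n_units: int
    degenerate: bool = False


def _classify_units(units: np.ndarray, min_variant_freq: float,
                    min_class_fraction: float) -> np.ndarray:
    """Class label per unit from alleles at systematic variant columns.

    Variant columns are columns whose minor-allele frequency across units is
    at least ``min_variant_freq`` — fixed substitutions that distinguish HOR
    unit classes stand far above the random per-copy mutation rate there.
    Units are assigned to the nearest anchor signature (signatures carried by
    at least ``min_class_fraction`` of units), which absorbs sporadic
    mutations hitting a variant column.
    """
    n = len(units)
    counts = np.stack([(units == b).sum(axis=0) for b in BASE_BYTES])
    major = counts.max(axis=0)
    minor_freq = 1.0 - major / n
    var_cols = np.flatnonzero(minor_freq >= min_variant_freq)
    if len(var_cols) == 0:
        return np.zeros(n, dtype=int)

    sigs = units[:, var_cols]
    sig_tuples = [tuple(row) for row in sigs]
    freq = Counter(sig_tuples)
    min_count = max(2, int(np.ceil(min_class_fraction * n)))
    anchors = [np.array(sig) for sig, c in freq.most_common() if c >= min_count]
    if not anchors:
        return np.zeros(n, dtype=int)
    anchor_mat = np.stack(anchors)
    # Hamming distance of each unit signature to each anchor
    dists = (sigs[:, None, :] != anchor_mat[None, :, :]).sum(axis=2)
    return np.argmin(dists, axis=1)


def _class_string_period(classes: np.ndarray, max_period: int,
                         min_explained: float) -> tuple[int, float]:
    """Smallest period whose positional majority explains >= min_explained.

    Falls back to the best-explaining period when none reaches the bar
    (conforming_fraction < min_explained then signals non-periodicity).
    """
    n = len(classes)
    best_k, best_frac = 1, -1.0
    for k in range(1, max_period + 1):
        explained = 0
        for j in range(k):
            col = classes[j::k]
            if len(col):
                explained += int(Counter(col).most_common(1)[0][1])
        frac = explained / n
        if frac >= min_explained:
            return k, frac
        if frac > best_frac:
            best_k, best_frac = k, frac
    return best_k, best_frac


def decompose_hor(array_seq: str, monomer: SatelliteMonomer,
                  max_hor_period: int = 12, min_explained: float = 0.9,
                  min_variant_freq: float = 0.1,
                  min_class_fraction: float = 0.05) -> HORStructure:
    """Decompose a satellite array into its higher-order repeat structure.

    The array is segmented into monomer-length units at the phase that best
    matches the monomer consensus, units are classified by their alleles at
    systematic variant columns, and the unit-class string is tested for
    periods 1..``max_hor_period``. Arrays whose mean unit identity to the
    consensus falls below 70% are flagged degenerate.
    """
    p = monomer.length
    a = encode_seq(array_seq)
    if len(a) < 20 * p:
        raise ValueError("array must contain at least 20 monomer copies")

    # The discovered consensus is defined only up to cyclic rotation, so the
    # segmentation phase cannot be anchored to it. The boundary-aligned phase
    # is the one where units straddle the fewest class boundaries, i.e. the
    # majority unit class is largest; mis-phased cuts split each variant
    # unit's substitutions across two segmented units and dilute the classes.
    best = None  # (majority_share, -offset, units, classes)
    for offset in range(p):
        n = (len(a) - offset) // p
        if n < 20:
            continue
        units = a[offset: offset + n * p].reshape(n, p)
        classes = _classify_units(units, min_variant_freq, min_class_fraction)
        share = Counter(classes).most_common(1)[0][1] / n
        key = (share, -offset)
        if best is None or key > best[0]:
            best = (key, units, classes)
    if best is None:
        raise ValueError("array must contain at least 20 monomer copies")
    _, units, classes = best
    n = len(units)

    _, self_cons, self_ident = _units_consensus(units.reshape(-1), p)
    if self_ident < 0.70:
        log.warning("HOR decomposition degenerate: mean unit identity %.2f", self_ident)
        return HORStructure(np.zeros(n, dtype=int), 1, p, (), 0.0, p, n,
                            degenerate=True)
    k, frac = _class_string_period(classes, max_hor_period, min_explained)

    global_major = Counter(classes).most_common(1)[0][0]
    variant_idx = []
    for j in range(k):
        col = classes[j::k]
        if len(col) and Counter(col).most_common(1)[0][0] != global_major:
            variant_idx.append(j)
    return HORStructure(classes, k, k * p, tuple(variant_idx), frac, p, n)


# ---------------------------------------------------------------------------
# Genome-wide copy quantification
# ---------------------------------------------------------------------------

def _window_identity(a: np.ndarray, motif: np.ndarray) -> np.ndarray:
    """Identity of every monomer-length window to the motif (both handled
    by the caller); matches / motif length, so N counts as mismatch."""
    p = len(motif)
    L = len(a)
    if L < p:
        return np.zeros(0)
    acc = np.zeros(L - p + 1, dtype=np.int32)
    for j in range(p):
        acc += a[j: L - p + 1 + j] == motif[j]
    return acc / p


@dataclass
class CopyHits:
    chrom: str
    starts: np.ndarray          # hit start positions (0-based)
    strands: np.ndarray         # '+' or '-'
    identities: np.ndarray

    @property
    def count(self) -> int:
        return len(self.starts)


def quantify_copies(genome: list[GenomeRecord], monomer: SatelliteMonomer,
                    min_identity: float = 0.96) -> dict[str, CopyHits]:
    """Greedy non-overlapping tiling of monomer matches on both strands.

    A genome position opens a copy when its monomer-length window matches the
    consensus (or its reverse complement) at >= ``min_identity``; the scan
    then jumps one monomer length, so counts are tiled, not overlapping.
    """
    fwd = encode_seq(monomer.consensus)
    rev = encode_seq(revcomp(monomer.consensus))
    p = monomer.length
    out: dict[str, CopyHits] = {}
    for rec in genome:
        a = encode_seq(rec.seq)
        id_f = _window_identity(a, fwd)
        id_r = _window_identity(a, rev)
        if len(id_f) == 0:
            out[rec.id] = CopyHits(rec.id, np.array([], int), np.array([], "U1"),
                                   np.array([]))
            continue
        best = np.maximum(id_f, id_r)
        candidates = np.flatnonzero(best >= min_identity)
        starts, strands, idents = [], [], []
        next_free = 0
        for i in candidates:
            if i < next_free:
                continue
            starts.append(int(i))
            strands.append("+" if id_f[i] >= id_r[i] else "-")
            idents.append(float(best[i]))
            next_free = i + p
        out[rec.id] = CopyHits(rec.id, np.array(starts, int),
                               np.array(strands, dtype="U1"), np.array(idents))
    return out


# ---------------------------------------------------------------------------
# Centromere delineation and morphology
# ---------------------------------------------------------------------------

@dataclass
class CentromereCall:
    chrom: str
    called: bool
    interval: Interval | None = None
    copy_count: int = 0
    density: np.ndarray = field(default_factory=lambda: np.array([], int))
    window: int = 10_000
    short_arm: int = 0
    long_arm: int = 0
    ls_ratio: float = float("nan")
    secondary_blocks: list[Interval] = field(default_factory=list)


def call_centromeres(genome: list[GenomeRecord], hits: dict[str, CopyHits],
                     monomer_length: int, window: int = 10_000,
                     min_window_copies: int | None = None,
                     merge_gap: int = 1) -> dict[str, CentromereCall]:
    """Delineate one centromere per chromosome from satellite copy density.

    Windows whose tiled copies cover at least 20% of the window (the default
    ``min_window_copies``) are satellite-positive; positive windows within
    ``merge_gap`` windows of each other merge into blocks, and the largest
    block is the centromere call. Additional blocks are reported as
    secondary; chromosomes with no positive window are explicitly uncalled.
    """
    if min_window_copies is None:
        min_window_copies = max(1, int(np.ceil(0.2 * window / monomer_length)))
    out: dict[str, CentromereCall] = {}
    for rec in genome:
        L = len(rec.seq)
        n_windows = max(1, -(-L // window))
        h = hits.get(rec.id)
        counts = np.zeros(n_windows, dtype=int)
        if h is not None and h.count:
            idx = np.minimum(h.starts // window, n_windows - 1)
            np.add.at(counts, idx, 1)
        positive = np.flatnonzero(counts >= min_window_copies)
        if len(positive) == 0:
            out[rec.id] = CentromereCall(rec.id, called=False, density=counts,
                                         window=window)
            continue
        # merge near-adjacent positive windows into blocks
        blocks: list[list[int]] = [[positive[0], positive[0]]]
        for w in positive[1:]:
            if w - blocks[-1][1] <= merge_gap + 1:
                blocks[-1][1] = w
            else:
                blocks.append([w, w])

        def block_key(b):
            in_block = (h.starts >= b[0] * window) & (h.starts < (b[1] + 1) * window)
            return ((b[1] - b[0] + 1), int(in_block.sum()))

        blocks.sort(key=block_key, reverse=True)
        main = blocks[0]
        in_main = (h.starts >= main[0] * window) & (h.starts < (main[1] + 1) * window)
        start = int(h.starts[in_main].min())
        end = int(h.starts[in_main].max()) + monomer_length
        iv = Interval(rec.id, start, end, "centromere")
        short = min(start, L - end)
        long_ = max(start, L - end)
        secondary = []
        for b in blocks[1:]:
            in_b = (h.starts >= b[0] * window) & (h.starts < (b[1] + 1) * window)
            if in_b.any():
                secondary.append(Interval(rec.id, int(h.starts[in_b].min()),
                                          int(h.starts[in_b].max()) + monomer_length,
                                          "secondary_satellite_block"))
                log.warning("%s: secondary satellite block at %s", rec.id, secondary[-1])
        out[rec.id] = CentromereCall(
            rec.id, True, iv, int(in_main.sum()), counts, window,
            short, long_, (long_ / short) if short > 0 else float("inf"),
            secondary)
    return out


#: Levan-convention arm-ratio cutoffs (upper bounds per class)
DEFAULT_MORPHOLOGY_CUTOFFS = (
    ("metacentric", 1.7),
    ("submetacentric", 3.0),
    ("subtelocentric", 7.0),
    ("acrocentric", float("inf")),
)


def classify_morphology(call: CentromereCall,
                        cutoffs=DEFAULT_MORPHOLOGY_CUTOFFS) -> str:
    """Morphology class from the long/short arm ratio (Levan convention)."""
    if not call.called:
        raise ValueError(f"{call.chrom}: no centromere call")
    if call.short_arm == 0:
        return "telocentric"
    for label, upper in cutoffs:
        if call.ls_ratio <= upper:
            return label
    return cutoffs[-1][0]
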