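"""Telomere detection, T2T completeness classification, and telomere patching.

A chromosome end is telomere-complete when it carries at least ``min_copies``
tandem copies of the vertebrate telomeric hexamer — TTAGGG on the G-rich q
terminus, CCCTAA on the C-rich p terminus of the forward strand. Copies are
counted as non-overlapping exact hexamer matches in the maximal tandem run
whose outer edge lies within a terminal search window, tolerating a bounded
number of divergent hexamers per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .io_formats import GenomeRecord, Interval, revcomp

log = logging.getLogger("satkit")

DEFAULT_MOTIF = "TTAGGG"


@dataclass
class EndReport:
    copies: int
    run_start: int | None      # 0-based start of the counted run
    run_end: int | None        # half-open end
    motif: str


@dataclass
class TelomereReport:
    chrom: str
    p: EndReport
    q: EndReport
    terminal_window: int


class T2TStatus(Enum):
    COMPLETE = "complete"
    MISSING_P = "missing_p"
    MISSING_Q = "missing_q"
    MISSING_BOTH = "missing_both"


def _best_run(seq: str, motif: str, max_interruptions: int = 1) -> tuple[int, int, int]:
    """Largest tandem run of non-overlapping exact motif copies.

    Runs are chains of matches spaced one motif apart; up to
    ``max_interruptions`` single divergent hexamers may be skipped per run.
    Returns (copies, run_start, run_end); (0, -1, -1) when no match.
    """
    k = len(motif)
    matches = []
    i = 0
    while i <= len(seq) - k:
        if seq[i:i + k] == motif:
            matches.append(i)
            i += k
        else:
            i += 1
    if not matches:
        return 0, -1, -1

    best = (0, -1, -1)
    n = len(matches)
    for si in range(n):
        copies, interruptions = 1, 0
        last = matches[si]
        j = si + 1
        while j < n:
            gap = matches[j] - (last + k)
            if gap == 0:
                copies += 1
                last = matches[j]
            elif gap == k and interruptions < max_interruptions:
                interruptions += 1
                copies += 1
                last = matches[j]
            else:
                break
            j += 1
        if copies > best[0]:
            best = (copies, matches[si], last + k)
    return best


def scan_telomeres(record: GenomeRecord, motif: str = DEFAULT_MOTIF,
                   terminal_window: int = 10_000,
                   max_interruptions: int = 1) -> TelomereReport:
    """Count telomeric hexamer copies at both chromosome ends.

    The q end is scanned for ``motif`` (G-strand class) and the p end for its
    reverse complement; a run only counts if its outer edge falls inside
    ``terminal_window`` of the respective end. Sequences shorter than two
    motifs report zero copies.
    """
    if len(motif) != 6:
        raise ValueError("telomeric motif must be a hexamer")
    seq = record.seq
    window = min(terminal_window, len(seq))
    p_motif = revcomp(motif)

    if len(seq) < 2 * len(motif):
        empty_p = EndReport(0, None, None, p_motif)
        empty_q = EndReport(0, None, None, motif)
        return TelomereReport(record.id, empty_p, empty_q, terminal_window)

    p_seq = seq[:window]
    p_copies, p_start, p_end = _best_run(p_seq, p_motif, max_interruptions)
    p_rep = EndReport(p_copies, p_start if p_copies else None,
                      p_end if p_copies else None, p_motif)

    q_off = len(seq) - window
    q_seq = seq[q_off:]
    q_copies, q_start, q_end = _best_run(q_seq, motif, max_interruptions)
    q_rep = EndReport(q_copies, q_off + q_start if q_copies else None,
                      q_off + q_end if q_copies else None, motif)
    return TelomereReport(record.id, p_rep, q_rep, terminal_window)


def classify_t2t(report: TelomereReport, min_copies: int = 10) -> T2TStatus:
    """T2T completeness: both ends need >= min_copies motif copies."""
    p_ok = report.p.copies >= min_copies
    q_ok = report.q.copies >= min_copies
    if p_ok and q_ok:
        return T2TStatus.COMPLETE
    if not p_ok and not q_ok:
        return T2TStatus.MISSING_BOTH
    return T2TStatus.MISSING_P if not p_ok else T2TStatus.MISSING_Q


# ---------------------------------------------------------------------------
# Patching a missing telomere from a donor contig
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """Alignment anchor pairing a donor interval to a chromosomal interval."""

    chrom_interval: Interval
    donor_interval: Interval
    strand: str = "+"          # donor orientation relative to the chromosome

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("anchor strand must be '+' or '-'")


@dataclass
class PatchProvenance:
    chrom: str
    end: str
    donor_id: str
    anchor: Anchor
    bases_replaced: int
    bases_added: int


class PatchError(ValueError):
    pass


def patch_telomere(chrom: GenomeRecord, donor: GenomeRecord, anchor: Anchor,
                   end: str, motif: str = DEFAULT_MOTIF, min_copies: int = 10,
                   max_anchor_distance: int = 100_000,
                   terminal_window: int = 10_000) -> tuple[GenomeRecord, PatchProvenance]:
    """Replace a telomere-less chromosome end with a donor contig's terminus.

    The chromosome sequence distal to the anchor is replaced by the donor's
    distal sequence, reverse-complemented for '-' anchors. Refused when the
    end is already complete, the anchor sits too far from the target end, or
    the donor carries fewer than ``min_copies`` motif copies distal to its
    anchored interval.
    """
    if end not in ("p", "q"):
        raise ValueError("end must be 'p' or 'q'")
    report = scan_telomeres(chrom, motif, terminal_window)
    existing = report.p.copies if end == "p" else report.q.copies
    if existing >= min_copies:
        raise PatchError(f"{chrom.id} {end}-end already telomere-complete; patch refused")

    ci = anchor.chrom_interval
    dist = ci.start if end == "p" else len(chrom.seq) - ci.end
    if dist > max_anchor_distance:
        raise PatchError(
            f"anchor is {dist} bp from the {end} end (max {max_anchor_distance})")

    di = anchor.donor_interval
    # donor sequence distal to the anchor, oriented as the chromosome strand
    if end == "q":
        distal = donor.seq[di.end:] if anchor.strand == "+" else revcomp(donor.seq[:di.start])
    else:
        distal = donor.seq[:di.start] if anchor.strand == "+" else revcomp(donor.seq[di.end:])

    distal_rec = GenomeRecord("distal", distal)
    distal_scan = scan_telomeres(distal_rec, motif, terminal_window=max(len(distal), 12))
    distal_copies = distal_scan.p.copies if end == "p" else distal_scan.q.copies
    if distal_copies < min_copies:
        raise PatchError(
            f"donor {donor.id} has no distal telomere at the {end} side "
            f"({distal_copies} < {min_copies} copies)")

    if end == "q":
        replaced = len(chrom.seq) - ci.end
        new_seq = chrom.seq[:ci.end] + distal
    else:
        replaced = ci.start
        new_seq = distal + chrom.seq[ci.start:]
    patched = GenomeRecord(chrom.id, new_seq)
    prov = PatchProvenance(chrom.id, end, donor.id, anchor, replaced, len(distal))
    log.info("patched %s %s-end from donor %s (%d bp replaced, %d bp added)",
             chrom.id, end, donor.id, replaced, len(distal))
    return patched, prov
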