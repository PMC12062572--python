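"""Read-level SV signature extraction.

Once the window model has flagged candidate regions, the alignments in
those regions are re-scanned and every read-level observation implying a
structural variant is recorded as an ``SVSignature``: large CIGAR D/I
operations inside one alignment, and junctions between the aligned
segments of a split read (primary + SA-tag supplementaries).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pysam

from .features import read_error_rate, _parse_sa, DEFAULT_MIN_MAPQ
from .model import CandidateRegion

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")

DEFAULT_MIN_SV_CANDIDATE = 30  # bp; final VCF filter applies >= 50 downstream
JUNCTION_SLACK = 100  # read-coordinate gap/overlap ignored when classifying


@dataclass
class SVSignature:
    """One read-level SV observation."""

    svtype: str
    contig: str
    pos: int
    length: int
    read_name: str
    mate_contig: str | None = None
    mate_pos: int | None = None
    read_error_rate: float = 0.0

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype == "BND":
            if self.mate_contig is None or self.mate_pos is None:
                raise ValueError("BND signature requires both ends")
        elif self.length <= 0:
            raise ValueError("non-BND signature requires positive length")

    @property
    def end(self) -> int:
        return self.pos + (self.length if self.svtype in ("DEL", "DUP", "INV") else 0)


@dataclass
class _Segment:
    """One aligned segment of a read, with its read-coordinate span."""

    contig: str
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'
    read_start: int  # position within the original read (forward orientation)
    read_end: int


def _cigar_stats(cigartuples) -> tuple[int, int, int, int]:
    """(leading clip, trailing clip, query aligned length, ref aligned length)."""
    lead = trail = q = r = 0
    ops = list(cigartuples)
    if ops and ops[0][0] in (4, 5):
        lead = ops[0][1]
        ops = ops[1:]
    if ops and ops[-1][0] in (4, 5):
        trail = ops[-1][1]
        ops = ops[:-1]
    for op, length in ops:
        if op in (0, 1, 7, 8):
            q += length
        if op in (0, 2, 3, 7, 8):
            r += length
    return lead, trail, q, r


def _parse_cigar_string(cigar: str) -> list[tuple[int, int]]:
    codes = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((codes[ch], int(num)))
            num = ""
    return out


def signatures_from_cigar(aln: pysam.AlignedSegment,
                          min_sv_candidate: int = DEFAULT_MIN_SV_CANDIDATE,
                          ) -> list[SVSignature]:
    """DEL/INS signatures from large D/I operations of a primary alignment."""
    out: list[SVSignature] = []
    try:
        cig = aln.cigartuples or []
    except ValueError:
        warnings.warn(f"malformed CIGAR on read {aln.query_name}; skipped")
        return out
    err = read_error_rate(aln) or 0.0
    ref = aln.reference_start
    for op, length in cig:
        if op == 2:  # D consumes reference
            if length >= min_sv_candidate:
                out.append(SVSignature("DEL", aln.reference_name, ref, length,
                                       aln.query_name, read_error_rate=err))
            ref += length
        elif op == 1:  # I anchored at current ref position
            if length >= min_sv_candidate:
                out.append(SVSignature("INS", aln.reference_name, ref, length,
                                       aln.query_name, read_error_rate=err))
        elif op in (0, 3, 7, 8):
            ref += length
    return out


def segments_of_read(aln: pysam.AlignedSegment,
                     min_mapq: int = DEFAULT_MIN_MAPQ) -> list[_Segment]:
    """Primary segment plus SA-tag segments, ordered by read coordinate."""
    lead, trail, q, _ = _cigar_stats(aln.cigartuples or [])
    if aln.is_reverse:
        lead, trail = trail, lead
    segs = [_Segment(aln.reference_name, aln.reference_start, aln.reference_end,
                     "-" if aln.is_reverse else "+", lead, lead + q)]
    if aln.has_tag("SA"):
        for rname, spos, strand, cigar, mapq, _nm in _parse_sa(aln.get_tag("SA")):
            if mapq < min_mapq:
                continue
            slead, strail, sq, sr = _cigar_stats(_parse_cigar_string(cigar))
            if strand == "-":
                slead, strail = strail, slead
            segs.append(_Segment(rname, spos, spos + sr, strand, slead, slead + sq))
    segs.sort(key=lambda s: (s.read_start, s.read_end))
    return segs


def signatures_from_splits(segments: list[_Segment], read_name: str,
                           min_sv_candidate: int = DEFAULT_MIN_SV_CANDIDATE,
                           error_rate: float = 0.0) -> list[SVSignature]:
    """Classify adjacent split-alignment segment pairs into SV signatures.

    For each consecutive pair along the read: different contigs give a
    breakend pair; opposite strands an inversion spanning the junctions;
    same-strand backward reference order a tandem duplication of the
    overlapped span; otherwise a reference gap is a deletion and an
    unaligned read gap an insertion.
    """
    out: list[SVSignature] = []
    for s1, s2 in zip(segments, segments[1:]):
        read_gap = s2.read_start - s1.read_end
        if s1.contig != s2.contig:
            j1 = s1.ref_end if s1.strand == "+" else s1.ref_start
            j2 = s2.ref_start if s2.strand == "+" else s2.ref_end
            out.append(SVSignature("BND", s1.contig, j1, 0, read_name,
                                   mate_contig=s2.contig, mate_pos=j2,
                                   read_error_rate=error_rate))
            continue
        if s1.strand != s2.strand:
            j1 = s1.ref_end if s1.strand == "+" else s1.ref_start
            j2 = s2.ref_end if s2.strand == "-" else s2.ref_start
            lo, hi = min(j1, j2), max(j1, j2)
            if hi - lo >= min_sv_candidate:
                out.append(SVSignature("INV", s1.contig, lo, hi - lo, read_name,
                                       read_error_rate=error_rate))
            continue
        # normalize a reverse-strand colinear pair to forward geometry
        a, b = (s1, s2) if s1.strand == "+" else (s2, s1)
        ref_gap = b.ref_start - a.ref_end
        if ref_gap < 0 and -ref_gap >= min_sv_candidate:
            length = a.ref_end - b.ref_start
            out.append(SVSignature("DUP", s1.contig, b.ref_start, length,
                                   read_name, read_error_rate=error_rate))
        elif ref_gap >= min_sv_candidate and ref_gap >= read_gap + JUNCTION_SLACK:
            out.append(SVSignature("DEL", s1.contig, a.ref_end, ref_gap,
                                   read_name, read_error_rate=error_rate))
        elif read_gap >= min_sv_candidate and read_gap > max(ref_gap, 0):
            ins_len = read_gap - max(ref_gap, 0)
            if ins_len >= min_sv_candidate:
                out.append(SVSignature("INS", s1.contig, a.ref_end, ins_len,
                                       read_name, read_error_rate=error_rate))
    return out


def extract_signatures(
    alignment_source,
    region: CandidateRegion,
    min_sv_candidate: int = DEFAULT_MIN_SV_CANDIDATE,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    flank: int = 1000,
) -> list[SVSignature]:
    """All signatures whose breakpoints fall in ``region`` +/- ``flank``.

    Split-read junctions are derived from each primary alignment's SA tag,
    so supplementary records themselves are skipped (their evidence is
    already represented); this also keeps each junction counted once per
    read.  Results are sorted for order-invariance.
    """
    bam = (alignment_source if isinstance(alignment_source, pysam.AlignmentFile)
           else pysam.AlignmentFile(alignment_source))
    lo = max(0, region.start - flank)
    hi = region.end + flank
    sample_rates: list[float] = []
    out: list[SVSignature] = []
    for aln in bam.fetch(region.contig, lo, hi):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        err = read_error_rate(aln)
        if err is not None:
            sample_rates.append(err)
        err = err or 0.0
        out.extend(signatures_from_cigar(aln, min_sv_candidate))
        segs = segments_of_read(aln, min_mapq)
        if len(segs) > 1:
            out.extend(signatures_from_splits(segs, aln.query_name,
                                              min_sv_candidate, err))
    mean_rate = float(np.mean(sample_rates)) if sample_rates else 0.0
    kept = []
    for sig in out:
        if sig.read_error_rate == 0.0:
            sig.read_error_rate = mean_rate
        if sig.contig == region.contig and lo <= sig.pos <= hi:
            kept.append(sig)
    kept.sort(key=lambda s: (s.svtype, s.pos, s.length, s.read_name,
                             s.mate_contig or "", s.mate_pos or -1))
    return kept
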