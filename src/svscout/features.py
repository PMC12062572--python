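"""Per-site alignment feature extraction.

Each reference site in a scanned region gets a 20-channel count vector:
10 variant-evidence channels per strand (forward block first).  The
channels summarise the alignment signals that betray structural variants
in long reads — intra-alignment CIGAR gaps, soft clips, split-read
junction patterns from SA tags, and anomalously error-rich coverage.

Channel layout (per strand block):

  0  read depth (aligned span coverage)
  1  deletion coverage: reference positions under a CIGAR D op >= min_op
  2  insertion anchors: reference position of a CIGAR I op >= min_op
  3  left soft-clip count (clip at the alignment's reference start)
  4  right soft-clip count (clip at the alignment's reference end)
  5  split-read breakend: SA segment on the same contig, same strand
  6  inverted-orientation split: SA segment on the opposite strand
  7  duplication-pattern split: SA segment overlapping/behind the primary
  8  inter-contig split: SA segment on a different contig
  9  low-identity coverage: span of reads whose edit fraction exceeds
     twice the regional mean

The channel set is deliberately isolated behind ``CHANNEL_NAMES`` /
``_read_events`` so an alternative feature definition can be swapped in
without touching the model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

N_CHANNELS_PER_STRAND = 10
N_CHANNELS = 2 * N_CHANNELS_PER_STRAND

CHANNEL_NAMES = (
    "depth",
    "del_coverage",
    "ins_anchor",
    "left_clip",
    "right_clip",
    "split_same",
    "split_inverted",
    "split_dup",
    "split_intercontig",
    "low_identity",
)

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_OP = 30  # smallest CIGAR D/I counted as a variant event

SUBMATRIX_SIZE = 200
SUBMATRICES_PER_WINDOW = 10
WINDOW_SIZE = SUBMATRIX_SIZE * SUBMATRICES_PER_WINDOW

# CIGAR op codes (pysam numeric): M=0 I=1 D=2 N=3 S=4 H=5 =7 X=8
_REF_CONSUMING = {0, 2, 3, 7, 8}
_QUERY_CONSUMING = {0, 1, 4, 7, 8}


class ContigNotFoundError(KeyError):
    pass


@dataclass
class FeatureMatrix:
    """Dense per-site counts over a half-open region [start, start+len)."""

    contig: str
    start: int
    counts: np.ndarray  # (span, 20) non-negative

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_CHANNELS:
            raise ValueError(f"counts must be (span, {N_CHANNELS})")

    @property
    def span(self) -> int:
        return self.counts.shape[0]

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class WindowBatch:
    """A 2000 bp window tiled into ten 200 bp submatrices."""

    contig: str
    start: int
    submatrices: np.ndarray  # (10, 200, 20)
    pad_mask: np.ndarray = field(default=None)  # (10,) True where fully padded

    def __post_init__(self):
        if self.submatrices.shape != (SUBMATRICES_PER_WINDOW, SUBMATRIX_SIZE, N_CHANNELS):
            raise ValueError("submatrices must be (10, 200, 20)")
        if self.pad_mask is None:
            self.pad_mask = np.zeros(SUBMATRICES_PER_WINDOW, dtype=bool)

    def submatrix_interval(self, i: int) -> tuple[int, int]:
        s = self.start + i * SUBMATRIX_SIZE
        return s, s + SUBMATRIX_SIZE


@dataclass
class _ReadEvents:
    """Events of one primary alignment, in reference coordinates."""

    strand_rev: bool
    ref_start: int
    ref_end: int
    del_intervals: list[tuple[int, int]]
    ins_anchors: list[int]
    left_clip: bool
    right_clip: bool
    sa_events: list[tuple[int, int]]  # (channel, ref position)
    error_rate: float | None


def read_error_rate(aln: pysam.AlignedSegment) -> float | None:
    """Per-read edit fraction from the NM tag over the aligned length."""
    try:
        nm = aln.get_tag("NM")
    except KeyError:
        return None
    aligned = aln.query_alignment_length
    return nm / aligned if aligned else None


def _parse_sa(tag: str):
    segs = []
    for part in tag.rstrip(";").split(";"):
        if not part:
            continue
        rname, pos, strand, cigar, mapq, nm = part.split(",")
        segs.append((rname, int(pos) - 1, strand, cigar, int(mapq), int(nm)))
    return segs


def _read_events(aln: pysam.AlignedSegment, min_op: int) -> _ReadEvents:
    ref = aln.reference_start
    dels: list[tuple[int, int]] = []
    ins: list[int] = []
    cig = aln.cigartuples or []
    for op, length in cig:
        if op == 2:  # D
            if length >= min_op:
                dels.append((ref, ref + length))
            ref += length
        elif op == 1:  # I
            if length >= min_op:
                ins.append(ref)
        elif op in _REF_CONSUMING:
            ref += length
    left_clip = bool(cig) and cig[0][0] in (4, 5)
    right_clip = bool(cig) and cig[-1][0] in (4, 5)

    sa_events: list[tuple[int, int]] = []
    if aln.has_tag("SA"):
        p_start, p_end = aln.reference_start, aln.reference_end
        p_strand = "-" if aln.is_reverse else "+"
        for rname, spos, sstrand, _scigar, smapq, _snm in _parse_sa(aln.get_tag("SA")):
            if smapq < DEFAULT_MIN_MAPQ:
                continue
            # the junction sits at the primary's breakend nearer the partner
            if rname != aln.reference_name:
                anchor = p_end - 1 if spos >= p_start else p_start
                sa_events.append((8, anchor))
            elif sstrand != p_strand:
                anchor = p_end - 1 if spos >= p_start else p_start
                sa_events.append((6, anchor))
            elif spos < p_end and spos >= p_start - 10 * WINDOW_SIZE:
                # partner starts behind/within the primary: tandem-duplication walk
                sa_events.append((7, max(spos, p_start)))
            else:
                anchor = p_end - 1 if spos >= p_end else p_start
                sa_events.append((5, anchor))

    return _ReadEvents(
        strand_rev=aln.is_reverse,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        del_intervals=dels,
        ins_anchors=ins,
        left_clip=left_clip,
        right_clip=right_clip,
        sa_events=sa_events,
        error_rate=read_error_rate(aln),
    )


def _open_bam(alignment_source) -> pysam.AlignmentFile:
    if isinstance(alignment_source, pysam.AlignmentFile):
        return alignment_source
    path = os.fspath(alignment_source)
    try:
        return pysam.AlignmentFile(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {path!r}: {exc}") from exc


def extract_site_features(
    alignment_source,
    region: tuple[str, int, int],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_op: int = DEFAULT_MIN_OP,
) -> FeatureMatrix:
    """Count per-site variant evidence over ``region`` (0-based half-open).

    Secondary alignments are ignored; supplementary records are skipped
    (their junction evidence arrives through the primary's SA tag) and
    reads under the mapping-quality floor are excluded entirely.
    """
    contig, start, end = region
    if end <= start:
        raise ValueError("region end must exceed start")
    bam = _open_bam(alignment_source)
    if contig not in bam.references:
        raise ContigNotFoundError(f"contig {contig!r} not in alignment header")

    events: list[_ReadEvents] = []
    for aln in bam.fetch(contig, start, end):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        events.append(_read_events(aln, min_op))

    counts = np.zeros((end - start, N_CHANNELS), dtype=np.float32)
    rates = [e.error_rate for e in events if e.error_rate is not None]
    mean_rate = float(np.mean(rates)) if rates else 0.0
    lo = start

    def clip_span(a: int, b: int) -> tuple[int, int]:
        return max(a, start) - lo, min(b, end) - lo

    for e in events:
        base = N_CHANNELS_PER_STRAND if e.strand_rev else 0
        a, b = clip_span(e.ref_start, e.ref_end)
        if a < b:
            counts[a:b, base + 0] += 1
        for da, db in e.del_intervals:
            a, b = clip_span(da, db)
            if a < b:
                counts[a:b, base + 1] += 1
        for p in e.ins_anchors:
            if start <= p < end:
                counts[p - lo, base + 2] += 1
        if e.left_clip and start <= e.ref_start < end:
            counts[e.ref_start - lo, base + 3] += 1
        if e.right_clip and start <= e.ref_end - 1 < end:
            counts[e.ref_end - 1 - lo, base + 4] += 1
        for chan, p in e.sa_events:
            if start <= p < end:
                counts[p - lo, base + chan] += 1
        if e.error_rate is not None and mean_rate > 0 and e.error_rate > 2.0 * mean_rate:
            a, b = clip_span(e.ref_start, e.ref_end)
            if a < b:
                counts[a:b, base + 9] += 1

    return FeatureMatrix(contig=contig, start=start, counts=counts)


def tile_windows(matrix: FeatureMatrix) -> list[WindowBatch]:
    """Tile a feature matrix into consecutive 2000 bp ``WindowBatch`` blocks.

    A trailing partial window is zero-padded; submatrices holding no real
    positions at all are flagged in ``pad_mask``.
    """
    span = matrix.span
    if span == 0:
        return []
    n_windows = (span + WINDOW_SIZE - 1) // WINDOW_SIZE
    padded = np.zeros((n_windows * WINDOW_SIZE, N_CHANNELS), dtype=np.float32)
    padded[:span] = matrix.counts
    batches = []
    for w in range(n_windows):
        block = padded[w * WINDOW_SIZE:(w + 1) * WINDOW_SIZE]
        subs = block.reshape(SUBMATRICES_PER_WINDOW, SUBMATRIX_SIZE, N_CHANNELS)
        filled = span - w * WINDOW_SIZE  # real positions in this window
        first_empty = max(0, min(SUBMATRICES_PER_WINDOW,
                                 -(-filled // SUBMATRIX_SIZE) if filled > 0 else 0))
        mask = np.arange(SUBMATRICES_PER_WINDOW) >= first_empty
        batches.append(WindowBatch(
            contig=matrix.contig,
            start=matrix.start + w * WINDOW_SIZE,
            submatrices=subs.copy(),
            pad_mask=mask,
        ))
    return batches
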