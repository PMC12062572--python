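"""Synthetic long-read alignment simulator and evaluation harness.

The simulator emulates a benchmark built from a variant-implanted donor
genome sequenced with error-prone long reads: it synthesises a random
reference, implants DEL/INS/DUP/INV/TRA events into one or both donor
haplotypes, and then constructs each read's alignment *analytically*
from the truth — a read crossing a deletion receives a CIGAR D
operation, an insertion an I operation, and inversion / duplication /
translocation junctions become split alignments with SA tags and the
correct strands.  No external aligner is involved, which makes every
BAM byte a deterministic function of the seed.  Sequencing noise is
substitutions plus small (1-3 bp) indels, reflected in each record's
CIGAR, sequence and NM tag; small indels never approach the 30 bp
signature floor, so noise cannot mimic an SV.

Also here: per-submatrix training labels from a truth set, and the
precision/recall/F1 evaluation used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .features import SUBMATRIX_SIZE, WindowBatch
from .vcfio import TruthVariant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")

_MIN_SEGMENT = 100  # smallest alignable split segment, bp


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated benchmark."""

    ref_length: int = 1_000_000       # per contig
    n_contigs: int = 2
    n_sv: dict = field(default_factory=lambda: {t: 20 for t in SV_TYPES})
    size_range: dict = field(default_factory=lambda: {
        "DEL": (60, 2000), "INS": (60, 2000), "DUP": (60, 2000),
        "INV": (60, 2000), "TRA": (0, 0)})
    het_fraction: float = 0.5
    coverage: float = 30.0
    read_length_mean: float = 8000.0
    read_length_sd: float = 1500.0
    error_rate: float = 0.10
    seed: int = 1

    def __post_init__(self):
        if not (0.0 <= self.het_fraction <= 1.0):
            raise SimConfigError("het_fraction must lie in [0, 1]")
        if self.coverage <= 0:
            raise SimConfigError("coverage must be positive")
        if self.ref_length < 10_000:
            raise SimConfigError("ref_length must be at least 10 kb")
        if self.n_sv.get("TRA", 0) > 0 and self.n_contigs < 2:
            raise SimConfigError("translocations require at least 2 contigs")


@dataclass
class _Block:
    """One donor segment: a reference slice or novel inserted sequence."""

    contig: str | None
    start: int
    end: int
    strand: int = 1  # +1 forward, -1 inverted
    novel: np.ndarray | None = None  # uint8 codes, donor orientation

    @property
    def length(self) -> int:
        return len(self.novel) if self.novel is not None else self.end - self.start


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def simulate_reference(length: int, seed: int, n_contigs: int = 1
                       ) -> dict[str, np.ndarray]:
    """Uniform-random contigs as uint8 base codes (A=0 C=1 G=2 T=3)."""
    if length < 10_000:
        raise SimConfigError("reference length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": rng.integers(0, 4, length, dtype=np.uint8)
            for i in range(n_contigs)}


def write_reference_fasta(reference: dict[str, np.ndarray], path,
                          width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in reference.items():
            fh.write(f">{name}\n")
            seq = _decode(codes)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    pysam.faidx(str(path))


# -- SV implantation ---------------------------------------------------------

def _place_positions(rng, contig_lengths: dict[str, int], wanted: list[int],
                     margin: int, edge: int = 10_000,
                     max_tries: int = 20_000) -> list[tuple[str, int]]:
    """Place event anchors (given their ref spans) with pairwise spacing."""
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    out: list[tuple[str, int]] = []
    contigs = list(contig_lengths)
    for span in wanted:
        for attempt in range(max_tries):
            contig = contigs[int(rng.integers(len(contigs)))]
            hi = contig_lengths[contig] - edge - span
            if hi <= edge:
                continue
            pos = int(rng.integers(edge, hi))
            ok = all(pos + span + margin <= s or e + margin <= pos
                     for s, e in placed[contig])
            if ok:
                placed[contig].append((pos, pos + span))
                out.append((contig, pos))
                break
        else:
            raise SimConfigError(
                "could not place all SVs; reference too small for the load")
    return out


def implant_svs(reference: dict[str, np.ndarray], config: SimConfig
                ) -> tuple[list[dict[str, list[_Block]]], list[TruthVariant]]:
    """Implant SVs; returns two donor haplotypes (block lists) + truth.

    Heterozygous events go to one randomly chosen haplotype, homozygous
    to both.  Translocations are reciprocal exchanges between the first
    two contigs; their breakpoints are generated in matched sorted order
    so derivative chromosomes alternate cleanly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    contig_lengths = {c: len(s) for c, s in reference.items()}
    max_size = max(hi for _, hi in config.size_range.values()) or 2000
    margin = 2 * max_size

    events: list[TruthVariant] = []
    spans, kinds = [], []
    for svtype in ("DEL", "INS", "DUP", "INV"):
        lo, hi = config.size_range.get(svtype, (60, 2000))
        for _ in range(config.n_sv.get(svtype, 0)):
            size = int(rng.integers(lo, hi + 1))
            spans.append(size if svtype != "INS" else 1)
            kinds.append((svtype, size))
    anchors = _place_positions(rng, contig_lengths, spans, margin)
    ins_seqs: dict[tuple[str, int], np.ndarray] = {}
    for (svtype, size), (contig, pos) in zip(kinds, anchors):
        het = rng.random() < config.het_fraction
        gt = "0/1" if het else "1/1"
        end = pos + (size if svtype != "INS" else 0)
        events.append(TruthVariant(svtype, contig, pos, end, size, gt))
        if svtype == "INS":
            ins_seqs[(contig, pos)] = rng.integers(0, 4, size, dtype=np.uint8)

    n_tra = config.n_sv.get("TRA", 0)
    tra_events: list[TruthVariant] = []
    if n_tra:
        c1, c2 = list(contig_lengths)[:2]
        blocked = {c: sorted((e.pos - margin, e.end + margin)
                             for e in events if e.contig == c)
                   for c in (c1, c2)}

        def free_positions(contig: str, n: int) -> list[int]:
            got: list[int] = []
            for _ in range(50_000):
                if len(got) == n:
                    break
                p = int(rng.integers(10_000, contig_lengths[contig] - 10_000))
                if any(s <= p < e for s, e in blocked[contig]):
                    continue
                if any(abs(p - q) < margin for q in got):
                    continue
                got.append(p)
            if len(got) < n:
                raise SimConfigError("could not place translocation breakpoints")
            return sorted(got)

        pa, pb = free_positions(c1, n_tra), free_positions(c2, n_tra)
        for a, b in zip(pa, pb):
            het = rng.random() < config.het_fraction
            tra_events.append(TruthVariant("TRA", c1, a, a, 0,
                                           "0/1" if het else "1/1",
                                           mate_contig=c2, mate_pos=b))
    truth = sorted(events + tra_events,
                   key=lambda t: (t.contig, t.pos, t.svtype))

    hap_of_het = {id(t): int(rng.integers(2)) for t in truth if t.genotype == "0/1"}
    haplotypes = []
    for hap in (0, 1):
        mine = [t for t in truth
                if t.genotype == "1/1" or hap_of_het.get(id(t)) == hap]
        haplotypes.append(_build_donor(reference, mine, ins_seqs))
    return haplotypes, truth


def _build_donor(reference, events: list[TruthVariant],
                 ins_seqs) -> dict[str, list[_Block]]:
    donor: dict[str, list[_Block]] = {}
    for contig, codes in reference.items():
        blocks: list[_Block] = []
        cursor = 0
        for ev in sorted((e for e in events
                          if e.contig == contig and e.svtype != "TRA"),
                         key=lambda e: e.pos):
            if ev.pos > cursor:
                blocks.append(_Block(contig, cursor, ev.pos))
            if ev.svtype == "DEL":
                cursor = ev.end
            elif ev.svtype == "INS":
                blocks.append(_Block(None, 0, 0, novel=ins_seqs[(contig, ev.pos)]))
                cursor = ev.pos
            elif ev.svtype == "DUP":
                blocks.append(_Block(contig, ev.pos, ev.end))
                blocks.append(_Block(contig, ev.pos, ev.end))
                cursor = ev.end
            elif ev.svtype == "INV":
                blocks.append(_Block(contig, ev.pos, ev.end, strand=-1))
                cursor = ev.end
        if cursor < len(codes):
            blocks.append(_Block(contig, cursor, len(codes)))
        donor[contig] = blocks

    tras = [e for e in events if e.svtype == "TRA"]
    if tras:
        c1 = tras[0].contig
        c2 = tras[0].mate_contig
        pa = [t.pos for t in tras]
        pb = [t.mate_pos for t in tras]
        pieces_a = _cut_stream(donor[c1], pa)
        pieces_b = _cut_stream(donor[c2], pb)
        der1, der2 = [], []
        for i in range(len(pieces_a)):
            src_a, src_b = (der1, der2) if i % 2 == 0 else (der2, der1)
            src_a.extend(pieces_a[i])
            src_b.extend(pieces_b[i])
        donor[c1], donor[c2] = der1, der2
    return donor


def _cut_stream(blocks: list[_Block], cuts: list[int]) -> list[list[_Block]]:
    """Cut a block stream at reference coordinates (within plain + blocks)."""
    pieces: list[list[_Block]] = []
    current: list[_Block] = []
    remaining = list(blocks)
    for cut in cuts:
        nxt: list[_Block] = []
        for i, b in enumerate(remaining):
            if (b.novel is None and b.strand == 1 and b.start < cut <= b.end
                    and b.contig is not None):
                if cut > b.start:
                    current.append(_Block(b.contig, b.start, cut))
                if cut < b.end:
                    nxt.append(_Block(b.contig, cut, b.end))
                nxt.extend(remaining[i + 1:])
                break
            current.append(b)
        else:
            raise SimConfigError("translocation breakpoint inside another event")
        pieces.append(current)
        current = []
        remaining = nxt
    pieces.append(remaining)
    return pieces


# -- read construction -------------------------------------------------------

@dataclass
class _Record:
    contig: str
    strand: int
    ref_start: int
    ops: list  # [(op_char, length)] reference orientation, M/I/D only
    seq_codes: list  # aligned-portion fragments, reference orientation
    nm: int
    q_start: int = 0  # read-orientation query interval of the aligned part
    q_end: int = 0

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.ops if op in "MD")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


def _noisy_block(fragment: np.ndarray, rng, p_sub: float, p_ind: float
                 ) -> tuple[list, np.ndarray, int]:
    """Align a reference fragment with substitutions and 1-3 bp indels.

    Returns (ops, query codes of the aligned portion in reference
    orientation, NM contribution).
    """
    L = len(fragment)
    query = fragment.copy()
    sub_mask = rng.random(L) < p_sub
    n_sub = int(sub_mask.sum())
    if n_sub:
        query[sub_mask] = (query[sub_mask] + rng.integers(1, 4, n_sub)) % 4

    n_ins = rng.binomial(L, p_ind / 2.0)
    n_del = rng.binomial(L, p_ind / 2.0)
    events = sorted(
        [(int(p), "I", int(rng.integers(1, 4))) for p in rng.integers(1, max(L, 2), n_ins)] +
        [(int(p), "D", int(rng.integers(1, 4))) for p in rng.integers(1, max(L, 2), n_del)]
    )
    ops: list = []
    out: list[np.ndarray] = []
    cursor, nm = 0, n_sub

    def emit_m(upto: int):
        nonlocal cursor
        if upto > cursor:
            ops.append(("M", upto - cursor))
            out.append(query[cursor:upto])
            cursor = upto

    for pos, kind, size in events:
        if pos <= cursor or pos >= L:
            continue
        emit_m(pos)
        if kind == "I":
            ops.append(("I", size))
            out.append(rng.integers(0, 4, size, dtype=np.uint8))
            nm += size
        else:
            size = min(size, L - cursor - 1)
            if size <= 0:
                continue
            ops.append(("D", size))
            cursor += size
            nm += size
    emit_m(L)
    merged: list = []
    for op, l in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + l)
        else:
            merged.append((op, l))
    q = np.concatenate(out) if out else np.zeros(0, dtype=np.uint8)
    return merged, q, nm


def _slice_blocks(blocks: list[_Block], lo: int, hi: int) -> list[_Block]:
    """Donor-coordinate slice [lo, hi) of a block stream."""
    out: list[_Block] = []
    cursor = 0
    for b in blocks:
        blen = b.length
        s, e = max(lo, cursor), min(hi, cursor + blen)
        if s < e:
            off_s, off_e = s - cursor, e - cursor
            if b.novel is not None:
                out.append(_Block(None, 0, 0, novel=b.novel[off_s:off_e]))
            elif b.strand == 1:
                out.append(_Block(b.contig, b.start + off_s, b.start + off_e))
            else:
                # inverted: donor offset counts from the reference end
                out.append(_Block(b.contig, b.end - off_e, b.end - off_s,
                                  strand=-1))
        cursor += blen
        if cursor >= hi:
            break
    return out


def _build_read(read_blocks: list[_Block], reference, rng,
                p_sub: float, p_ind: float
                ) -> tuple[list[_Record], np.ndarray]:
    """Construct alignment records and the read sequence for one read."""
    records: list[_Record] = []
    read_parts: list[np.ndarray] = []
    read_len = 0
    current: _Record | None = None
    pending_ins = 0  # novel bases waiting to join the open record

    for blk in read_blocks:
        if blk.novel is not None:
            read_parts.append(blk.novel)
            read_len += len(blk.novel)
            pending_ins += len(blk.novel)
            continue
        frag = reference[blk.contig][blk.start:blk.end]
        if blk.strand == -1:
            frag = _revcomp_codes(frag)  # donor orientation
        ops, q_ref, nm = _noisy_block(
            frag if blk.strand == 1 else _revcomp_codes(frag), rng, p_sub, p_ind)
        # q_ref is reference-orientation; the read receives donor orientation
        q_read = q_ref if blk.strand == 1 else _revcomp_codes(q_ref)
        q_start = read_len
        read_parts.append(q_read)
        read_len += len(q_read)

        joinable = (
            current is not None and blk.strand == 1 and current.strand == 1
            and blk.contig == current.contig
            and blk.start >= current.ref_end
        )
        if joinable:
            if pending_ins:
                current.ops.append(("I", pending_ins))
                current.nm += pending_ins
            gap = blk.start - current.ref_end
            if gap > 0:
                current.ops.append(("D", gap))
                current.nm += gap
            current.ops.extend(ops)
            current.seq_codes.append(q_ref)
            current.nm += nm
            current.q_end = read_len
        else:
            if blk.end - blk.start >= _MIN_SEGMENT:
                current = _Record(blk.contig, blk.strand,
                                  blk.start, list(ops), [q_ref], nm,
                                  q_start, read_len)
                records.append(current)
            else:
                current = None  # fragment too small to align; stays clipped
        pending_ins = 0

    seq = (np.concatenate(read_parts) if read_parts
           else np.zeros(0, dtype=np.uint8))
    records = [r for r in records
               if sum(l for op, l in r.ops if op == "M") >= _MIN_SEGMENT]
    return records, seq


def _merge_ops(ops: list) -> list:
    merged: list = []
    for op, l in ops:
        if l <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + l)
        else:
            merged.append((op, l))
    return merged


def _cigar_string(rec: _Record, read_len: int) -> str:
    if rec.strand == 1:
        lead, trail = rec.q_start, read_len - rec.q_end
    else:
        lead, trail = read_len - rec.q_end, rec.q_start
    parts = []
    if lead:
        parts.append(f"{lead}S")
    parts.extend(f"{l}{op}" for op, l in _merge_ops(rec.ops))
    if trail:
        parts.append(f"{trail}S")
    return "".join(parts)


_OP_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


def _cigar_tuples(rec: _Record, read_len: int) -> list[tuple[int, int]]:
    if rec.strand == 1:
        lead, trail = rec.q_start, read_len - rec.q_end
    else:
        lead, trail = read_len - rec.q_end, rec.q_start
    out = []
    if lead:
        out.append((4, lead))
    out.extend((_OP_CODE[op], l) for op, l in _merge_ops(rec.ops))
    if trail:
        out.append((4, trail))
    return out


def simulate_alignments(haplotypes, truth, reference, config: SimConfig,
                        bam_path) -> str:
    """Sample reads from the donor haplotypes and write a sorted BAM.

    Each haplotype is sequenced to half the requested coverage.  Reads
    are placed uniformly on each donor contig; their alignments are the
    analytic decomposition of the crossed donor segments, with split
    records and SA tags at inversion/duplication/translocation junctions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    p_sub = 0.6 * config.error_rate
    p_ind = 0.4 * config.error_rate

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()],
        "PG": [{"ID": "svscout-sim", "PN": "svscout-sim"}],
    })
    bam_path = str(bam_path)
    tmp = bam_path + ".unsorted.bam"
    n_read = 0
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for hap_idx, donor in enumerate(haplotypes):
            for donor_name, blocks in donor.items():
                donor_len = sum(b.length for b in blocks)
                n_reads = int(round((config.coverage / 2.0) * donor_len
                                    / config.read_length_mean))
                for _ in range(n_reads):
                    L = int(np.clip(rng.normal(config.read_length_mean,
                                               config.read_length_sd),
                                    1000, None))
                    start = int(rng.integers(0, max(donor_len - 200, 1)))
                    stop = min(start + L, donor_len)
                    rb = _slice_blocks(blocks, start, stop)
                    records, seq = _build_read(rb, reference, rng, p_sub, p_ind)
                    if not records or len(seq) == 0:
                        continue
                    if rng.random() < 0.5:  # sequencing strand
                        read_len = len(seq)
                        seq = _revcomp_codes(seq)
                        for r in records:
                            r.strand *= -1
                            r.q_start, r.q_end = (read_len - r.q_end,
                                                  read_len - r.q_start)
                    n_read += 1
                    qname = f"sim_h{hap_idx}_{donor_name}_{n_read}"
                    _write_read(out, records, seq, qname)
    pysam.sort("-o", bam_path, tmp)
    pysam.index(bam_path)
    import os
    os.remove(tmp)
    return bam_path


def _write_read(out: pysam.AlignmentFile, records: list[_Record],
                seq: np.ndarray, qname: str) -> None:
    read_len = len(seq)
    primary = max(range(len(records)), key=lambda i: records[i].q_span)
    sa_strings = [
        f"{r.contig},{r.ref_start + 1},{'+' if r.strand == 1 else '-'},"
        f"{_cigar_string(r, read_len)},60,{r.nm};"
        for r in records
    ]
    for i, rec in enumerate(records):
        a = pysam.AlignedSegment(out.header)
        a.query_name = qname
        a.reference_name = rec.contig
        a.reference_start = rec.ref_start
        a.mapping_quality = 60
        a.flag = (16 if rec.strand == -1 else 0) | (0 if i == primary else 2048)
        a.cigartuples = _cigar_tuples(rec, read_len)
        stored = seq if rec.strand == 1 else _revcomp_codes(seq)
        a.query_sequence = _decode(stored)
        a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
        a.set_tag("NM", rec.nm)
        if len(records) > 1:
            others = "".join(s for j, s in enumerate(sa_strings) if j != i)
            a.set_tag("SA", others)
        out.write(a)


# -- labels and evaluation ---------------------------------------------------

def truth_intervals(truth: list[TruthVariant]) -> dict[str, list[tuple[int, int]]]:
    """Per-contig SV intervals; INS and breakends become 1 bp anchors."""
    out: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        if t.svtype in ("TRA", "BND"):
            out.setdefault(t.contig, []).append((t.pos, t.pos + 1))
            out.setdefault(t.mate_contig, []).append((t.mate_pos, t.mate_pos + 1))
        elif t.svtype == "INS":
            out.setdefault(t.contig, []).append((t.pos, t.pos + 1))
        else:
            out.setdefault(t.contig, []).append((t.pos, t.end))
    return {c: sorted(v) for c, v in out.items()}


def label_windows(truth: list[TruthVariant],
                  windows: list[WindowBatch]) -> list[np.ndarray]:
    """Binary per-submatrix labels: 1 iff the 200 bp block overlaps an SV."""
    ivals = truth_intervals(truth)
    labels = []
    for w in windows:
        lab = np.zeros(len(w.pad_mask), dtype=np.float32)
        for i in range(len(lab)):
            s, e = w.submatrix_interval(i)
            lab[i] = float(any(ts < e and s < te
                               for ts, te in ivals.get(w.contig, [])))
        lab[w.pad_mask] = 0.0
        labels.append(lab)
    return labels


@dataclass
class TypeMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    offsets: list = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def median_offset(self) -> float:
        return float(np.median(self.offsets)) if self.offsets else float("nan")


def _canonical_bnd(contig, pos, mate_contig, mate_pos):
    a, b = (contig, pos), (mate_contig, mate_pos)
    return (a, b) if a <= b else (b, a)


def _normalise(items, pass_only: bool):
    intra, bnd = [], []
    seen_pairs = set()
    for it in items:
        if pass_only and getattr(it, "filter", "PASS") != "PASS":
            continue
        svtype = "TRA" if it.svtype in ("TRA", "BND") else it.svtype
        if svtype == "TRA":
            key = _canonical_bnd(it.contig, it.pos, it.mate_contig, it.mate_pos)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            bnd.append(key)
        else:
            length = getattr(it, "length", None)
            if length is None:
                length = getattr(it, "svlen")
            intra.append((svtype, it.contig, it.pos, abs(length)))
    return intra, bnd


def evaluate_calls(calls, truth, pos_tolerance: int = 500,
                   len_ratio: float = 0.7, pass_only: bool = True
                   ) -> dict[str, TypeMetrics]:
    """Match calls to truth per type and report precision/recall/F1.

    A call matches a truth entry of the same type when the breakpoint
    difference is at most ``pos_tolerance`` (boundary inclusive) and the
    shorter length is at least ``len_ratio`` of the longer (skipped for
    breakends, which instead require both ends to be within tolerance).
    Matching is one-to-one and greedy by position.  The ``overall`` entry
    aggregates all types.
    """
    call_intra, call_bnd = _normalise(calls, pass_only)
    true_intra, true_bnd = _normalise(truth, pass_only=False)

    metrics = {t: TypeMetrics() for t in SV_TYPES}
    for svtype in ("DEL", "INS", "DUP", "INV"):
        cs = sorted((c for c in call_intra if c[0] == svtype),
                    key=lambda c: (c[1], c[2]))
        ts = [t for t in true_intra if t[0] == svtype]
        used = [False] * len(ts)
        m = metrics[svtype]
        for _, contig, pos, length in cs:
            best, best_d = -1, None
            for j, (_, tc, tp_, tl) in enumerate(ts):
                if used[j] or tc != contig:
                    continue
                d = abs(pos - tp_)
                if d > pos_tolerance:
                    continue
                if min(length, tl) / max(length, tl, 1) < len_ratio:
                    continue
                if best_d is None or d < best_d:
                    best, best_d = j, d
            if best >= 0:
                used[best] = True
                m.tp += 1
                m.offsets.append(best_d)
            else:
                m.fp += 1
        m.fn = used.count(False)

    m = metrics["TRA"]
    used = [False] * len(true_bnd)
    for (c1, p1), (c2, p2) in call_bnd:
        best, best_d = -1, None
        for j, ((tc1, tp1), (tc2, tp2)) in enumerate(true_bnd):
            if used[j] or (tc1, tc2) != (c1, c2):
                continue
            d1, d2 = abs(p1 - tp1), abs(p2 - tp2)
            if d1 <= pos_tolerance and d2 <= pos_tolerance:
                d = max(d1, d2)
                if best_d is None or d < best_d:
                    best, best_d = j, d
        if best >= 0:
            used[best] = True
            m.tp += 1
            m.offsets.append(best_d)
        else:
            m.fp += 1
    m.fn = used.count(False)

    overall = TypeMetrics()
    for t in SV_TYPES:
        overall.tp += metrics[t].tp
        overall.fp += metrics[t].fp
        overall.fn += metrics[t].fn
        overall.offsets.extend(metrics[t].offsets)
    metrics["overall"] = overall
    return metrics


# -- one-call convenience ----------------------------------------------------

@dataclass
class Simulation:
    config: SimConfig
    reference: dict[str, np.ndarray]
    truth: list[TruthVariant]
    bam_path: str
    fasta_path: str | None = None

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


def simulate(config: SimConfig, outdir, write_fasta: bool = True) -> Simulation:
    """Reference + implanted donor + reads; writes BAM (+ FASTA) to outdir."""
    import os
    os.makedirs(str(outdir), exist_ok=True)
    reference = simulate_reference(config.ref_length, config.seed,
                                   config.n_contigs)
    if any(config.n_sv.get(t, 0) for t in SV_TYPES):
        haplotypes, truth = implant_svs(reference, config)
    else:
        haplotypes = [{c: [_Block(c, 0, len(s))] for c, s in reference.items()}
                      for _ in range(2)]
        truth = []
    bam = os.path.join(str(outdir), "reads.bam")
    simulate_alignments(haplotypes, truth, reference, config, bam)
    fasta = None
    if write_fasta:
        fasta = os.path.join(str(outdir), "ref.fa")
        write_reference_fasta(reference, fasta)
    return Simulation(config, reference, truth, bam, fasta)
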