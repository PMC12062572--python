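"""VCF input/output.

Calls are emitted as VCF 4.2 with symbolic ALT alleles (<DEL>, <INS>,
<DUP>, <INV>) and translocations as two mated BND records in bracket
notation.  Internal coordinates are 0-based half-open; POS is written
1-based at the variant's first affected base and END as POS + |SVLEN|
for reference-consuming types.  SVLEN is negative for deletions and
positive otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pysam

from . import __version__
from .calling import SVCall


@dataclass
class TruthVariant:
    """One truth-set entry (coordinates 0-based)."""

    svtype: str
    contig: str
    pos: int
    end: int
    length: int
    genotype: str = "./."
    mate_contig: str | None = None
    mate_pos: int | None = None


_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant; negative for deletions">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Distinct reads supporting the variant">',
    '##INFO=<ID=MIN_SUPPORT,Number=1,Type=Integer,Description="Dynamic minimum-support threshold at this locus">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner contig of a breakend">',
    '##INFO=<ID=END2,Number=1,Type=Integer,Description="Partner position of a breakend (1-based)">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of the mate breakend">',
    '##FILTER=<ID=MinSupport,Description="Supporting reads below the dynamic threshold">',
    '##FILTER=<ID=MinLength,Description="Median variant length below the reporting floor">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting reads">',
]


def _build_header(contig_metadata: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##source=svscout-{__version__}")
    for name, length in contig_metadata.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for line in _HEADER_LINES:
        header.add_line(line)
    header.add_sample("SAMPLE")
    return header


def _ref_base(reference, contig: str, pos: int) -> str:
    if reference is None:
        return "N"
    seq = reference[contig][pos:pos + 1]
    base = str(seq.seq if hasattr(seq, "seq") else seq)
    return base.upper() or "N"


def write_vcf(calls: list[SVCall], contig_metadata: dict[str, int], output,
              reference=None, tabix: bool = False) -> None:
    """Write calls as sorted VCF; BNDs become two mated bracket records.

    ``contig_metadata`` maps contig name to length and must cover every
    call; ``reference`` is an optional ``pyfaidx.Fasta`` for REF bases.
    """
    for call in calls:
        if call.contig not in contig_metadata:
            raise ValueError(f"call on unknown contig {call.contig!r}")
        if call.mate_contig is not None and call.mate_contig not in contig_metadata:
            raise ValueError(f"call on unknown contig {call.mate_contig!r}")

    order = {name: i for i, name in enumerate(contig_metadata)}
    header = _build_header(contig_metadata)
    records: list[tuple[int, int, str]] = []  # (contig rank, pos, line) for sorting

    counter = 0
    for call in sorted(calls, key=lambda c: (order[c.contig], c.pos)):
        counter += 1
        if call.svtype == "BND":
            id1 = f"svscout.BND.{counter}a"
            id2 = f"svscout.BND.{counter}b"
            for this_id, mate_id, contig, pos, chr2, pos2 in (
                (id1, id2, call.contig, call.pos, call.mate_contig, call.mate_pos),
                (id2, id1, call.mate_contig, call.mate_pos, call.contig, call.pos),
            ):
                rec = header.new_record()
                rec.contig = contig
                rec.start = pos
                ref = _ref_base(reference, contig, pos)
                rec.alleles = (ref, f"{ref}[{chr2}:{pos2 + 1}[")
                rec.id = this_id
                rec.info["SVTYPE"] = "BND"
                rec.info["SUPPORT"] = call.support
                rec.info["MIN_SUPPORT"] = call.min_support_threshold
                rec.info["CHR2"] = chr2
                rec.info["END2"] = pos2 + 1
                rec.info["MATEID"] = mate_id
                rec.filter.add(call.filter)
                rec.samples["SAMPLE"]["GT"] = _gt_tuple(call.genotype)
                rec.samples["SAMPLE"]["DV"] = call.support
                records.append((order[contig], pos, str(rec)))
        else:
            rec = header.new_record()
            rec.contig = call.contig
            rec.start = call.pos
            ref = _ref_base(reference, call.contig, call.pos)
            rec.alleles = (ref, f"<{call.svtype}>")
            rec.id = f"svscout.{call.svtype}.{counter}"
            rec.info["SVTYPE"] = call.svtype
            svlen = -call.svlen if call.svtype == "DEL" else call.svlen
            rec.info["SVLEN"] = svlen
            # END = POS + |SVLEN| for reference-consuming types; END = POS for INS
            rec.stop = call.pos + (call.svlen if call.svtype != "INS" else 0) + 1
            rec.info["SUPPORT"] = call.support
            rec.info["MIN_SUPPORT"] = call.min_support_threshold
            rec.filter.add(call.filter)
            rec.samples["SAMPLE"]["GT"] = _gt_tuple(call.genotype)
            rec.samples["SAMPLE"]["DV"] = call.support
            records.append((order[call.contig], call.pos, str(rec)))

    records.sort(key=lambda t: (t[0], t[1]))
    path = str(output)
    if path.endswith(".gz"):
        body = str(header) + "".join(line for _, _, line in records)
        with pysam.BGZFile(path, "wb") as fh:
            fh.write(body.encode())
        if tabix:
            pysam.tabix_index(path, preset="vcf", force=True)
    else:
        with open(path, "w") as fh:
            fh.write(str(header))
            for _, _, line in records:
                fh.write(line)


def _gt_tuple(gt: str):
    if gt in ("./.", None):
        return (None, None)
    a, b = gt.split("/")
    return (int(a), int(b))


def _gt_str(sample) -> str:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return "./."
    return "/".join(str(a) for a in gt)


def _info_get(rec, key):
    """INFO lookup tolerant of keys the header never declared."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def read_truth_vcf(path) -> list[TruthVariant]:
    """Read an SV VCF into truth entries (0-based coordinates).

    Symbolic and sequence-resolved alleles are both accepted; SVTYPE,
    SVLEN and END are taken from INFO when present and inferred from the
    alleles otherwise.  Unresolvable records are skipped with a warning.
    """
    out: list[TruthVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gt = _gt_str(rec.samples[0]) if len(rec.samples) else "./."
            svtype = _info_get(rec, "SVTYPE")
            alt = rec.alts[0] if rec.alts else None
            if svtype is None and alt is not None:
                if alt.startswith("<") and alt.endswith(">"):
                    svtype = alt.strip("<>").split(":")[0]
                elif "[" in alt or "]" in alt:
                    svtype = "BND"
                elif rec.ref and len(rec.ref) != len(alt):
                    svtype = "DEL" if len(rec.ref) > len(alt) else "INS"
            if svtype in ("TRA", "BND"):
                chr2 = _info_get(rec, "CHR2")
                end2 = _info_get(rec, "END2")
                if chr2 is None and alt and ("[" in alt or "]" in alt):
                    inner = alt.replace("]", "[").split("[")[1]
                    chr2, p2 = inner.rsplit(":", 1)
                    end2 = int(p2)
                if chr2 is None:
                    warnings.warn(f"breakend without partner at {rec.contig}:{rec.pos}")
                    continue
                out.append(TruthVariant("BND", rec.contig, rec.start, rec.start, 0,
                                        gt, mate_contig=chr2, mate_pos=int(end2) - 1))
                continue
            if svtype is None:
                warnings.warn(
                    f"record at {rec.contig}:{rec.pos} has no resolvable SV type")
                continue
            svlen = _info_get(rec, "SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is None and alt is not None and not alt.startswith("<"):
                svlen = len(alt) - len(rec.ref)
            length = abs(int(svlen)) if svlen is not None else max(
                rec.stop - rec.start - 1, 0)
            end = rec.start + (length if svtype in ("DEL", "DUP", "INV") else 0)
            out.append(TruthVariant(svtype, rec.contig, rec.start, end, length, gt))
    return out
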