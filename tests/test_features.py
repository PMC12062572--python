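"""Feature extraction: per-site stranded counts and window tiling."""

import numpy as np
import pytest

from svscout.features import (ContigNotFoundError, FeatureMatrix,
                              extract_site_features, tile_windows,
                              N_CHANNELS, SUBMATRIX_SIZE, WINDOW_SIZE)

CONTIGS = {"chrA": 50_000, "chrB": 50_000}


def brute_force_del_coverage(reads, region_start, region_end, min_op=30):
    """Independent CIGAR re-parse: per-site deletion coverage by strand."""
    import re

    span = region_end - region_start
    fwd, rev = np.zeros(span), np.zeros(span)
    for r in reads:
        ref = r["pos"]
        for num, op in re.findall(r"(\d+)([MIDNSHP=X])", r["cigar"]):
            n = int(num)
            if op == "D":
                if n >= min_op:
                    for p in range(ref, ref + n):
                        if region_start <= p < region_end:
                            (rev if r.get("flag", 0) & 16 else fwd)[
                                p - region_start] += 1
                ref += n
            elif op in "MN=X":
                ref += n
    return fwd, rev


def test_empty_region_gives_all_zero_matrix(bam_factory):
    bam = bam_factory(CONTIGS, [])
    fm = extract_site_features(bam, ("chrA", 1000, 3000))
    assert fm.counts.shape == (2000, N_CHANNELS)
    assert not fm.counts.any()


def test_unknown_contig_raises(bam_factory):
    bam = bam_factory(CONTIGS, [])
    with pytest.raises(ContigNotFoundError):
        extract_site_features(bam, ("chrZ", 0, 100))


@pytest.mark.parametrize("flag,block", [(0, slice(0, 10)), (16, slice(10, 20))])
def test_deletion_counts_match_cigar_walk_on_one_strand(bam_factory, flag, block):
    """A 100 bp D op marks exactly the deleted sites on the read's strand."""
    reads = [{"qname": "r1", "contig": "chrA", "pos": 1000,
              "cigar": "50M100D50M", "flag": flag, "tags": {"NM": 100}}]
    bam = bam_factory(CONTIGS, reads)
    fm = extract_site_features(bam, ("chrA", 900, 1400))
    fwd_expect, rev_expect = brute_force_del_coverage(reads, 900, 1400)
    got = fm.counts[:, block]
    other = fm.counts[:, slice(10, 20) if flag == 0 else slice(0, 10)]
    expect = rev_expect if flag & 16 else fwd_expect
    np.testing.assert_array_equal(got[:, 1], expect)
    assert not other.any()
    # depth covers the whole aligned reference span (including the D op)
    assert got[:, 0].sum() == 200


def test_small_cigar_ops_below_floor_are_ignored(bam_factory):
    bam = bam_factory(CONTIGS, [
        {"qname": "r1", "contig": "chrA", "pos": 1000,
         "cigar": "50M10D50M5I40M", "tags": {"NM": 15}}])
    fm = extract_site_features(bam, ("chrA", 900, 1300))
    assert not fm.counts[:, 1].any() and not fm.counts[:, 2].any()


def test_low_mapq_and_secondary_reads_excluded(bam_factory):
    bam = bam_factory(CONTIGS, [
        {"qname": "r1", "contig": "chrA", "pos": 1000, "cigar": "100M",
         "mapq": 5},
        {"qname": "r2", "contig": "chrA", "pos": 1000, "cigar": "100M",
         "flag": 256},
    ])
    fm = extract_site_features(bam, ("chrA", 900, 1200))
    assert not fm.counts.any()


def test_doubling_reads_doubles_every_count(bam_factory):
    reads = [
        {"qname": "r1", "contig": "chrA", "pos": 1000,
         "cigar": "30S50M40D50M", "tags": {"NM": 40}},
        {"qname": "r2", "contig": "chrA", "pos": 1200,
         "cigar": "50M35I50M20S", "flag": 16, "tags": {"NM": 35}},
    ]
    doubled = reads + [dict(r, qname=r["qname"] + "x") for r in reads]
    fm1 = extract_site_features(bam_factory(CONTIGS, reads), ("chrA", 900, 1500))
    fm2 = extract_site_features(bam_factory(CONTIGS, doubled), ("chrA", 900, 1500))
    np.testing.assert_array_equal(fm2.counts, 2 * fm1.counts)


def test_record_order_invariance(bam_factory):
    reads = [
        {"qname": "a", "contig": "chrA", "pos": 1000, "cigar": "40S100M",
         "tags": {"NM": 3}},
        {"qname": "b", "contig": "chrA", "pos": 1000, "cigar": "100M40S",
         "tags": {"NM": 1}},
        {"qname": "c", "contig": "chrA", "pos": 1000, "cigar": "100M",
         "flag": 16, "tags": {"NM": 2}},
    ]
    fm1 = extract_site_features(bam_factory(CONTIGS, reads), ("chrA", 950, 1150))
    fm2 = extract_site_features(bam_factory(CONTIGS, reads[::-1]), ("chrA", 950, 1150))
    np.testing.assert_array_equal(fm1.counts, fm2.counts)


def test_split_read_channels_from_sa_tag(bam_factory):
    reads = [
        # same contig, same strand, forward order -> split_same (ch 5)
        {"qname": "s1", "contig": "chrA", "pos": 1000, "cigar": "1000M1000S",
         "tags": {"NM": 0, "SA": "chrA,12001,+,1000S1000M,60,0;"}},
        # opposite strand -> inverted split (ch 6)
        {"qname": "s2", "contig": "chrA", "pos": 1000, "cigar": "1000M1000S",
         "tags": {"NM": 0, "SA": "chrA,5001,-,1000S1000M,60,0;"}},
        # different contig -> inter-contig split (ch 8)
        {"qname": "s3", "contig": "chrA", "pos": 1000, "cigar": "1000M1000S",
         "tags": {"NM": 0, "SA": "chrB,7001,+,1000S1000M,60,0;"}},
    ]
    fm = extract_site_features(bam_factory(CONTIGS, reads), ("chrA", 900, 2100))
    assert fm.counts[:, 5].sum() == 1
    assert fm.counts[:, 6].sum() == 1
    assert fm.counts[:, 8].sum() == 1


@pytest.mark.parametrize("span,n_batches,pads", [
    (4000, 2, [0, 0]),
    (2100, 2, [0, 9]),
    (200, 1, [9]),
])
def test_tile_windows_padding(span, n_batches, pads):
    fm = FeatureMatrix("chrA", 0, np.ones((span, N_CHANNELS), dtype=np.float32))
    batches = tile_windows(fm)
    assert len(batches) == n_batches
    for b, n_pad in zip(batches, pads):
        assert int(b.pad_mask.sum()) == n_pad
        assert not b.submatrices[b.pad_mask].any()
    # every input position appears exactly once
    total = sum(b.submatrices[:, :, 0].sum() for b in batches)
    assert total == span


def test_tile_windows_empty_matrix():
    fm = FeatureMatrix("chrA", 0, np.zeros((0, N_CHANNELS)))
    assert tile_windows(fm) == []


def test_feature_channel_totals_match_bruteforce_on_simulation(tiny_sim):
    """Sum over sites of the deletion channel equals an independent count."""
    import pysam

    fm = extract_site_features(tiny_sim.bam_path, ("chr1", 0, 120_000))
    reads = []
    with pysam.AlignmentFile(tiny_sim.bam_path) as bam:
        for aln in bam.fetch("chr1"):
            if aln.is_secondary or aln.is_supplementary:
                continue
            reads.append({"pos": aln.reference_start,
                          "cigar": aln.cigarstring,
                          "flag": aln.flag})
    fwd, rev = brute_force_del_coverage(reads, 0, 120_000)
    np.testing.assert_array_equal(fm.counts[:, 1], fwd)
    np.testing.assert_array_equal(fm.counts[:, 11], rev)
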