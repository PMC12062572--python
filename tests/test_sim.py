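"""Simulator: determinism, construction invariants, labels, evaluation."""

import hashlib

import numpy as np
import pysam
import pytest

from svscout.calling import SVCall
from svscout.features import WindowBatch, N_CHANNELS
from svscout.sim import (SimConfig, SimConfigError, TruthVariant,
                         evaluate_calls, implant_svs, label_windows,
                         simulate, simulate_reference, _decode)

TYPES = ("DEL", "INS", "DUP", "INV", "TRA")


class TestReference:
    def test_deterministic_per_seed(self):
        a = simulate_reference(20_000, 5)
        b = simulate_reference(20_000, 5)
        assert all(np.array_equal(a[c], b[c]) for c in a)

    def test_different_seeds_diverge(self):
        a = simulate_reference(20_000, 5)["chr1"]
        b = simulate_reference(20_000, 6)["chr1"]
        assert (a != b).mean() > 0.2  # expected ~0.75

    def test_gc_fraction_concentrates(self):
        seq = simulate_reference(100_000, 1)["chr1"]
        gc = np.isin(seq, (1, 2)).mean()
        assert 0.45 <= gc <= 0.55

    def test_too_short_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_reference(5000, 1)


class TestImplant:
    def _config(self, **kw):
        base = dict(ref_length=150_000, n_contigs=2,
                    n_sv={t: 0 for t in TYPES},
                    size_range={t: (60, 500) for t in TYPES},
                    coverage=10.0, seed=9)
        base.update(kw)
        return SimConfig(**base)

    def test_homozygous_deletion_shortens_both_haplotypes(self):
        cfg = self._config(n_sv={"DEL": 1, "INS": 0, "DUP": 0, "INV": 0,
                                 "TRA": 0},
                           size_range={"DEL": (500, 500)}, het_fraction=0.0)
        ref = simulate_reference(cfg.ref_length, cfg.seed, 2)
        haps, truth = implant_svs(ref, cfg)
        assert len(truth) == 1 and truth[0].genotype == "1/1"
        contig = truth[0].contig
        for hap in haps:
            donor_len = sum(b.length for b in hap[contig])
            assert donor_len == len(ref[contig]) - 500

    def test_insertion_lengthens_donor(self):
        cfg = self._config(n_sv={"DEL": 0, "INS": 1, "DUP": 0, "INV": 0,
                                 "TRA": 0},
                           size_range={"INS": (300, 300)}, het_fraction=0.0)
        ref = simulate_reference(cfg.ref_length, cfg.seed, 2)
        haps, truth = implant_svs(ref, cfg)
        contig = truth[0].contig
        for hap in haps:
            donor_len = sum(b.length for b in hap[contig])
            assert donor_len == len(ref[contig]) + 300

    def test_truth_size_matches_request(self):
        cfg = self._config(n_sv={t: 2 for t in TYPES})
        ref = simulate_reference(cfg.ref_length, cfg.seed, 2)
        _, truth = implant_svs(ref, cfg)
        assert len(truth) == 10
        by_type = {t: sum(x.svtype == t for x in truth) for t in TYPES}
        assert all(v == 2 for v in by_type.values())

    def test_infeasible_load_raises(self):
        cfg = self._config(ref_length=12_000,
                           n_sv={"DEL": 50, "INS": 0, "DUP": 0, "INV": 0,
                                 "TRA": 0},
                           size_range={"DEL": (2000, 2000)})
        ref = simulate_reference(cfg.ref_length, cfg.seed, 2)
        with pytest.raises(SimConfigError):
            implant_svs(ref, cfg)

    def test_tra_requires_two_contigs(self):
        with pytest.raises(SimConfigError):
            self._config(n_contigs=1, n_sv={"TRA": 1, "DEL": 0, "INS": 0,
                                            "DUP": 0, "INV": 0})


class TestAlignments:
    def test_full_determinism_per_seed(self, tmp_path):
        cfg = SimConfig(ref_length=60_000, n_contigs=2,
                        n_sv={t: 1 for t in TYPES},
                        size_range={t: (60, 300) for t in TYPES},
                        coverage=8.0, seed=21)
        s1 = simulate(cfg, tmp_path / "a", write_fasta=False)
        s2 = simulate(cfg, tmp_path / "b", write_fasta=False)
        assert s1.truth == s2.truth

        def digest(path):
            h = hashlib.sha256()
            with pysam.AlignmentFile(path) as bam:
                for aln in bam:
                    h.update(aln.to_string().encode())
            return h.hexdigest()

        assert digest(s1.bam_path) == digest(s2.bam_path)

    def test_cigar_query_consistency_and_nm(self, tiny_sim):
        """Query-consuming CIGAR length equals SEQ length on every record."""
        with pysam.AlignmentFile(tiny_sim.bam_path) as bam:
            n = 0
            for aln in bam:
                q = sum(l for op, l in aln.cigartuples if op in (0, 1, 4, 7, 8))
                assert q == len(aln.query_sequence)
                assert aln.has_tag("NM")
                n += 1
        assert n > 0

    def test_mean_depth_tracks_requested_coverage(self, tiny_sim):
        with pysam.AlignmentFile(tiny_sim.bam_path) as bam:
            aligned = sum(a.reference_length or 0 for a in bam.fetch("chr1")
                          if not a.is_supplementary)
            depth = aligned / 120_000
        assert abs(depth - tiny_sim.config.coverage) <= 0.15 * tiny_sim.config.coverage

    def test_read_spanning_homozygous_del_carries_d_op(self, tmp_path):
        cfg = SimConfig(ref_length=60_000, n_contigs=2,
                        n_sv={"DEL": 1, "INS": 0, "DUP": 0, "INV": 0, "TRA": 0},
                        size_range={"DEL": (120, 120)},
                        het_fraction=0.0, coverage=15.0, seed=33)
        s = simulate(cfg, tmp_path, write_fasta=False)
        t = s.truth[0]
        hits = 0
        with pysam.AlignmentFile(s.bam_path) as bam:
            for aln in bam.fetch(t.contig, t.pos - 100, t.end + 100):
                if aln.reference_start < t.pos - 50 and \
                        (aln.reference_end or 0) > t.end + 50:
                    ref = aln.reference_start
                    for op, l in aln.cigartuples:
                        if op == 2 and l >= 110 and abs(ref - t.pos) <= 15:
                            hits += 1
                        if op in (0, 2, 3, 7, 8):
                            ref += l
        assert hits >= 0.5 * cfg.coverage

    def test_het_sv_alt_read_fraction_binomial(self, tmp_path):
        cfg = SimConfig(ref_length=60_000, n_contigs=2,
                        n_sv={"DEL": 1, "INS": 0, "DUP": 0, "INV": 0, "TRA": 0},
                        size_range={"DEL": (200, 200)},
                        het_fraction=1.0, coverage=30.0, seed=44)
        s = simulate(cfg, tmp_path, write_fasta=False)
        t = s.truth[0]
        assert t.genotype == "0/1"
        carriers = 0
        with pysam.AlignmentFile(s.bam_path) as bam:
            for aln in bam.fetch(t.contig, t.pos - 50, t.end + 50):
                if any(op == 2 and l >= 150 for op, l in aln.cigartuples):
                    carriers += 1
        assert 8 <= carriers <= 22  # ~15 expected at 30x het


class TestLabelsAndEvaluation:
    def test_labels_far_from_svs_are_zero(self):
        truth = [TruthVariant("DEL", "chr1", 50_000, 50_500, 500, "1/1")]
        w = WindowBatch("chr1", 0, np.zeros((10, 200, N_CHANNELS),
                                            dtype=np.float32))
        labels = label_windows(truth, [w])[0]
        assert not labels.any()

    def test_internal_del_labels_adjacent_blocks(self):
        truth = [TruthVariant("DEL", "chr1", 1000, 1500, 500, "1/1")]
        w = WindowBatch("chr1", 0, np.zeros((10, 200, N_CHANNELS),
                                            dtype=np.float32))
        labels = label_windows(truth, [w])[0]
        assert labels.sum() >= 2
        assert labels[5] == 1 and labels[6] == 1
        again = label_windows(truth, [w])[0]
        np.testing.assert_array_equal(labels, again)

    def _truth(self):
        return [TruthVariant("DEL", "chr1", 10_000, 10_400, 400, "1/1"),
                TruthVariant("INS", "chr1", 30_000, 30_000, 250, "0/1"),
                TruthVariant("TRA", "chr1", 50_000, 50_000, 0, "1/1",
                             mate_contig="chr2", mate_pos=70_000)]

    def _call_from(self, t, dpos=0, dlen=0):
        svtype = "BND" if t.svtype == "TRA" else t.svtype
        return SVCall(contig=t.contig, pos=t.pos + dpos, end=t.end + dpos,
                      svtype=svtype, svlen=t.length + dlen, support=10,
                      genotype=t.genotype, filter="PASS",
                      min_support_threshold=3, mate_contig=t.mate_contig,
                      mate_pos=t.mate_pos)

    def test_perfect_calls_score_one(self):
        truth = self._truth()
        m = evaluate_calls([self._call_from(t) for t in truth], truth)
        assert m["overall"].precision == m["overall"].recall == 1.0
        assert m["overall"].f1 == 1.0

    def test_empty_calls_zero_recall_and_reported_zero_precision(self):
        truth = self._truth()
        m = evaluate_calls([], truth)
        assert m["overall"].recall == 0.0
        assert m["overall"].precision == 0.0

    def test_boundary_tolerance_inclusive(self):
        truth = [self._truth()[0]]
        exact = evaluate_calls([self._call_from(truth[0], dpos=500)], truth,
                               pos_tolerance=500)
        assert exact["DEL"].tp == 1
        over = evaluate_calls([self._call_from(truth[0], dpos=501)], truth,
                              pos_tolerance=500)
        assert over["DEL"].tp == 0

    def test_length_ratio_gate(self):
        truth = [self._truth()[0]]  # length 400
        bad = evaluate_calls([self._call_from(truth[0], dlen=-250)], truth,
                             len_ratio=0.7)
        assert bad["DEL"].tp == 0  # 150/400 < 0.7

    def test_matching_is_one_to_one(self):
        truth = [self._truth()[0]]
        calls = [self._call_from(truth[0]), self._call_from(truth[0], dpos=50)]
        m = evaluate_calls(calls, truth)
        assert m["DEL"].tp == 1 and m["DEL"].fp == 1
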