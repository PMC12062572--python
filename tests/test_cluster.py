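"""Mean-shift clustering, bandwidth policy, length refinement, TRA pairing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svscout.cluster import (ClusterConfig, mean_shift, pair_translocations,
                             refine_by_length, select_bandwidth,
                             cluster_signatures)
from svscout.signatures import SVSignature


def grid_kde_mode_oracle(positions, bandwidth):
    """Exhaustive 1-unit-grid KDE oracle, independent of mean shift.

    Density is evaluated on an integer grid; each point hill-climbs the
    discrete density to a local maximum; maxima closer than bandwidth/2
    merge (ties toward the smaller coordinate).  Returns the partition of
    input indices as a set of frozensets.
    """
    pts = np.asarray(positions, dtype=float)
    grid = np.arange(np.floor(pts.min()), np.ceil(pts.max()) + 1)
    dens = np.exp(-0.5 * ((grid[:, None] - pts[None, :]) / bandwidth) ** 2).sum(1)

    def climb(i):
        while True:
            if i > 0 and dens[i - 1] > dens[i]:
                i -= 1
            elif i + 1 < len(dens) and dens[i + 1] > dens[i]:
                i += 1
            else:
                return i

    peak = [climb(int(round(p - grid[0]))) for p in pts]
    # merge peaks within bandwidth/2, smaller coordinate first
    labels = {}
    for p in sorted(set(peak)):
        for q in labels:
            if abs(grid[p] - grid[q]) < bandwidth / 2:
                labels[p] = labels[q]
                break
        else:
            labels[p] = p
    groups = {}
    for idx, p in enumerate(peak):
        groups.setdefault(labels[p], []).append(idx)
    return {frozenset(g) for g in groups.values()}


def _partition(clusters):
    return {frozenset(c["indices"]) for c in clusters}


class TestMeanShift:
    def test_degenerate_identical_points(self):
        out = mean_shift([500, 500, 500], 1000)
        assert len(out) == 1 and out[0]["mode"] == pytest.approx(500)

    def test_two_well_separated_groups(self):
        out = mean_shift([100, 110, 120, 5000, 5010], 300)
        assert _partition(out) == {frozenset({0, 1, 2}), frozenset({3, 4})}
        assert out[0]["mode"] == pytest.approx(110, abs=5)
        assert out[1]["mode"] == pytest.approx(5005, abs=5)

    def test_singleton(self):
        out = mean_shift([42], 500)
        assert len(out) == 1 and out[0]["mode"] == pytest.approx(42, abs=1)

    def test_empty_and_bad_bandwidth(self):
        assert mean_shift([], 100) == []
        with pytest.raises(ValueError):
            mean_shift([1, 2], 0)

    def test_matches_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        mismatches = 0
        for trial in range(200):
            n = int(rng.integers(2, 21))
            pts = np.sort(rng.uniform(0, 10_000, n)).tolist()
            bw = float(rng.choice([300, 500, 1000, 1500]))
            got = _partition(mean_shift(pts, bw))
            want = grid_kde_mode_oracle(pts, bw)
            if got != want:
                mismatches += 1
        assert mismatches == 0

    def test_shift_equivariance_and_permutation_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 5000, 15).tolist()
        base = mean_shift(pts, 400)
        shifted = mean_shift([p + 1234.5 for p in pts], 400)
        assert _partition(base) == _partition(shifted)
        for b, s in zip(base, shifted):
            assert s["mode"] - b["mode"] == pytest.approx(1234.5, abs=1e-6)
        perm = list(range(len(pts)))[::-1]
        out_perm = mean_shift([pts[i] for i in perm], 400)
        remapped = {frozenset(perm[i] for i in c["indices"]) for c in out_perm}
        assert remapped == _partition(base)


class TestBandwidthPolicy:
    @pytest.mark.parametrize("svtype,expect", [
        ("DEL", 1000), ("INS", 300), ("DUP", 500), ("INV", 500)])
    def test_per_type_defaults_at_high_error(self, svtype, expect):
        assert select_bandwidth(svtype, 0.15) == expect

    def test_low_error_reads_widen_to_1500(self):
        for svtype in ("DEL", "INS", "DUP", "INV"):
            assert select_bandwidth(svtype, 0.05) == 1500

    def test_breakends_rejected(self):
        with pytest.raises(ValueError):
            select_bandwidth("BND", 0.15)


def _sig(svtype, pos, length, name, contig="c"):
    return SVSignature(svtype, contig, pos, length, name)


class TestRefineByLength:
    def test_uniform_lengths_stay_together(self):
        members = [_sig("DEL", 100, 100, f"r{i}") for i in range(3)]
        assert len(refine_by_length(members, 0.7)) == 1

    def test_disparate_lengths_split(self):
        members = [_sig("DEL", 100, 100, "a"), _sig("DEL", 100, 500, "b")]
        subs = refine_by_length(members, 0.7)  # median 300, threshold 210
        assert [len(s) for s in subs] == [1, 1]

    def test_single_member(self):
        assert len(refine_by_length([_sig("DEL", 5, 80, "a")], 0.7)) == 1

    def test_partition_is_exact(self):
        rng = np.random.default_rng(3)
        members = [_sig("INS", 10, int(l), f"r{i}")
                   for i, l in enumerate(rng.integers(50, 2000, 25))]
        subs = refine_by_length(members, 0.7)
        flat = [m for s in subs for m in s]
        assert sorted(id(m) for m in flat) == sorted(id(m) for m in members)

    @given(st.lists(st.integers(50, 3000), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_subcluster_count_monotone_in_ratio(self, lengths):
        members = [_sig("DEL", 0, l, f"r{i}") for i, l in enumerate(lengths)]
        counts = [len(refine_by_length(members, r))
                  for r in (1.0, 0.7, 0.4, 0.1)]
        assert counts == sorted(counts)


class TestTranslocationPairing:
    def test_co_located_pairs_cluster(self):
        a = SVSignature("BND", "A", 1000, 0, "r1", mate_contig="B", mate_pos=5000)
        b = SVSignature("BND", "A", 1010, 0, "r2", mate_contig="B", mate_pos=5005)
        out = pair_translocations([a, b], 1000)
        assert len(out) == 1
        assert out[0].mode_position == pytest.approx(1005)
        assert out[0].mate_position == pytest.approx(5002.5)

    def test_different_contig_pairs_stay_apart(self):
        a = SVSignature("BND", "A", 1000, 0, "r1", mate_contig="B", mate_pos=5000)
        b = SVSignature("BND", "A", 1000, 0, "r2", mate_contig="C", mate_pos=5000)
        assert len(pair_translocations([a, b], 1000)) == 2

    def test_empty_input(self):
        assert pair_translocations([], 1000) == []

    def test_swapped_ends_canonicalised_together(self):
        a = SVSignature("BND", "A", 1000, 0, "r1", mate_contig="B", mate_pos=5000)
        b = SVSignature("BND", "B", 5003, 0, "r2", mate_contig="A", mate_pos=997)
        out = pair_translocations([a, b], 1000)
        assert len(out) == 1 and out[0].contig == "A" and out[0].mate_contig == "B"


def test_cluster_signatures_groups_by_contig_and_type():
    sigs = ([_sig("DEL", 1000 + i, 200, f"a{i}") for i in range(5)] +
            [_sig("DEL", 50_000 + i, 300, f"b{i}") for i in range(5)] +
            [_sig("DEL", 1000 + i, 200, f"c{i}", contig="d")
             for i in range(3)] +
            [_sig("INS", 1000, 100, "x")])
    clusters = cluster_signatures(sigs, "DEL", mean_error_rate=0.15)
    assert len(clusters) == 3
    assert all(c.svtype == "DEL" for c in clusters)
    for c in clusters:
        assert sum(len(s) for s in c.subclusters) == len(c.members)
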