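"""Breakpoint clustering.

Signatures of one SV event scatter around the true breakpoint because of
sequencing error and alignment ambiguity.  They are grouped by mean-shift
mode seeking on the breakpoint coordinate under a Gaussian kernel whose
bandwidth depends on SV type and on the sample's mean read error rate:
1000 bp for DEL, 300 bp for INS, 500 bp for DUP and INV, widened to
1500 bp for low-error (< 0.10) reads.  Each positional cluster is then
refined by length: members are sorted by SV length and split into
subclusters wherever the next length differs from the subcluster's first
member by at least ``median_length * length_ratio`` (default ratio 0.7).
Translocation breakends carry two coordinates and are paired directly on
position instead of density clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signatures import SVSignature


@dataclass
class ClusterConfig:
    bandwidth_del: float = 1000.0
    bandwidth_ins: float = 300.0
    bandwidth_dup: float = 500.0
    bandwidth_inv: float = 500.0
    high_quality_bandwidth: float = 1500.0
    high_quality_error_cutoff: float = 0.10
    length_ratio: float = 0.7
    tra_tolerance: float = 1000.0

    def __post_init__(self):
        for bw in (self.bandwidth_del, self.bandwidth_ins, self.bandwidth_dup,
                   self.bandwidth_inv, self.high_quality_bandwidth):
            if bw <= 0:
                raise ValueError("bandwidths must be positive")
        if not (0.0 < self.length_ratio <= 1.0):
            raise ValueError("length_ratio must be in (0, 1]")


@dataclass
class SVCluster:
    svtype: str
    members: list[SVSignature]
    mode_position: float
    contig: str = ""
    median_length: float = 0.0
    subclusters: list[list[SVSignature]] = field(default_factory=list)
    # TRA clusters carry the paired end
    mate_contig: str | None = None
    mate_position: float | None = None


def select_bandwidth(svtype: str, mean_error_rate: float,
                     config: ClusterConfig | None = None) -> float:
    """Bandwidth for one SV type given the sample's mean read error rate."""
    config = config or ClusterConfig()
    if svtype == "BND":
        raise ValueError("translocations are paired positionally, not density-clustered")
    table = {"DEL": config.bandwidth_del, "INS": config.bandwidth_ins,
             "DUP": config.bandwidth_dup, "INV": config.bandwidth_inv}
    if svtype not in table:
        raise ValueError(f"unknown svtype {svtype!r}")
    if mean_error_rate < config.high_quality_error_cutoff:
        return config.high_quality_bandwidth
    return table[svtype]


def mean_shift(positions, bandwidth: float,
               tol: float = 0.01, max_iter: int = 2000) -> list[dict]:
    """Gaussian-kernel mean-shift clustering of 1-D breakpoint positions.

    Every point ascends the kernel density estimate until its shift drops
    below ``tol`` or ``max_iter`` iterations (the tolerance is well below
    1 bp so trajectories do not stall on shallow density shoulders);
    points whose modes land within ``bandwidth / 2`` of each other share
    a cluster.  Returns
    one dict per cluster with keys ``mode`` and ``indices`` (into the
    input), ordered by mode.  Ties in mode merging resolve toward the
    smaller coordinate.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.size == 0:
        return []
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = pts.copy()
    active = np.ones(pts.size, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        d = x[active, None] - pts[None, :]
        w = np.exp(-0.5 * (d / bandwidth) ** 2)
        new = (w @ pts) / w.sum(axis=1)
        shift = np.abs(new - x[active])
        x[active] = new
        still = shift >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    order = np.argsort(x, kind="stable")
    clusters: list[dict] = []
    for i in order:
        if clusters and x[i] - clusters[-1]["_anchor"] < bandwidth / 2.0:
            clusters[-1]["indices"].append(int(i))
        else:
            clusters.append({"_anchor": x[i], "indices": [int(i)]})
    for c in clusters:
        member_modes = x[c["indices"]]
        c["mode"] = float(np.median(member_modes))
        del c["_anchor"]
        c["indices"].sort()
    clusters.sort(key=lambda c: c["mode"])
    return clusters


def refine_by_length(members: list[SVSignature],
                     length_ratio: float = 0.7) -> list[list[SVSignature]]:
    """Split a positional cluster into length-homogeneous subclusters.

    Members are scanned in ascending length order; a new subcluster opens
    whenever the next length differs from the open subcluster's first
    (shortest) member by at least the cluster median length times
    ``length_ratio``.
    """
    if not members:
        return []
    ordered = sorted(members, key=lambda s: (s.length, s.pos, s.read_name))
    median = float(np.median([s.length for s in ordered]))
    threshold = median * length_ratio
    subclusters: list[list[SVSignature]] = [[ordered[0]]]
    for sig in ordered[1:]:
        if sig.length - subclusters[-1][0].length < threshold:
            subclusters[-1].append(sig)
        else:
            subclusters.append([sig])
    return subclusters


def cluster_signatures(signatures: list[SVSignature], svtype: str,
                       mean_error_rate: float,
                       config: ClusterConfig | None = None) -> list[SVCluster]:
    """Mean-shift + length refinement for one intra-contig SV type."""
    config = config or ClusterConfig()
    sigs = [s for s in signatures if s.svtype == svtype]
    if not sigs:
        return []
    bandwidth = select_bandwidth(svtype, mean_error_rate, config)
    out: list[SVCluster] = []
    by_contig: dict[str, list[SVSignature]] = {}
    for s in sigs:
        by_contig.setdefault(s.contig, []).append(s)
    for contig in sorted(by_contig):
        group = sorted(by_contig[contig],
                       key=lambda s: (s.pos, s.length, s.read_name))
        for c in mean_shift([s.pos for s in group], bandwidth):
            members = [group[i] for i in c["indices"]]
            cluster = SVCluster(
                svtype=svtype, members=members, mode_position=c["mode"],
                contig=contig,
                median_length=float(np.median([m.length for m in members])),
            )
            cluster.subclusters = refine_by_length(members, config.length_ratio)
            out.append(cluster)
    return out


def pair_translocations(bnd_signatures: list[SVSignature],
                        tra_tolerance: float = 1000.0) -> list[SVCluster]:
    """Group breakend signatures whose two ends co-locate.

    Two breakends join a cluster iff they connect the same ordered contig
    pair and both positional differences to the cluster's running medians
    are within ``tra_tolerance``.  Cluster breakpoints are the medians of
    each end.
    """
    canon: dict[tuple[str, str], list[tuple[int, int, SVSignature]]] = {}
    for s in bnd_signatures:
        if s.svtype != "BND":
            raise ValueError("pair_translocations accepts only BND signatures")
        end1 = (s.contig, s.pos)
        end2 = (s.mate_contig, s.mate_pos)
        if end2 < end1:
            end1, end2 = end2, end1
        canon.setdefault((end1[0], end2[0]), []).append((end1[1], end2[1], s))

    clusters: list[SVCluster] = []
    for (c1, c2) in sorted(canon):
        groups: list[dict] = []
        for p1, p2, sig in sorted(canon[(c1, c2)], key=lambda t: (t[0], t[1])):
            placed = False
            for g in groups:
                if (abs(p1 - np.median(g["p1"])) <= tra_tolerance and
                        abs(p2 - np.median(g["p2"])) <= tra_tolerance):
                    g["p1"].append(p1)
                    g["p2"].append(p2)
                    g["members"].append(sig)
                    placed = True
                    break
            if not placed:
                groups.append({"p1": [p1], "p2": [p2], "members": [sig]})
        for g in groups:
            clusters.append(SVCluster(
                svtype="BND", members=g["members"],
                mode_position=float(np.median(g["p1"])), contig=c1,
                mate_contig=c2, mate_position=float(np.median(g["p2"])),
            ))
            clusters[-1].subclusters = [g["members"]]
    return clusters
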