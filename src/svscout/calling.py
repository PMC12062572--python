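"""Variant calling: dynamic read-support filtering and genotyping.

A subcluster becomes a call when its distinct supporting reads reach a
coverage-adaptive threshold

    min_support = ceil( mu * C_global**phi * (1 + rho * tanh((C_local - C_global) / C_global)) )

clamped below at ``floor``.  C_global is the genome-wide mean depth,
C_local the depth around the locus; in the high-error / low-coverage
regime (read error rate >= 0.10 or C_global < 10) a softer parameter set
(mu, rho) is substituted so sparse but genuine signals survive.

Genotypes are decided by majority vote over three methods — Bayesian
posterior (binomial likelihood times configurable priors), an EM
reweighting of the genotype mixture, and the simple read-support ratio
rule (ref fraction > 0.7 -> 0/0, alt fraction > 0.7 -> 1/1, else 0/1) —
with the Bayesian result breaking three-way ties.  The pure-likelihood
argmax is retained as a diagnostic alongside the votes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.stats import binom

from .cluster import SVCluster
from .features import DEFAULT_MIN_MAPQ

GENOTYPES = ("0/0", "0/1", "1/1")

DEFAULT_MIN_SVLEN = 50


@dataclass
class SupportModelParams:
    """Parameters of the dynamic minimum-support formula."""

    mu: float = 1.0
    phi: float = 0.6  # coverage power exponent
    rho: float = 0.4
    error_rate_cutoff: float = 0.10
    low_coverage_cutoff: float = 10.0
    adjusted_mu: float = 0.8
    adjusted_rho: float = 0.3
    floor: int = 2

    def __post_init__(self):
        if self.mu <= 0 or not (0 < self.phi <= 1) or self.rho < 0:
            raise ValueError("require mu > 0, 0 < phi <= 1, rho >= 0")
        if self.floor < 1:
            raise ValueError("floor must be >= 1")

    def effective(self, c_global: float, error_rate: float) -> tuple[float, float]:
        """(mu, rho) after the high-error / low-coverage regime switch."""
        if error_rate >= self.error_rate_cutoff or c_global < self.low_coverage_cutoff:
            return self.adjusted_mu, self.adjusted_rho
        return self.mu, self.rho


@dataclass
class GenotypeEvidence:
    ref_support: int
    alt_support: int
    epsilon: float

    def __post_init__(self):
        if self.ref_support < 0 or self.alt_support < 0:
            raise ValueError("supports must be non-negative")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")

    @property
    def total(self) -> int:
        return self.ref_support + self.alt_support


@dataclass
class SVCall:
    contig: str
    pos: int
    end: int
    svtype: str
    svlen: int
    support: int
    genotype: str
    filter: str
    min_support_threshold: int
    method_votes: dict = field(default_factory=dict)
    mate_contig: str | None = None
    mate_pos: int | None = None
    likelihood_argmax: str | None = None


def min_support(c_global: float, c_local: float,
                params: SupportModelParams | None = None,
                error_rate: float = 0.0) -> int:
    """Dynamic minimum supporting-read threshold for one locus."""
    params = params or SupportModelParams()
    if c_global <= 0:
        raise ValueError("c_global must be positive")
    if c_local < 0:
        raise ValueError("c_local must be non-negative")
    mu, rho = params.effective(c_global, error_rate)
    raw = mu * c_global ** params.phi * (
        1.0 + rho * math.tanh((c_local - c_global) / c_global))
    return max(params.floor, math.ceil(raw - 1e-9))


# -- genotyping --------------------------------------------------------------

def _alt_probs(epsilon: float) -> dict[str, float]:
    return {"0/0": epsilon, "0/1": 0.5, "1/1": 1.0 - epsilon}


def genotype_likelihoods(evidence: GenotypeEvidence) -> dict[str, float]:
    """Binomial log-likelihood of the alt read count under each genotype."""
    if evidence.total == 0:
        raise ValueError("cannot genotype a locus with zero informative reads")
    n, k = evidence.total, evidence.alt_support
    return {gt: float(binom.logpmf(k, n, p))
            for gt, p in _alt_probs(evidence.epsilon).items()}


def genotype_bayes(likelihoods: dict[str, float],
                   priors: dict[str, float] | None = None,
                   ) -> tuple[str, dict[str, float]]:
    """Posterior-argmax genotype from log-likelihoods and priors."""
    priors = priors or {"0/0": 0.4, "0/1": 0.4, "1/1": 0.2}
    if abs(sum(priors.values()) - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    log_post = {gt: likelihoods[gt] + math.log(priors[gt]) if priors[gt] > 0
                else -math.inf for gt in GENOTYPES}
    m = max(log_post.values())
    if not math.isfinite(m):
        raise ValueError("zero posterior normalization")
    unnorm = {gt: math.exp(lp - m) for gt, lp in log_post.items()}
    z = sum(unnorm.values())
    post = {gt: v / z for gt, v in unnorm.items()}
    best = max(GENOTYPES, key=lambda gt: post[gt])
    return best, post


def genotype_em(evidence: GenotypeEvidence, max_iter: int = 100,
                tol: float = 1e-6) -> tuple[str, dict[str, float], bool]:
    """EM reweighting of the genotype mixture for one locus.

    E-step: responsibilities of each genotype for the observed counts
    under the current weights; M-step: weights <- responsibilities.
    Returns (argmax genotype, final weights, converged flag).
    """
    lik = {gt: math.exp(v) for gt, v in genotype_likelihoods(evidence).items()}
    weights = {gt: 1.0 / 3.0 for gt in GENOTYPES}
    converged = False
    for _ in range(max_iter):
        resp = {gt: weights[gt] * lik[gt] for gt in GENOTYPES}
        z = sum(resp.values())
        if z <= 0:
            break
        new = {gt: r / z for gt, r in resp.items()}
        delta = max(abs(new[gt] - weights[gt]) for gt in GENOTYPES)
        weights = new
        if delta < tol:
            converged = True
            break
    best = max(GENOTYPES, key=lambda gt: weights[gt])
    return best, weights, converged


def genotype_ratio(evidence: GenotypeEvidence, threshold: float = 0.7) -> str:
    """Read-support ratio rule."""
    if evidence.total == 0:
        raise ValueError("cannot genotype a locus with zero informative reads")
    ref_frac = evidence.ref_support / evidence.total
    if ref_frac > threshold:
        return "0/0"
    if 1.0 - ref_frac > threshold:
        return "1/1"
    return "0/1"


def genotype_vote(bayes_result: str, em_result: str, ratio_result: str) -> str:
    """Majority vote; a three-way tie falls back to the Bayesian result."""
    votes = (bayes_result, em_result, ratio_result)
    for gt in GENOTYPES:
        if votes.count(gt) >= 2:
            return gt
    return bayes_result


def genotype_locus(evidence: GenotypeEvidence,
                   priors: dict[str, float] | None = None,
                   ratio_threshold: float = 0.7) -> tuple[str, dict[str, str]]:
    """Run all methods on one locus; returns (final genotype, per-method)."""
    lik = genotype_likelihoods(evidence)
    bayes_gt, _ = genotype_bayes(lik, priors)
    em_gt, _, _ = genotype_em(evidence)
    ratio_gt = genotype_ratio(evidence, ratio_threshold)
    final = genotype_vote(bayes_gt, em_gt, ratio_gt)
    votes = {"bayes": bayes_gt, "em": em_gt, "ratio": ratio_gt,
             "likelihood": max(GENOTYPES, key=lambda g: lik[g])}
    return final, votes


# -- coverage bookkeeping ----------------------------------------------------

class AlignmentCoverage:
    """Primary-read interval index for global/local depth and spanning reads."""

    def __init__(self, alignment_source, min_mapq: int = DEFAULT_MIN_MAPQ):
        bam = (alignment_source if isinstance(alignment_source, pysam.AlignmentFile)
               else pysam.AlignmentFile(alignment_source))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._names: dict[str, np.ndarray] = {}
        total_bases = 0
        error_rates: list[float] = []
        for contig in bam.references:
            starts, ends, names = [], [], []
            for aln in bam.fetch(contig):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.mapping_quality < min_mapq:
                    continue
                starts.append(aln.reference_start)
                ends.append(aln.reference_end)
                names.append(aln.query_name)
                total_bases += aln.reference_end - aln.reference_start
                if aln.has_tag("NM") and aln.query_alignment_length:
                    error_rates.append(aln.get_tag("NM") / aln.query_alignment_length)
            self._starts[contig] = np.asarray(starts, dtype=np.int64)
            self._ends[contig] = np.asarray(ends, dtype=np.int64)
            self._names[contig] = np.asarray(names, dtype=object)
        total_len = sum(bam.lengths)
        self.global_coverage = total_bases / total_len if total_len else 0.0
        self.mean_error_rate = float(np.mean(error_rates)) if error_rates else 0.0

    def local_coverage(self, contig: str, lo: int, hi: int) -> float:
        if contig not in self._starts or hi <= lo:
            return 0.0
        s, e = self._starts[contig], self._ends[contig]
        overlap = np.clip(np.minimum(e, hi) - np.maximum(s, lo), 0, None)
        return float(overlap.sum()) / (hi - lo)

    def spanning_reads(self, contig: str, lo: int, hi: int) -> set[str]:
        if contig not in self._starts:
            return set()
        s, e = self._starts[contig], self._ends[contig]
        mask = (s <= lo) & (e >= hi)
        return set(self._names[contig][mask])


# -- cluster -> call ---------------------------------------------------------

def call_variants(
    clusters: list[SVCluster],
    coverage: AlignmentCoverage,
    params: SupportModelParams | None = None,
    priors: dict[str, float] | None = None,
    min_svlen: int = DEFAULT_MIN_SVLEN,
    local_window: int = 500,
    span_flank: int = 50,
) -> list[SVCall]:
    """Turn subclusters into filtered, genotyped calls.

    Support is the number of distinct reads in a subcluster (each read
    contributes at most one signature per type there by construction).
    A call PASSes when support reaches the dynamic threshold and, for
    intra-contig types, the median length reaches ``min_svlen``; failed
    records are retained with a filter label.
    """
    params = params or SupportModelParams()
    calls: list[SVCall] = []
    for cluster in clusters:
        for members in (cluster.subclusters or [cluster.members]):
            if not members:
                continue
            read_names = {m.read_name for m in members}
            support = len(read_names)
            err = float(np.mean([m.read_error_rate for m in members]))
            if cluster.svtype == "BND":
                # both breakend ends come from the cluster's canonical medians
                pos = int(round(cluster.mode_position))
                end = pos
                svlen = 0
                mate_contig = cluster.mate_contig
                mate_pos = int(round(cluster.mate_position))
            else:
                pos = int(round(float(np.median([m.pos for m in members]))))
                svlen = int(round(float(np.median([m.length for m in members]))))
                end = pos + (svlen if cluster.svtype in ("DEL", "DUP", "INV") else 0)
                mate_contig = mate_pos = None

            c_local = coverage.local_coverage(
                cluster.contig, pos - local_window, max(end, pos) + local_window)
            threshold = min_support(max(coverage.global_coverage, 1e-6), c_local,
                                    params, error_rate=err)

            spanning = coverage.spanning_reads(
                cluster.contig, pos - span_flank, max(end, pos) + span_flank)
            ref_reads = spanning - read_names
            epsilon = min(max(coverage.mean_error_rate, 0.02), 0.45)
            if support + len(ref_reads) > 0:
                evidence = GenotypeEvidence(len(ref_reads), support, epsilon)
                genotype, votes = genotype_locus(evidence, priors)
            else:
                genotype, votes = "./.", {}

            if support < threshold:
                status = "MinSupport"
            elif cluster.svtype != "BND" and svlen < min_svlen:
                status = "MinLength"
            else:
                status = "PASS"
            calls.append(SVCall(
                contig=cluster.contig, pos=pos, end=max(end, pos),
                svtype=cluster.svtype, svlen=svlen, support=support,
                genotype=genotype, filter=status,
                min_support_threshold=threshold, method_votes=votes,
                mate_contig=mate_contig, mate_pos=mate_pos,
                likelihood_argmax=votes.get("likelihood"),
            ))
    calls.sort(key=lambda c: (c.contig, c.pos, c.svtype, c.svlen))
    return calls
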