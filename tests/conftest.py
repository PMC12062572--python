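"""Shared fixtures: hand-built alignment files and session-scoped
pipeline runs reused across the suite (training and benchmark
simulations are expensive, so they are computed once)."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pysam
import pytest

from svscout.model import save_model
from svscout.pipeline import (call_pipeline, default_training_sims,
                              train_default_model, training_sim_config,
                              ablation_study)
from svscout.sim import SimConfig, evaluate_calls, simulate

TRAIN_SEED = 7          # independent of the benchmark SimConfig seed (1)
BENCH_SEED = 1


def make_bam(path, contigs: dict[str, int], reads: list[dict]) -> str:
    """Write a small sorted+indexed BAM from read dicts.

    Each dict: qname, contig, pos (0-based), cigar; optional flag, mapq,
    tags (dict), seq.  The sequence defaults to 'A' * query length.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": l} for c, l in contigs.items()],
    })
    path = str(path)
    tmp = path + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r["qname"]
            a.reference_name = r["contig"]
            a.reference_start = r["pos"]
            a.cigarstring = r["cigar"]
            a.flag = r.get("flag", 0)
            a.mapping_quality = r.get("mapq", 60)
            qlen = a.infer_query_length() or 0
            a.query_sequence = r.get("seq", "A" * qlen)
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            for tag, value in r.get("tags", {}).items():
                a.set_tag(tag, value)
            fh.write(a)
    pysam.sort("-o", path, tmp)
    pysam.index(path)
    return path


@pytest.fixture()
def bam_factory(tmp_path):
    counter = [0]

    def _make(contigs, reads):
        counter[0] += 1
        return make_bam(tmp_path / f"t{counter[0]}.bam", contigs, reads)

    return _make


# -- session-scoped heavy artefacts -----------------------------------------

@pytest.fixture(scope="session")
def trained(tmp_path_factory):
    """Default full model trained on the built-in protocol (seed 7)."""
    workdir = tmp_path_factory.mktemp("train")
    model, metrics = train_default_model(TRAIN_SEED, workdir)
    model_path = workdir / "model.npz"
    save_model(model, model_path)
    return SimpleNamespace(model=model, metrics=metrics, path=model_path)


@pytest.fixture(scope="session")
def default_benchmark(tmp_path_factory, trained):
    """Default-condition benchmark: 2x1 Mb, 20 SVs/type, 30x, error 0.10."""
    outdir = tmp_path_factory.mktemp("bench")
    sim = simulate(SimConfig(seed=BENCH_SEED), outdir, write_fasta=False)
    calls, report = call_pipeline(sim.bam_path, trained.model)
    metrics = evaluate_calls(calls, sim.truth, pos_tolerance=500, len_ratio=0.7)
    return SimpleNamespace(sim=sim, calls=calls, report=report, metrics=metrics)


@pytest.fixture(scope="session")
def lowcov_benchmark(tmp_path_factory, trained):
    """Same conditions at 5x coverage (robustness check)."""
    outdir = tmp_path_factory.mktemp("bench5x")
    sim = simulate(SimConfig(seed=BENCH_SEED, coverage=5.0), outdir,
                   write_fasta=False)
    calls, report = call_pipeline(sim.bam_path, trained.model)
    metrics = evaluate_calls(calls, sim.truth, pos_tolerance=500, len_ratio=0.7)
    return SimpleNamespace(sim=sim, calls=calls, report=report, metrics=metrics)


@pytest.fixture(scope="session")
def negative_run(tmp_path_factory, trained):
    """SV-free simulation at 30x: the self-alignment negative control."""
    outdir = tmp_path_factory.mktemp("negctl")
    cfg = SimConfig(seed=97, n_sv={t: 0 for t in
                                   ("DEL", "INS", "DUP", "INV", "TRA")})
    sim = simulate(cfg, outdir, write_fasta=False)
    calls, report = call_pipeline(sim.bam_path, trained.model)
    return SimpleNamespace(sim=sim, calls=calls, report=report)


@pytest.fixture(scope="session")
def ablation(tmp_path_factory):
    """Three-variant ablation on one synthetic split."""
    workdir = tmp_path_factory.mktemp("ablation")
    train_sims = default_training_sims(TRAIN_SEED, workdir)
    val_sim = simulate(training_sim_config(84, 20.0), workdir / "val",
                       write_fasta=False)
    return ablation_study(train_sims, val_sim, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """Small, fast simulation for unit-level checks."""
    outdir = tmp_path_factory.mktemp("tinysim")
    cfg = SimConfig(
        ref_length=120_000, n_contigs=2,
        n_sv={t: 3 for t in ("DEL", "INS", "DUP", "INV", "TRA")},
        size_range={"DEL": (60, 800), "INS": (60, 800), "DUP": (60, 800),
                    "INV": (60, 800), "TRA": (0, 0)},
        coverage=20.0, seed=3)
    return simulate(cfg, outdir)
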