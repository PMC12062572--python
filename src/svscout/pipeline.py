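"""End-to-end orchestration: BAM -> features -> model -> signatures ->
clusters -> calls.

Contigs are processed independently in deterministic header order;
feature extraction is chunked (chunk boundaries fall on window
boundaries, and per-site counts are chunk-independent) so memory stays
bounded on long contigs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pysam

from .calling import (AlignmentCoverage, SVCall, SupportModelParams,
                      call_variants, DEFAULT_MIN_SVLEN)
from .cluster import ClusterConfig, cluster_signatures, pair_translocations
from .features import WINDOW_SIZE, extract_site_features, tile_windows
from .model import (ModelConfig, WindowClassifier, predictions_to_regions,
                    predict_windows, train_model)
from .signatures import SVSignature, extract_signatures
from .sim import Simulation, label_windows

log = logging.getLogger("svscout")

CHUNK = 100 * WINDOW_SIZE  # 200 kb


@dataclass
class CallReport:
    n_windows: int = 0
    n_candidate_regions: int = 0
    n_signatures: int = 0
    counts_by_type: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


def iter_windows(bam_path, contig: str, length: int, chunk: int = CHUNK):
    """Tiled WindowBatches over one contig, in coordinate order."""
    for lo in range(0, length, chunk):
        hi = min(lo + chunk, length)
        fm = extract_site_features(bam_path, (contig, lo, hi))
        yield from tile_windows(fm)


def contig_windows(bam_path, contigs: dict[str, int]):
    for contig in contigs:
        yield from iter_windows(bam_path, contig, contigs[contig])


def _dedup_signatures(sigs: list[SVSignature]) -> list[SVSignature]:
    seen = set()
    out = []
    for s in sigs:
        if s.svtype == "BND":
            # the same junction is seen once from each side; canonicalise
            ends = sorted([(s.contig, s.pos), (s.mate_contig, s.mate_pos)])
            key = (s.read_name, "BND", *ends[0], *ends[1])
        else:
            key = (s.read_name, s.svtype, s.contig, s.pos, s.length)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def call_pipeline(
    bam_path,
    model: WindowClassifier,
    support_params: SupportModelParams | None = None,
    cluster_config: ClusterConfig | None = None,
    priors: dict[str, float] | None = None,
    min_svlen: int = DEFAULT_MIN_SVLEN,
    max_gap: int = 0,
) -> tuple[list[SVCall], CallReport]:
    """Run the full calling pipeline on a sorted, indexed BAM."""
    cluster_config = cluster_config or ClusterConfig()
    report = CallReport()
    t0 = time.time()

    with pysam.AlignmentFile(str(bam_path)) as bam:
        contigs = dict(zip(bam.references, bam.lengths))

    predictions = []
    for contig, length in contigs.items():
        batches = list(iter_windows(bam_path, contig, length))
        report.n_windows += len(batches)
        predictions.extend(predict_windows(batches, model))
    report.stage_seconds["features_and_model"] = round(time.time() - t0, 2)

    t1 = time.time()
    regions = predictions_to_regions(
        predictions, model.config.positive_threshold, max_gap)
    report.n_candidate_regions = len(regions)

    signatures: list[SVSignature] = []
    for region in regions:
        signatures.extend(extract_signatures(bam_path, region))
    signatures = _dedup_signatures(signatures)
    report.n_signatures = len(signatures)
    report.stage_seconds["signatures"] = round(time.time() - t1, 2)

    t2 = time.time()
    coverage = AlignmentCoverage(bam_path)
    mean_err = coverage.mean_error_rate
    clusters = []
    for svtype in ("DEL", "INS", "DUP", "INV"):
        clusters.extend(cluster_signatures(signatures, svtype, mean_err,
                                           cluster_config))
    bnds = [s for s in signatures if s.svtype == "BND"]
    clusters.extend(pair_translocations(bnds, cluster_config.tra_tolerance))

    calls = call_variants(clusters, coverage, support_params, priors,
                          min_svlen=min_svlen)
    report.stage_seconds["cluster_and_call"] = round(time.time() - t2, 2)
    for c in calls:
        if c.filter == "PASS":
            report.counts_by_type[c.svtype] = (
                report.counts_by_type.get(c.svtype, 0) + 1)
    return calls, report


# -- training ---------------------------------------------------------------

def labeled_windows_from_sim(sim: Simulation) -> list[tuple]:
    """(WindowBatch, per-submatrix labels) pairs for a whole simulation."""
    windows = list(contig_windows(sim.bam_path, sim.contig_lengths))
    labels = label_windows(sim.truth, windows)
    return list(zip(windows, labels))


def train_on_sims(sims: list[Simulation], config: ModelConfig,
                  epochs: int = 20, early_stop_patience: int = 5,
                  **kwargs) -> tuple[WindowClassifier, list[dict]]:
    data = []
    for sim in sims:
        data.extend(labeled_windows_from_sim(sim))
    return train_model(data, config, epochs=epochs,
                       early_stop_patience=early_stop_patience, **kwargs)


# Default training protocol: two modest simulations at 30x and 10x so the
# classifier sees depth variation; 6 SVs per type per simulation keeps the
# placement spacing feasible on 300 kb contigs.
TRAIN_COVERAGES = (30.0, 10.0)


def training_sim_config(seed: int, coverage: float):
    from .sim import SimConfig

    return SimConfig(
        ref_length=300_000, n_contigs=2,
        n_sv={t: 6 for t in ("DEL", "INS", "DUP", "INV", "TRA")},
        size_range={"DEL": (60, 1000), "INS": (60, 1000), "DUP": (60, 1000),
                    "INV": (60, 1000), "TRA": (0, 0)},
        coverage=coverage, seed=seed,
    )


def default_training_sims(seed: int, workdir) -> list[Simulation]:
    from .sim import simulate

    return [
        simulate(training_sim_config(seed + 1000 + i, cov),
                 f"{workdir}/trainsim{i}", write_fasta=False)
        for i, cov in enumerate(TRAIN_COVERAGES)
    ]


def train_default_model(seed: int, workdir, variant: str = "full",
                        epochs: int = 20, early_stop_patience: int = 5,
                        **kwargs) -> tuple[WindowClassifier, list[dict]]:
    """Train the standard model on the built-in simulation protocol."""
    sims = default_training_sims(seed, workdir)
    config = ModelConfig(seed=seed, variant=variant)
    return train_on_sims(sims, config, epochs=epochs,
                         early_stop_patience=early_stop_patience,
                         batch_size=32, **kwargs)


def _binary_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


def classification_metrics(model: WindowClassifier, sim: Simulation) -> dict:
    """Model classification quality on a labelled simulation.

    Reported at two granularities: per 200 bp submatrix, and per 2 kb
    window (a window is positive when any of its live submatrices is).
    The window level is the unit that matters downstream — adjacent
    positive submatrices merge into one candidate region — while the
    submatrix level is sensitive to harmless spill-over of positive
    probability into blocks bordering a variant.
    """
    data = labeled_windows_from_sim(sim)
    x = np.stack([b.submatrices for b, _ in data])
    mask = np.stack([b.pad_mask for b, _ in data])
    y = np.stack([l for _, l in data])
    probs = np.concatenate([model.predict_proba(x[i:i + 64], mask[i:i + 64])
                            for i in range(0, len(x), 64)])
    live = ~mask
    thr = model.config.positive_threshold
    return {
        "submatrix": _binary_metrics(probs[live] >= thr, y[live] > 0.5),
        "window": _binary_metrics((probs >= thr).any(axis=1),
                                  (y > 0.5).any(axis=1)),
    }


def ablation_study(train_sims: list[Simulation], val_sim: Simulation,
                   seed: int, epochs: int = 20, early_stop_patience: int = 5,
                   variants=("full", "cnn_only", "transformer_only")) -> dict:
    """Train each model variant on the same split; validate on held-out data.

    Mirrors the three-way comparison between the complete model, the
    convolutional encoder alone, and the transformer with a linear patch
    embedding, all under a fixed epoch budget with early stopping.
    """
    results = {}
    for variant in variants:
        config = ModelConfig(seed=seed, variant=variant)
        model, metrics = train_on_sims(train_sims, config, epochs=epochs,
                                       early_stop_patience=early_stop_patience,
                                       batch_size=32)
        results[variant] = {
            "val": classification_metrics(model, val_sim),
            "epochs_run": len(metrics),
            "final_train_loss": metrics[-1]["train_loss"],
            "metrics": metrics,
        }
    return results
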