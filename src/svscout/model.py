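"""Window classification model.

A 2000 bp window arrives as ten 200 bp submatrices of 20 alignment
feature channels.  Each submatrix is encoded locally — two 1-D
convolutions over the position axis followed by channel-then-spatial
attention and global pooling — and the ten embeddings are passed through
a small transformer encoder (sinusoidal positional encoding over the ten
slots, multi-head self-attention) so that evidence spread across
submatrices is shared before a per-submatrix binary head scores each
200 bp block for SV content.  Adjacent positive blocks are merged into
candidate regions by taking the min of starts and max of ends.

Three variants exist for ablation: ``full`` (CNN encoder + transformer),
``cnn_only`` (CNN encoder, per-submatrix head, no cross-submatrix
attention) and ``transformer_only`` (a linear patch embedding replaces
the convolutional encoder).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .features import (
    WindowBatch,
    SUBMATRIX_SIZE,
    SUBMATRICES_PER_WINDOW,
    N_CHANNELS,
)

VARIANTS = ("full", "cnn_only", "transformer_only")


@dataclass
class ModelConfig:
    conv_channels: tuple[int, int] = (16, 32)
    attention_reduction_ratio: int = 8
    embed_dim: int = 64
    n_heads: int = 4
    n_layers: int = 2
    feedforward_dim: int = 128
    dropout: float = 0.0
    positive_threshold: float = 0.5
    variant: str = "full"
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not (0.0 < self.positive_threshold < 1.0):
            raise ValueError("positive_threshold must be in (0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.conv_channels = tuple(self.conv_channels)


@dataclass
class WindowPrediction:
    contig: str
    start: int
    probabilities: np.ndarray  # (10,)

    def submatrix_intervals(self) -> list[tuple[int, int]]:
        return [(self.start + i * SUBMATRIX_SIZE,
                 self.start + (i + 1) * SUBMATRIX_SIZE)
                for i in range(SUBMATRICES_PER_WINDOW)]


@dataclass(frozen=True, order=True)
class CandidateRegion:
    contig: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must be < end")


def _sinusoidal_encoding(n_pos: int, dim: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


class _ChannelAttention(nn.Module):
    """Squeeze-excite over feature channels from pooled position axis."""

    def __init__(self, channels: int, ratio: int, rng):
        hidden = max(channels // ratio, 4)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=-2)           # (..., C)
        mx = x.max(axis=-2)
        att = nn.sigmoid(self.fc2(nn.relu(self.fc1(avg))) +
                         self.fc2(nn.relu(self.fc1(mx))))
        return x * att.reshape(*att.shape[:-1], 1, att.shape[-1])


class _SpatialAttention(nn.Module):
    """Position-axis gate from channel-pooled summaries."""

    def __init__(self, rng):
        self.conv = nn.Conv1d(2, 1, 7, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=-1, keepdims=True)
        mx = x.max(axis=-1, keepdims=True)
        pooled_np = np.concatenate([avg.data, mx.data], axis=-1)
        pooled = nn.Tensor(pooled_np, True)
        pooled._prev = (avg, mx)

        def bwd(g):
            avg._accumulate(g[..., :1])
            mx._accumulate(g[..., 1:])

        pooled._backward = bwd
        gate = nn.sigmoid(self.conv(pooled))  # (..., L, 1)
        return x * gate


class _CnnEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        c1, c2 = cfg.conv_channels
        self.conv1 = nn.Conv1d(N_CHANNELS, c1, 5, rng)
        self.conv2 = nn.Conv1d(c1, c2, 5, rng)
        self.chan_att = _ChannelAttention(c2, cfg.attention_reduction_ratio, rng)
        self.spat_att = _SpatialAttention(rng)
        self.project = nn.Linear(c2, cfg.embed_dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.conv1(x))
        h = nn.relu(self.conv2(h))
        h = self.chan_att(h)
        h = self.spat_att(h)
        return self.project(h.mean(axis=-2))


class _PatchEncoder(nn.Module):
    """Linear patch embedding of a flattened 200x20 submatrix."""

    def __init__(self, cfg: ModelConfig, rng):
        self.fc = nn.Linear(SUBMATRIX_SIZE * N_CHANNELS, cfg.embed_dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        lead = x.shape[:-2]
        return self.fc(x.reshape(*lead, SUBMATRIX_SIZE * N_CHANNELS))


class _MultiHeadSelfAttention(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        d = cfg.embed_dim
        self.n_heads = cfg.n_heads
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.wo.w.data[:] = 0.0  # residual branch starts at identity

    def __call__(self, x: nn.Tensor, key_mask: np.ndarray) -> nn.Tensor:
        B, T, D = x.shape
        H = self.n_heads
        dh = D // H

        def split(t: nn.Tensor) -> nn.Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        # exclude padded submatrices from attention
        bias = np.where(key_mask[:, None, None, :], -1e9, 0.0).astype(np.float32)
        att = nn.softmax(scores + nn.Tensor(bias), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.wo(out)


class _TransformerLayer(nn.Module):
    """Pre-norm residual block: stable to train without warmup."""

    def __init__(self, cfg: ModelConfig, rng):
        self.attn = _MultiHeadSelfAttention(cfg, rng)
        self.norm1 = nn.LayerNorm(cfg.embed_dim)
        self.ff1 = nn.Linear(cfg.embed_dim, cfg.feedforward_dim, rng)
        self.ff2 = nn.Linear(cfg.feedforward_dim, cfg.embed_dim, rng)
        self.ff2.w.data[:] = 0.0  # residual branch starts at identity
        self.norm2 = nn.LayerNorm(cfg.embed_dim)
        self.p_drop = cfg.dropout

    def __call__(self, x, key_mask, rng):
        h = x + nn.dropout(self.attn(self.norm1(x), key_mask), self.p_drop, rng)
        ff = self.ff2(nn.relu(self.ff1(self.norm2(h))))
        return h + nn.dropout(ff, self.p_drop, rng)


class WindowClassifier(nn.Module):
    """Scores each 200 bp submatrix of a 2000 bp window for SV content."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.variant == "transformer_only":
            self.encoder = _PatchEncoder(config, rng)
        else:
            self.encoder = _CnnEncoder(config, rng)
        if config.variant == "cnn_only":
            self.layers = []
            self.input_norm = None
            self.final_norm = None
        else:
            self.layers = [_TransformerLayer(config, rng)
                           for _ in range(config.n_layers)]
            # normalise content before adding position so neither dominates
            self.input_norm = nn.LayerNorm(config.embed_dim)
            self.final_norm = nn.LayerNorm(config.embed_dim)
        self.head = nn.Linear(config.embed_dim, 1, rng)
        self.pos_enc = _sinusoidal_encoding(SUBMATRICES_PER_WINDOW, config.embed_dim)

    def forward_logits(self, x: np.ndarray, pad_mask: np.ndarray,
                       train_rng: np.random.Generator | None = None) -> nn.Tensor:
        """x: (B, 10, 200, 20) raw counts; returns logits (B, 10)."""
        if x.shape[1:] != (SUBMATRICES_PER_WINDOW, SUBMATRIX_SIZE, N_CHANNELS):
            raise ValueError(f"bad window batch shape {x.shape}")
        xt = nn.Tensor(np.log1p(x.astype(np.float32)))
        emb = self.encoder(xt)  # (B, 10, D)
        if self.layers:
            emb = self.input_norm(emb) + nn.Tensor(self.pos_enc)
            for layer in self.layers:
                emb = layer(emb, pad_mask, train_rng)
            emb = self.final_norm(emb)
        B = x.shape[0]
        return self.head(emb).reshape(B, SUBMATRICES_PER_WINDOW)

    def predict_proba(self, x: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        logits = self.forward_logits(x, pad_mask)
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        probs[pad_mask] = 0.0
        return probs


def encode_submatrix(submatrix: np.ndarray, model: WindowClassifier) -> np.ndarray:
    """Embed a single 200x20 block with the model's local encoder."""
    sub = np.asarray(submatrix, dtype=np.float32)
    if sub.shape != (SUBMATRIX_SIZE, N_CHANNELS):
        raise ValueError(f"submatrix must be ({SUBMATRIX_SIZE}, {N_CHANNELS})")
    out = model.encoder(nn.Tensor(np.log1p(sub[None, :, :])))
    return out.data[0].copy()


def predict_window(batch: WindowBatch, model: WindowClassifier) -> WindowPrediction:
    probs = model.predict_proba(batch.submatrices[None], batch.pad_mask[None])[0]
    return WindowPrediction(contig=batch.contig, start=batch.start,
                            probabilities=probs)


def predict_windows(batches: list[WindowBatch], model: WindowClassifier,
                    chunk: int = 64) -> list[WindowPrediction]:
    preds: list[WindowPrediction] = []
    for i in range(0, len(batches), chunk):
        part = batches[i:i + chunk]
        x = np.stack([b.submatrices for b in part])
        mask = np.stack([b.pad_mask for b in part])
        probs = model.predict_proba(x, mask)
        preds.extend(WindowPrediction(b.contig, b.start, probs[j])
                     for j, b in enumerate(part))
    return preds


# -- training ----------------------------------------------------------------

def _epoch_metrics(probs: np.ndarray, labels: np.ndarray, weights: np.ndarray,
                   threshold: float) -> tuple[float, float]:
    live = weights > 0
    pred = probs[live] >= threshold
    truth = labels[live] > 0.5
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1_den = 2 * tp + fn + int(np.sum(pred & ~truth))
    f1 = 2 * tp / f1_den if f1_den else 0.0
    return recall, f1


def train_model(
    labeled_windows: list[tuple[WindowBatch, np.ndarray]],
    config: ModelConfig,
    epochs: int = 20,
    early_stop_patience: int = 5,
    lr: float = 1e-3,
    batch_size: int = 16,
    val_fraction: float = 0.2,
) -> tuple[WindowClassifier, list[dict]]:
    """Train a window classifier on per-submatrix binary labels.

    Labels are 1 where the 200 bp submatrix overlaps a truth SV interval.
    The loss is binary cross-entropy with the positive class weighted by
    the negative/positive label ratio; padded submatrices carry zero
    weight.  Returns the best-validation-loss model and per-epoch metrics
    (loss, recall TP/(TP+FN), F1 on train and validation splits).
    """
    import warnings

    if not labeled_windows:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)

    x = np.stack([b.submatrices for b, _ in labeled_windows])
    mask = np.stack([b.pad_mask for b, _ in labeled_windows])
    y = np.stack([np.asarray(l, dtype=np.float32) for _, l in labeled_windows])
    y[mask] = 0.0

    n = len(labeled_windows)
    order = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 4 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order[:0]

    live = ~mask[train_idx]
    n_pos = float(y[train_idx][live].sum())
    n_neg = float(live.sum() - n_pos)
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class training labels; proceeding anyway")
    pos_weight = (n_neg / n_pos) if n_pos > 0 else 1.0

    model = WindowClassifier(config)
    opt = nn.Adam(model.parameters(), lr=lr)
    drop_rng = np.random.default_rng(rng.integers(2**31))

    def weights_for(idx: np.ndarray) -> np.ndarray:
        w = np.where(y[idx] > 0.5, pos_weight, 1.0).astype(np.float32)
        w[mask[idx]] = 0.0
        return w

    def eval_split(idx: np.ndarray) -> tuple[float, float, float]:
        if idx.size == 0:
            return float("nan"), float("nan"), float("nan")
        probs = np.concatenate([
            model.predict_proba(x[idx[i:i + 64]], mask[idx[i:i + 64]])
            for i in range(0, idx.size, 64)
        ])
        logits = np.log(np.clip(probs, 1e-7, 1 - 1e-7)) - np.log1p(
            -np.clip(probs, 1e-7, 1 - 1e-7))
        w = weights_for(idx)
        loss = nn.bce_with_logits(nn.Tensor(logits), y[idx], w).data.item()
        recall, f1 = _epoch_metrics(probs, y[idx], w, config.positive_threshold)
        return loss, recall, f1

    metrics: list[dict] = []
    best_val = np.inf
    best_state = [p.copy() for p in model.state_arrays()]
    stale = 0
    for epoch in range(1, epochs + 1):
        perm = rng.permutation(train_idx)
        epoch_loss, seen = 0.0, 0
        batch_probs, batch_truth, batch_w = [], [], []
        for i in range(0, perm.size, batch_size):
            idx = perm[i:i + batch_size]
            model.zero_grad()
            logits = model.forward_logits(x[idx], mask[idx], train_rng=drop_rng)
            loss = nn.bce_with_logits(logits, y[idx], weights_for(idx))
            loss.backward()
            opt.step()
            epoch_loss += loss.data.item() * idx.size
            seen += idx.size
            batch_probs.append(1.0 / (1.0 + np.exp(-logits.data)))
            batch_truth.append(y[idx])
            batch_w.append(weights_for(idx))
        train_loss = epoch_loss / max(seen, 1)
        # running (within-epoch) training metrics: no extra forward pass
        train_recall, train_f1 = _epoch_metrics(
            np.concatenate(batch_probs), np.concatenate(batch_truth),
            np.concatenate(batch_w), config.positive_threshold)
        val_loss, val_recall, val_f1 = eval_split(val_idx)
        metrics.append({
            "epoch": epoch, "train_loss": train_loss,
            "train_recall": train_recall, "train_f1": train_f1,
            "val_loss": val_loss, "val_recall": val_recall, "val_f1": val_f1,
        })
        ref_loss = val_loss if val_idx.size else train_loss
        if ref_loss < best_val - 1e-6:
            best_val = ref_loss
            best_state = [p.copy() for p in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= early_stop_patience:
                break
    model.load_state_arrays(best_state)
    return model, metrics


def save_model(model: WindowClassifier, path) -> None:
    cfg = asdict(model.config)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> WindowClassifier:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config"]).decode())
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    model = WindowClassifier(ModelConfig(**cfg_dict))
    model.load_state_arrays(arrays)
    return model


# -- region merging ----------------------------------------------------------

def merge_regions(intervals: list[tuple[int, int]], contig: str = "",
                  max_gap: int = 0) -> list[CandidateRegion]:
    """Merge intervals within ``max_gap`` into [min(starts), max(ends)].

    Touching intervals merge at max_gap=0; output is sorted and disjoint.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged: list[list[int]] = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1] + max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [CandidateRegion(contig, s, e) for s, e in merged]


def predictions_to_regions(predictions: list[WindowPrediction],
                           threshold: float, max_gap: int = 0) -> list[CandidateRegion]:
    """Threshold per-submatrix probabilities and merge adjacent positives."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for pred in predictions:
        for (s, e), p in zip(pred.submatrix_intervals(), pred.probabilities):
            if p >= threshold:
                by_contig.setdefault(pred.contig, []).append((s, e))
    regions: list[CandidateRegion] = []
    for contig in sorted(by_contig):
        regions.extend(merge_regions(by_contig[contig], contig, max_gap))
    return regions
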