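"""Deep sleep stager: 1D-conv residual extractor + bi-LSTM + two FC layers.

Architecture.  Each 30-s window (3 axes x 900 samples at 30 Hz) passes
through a pre-activation residual convolutional network (ResNet V2 style,
1D) that pools to a per-epoch feature vector; a bidirectional LSTM runs over
the night's sequence of epoch features so each epoch's prediction can use
the whole-night context; two fully-connected layers map to the five AASM
stage logits.  The default preset stacks eight residual blocks (17 conv
layers, channels doubling with downsampling); the ``tiny`` preset (<100k
parameters) exercises the identical topology at desk scale.

Self-supervised pretraining.  The convolutional extractor can be pretrained
on unlabelled windows by multi-task transformation discrimination: each of
the enabled spatiotemporal transformations (time reversal, segment
permutation, time warp) is applied independently with probability 0.5 and a
per-task binary head learns to detect it; the joint loss is the sum of the
per-task cross-entropies.  The pretrained extractor weights warm-start
supervised training.

Training is subject-wise: cross-validation folds partition subjects, never
nights, so no subject contributes to both training and evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .agreement import make_folds
from .core import EPOCH_SECONDS, STAGES, EpochTensor, Hypnogram, TimeInBedWindow

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


@dataclass
class SleepNetConfig:
    # extractor: stem conv + pre-activation residual blocks
    stem_channels: int = 32
    stem_kernel: int = 8
    stem_stride: int = 2
    blocks: tuple = ((32, 5, 2), (32, 5, 1), (64, 5, 2), (64, 5, 1),
                     (128, 5, 2), (128, 5, 1), (256, 5, 2), (256, 5, 1))
    # recurrent head
    lstm_hidden: int = 128
    lstm_bidirectional: bool = True
    fc_hidden: int = 128
    n_classes: int = 5
    input_channels: int = 3
    input_samples: int = 900
    center_input: bool = True  # per-window gravity removal (mean over time)
    # training
    sequence_length: int = 64
    dropout: float = 0.1
    learning_rate: float = 3e-3
    batch_size: int = 8  # sequences per batch
    max_epochs: int = 3
    early_stop_patience: int = 2
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != 5:
            raise ValueError("training uses the five-class AASM alphabet")
        if (self.input_channels, self.input_samples) != (3, 900):
            raise ValueError("input shape is fixed at 3 x 900 (30 s at 30 Hz)")


def tiny_config(**overrides) -> SleepNetConfig:
    """Small preset (<100k parameters) for desk-scale training."""
    base = dict(
        stem_channels=8, stem_kernel=8, stem_stride=4,
        blocks=((16, 5, 4), (24, 5, 4)),
        lstm_hidden=16, fc_hidden=16,
        sequence_length=24, batch_size=8, dropout=0.0,
    )
    base.update(overrides)
    return SleepNetConfig(**base)


@dataclass
class SSLTaskConfig:
    tasks: tuple = ("time_reversal", "segment_permutation", "time_warp")
    apply_prob: float = 0.5
    permutation_segments: int = 4
    warp_knots: int = 4
    warp_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self):
        known = {"time_reversal", "segment_permutation", "time_warp"}
        if not self.tasks:
            raise ValueError("at least one self-supervision task must be enabled")
        if not set(self.tasks) <= known:
            raise ValueError(f"unknown tasks: {set(self.tasks) - known}")
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError("apply_prob must be in [0, 1]")


@dataclass
class StagePrediction:
    probabilities: np.ndarray  # (n_epochs, 5)
    labels: np.ndarray  # argmax stage strings
    epoch_times: pd.DatetimeIndex

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probabilities, columns=[f"p_{s}" for s in STAGES]
        )
        df.insert(0, "epoch_start", self.epoch_times)
        df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# SSL transformations


def apply_ssl_transform(window: np.ndarray, cfg: SSLTaskConfig, rng) -> tuple:
    """Apply each enabled transformation with its probability.

    Returns ``(transformed 3x900 window, applied flags per task)``.  Time
    reversal flips the time axis (an involution).  Segment permutation cuts
    the window into equal segments and shuffles them (identity permutations
    are redrawn so the "applied" label is truthful).  Time warp resamples
    the window along a smooth random monotone time distortion and back to
    900 samples.
    """
    w = np.asarray(window, dtype=float)
    labels = np.zeros(len(cfg.tasks), dtype=int)
    for i, task in enumerate(cfg.tasks):
        if rng.random() >= cfg.apply_prob:
            continue
        labels[i] = 1
        if task == "time_reversal":
            w = w[:, ::-1]
        elif task == "segment_permutation":
            n_seg = cfg.permutation_segments
            perm = rng.permutation(n_seg)
            while n_seg > 1 and (perm == np.arange(n_seg)).all():
                perm = rng.permutation(n_seg)
            segs = np.array_split(w, n_seg, axis=1)
            w = np.concatenate([segs[j] for j in perm], axis=1)
        elif task == "time_warp":
            L = w.shape[1]
            knots = np.linspace(0, L - 1, cfg.warp_knots + 2)
            speeds = np.exp(rng.normal(0.0, cfg.warp_sigma, size=cfg.warp_knots + 2))
            speed_t = np.interp(np.arange(L), knots, speeds)
            warped_t = np.cumsum(speed_t)
            warped_t = (warped_t - warped_t[0]) / (warped_t[-1] - warped_t[0]) * (L - 1)
            w = np.stack([np.interp(warped_t, np.arange(L), w[a]) for a in range(3)])
    return np.ascontiguousarray(w), labels


# ---------------------------------------------------------------------------
# model


class SleepNet:
    """Conv extractor + (bi)LSTM + two FC layers; forward (B,S,3,900)->(B,S,5)."""

    def __init__(self, cfg: SleepNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        layers = [nn.CenterTime()] if cfg.center_input else []
        layers.append(
            nn.Conv1d(cfg.input_channels, cfg.stem_channels, cfg.stem_kernel,
                      stride=cfg.stem_stride, rng=rng)
        )
        c_in = cfg.stem_channels
        for c_out, k, stride in cfg.blocks:
            layers.append(nn.PreActBlock1d(c_in, c_out, kernel=k, stride=stride, rng=rng))
            c_in = c_out
        layers += [nn.BatchNorm1d(c_in), nn.ReLU(), nn.GlobalAvgPool1d()]
        self.extractor = nn.Sequential(*layers)
        self.feature_dim = c_in
        if cfg.lstm_bidirectional:
            self.lstm = nn.BiLSTM(self.feature_dim, cfg.lstm_hidden, rng=rng)
            lstm_out = 2 * cfg.lstm_hidden
        else:
            self.lstm = None
            self._uni = nn._LSTMDirection(self.feature_dim, cfg.lstm_hidden, rng)
            lstm_out = cfg.lstm_hidden
        self.head = nn.Sequential(
            nn.Linear(lstm_out, cfg.fc_hidden, rng=rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, rng=np.random.default_rng(cfg.seed + 1)),
            nn.Linear(cfg.fc_hidden, cfg.n_classes, rng=rng),
        )

    # -- plumbing ----------------------------------------------------------
    def params(self):
        rec = self.lstm if self.lstm is not None else self._uni
        return self.extractor.params() + rec.params() + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _lstm_forward(self, x):
        if self.lstm is not None:
            return self.lstm.forward(x)
        return self._uni.forward(x)

    def _lstm_backward(self, d):
        if self.lstm is not None:
            return self.lstm.backward(d)
        return self._uni.backward(d)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[2:] != (3, 900):
            raise ValueError("expected input of shape (batch, seq, 3, 900)")
        B, S = x.shape[:2]
        feats = self.extractor.forward(
            np.asarray(x, dtype=float).reshape(B * S, 3, 900), train=train
        )
        h = self._lstm_forward(feats.reshape(B, S, self.feature_dim))
        logits = self.head.forward(h.reshape(B * S, -1), train=train)
        self._shape = (B, S)
        return logits.reshape(B, S, self.cfg.n_classes)

    def backward(self, dlogits: np.ndarray) -> None:
        B, S = self._shape
        dh = self.head.backward(dlogits.reshape(B * S, -1))
        dfeats = self._lstm_backward(dh.reshape(B, S, -1))
        self.extractor.backward(dfeats.reshape(B * S, self.feature_dim))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))


def build_sleepnet(cfg: SleepNetConfig) -> SleepNet:
    return SleepNet(cfg)


def save_model(model: SleepNet, path) -> None:
    """Checkpoint: .npz weights + plain-text JSON config sidecar."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"p{i:03d}"] = p.value
    bns = [l for l in nn.iter_layers(model.extractor) if isinstance(l, nn.BatchNorm1d)]
    for i, l in enumerate(bns):
        arrays[f"bn{i:03d}_mean"] = l.run_mean
        arrays[f"bn{i:03d}_var"] = l.run_var
        arrays[f"bn{i:03d}_t"] = np.array(l.n_updates)
    np.savez_compressed(path, **arrays)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(asdict(model.cfg), fh, indent=1)


def load_model(path) -> SleepNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        cfg_d = json.load(fh)
    cfg_d["blocks"] = tuple(tuple(b) for b in cfg_d["blocks"])
    model = SleepNet(SleepNetConfig(**cfg_d))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        for i, p in enumerate(model.params()):
            p.value[...] = z[f"p{i:03d}"]
        bns = [l for l in nn.iter_layers(model.extractor) if isinstance(l, nn.BatchNorm1d)]
        for i, l in enumerate(bns):
            l.run_mean[...] = z[f"bn{i:03d}_mean"]
            l.run_var[...] = z[f"bn{i:03d}_var"]
            l.n_updates = int(z[f"bn{i:03d}_t"])
    return model


# ---------------------------------------------------------------------------
# self-supervised pretraining


@dataclass
class SSLResult:
    extractor_state: dict
    task_auc: dict
    initial_loss: float
    final_loss: float


def _stack_unlabeled(unlabeled) -> np.ndarray:
    if isinstance(unlabeled, np.ndarray):
        return unlabeled
    chunks = [t.epochs[t.wear_mask] for t in unlabeled]
    return np.concatenate(chunks, axis=0)


def pretrain_ssl(
    model: SleepNet,
    unlabeled,
    ssl_cfg: SSLTaskConfig,
    epochs: int = 3,
    batch_size: int = 64,
    learning_rate: float = 3e-3,
    holdout_fraction: float = 0.2,
) -> SSLResult:
    """Multi-task transformation-discrimination pretraining.

    ``unlabeled``: array (N, 3, 900) or list of EpochTensors (wear epochs
    pooled).  One binary softmax head per enabled task sits on the pooled
    extractor features; the joint loss is the sum of per-task
    cross-entropies.  Returns the trained extractor state (for
    warm-starting supervised training) and held-out AUC per task.
    """
    from sklearn.metrics import roc_auc_score

    X = _stack_unlabeled(unlabeled)
    if len(X) < 10:
        raise ValueError("too few unlabeled windows for pretraining")
    rng = np.random.default_rng(ssl_cfg.seed)
    n_tasks = len(ssl_cfg.tasks)
    heads = [
        nn.Linear(model.feature_dim, 2, rng=np.random.default_rng(ssl_cfg.seed + 7 + i))
        for i in range(n_tasks)
    ]
    params = model.extractor.params() + [p for h in heads for p in h.params()]
    opt = nn.Adam(params, lr=learning_rate)

    n = len(X)
    n_hold = max(2, int(round(n * holdout_fraction)))
    perm = rng.permutation(n)
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]

    def transformed_batch(idx):
        xb = np.empty((len(idx), 3, 900))
        yb = np.empty((len(idx), n_tasks), dtype=int)
        for j, ii in enumerate(idx):
            xb[j], yb[j] = apply_ssl_transform(X[ii], ssl_cfg, rng)
        return xb, yb

    initial_loss = final_loss = None
    for ep in range(epochs):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            xb, yb = transformed_batch(idx)
            feats = model.extractor.forward(xb, train=True)
            opt.zero_grad()
            dfeats = np.zeros_like(feats)
            loss = 0.0
            for t, head in enumerate(heads):
                logits = head.forward(feats, train=True)
                l, dlog = nn.softmax_cross_entropy(logits, yb[:, t])
                loss += l
                dfeats += head.backward(dlog)
            model.extractor.backward(dfeats)
            opt.step()
            losses.append(loss)
        if ep == 0:
            initial_loss = float(losses[0])
        final_loss = float(np.mean(losses))

    # held-out AUC per task
    xh, yh = transformed_batch(hold_idx)
    feats = model.extractor.forward(xh, train=False)
    aucs = {}
    for t, head in enumerate(heads):
        p = nn.softmax(head.forward(feats, train=False))[:, 1]
        if len(set(yh[:, t])) < 2:
            aucs[ssl_cfg.tasks[t]] = float("nan")
        else:
            aucs[ssl_cfg.tasks[t]] = float(roc_auc_score(yh[:, t], p))
    return SSLResult(
        extractor_state=nn.get_full_state(model.extractor),
        task_auc=aucs,
        initial_loss=initial_loss,
        final_loss=final_loss,
    )


# ---------------------------------------------------------------------------
# supervised training


def _night_arrays(nights):
    """nights: iterable of (EpochTensor, Hypnogram, subject_id) ->
    list of (X float (n,3,900), y int, times, sid)."""
    out = []
    for tensor, hyp, sid in nights:
        # align hypnogram labels to tensor epochs by start time
        pos = tensor.epoch_start_times.get_indexer(hyp.epoch_start_times)
        ok = pos >= 0
        if not ok.any():
            raise ValueError(f"no overlapping epochs for subject {sid}")
        X = tensor.epochs[pos[ok]]
        y = np.array([STAGE_INDEX[l] for l in hyp.labels[ok]], dtype=int)
        out.append((X, y, hyp.epoch_start_times[ok], sid))
    return out


def _class_weights(y_all: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(y_all, minlength=n_classes).astype(float)
    w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1.0) / n_classes, 0.0)
    return w


def fit_sleepnet(model: SleepNet, nights, cfg: SleepNetConfig, rng=None) -> list:
    """Train on (EpochTensor, Hypnogram, subject) nights; returns per-pass losses.

    Each pass covers every night once with randomly phased non-overlapping
    crops of ``sequence_length`` epochs, shuffled into batches.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    data = nights if nights and isinstance(nights[0], tuple) and isinstance(nights[0][0], np.ndarray) else _night_arrays(nights)
    weights = (
        _class_weights(np.concatenate([y for _, y, *_ in data]), cfg.n_classes)
        if cfg.class_weighting
        else None
    )
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    S = cfg.sequence_length
    losses = []
    for _ in range(cfg.max_epochs):
        crops = []
        for ni, (X, y, *_rest) in enumerate(data):
            n = len(y)
            if n <= S:
                crops.append((ni, 0, n))
                continue
            phase = int(rng.integers(0, S))
            starts = list(range(phase, n - S + 1, S))
            if phase > 0:
                starts = [0] + starts  # keep the head of the night in play
            for s in starts:
                crops.append((ni, s, S))
        order = rng.permutation(len(crops))
        pass_losses = []
        lo = 0
        while lo < len(order):
            batch = [crops[i] for i in order[lo : lo + cfg.batch_size]]
            lo += cfg.batch_size
            # group by length for rectangular batching
            by_len: dict = {}
            for ni, s, ln in batch:
                by_len.setdefault(ln, []).append((ni, s))
            for ln, items in by_len.items():
                xb = np.stack([data[ni][0][s : s + ln] for ni, s in items]).astype(float)
                yb = np.stack([data[ni][1][s : s + ln] for ni, s in items])
                logits = model.forward(xb, train=True)
                flat_logits = logits.reshape(-1, cfg.n_classes)
                loss, dlog = nn.softmax_cross_entropy(flat_logits, yb.reshape(-1), weights)
                opt.zero_grad()
                model.backward(dlog.reshape(logits.shape))
                opt.step()
                pass_losses.append(loss)
        losses.append(float(np.mean(pass_losses)))
    return losses


@dataclass
class CVResult:
    folds: object
    predictions: dict  # subject_id -> StagePrediction (out-of-fold, all nights)
    truths: dict  # subject_id -> true stage labels aligned with predictions
    models: list = field(default_factory=list)


def train_sleepnet(
    nights,
    cfg: SleepNetConfig,
    k: int = 5,
    seed: int = 0,
    pretrained_state: dict | None = None,
    keep_models: bool = False,
) -> CVResult:
    """Subject-wise k-fold cross-validated training.

    ``nights``: list of (EpochTensor, Hypnogram, subject_id).  Optional
    ``pretrained_state`` (from ``pretrain_ssl``) warm-starts the extractor
    of every fold.  Returns out-of-fold predictions for every labelled
    epoch; raises if a subject would appear on both sides of a fold.
    """
    data = _night_arrays(nights)
    subjects = [sid for *_, sid in data]
    folds = make_folds(subjects, k=k, seed=seed)
    predictions: dict = {}
    truths: dict = {}
    models = []
    for i in range(k):
        test = set(folds.fold(i))
        train_data = [d for d in data if d[3] not in test]
        train_subjects = {d[3] for d in train_data}
        if train_subjects & test:
            raise RuntimeError("fold leakage: subject in both train and test")
        model = SleepNet(cfg)
        if pretrained_state is not None:
            nn.set_full_state(model.extractor, pretrained_state)
        fit_sleepnet(model, train_data, cfg, rng=np.random.default_rng(cfg.seed + 101 + i))
        for X, y, times, sid in data:
            if sid not in test:
                continue
            probs = model.predict_proba(X[None].astype(float))[0]
            pred = StagePrediction(
                probs,
                np.array(STAGES, dtype=object)[probs.argmax(axis=1)],
                times,
            )
            if sid in predictions:
                prev = predictions[sid]
                predictions[sid] = StagePrediction(
                    np.vstack([prev.probabilities, pred.probabilities]),
                    np.concatenate([prev.labels, pred.labels]),
                    prev.epoch_times.append(times),
                )
                truths[sid] = np.concatenate(
                    [truths[sid], np.array(STAGES, dtype=object)[y]]
                )
            else:
                predictions[sid] = pred
                truths[sid] = np.array(STAGES, dtype=object)[y]
        if keep_models:
            models.append(model)
    return CVResult(folds=folds, predictions=predictions, truths=truths, models=models)


def predict_stages(
    model: SleepNet, tensor: EpochTensor, window: TimeInBedWindow
) -> StagePrediction:
    """Stage probabilities for the epochs fully inside a time-in-bed window."""
    starts = tensor.epoch_start_times
    ends = starts + pd.Timedelta(seconds=EPOCH_SECONDS)
    inside = (starts >= window.start) & (ends <= window.end) & tensor.wear_mask
    if not inside.any():
        raise ValueError("window contains no epochs of the recording")
    X = tensor.epochs[inside][None].astype(float)
    probs = model.predict_proba(X)[0]
    return StagePrediction(
        probs,
        np.array(STAGES, dtype=object)[probs.argmax(axis=1)],
        starts[inside],
    )
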