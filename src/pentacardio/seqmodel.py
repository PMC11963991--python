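"""Shared sequence-classification machinery for motion and diagnosis.

A 10-s, 2000-sample segment is reduced to a timestamp sequence by block
pooling: each timestep summarizes one block of raw samples with per-channel
mean, standard deviation, minimum and maximum.  The default pooling factor
of 10 yields 200-timestamp evaluation sequences; training uses random
contiguous 50-timestamp crops of the same sequences (truncation for
training efficiency), so train and eval features share one distribution.

Model kinds: "transformer" (the in-house numpy encoder), plus
"decision_tree", "random_forest" and "feedforward" baselines from
scikit-learn consuming time-pooled summary statistics of the sequence.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, precision_recall_curve
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .nn import AdamW, TransformerClassifier
from .recording import Segment

MODEL_KINDS = ("transformer", "decision_tree", "random_forest", "feedforward")


@dataclass
class SequenceModelConfig:
    """Transformer architecture and optimization settings.

    The "full" preset is the full-size device configuration (512-d
    projection, 8 encoder layers, 4 heads, 1024-d feed-forward, AdamW at
    lr 1e-4, 10000 iterations, batch 1500); the default "desk" preset is
    scaled down for single-CPU training.
    """

    input_projection_dim: int = 64
    encoder_layers: int = 2
    attention_heads: int = 2
    feedforward_dim: int = 128
    n_classes: int = 4
    train_seq_len: int = 50
    eval_seq_len: int = 200
    pooling_factor: int = 10  # raw samples per timestep
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 1e-5
    iterations: int = 1500
    batch_size: int = 64
    n_checkpoints: int = 5

    def __post_init__(self):
        if min(
            self.input_projection_dim,
            self.encoder_layers,
            self.attention_heads,
            self.feedforward_dim,
            self.n_classes,
        ) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.input_projection_dim % self.attention_heads:
            raise ValueError("projection dim must be divisible by heads")


PRESETS = {
    "desk": SequenceModelConfig(),
    "full": SequenceModelConfig(
        input_projection_dim=512,
        encoder_layers=8,
        attention_heads=4,
        feedforward_dim=1024,
        lr=1e-4,
        iterations=10000,
        batch_size=1500,
    ),
}


def preset(name: str, **overrides) -> SequenceModelConfig:
    return replace(PRESETS[name], **overrides)


# ------------------------------------------------------------------ features

def prepare_sequence(
    segment: Segment,
    channels: list[str] | None = None,
    pooling_factor: int = 10,
) -> np.ndarray:
    """Pooled feature sequence, shape (n_blocks, 4 * n_channels).

    Each timestep covers ``pooling_factor`` raw samples and carries the
    per-channel block mean, std, min and max.  A 2000-sample segment with
    pooling 40 yields 50 timesteps; pooling 10 yields 200.
    """
    if pooling_factor <= 0:
        raise ValueError("pooling_factor must be positive")
    if channels is None:
        channels = list(segment.layout.mech_channels)
    x = segment.channels(channels)  # (C, n)
    n = (x.shape[1] // pooling_factor) * pooling_factor
    if n == 0:
        raise ValueError("segment shorter than one pooling block")
    blocks = x[:, :n].reshape(x.shape[0], -1, pooling_factor)  # (C, L, P)
    feats = np.stack(
        [blocks.mean(-1), blocks.std(-1), blocks.min(-1), blocks.max(-1)], axis=-1
    )  # (C, L, 4)
    return feats.transpose(1, 0, 2).reshape(feats.shape[1], -1)


def _summary_features(X: np.ndarray) -> np.ndarray:
    """Time-pooled summary for the classical baselines: (N, 2F)."""
    return np.concatenate([X.mean(axis=1), X.std(axis=1)], axis=1)


# ------------------------------------------------------------------ fitted model

@dataclass
class FittedSequenceClassifier:
    kind: str
    classes: list[str]
    channels: list[str]
    config: SequenceModelConfig
    norm_mean: np.ndarray
    norm_std: np.ndarray
    model: object
    training_log: dict = field(default_factory=dict)

    def _features(self, segments: list[Segment]) -> np.ndarray:
        X = np.stack(
            [
                prepare_sequence(s, self.channels, self.config.pooling_factor)
                for s in segments
            ]
        )
        return (X - self.norm_mean) / self.norm_std

    def predict_proba(self, segments: list[Segment]) -> np.ndarray:
        for s in segments:
            missing = [c for c in self.channels if c not in s.layout.channels]
            if missing:
                raise ValueError(f"segment lacks channels {missing[:3]}")
        X = self._features(segments)
        if self.kind == "transformer":
            return self.model.predict_proba(X)
        Z = _summary_features(X)
        proba = self.model.predict_proba(Z)
        # sklearn orders columns by its own classes_, remap to ours
        order = [list(self.model.classes_).index(i) for i in range(len(self.classes))]
        return proba[:, order]

    def predict(self, segments: list[Segment]) -> list[str]:
        p = self.predict_proba(segments)
        return [self.classes[i] for i in np.argmax(p, axis=1)]

    def save(self, path) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path) -> "FittedSequenceClassifier":
        with open(path, "rb") as f:
            obj = pickle.load(f)
        if not isinstance(obj, cls):
            raise TypeError("file does not contain a fitted classifier")
        return obj


def _stratified_batches(y: np.ndarray, n_classes: int, batch_size: int, iters: int, rng):
    """Yield per-iteration index batches with balanced class representation."""
    by_class = [np.flatnonzero(y == c) for c in range(n_classes)]
    for _ in range(iters):
        per = max(batch_size // n_classes, 1)
        idx = np.concatenate(
            [rng.choice(ix, size=per, replace=len(ix) < per) for ix in by_class]
        )
        rng.shuffle(idx)
        yield idx[:batch_size]


def train_sequence_classifier(
    segments: list[Segment],
    labels: list[str],
    model_kind: str = "transformer",
    config: SequenceModelConfig | None = None,
    seed: int = 0,
    channels: list[str] | None = None,
    class_order: list[str] | None = None,
) -> FittedSequenceClassifier:
    """Fit a sequence classifier; reproducible for a fixed seed.

    Transformer training draws stratified batches of random 50-timestamp
    crops and logs the cross-entropy on a fixed training subset at evenly
    spaced checkpoints.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if len(segments) != len(labels) or not segments:
        raise ValueError("segments and labels must be equal-length and non-empty")
    classes = class_order or sorted(set(labels))
    if len(set(labels)) < 2:
        raise ValueError("training needs at least 2 classes")
    if not set(labels) <= set(classes):
        raise ValueError("labels outside the declared class set")
    if config is None:
        config = preset("desk")
    config = replace(config, n_classes=len(classes))
    if channels is None:
        channels = list(segments[0].layout.mech_channels)

    rng = np.random.default_rng(seed)
    y = np.array([classes.index(l) for l in labels])
    Xraw = np.stack(
        [prepare_sequence(s, channels, config.pooling_factor) for s in segments]
    )
    mean = Xraw.mean(axis=(0, 1))
    std = Xraw.std(axis=(0, 1))
    std = np.where(std < 1e-12, 1.0, std)
    X = (Xraw - mean) / std
    N, L, F = X.shape

    log: dict = {"checkpoints": []}
    if model_kind == "transformer":
        net = TransformerClassifier(
            n_features=F,
            n_classes=len(classes),
            d_model=config.input_projection_dim,
            n_layers=config.encoder_layers,
            n_heads=config.attention_heads,
            d_ff=config.feedforward_dim,
            max_len=max(L, config.eval_seq_len),
            seed=int(rng.integers(2**31 - 1)),
        )
        opt = AdamW(
            net.params,
            lr=config.lr,
            betas=config.betas,
            weight_decay=config.weight_decay,
        )
        Lc = min(config.train_seq_len, L)
        mon = rng.choice(N, size=min(256, N), replace=False)
        mon_start = (L - Lc) // 2
        every = max(config.iterations // config.n_checkpoints, 1)
        log["checkpoints"].append(
            (0, net.loss(X[mon, mon_start : mon_start + Lc], y[mon], mon_start))
        )
        for it, idx in enumerate(
            _stratified_batches(y, len(classes), config.batch_size, config.iterations, rng),
            start=1,
        ):
            # one crop offset per batch; crops keep their in-sequence positions
            start = int(rng.integers(0, L - Lc + 1))
            loss, grads = net.loss_and_grads(X[idx, start : start + Lc], y[idx], start)
            opt.step(grads)
            if it % every == 0 or it == config.iterations:
                log["checkpoints"].append(
                    (it, net.loss(X[mon, mon_start : mon_start + Lc], y[mon], mon_start))
                )
        model = net
    else:
        Z = _summary_features(X)
        skseed = int(rng.integers(2**31 - 1))
        if model_kind == "decision_tree":
            model = DecisionTreeClassifier(random_state=skseed)
        elif model_kind == "random_forest":
            model = RandomForestClassifier(n_estimators=200, random_state=skseed, n_jobs=1)
        else:  # feedforward
            model = MLPClassifier(
                hidden_layer_sizes=(64,), max_iter=500, random_state=skseed
            )
        model.fit(Z, y)

    return FittedSequenceClassifier(
        kind=model_kind,
        classes=list(classes),
        channels=list(channels),
        config=config,
        norm_mean=mean,
        norm_std=std,
        model=model,
        training_log=log,
    )


# ------------------------------------------------------------------ evaluation

def evaluate_classifier(
    fitted: FittedSequenceClassifier,
    segments: list[Segment],
    labels: list[str],
) -> dict:
    """Confusion matrix, per-class precision/recall/F1, macro-F1, PR curves."""
    if not segments:
        raise ValueError("empty evaluation dataset")
    classes = fitted.classes
    y_true = np.array([classes.index(l) for l in labels])
    proba = fitted.predict_proba(segments)
    y_pred = np.argmax(proba, axis=1)
    cm = _sk_confusion(y_true, y_pred, labels=range(len(classes)))
    per_class = {}
    pr_curves = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        prec = tp / max(cm[:, i].sum(), 1)
        rec = tp / max(cm[i].sum(), 1)
        f1 = 2 * prec * rec / max(prec + rec, 1e-12)
        per_class[c] = {"precision": float(prec), "recall": float(rec), "f1": float(f1)}
        p, r, _ = precision_recall_curve(y_true == i, proba[:, i])
        pr_curves[c] = {"precision": p.tolist(), "recall": r.tolist()}
    macro = f1_score(y_true, y_pred, average="macro", labels=range(len(classes)))
    return {
        "classes": classes,
        "confusion_matrix": cm,
        "per_class": per_class,
        "per_class_accuracy": {c: per_class[c]["recall"] for c in classes},
        "macro_f1": float(macro),
        "accuracy": float(np.mean(y_true == y_pred)),
        "pr_curves": pr_curves,
    }
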