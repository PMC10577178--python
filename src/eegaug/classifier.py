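"""CNN diagnosis classifier (DeprNet-style) separating MDD from HC frames.

Five convolution + max-pooling + batch-normalization blocks followed by
three fully connected layers; sigmoid output, binary cross-entropy loss,
Adam with lr 5e-4, beta1 0.9, beta2 0.999, eps 1e-7. MDD is the positive
class. Pooling halves a dimension only while it still has extent >= 2, so
the five blocks fit any input without collapsing to zero size.

Accuracies are frame-level by default; subject-majority aggregation is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .containers import EEGError, WindowSet


@dataclass(frozen=True)
class ClassifierConfig:
    conv_blocks: int = 5
    conv_filters: tuple[int, ...] = (8, 16, 32, 32, 64)
    conv_kernel: tuple[int, int] = (3, 5)
    dense_units: tuple[int, ...] = (64, 32)
    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    epochs: int = 50
    batch_size: int = 32
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decision_threshold < 1.0:
            raise EEGError("decision threshold must lie in (0, 1)")
        if self.epochs < 1:
            raise EEGError("epochs must be >= 1")
        if len(self.conv_filters) != self.conv_blocks:
            raise EEGError("conv_filters must list one size per block")
        if len(self.dense_units) != 2:
            raise EEGError("dense_units lists the two hidden dense layers")


class ClassifierModel:
    """Frame -> probability of MDD, in [0, 1]."""

    def __init__(self, input_shape: tuple[int, int], config: ClassifierConfig,
                 seed: int | None = None):
        self.input_shape = tuple(input_shape)
        self.config = config
        c, t = self.input_shape
        if t < 2**config.conv_blocks:
            raise EEGError(
                f"time axis of {t} samples too small for "
                f"{config.conv_blocks} pooling stages"
            )
        rng = np.random.default_rng(config.seed if seed is None else seed)
        layers: list[nn.Layer] = []
        h, w, in_ch = c, t, 1
        for filt in config.conv_filters:
            layers.append(nn.Conv2D(in_ch, filt, config.conv_kernel, (1, 1),
                                    rng=rng))
            layers.append(nn.ReLU())
            pool = (2 if h >= 2 else 1, 2 if w >= 2 else 1)
            layers.append(nn.MaxPool2d(pool))
            layers.append(nn.BatchNorm2d(filt))
            h, w, in_ch = h // pool[0] or 1, w // pool[1] or 1, filt
        layers.append(nn.Flatten())
        dims = [in_ch * h * w, *config.dense_units]
        for i in range(len(dims) - 1):
            layers.append(nn.Dense(dims[i], dims[i + 1], rng=rng))
            layers.append(nn.ReLU())
        layers.append(nn.Dense(dims[-1], 1, rng=rng))
        layers.append(nn.Sigmoid())
        self.seq = nn.Sequential(layers)

    def predict_proba(self, frames: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference probabilities for (n, channels, samples)."""
        frames = np.asarray(frames, dtype=nn.DTYPE)
        if frames.shape[1:] != self.input_shape:
            raise EEGError(
                f"frame shape {frames.shape[1:]} != model input {self.input_shape}"
            )
        out = np.empty(frames.shape[0])
        for start in range(0, frames.shape[0], batch_size):
            chunk = frames[start : start + batch_size, None]
            out[start : start + batch_size] = self.seq.forward(chunk, False)[:, 0]
        return out


def build_classifier(input_shape: tuple[int, int],
                     config: ClassifierConfig) -> ClassifierModel:
    return ClassifierModel(input_shape, config)


def train_classifier(
    train: WindowSet, config: ClassifierConfig
) -> tuple[ClassifierModel, pd.DataFrame]:
    """Seeded minibatch training; returns the model and per-epoch history."""
    if len(set(train.groups)) < 2:
        raise EEGError("training set must contain both classes")
    ss = np.random.SeedSequence(config.seed)
    s_init, s_loop, s_stoch = ss.generate_state(3)
    model = ClassifierModel(train.frame_shape, config, seed=int(s_init))
    model.seq.seed_stochastic(np.random.default_rng(int(s_stoch)))
    rng = np.random.default_rng(int(s_loop))
    opt = nn.Adam(model.seq.all_params, config.learning_rate, config.beta1,
                  config.beta2, config.epsilon)
    x = train.frames.astype(nn.DTYPE)
    y = train.labels()
    n = x.shape[0]
    b = min(config.batch_size, n)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, b):
            idx = order[start : start + b]
            p = model.seq.forward(x[idx, None], True)[:, 0]
            pc = np.clip(p, 1e-7, 1.0 - 1e-7)
            yi = y[idx]
            losses.append(float(-np.mean(yi * np.log(pc) + (1 - yi) * np.log(1 - pc))))
            correct += int(((p >= config.decision_threshold) == (yi == 1.0)).sum())
            dp = ((pc - yi) / (pc * (1.0 - pc)) / len(idx)).astype(nn.DTYPE)
            model.seq.backward(dp[:, None])
            opt.step(model.seq.all_grads)
        history.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        })
    return model, pd.DataFrame(history)


def evaluate(
    model: ClassifierModel,
    test: WindowSet,
    threshold: float = 0.5,
    subject_majority: bool = False,
) -> dict[str, float]:
    """Frame-level metrics with MDD as the positive class.

    ``precision`` is reported as 0.0 when no frame is predicted positive.
    With ``subject_majority`` the per-subject majority vote replaces the
    individual frame predictions before counting.
    """
    if test.n_frames == 0:
        raise EEGError("empty test set")
    probs = model.predict_proba(test.frames)
    pred = probs >= threshold
    truth = test.groups == "MDD"
    if subject_majority:
        agg_pred, agg_truth = [], []
        for subject in test.subjects():
            mask = test.subject_ids == subject
            agg_pred.append(pred[mask].mean() >= 0.5)
            agg_truth.append(bool(truth[mask][0]))
        pred = np.array(agg_pred)
        truth = np.array(agg_truth)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    total = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / total,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }
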