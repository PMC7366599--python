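"""PropDRM: a feed-forward network over sparse propositional matrices.

A single hidden layer maps the binary instance-by-item matrix P through

    omega = sigmoid(W_o^T (ELU(Drop(W_1^T P + b_1))) + b_o)

i.e. affine -> (inverted) dropout on the pre-activation, training mode
only -> ELU -> affine -> per-class sigmoid.  Each class has an independent
sigmoid output trained with binary cross-entropy, averaged over the batch;
prediction is the argmax output.  Training traverses P in chunks of ``bs``
rows, densifying one chunk at a time so peak memory stays proportional to
bs * |W| rather than n * |W|.  Plain mini-batch SGD, all randomness seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .wordify import PropositionalMatrix

_EPS = 1e-7


@dataclass
class DRMConfig:
    hidden: int = 32
    dropout_rate: float = 0.2
    elu_c: float = 1.0
    learning_rate: float = 0.1
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.hidden < 1 or self.epochs < 0:
            raise ValueError("batch_size and hidden must be >= 1, epochs >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.elu_c <= 0:
            raise ValueError("learning_rate and elu_c must be positive")


@dataclass
class DRMModel:
    W1: np.ndarray            # input_dim x hidden
    b1: np.ndarray            # hidden
    Wo: np.ndarray            # hidden x |C|
    bo: np.ndarray            # |C|
    label_order: list
    config: DRMConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]


def elu(x, c: float = 1.0):
    """Exponential linear unit: c*(e^x - 1) for x < 0, x otherwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, c * np.expm1(x), x)
    return out if out.ndim else float(out)


def _elu_grad(x: np.ndarray, c: float) -> np.ndarray:
    return np.where(x < 0, c * np.exp(x), 1.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def densify_batch(P: PropositionalMatrix | sp.spmatrix, row_range: range | slice) -> np.ndarray:
    """Dense 0/1 block of the sparse matrix for one batch of rows."""
    m = P.matrix if isinstance(P, PropositionalMatrix) else P
    if isinstance(row_range, range):
        row_range = slice(row_range.start, row_range.stop)
    block = m[row_range]
    if block.shape[0] == 0:
        raise ValueError("empty row range")
    return np.asarray(block.todense(), dtype=float)


def forward(
    model: DRMModel,
    batch: np.ndarray,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """The network composition exactly as stated in the module docstring.

    In training mode the dropout mask is Bernoulli(1 - dropout_rate) with
    surviving pre-activations scaled by 1/(1 - dropout_rate); inference is
    deterministic.  Returns the batch x |C| probability matrix (plus the
    intermediate cache when requested for backpropagation).
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2 or batch.shape[1] != model.input_dim:
        raise ValueError(
            f"batch width {batch.shape} incompatible with input_dim {model.input_dim}"
        )
    cfg = model.config
    H = batch @ model.W1 + model.b1
    if training_mode and cfg.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = 1.0 - cfg.dropout_rate
        mask = (rng.random(H.shape) < keep) / keep
        Hd = H * mask
    else:
        mask = None
        Hd = H
    A = elu(Hd, cfg.elu_c)
    O = A @ model.Wo + model.bo
    probs = _sigmoid(O)
    if return_cache:
        return probs, (batch, Hd, mask, A)
    return probs


def bce_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Per-output binary cross-entropy, summed over classes, averaged over
    the batch.  Probabilities are clipped away from {0, 1}."""
    p = np.clip(np.asarray(probs, dtype=float), _EPS, 1 - _EPS)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    per_instance = -(y * np.log(p) + (1 - y) * np.log1p(-p)).sum(axis=1)
    return float(per_instance.mean())


def init_drm(input_dim: int, n_classes: int, cfg: DRMConfig,
             label_order: Sequence) -> DRMModel:
    """He-style normal initialization, reproducible under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    W1 = rng.normal(0, np.sqrt(2.0 / max(input_dim, 1)), size=(input_dim, cfg.hidden))
    Wo = rng.normal(0, np.sqrt(2.0 / cfg.hidden), size=(cfg.hidden, n_classes))
    return DRMModel(W1=W1, b1=np.zeros(cfg.hidden), Wo=Wo, bo=np.zeros(n_classes),
                    label_order=list(label_order), config=cfg)


def _one_hot(labels: Sequence, label_order: list) -> np.ndarray:
    idx = {lab: j for j, lab in enumerate(label_order)}
    Y = np.zeros((len(labels), len(label_order)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def backward(model: DRMModel, cache, probs: np.ndarray, targets: np.ndarray):
    """Gradients of the batch-mean BCE w.r.t. all parameters."""
    X, Hd, mask, A = cache
    bs = X.shape[0]
    dO = (probs - targets) / bs            # sigmoid + BCE cancellation
    dWo = A.T @ dO
    dbo = dO.sum(axis=0)
    dA = dO @ model.Wo.T
    dHd = dA * _elu_grad(Hd, model.config.elu_c)
    dH = dHd if mask is None else dHd * mask
    dW1 = X.T @ dH
    db1 = dH.sum(axis=0)
    return dW1, db1, dWo, dbo


def train_drm(
    P: PropositionalMatrix,
    labels: Sequence,
    cfg: DRMConfig = DRMConfig(),
) -> DRMModel:
    """Mini-batch SGD over shuffled epochs on densified chunks of P."""
    label_order = sorted(set(labels), key=str)
    if len(label_order) < 2:
        raise ValueError("training requires at least two classes")
    n, d = P.shape
    model = init_drm(d, len(label_order), cfg, label_order)
    Y = _one_hot(labels, label_order)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    M = P.matrix.tocsr()
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            rows = perm[start:start + cfg.batch_size]
            X = densify_batch(M[rows], slice(None))
            yb = Y[rows]
            probs, cache = forward(model, X, training_mode=True, rng=rng,
                                   return_cache=True)
            loss = bce_loss(probs, yb)
            losses.append(loss * len(rows))
            dW1, db1, dWo, dbo = backward(model, cache, probs, yb)
            lr = cfg.learning_rate
            model.W1 -= lr * dW1
            model.b1 -= lr * db1
            model.Wo -= lr * dWo
            model.bo -= lr * dbo
        mean_loss = sum(losses) / n
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"non-finite loss in epoch {_epoch}; lower the learning rate"
            )
        model.loss_trace.append(mean_loss)
    return model


@dataclass
class PredictionBatch:
    probabilities: np.ndarray   # batch x |C|, each in (0, 1)
    labels: list


def predict_drm(model: DRMModel, P: PropositionalMatrix | sp.spmatrix,
                batch_size: int | None = None) -> PredictionBatch:
    """Deterministic inference in densified chunks; argmax label per row."""
    m = P.matrix if isinstance(P, PropositionalMatrix) else sp.csr_matrix(P)
    if m.shape[1] != model.input_dim:
        raise ValueError(f"matrix width {m.shape[1]} != input_dim {model.input_dim}")
    bs = batch_size or model.config.batch_size
    chunks = []
    for start in range(0, m.shape[0], bs):
        X = densify_batch(m, range(start, min(start + bs, m.shape[0])))
        chunks.append(forward(model, X, training_mode=False))
    probs = np.vstack(chunks)
    labels = [model.label_order[j] for j in probs.argmax(axis=1)]
    return PredictionBatch(probabilities=probs, labels=labels)


def positive_scores(pred: PredictionBatch, label_order: list, positive_label) -> np.ndarray:
    """Binary decision score: the positive-output probability."""
    return pred.probabilities[:, label_order.index(positive_label)]


def save_model(model: DRMModel, path: str | Path) -> None:
    meta = {"kind": "propdrm", "label_order": [str(l) for l in model.label_order],
            "config": vars(model.config)}
    np.savez(path, W1=model.W1, b1=model.b1, Wo=model.Wo, bo=model.bo,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_model(path: str | Path) -> DRMModel:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta["kind"] != "propdrm":
        raise ValueError(f"not a propdrm model: {meta['kind']}")
    return DRMModel(W1=data["W1"], b1=data["b1"], Wo=data["Wo"], bo=data["bo"],
                    label_order=meta["label_order"],
                    config=DRMConfig(**meta["config"]))
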