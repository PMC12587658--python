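"""1D convolutional enhancer classifier over DNA sequences.

The model scores a one-hot encoded sequence (plus a scalar GC-content
feature) with a probability of being an enhancer, and the probability is
binned into strong / weak / non-enhancer classes.  Architecture: two
convolution blocks (32 filters x width 12, max-pool 4; 64 filters x
width 8, max-pool 4), global max pooling, the GC scalar concatenated
before a 32-unit dense layer, and a sigmoid output — deliberately
minimal motif-detector capacity, trainable on a CPU in minutes.

The network is implemented directly in numpy (windowed tensordot
convolutions, Adam, inverted dropout); all randomness — initialisation,
shuffling, dropout — is controlled by ``ClassifierConfig.seed``, so a
seeded training run is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .formats_io import SequenceRecord

__all__ = [
    "EncodedExample",
    "ClassifierConfig",
    "EnhancerCall",
    "EnhancerCNN",
    "one_hot_encode",
    "split_train_test",
    "train",
    "predict_proba",
    "classify",
    "save_model",
    "load_model",
]

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
CLASS_STRONG = "strong"
CLASS_WEAK = "weak"
CLASS_NON = "non"


@dataclass
class EncodedExample:
    """One-hot matrix (4 x L, rows A,C,G,T) plus GC scalar and optional label.

    N bases map to all-zero columns; ``gc`` is computed on the original,
    uncropped sequence over non-N bases (so cropping cannot change it).
    """

    sequence_id: str
    onehot: np.ndarray  # (4, L) float32
    gc: float
    label: int | None = None
    gc_undefined: bool = False  # all-N input: gc reported as 0.0


@dataclass
class ClassifierConfig:
    input_length: int = 600
    conv_blocks: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(32, 12, 4), (64, 8, 4)]
    )  # (n_filters, kernel_width, pool_width)
    dense_units: int = 32
    dropout: float = 0.25
    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 32
    seed: int = 0
    test_fraction: float = 0.2
    strong_threshold: float = 0.8
    weak_threshold: float = 0.5
    use_gc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.weak_threshold < self.strong_threshold < 1:
            raise ValueError(
                "need 0 < weak_threshold < strong_threshold < 1, got "
                f"{self.weak_threshold}/{self.strong_threshold}"
            )
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class EnhancerCall:
    sequence_id: str
    probability: float
    enhancer_class: str  # strong / weak / non


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def one_hot_encode(record: SequenceRecord, L: int) -> EncodedExample:
    """Encode a sequence to a 4 x L one-hot matrix plus GC scalar.

    Longer sequences are centre-cropped to L; shorter ones are
    symmetrically zero-padded.  The GC fraction is taken from the
    original sequence before any cropping.
    """
    seq = record.sequence
    if not seq:
        raise ValueError(f"record {record.id!r} has empty sequence")
    gc_undefined = all(c == "N" for c in seq)
    gc = 0.0 if gc_undefined else record.gc_content

    if len(seq) > L:
        off = (len(seq) - L) // 2
        seq = seq[off : off + L]
        pad_left = 0
    else:
        pad_left = (L - len(seq)) // 2

    onehot = np.zeros((4, L), dtype=np.float32)
    for j, base in enumerate(seq):
        row = _BASE_ROW.get(base)
        if row is not None:
            onehot[row, pad_left + j] = 1.0
    return EncodedExample(record.id, onehot, gc, gc_undefined=gc_undefined)


def split_train_test(
    examples: list[EncodedExample], test_fraction: float, seed: int
) -> tuple[list[EncodedExample], list[EncodedExample]]:
    """Label-stratified, seeded, disjoint train/test split."""
    if len(examples) < 10:
        raise ValueError("need at least 10 labelled examples to split")
    labels = {ex.label for ex in examples}
    if None in labels:
        raise ValueError("all examples must be labelled before splitting")
    if len(labels) < 2:
        raise ValueError("single-class input: both labels must be present")
    rng = np.random.default_rng(seed)
    train_set: list[EncodedExample] = []
    test_set: list[EncodedExample] = []
    for label in sorted(labels):
        group = [ex for ex in examples if ex.label == label]
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test_idx = set(order[:n_test].tolist())
        for i, ex in enumerate(group):
            (test_set if i in test_idx else train_set).append(ex)
    return train_set, test_set


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    # X (N,C,L), W (F,C,K) -> out (N,F,Lout)
    win = sliding_window_view(X, W.shape[2], axis=2)  # (N,C,Lout,K)
    out = np.tensordot(win, W, axes=([1, 3], [1, 2]))  # (N,Lout,F)
    return np.ascontiguousarray(out.transpose(0, 2, 1)) + b[None, :, None], win


def _conv_backward(dout: np.ndarray, win: np.ndarray, W: np.ndarray, in_len: int):
    # dout (N,F,Lout)
    db = dout.sum(axis=(0, 2))
    dW = np.tensordot(dout, win, axes=([0, 2], [0, 2]))  # (F,C,K)
    N, C = win.shape[0], win.shape[1]
    Lout, K = dout.shape[2], W.shape[2]
    dX = np.zeros((N, C, in_len), dtype=win.dtype)
    dwin = np.tensordot(dout, W, axes=(1, 0))  # (N,Lout,C,K)
    dwin = dwin.transpose(0, 2, 1, 3)  # (N,C,Lout,K)
    for k in range(K):
        dX[:, :, k : k + Lout] += dwin[:, :, :, k]
    return dX, dW, db


def _maxpool_forward(X: np.ndarray, p: int):
    # X (N,F,L) -> (N,F,L//p), non-overlapping
    N, F, L = X.shape
    Lp = L // p
    Xt = X[:, :, : Lp * p].reshape(N, F, Lp, p)
    arg = Xt.argmax(axis=3)
    out = np.take_along_axis(Xt, arg[..., None], axis=3)[..., 0]
    return out, (arg, X.shape)


def _maxpool_backward(dout: np.ndarray, cache, p: int):
    arg, shape = cache
    N, F, L = shape
    Lp = dout.shape[2]
    dXt = np.zeros((N, F, Lp, p), dtype=dout.dtype)
    np.put_along_axis(dXt, arg[..., None], dout[..., None], axis=3)
    dX = np.zeros(shape, dtype=dout.dtype)
    dX[:, :, : Lp * p] = dXt.reshape(N, F, Lp * p)
    return dX


class EnhancerCNN:
    """Compact numpy 1D CNN with a concatenated GC-content feature."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 4
        length = config.input_length
        for i, (nf, kw, pw) in enumerate(config.conv_blocks):
            if length < kw:
                raise ValueError("input too short for conv stack")
            scale = np.sqrt(2.0 / (c_in * kw))
            self.params[f"W{i}"] = rng.normal(0, scale, (nf, c_in, kw)).astype(np.float64)
            self.params[f"b{i}"] = np.zeros(nf)
            length = (length - kw + 1) // pw
            c_in = nf
        feat = c_in + (1 if config.use_gc else 0)
        self.params["Wd"] = rng.normal(0, np.sqrt(2.0 / feat), (feat, config.dense_units))
        self.params["bd"] = np.zeros(config.dense_units)
        self.params["Wo"] = rng.normal(
            0, np.sqrt(1.0 / config.dense_units), (config.dense_units, 1)
        )
        self.params["bo"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def forward(
        self, X: np.ndarray, gc: np.ndarray, dropout_rng: np.random.Generator | None = None
    ):
        """Probabilities for a batch; dropout active only when a generator
        is supplied (training mode)."""
        cfg = self.config
        cache: list = []
        A = X.astype(np.float64)
        for i, (nf, kw, pw) in enumerate(cfg.conv_blocks):
            Z, win = _conv_forward(A, self.params[f"W{i}"], self.params[f"b{i}"])
            R = np.maximum(Z, 0.0)
            P, pool_cache = _maxpool_forward(R, pw)
            cache.append((win, Z, pool_cache, A.shape[2]))
            A = P
        # global max pool
        garg = A.argmax(axis=2)
        feat = np.take_along_axis(A, garg[:, :, None], axis=2)[:, :, 0]  # (N,F)
        cache.append((garg, A.shape))
        if cfg.use_gc:
            feat = np.concatenate([feat, gc[:, None]], axis=1)
        Zd = feat @ self.params["Wd"] + self.params["bd"]
        Rd = np.maximum(Zd, 0.0)
        if dropout_rng is not None and cfg.dropout > 0:
            mask = (dropout_rng.random(Rd.shape) >= cfg.dropout) / (1 - cfg.dropout)
            Rd = Rd * mask
        else:
            mask = None
        logits = (Rd @ self.params["Wo"] + self.params["bo"])[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logits))
        cache.append((feat, Zd, Rd, mask))
        return prob, cache

    def predict(self, X: np.ndarray, gc: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(X, gc, dropout_rng=None)
        return prob

    # -- backward + Adam ---------------------------------------------------

    def _backward(self, X, prob, y, cache) -> dict[str, np.ndarray]:
        cfg = self.config
        n = len(y)
        grads: dict[str, np.ndarray] = {}
        feat, Zd, Rd, mask = cache[-1]
        dlogits = (prob - y) / n  # BCE + sigmoid
        grads["Wo"] = Rd.T @ dlogits[:, None]
        grads["bo"] = np.array([dlogits.sum()])
        dRd = dlogits[:, None] @ self.params["Wo"].T
        if mask is not None:
            dRd = dRd * mask
        dZd = dRd * (Zd > 0)
        grads["Wd"] = feat.T @ dZd
        grads["bd"] = dZd.sum(axis=0)
        dfeat = dZd @ self.params["Wd"].T
        if cfg.use_gc:
            dfeat = dfeat[:, :-1]  # GC scalar has no upstream parameters
        garg, pooled_shape = cache[-2]
        dA = np.zeros(pooled_shape)
        np.put_along_axis(dA, garg[:, :, None], dfeat[:, :, None], axis=2)
        for i in range(len(cfg.conv_blocks) - 1, -1, -1):
            nf, kw, pw = cfg.conv_blocks[i]
            win, Z, pool_cache, in_len = cache[i]
            dR = _maxpool_backward(dA, pool_cache, pw)
            dZ = dR * (Z > 0)
            dA, dW, db = _conv_backward(dZ, win, self.params[f"W{i}"], in_len)
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stack(examples: list[EncodedExample]):
    X = np.stack([ex.onehot for ex in examples])
    gc = np.array([ex.gc for ex in examples], dtype=float)
    y = np.array(
        [-1 if ex.label is None else ex.label for ex in examples], dtype=float
    )
    return X, gc, y


def train(
    train_set: list[EncodedExample], config: ClassifierConfig
) -> tuple[EnhancerCNN, list[float]]:
    """Train the CNN; returns the model and the per-epoch mean loss log.

    Rejects degenerate single-class input before training; aborts with
    diagnostics if the loss goes non-finite.
    """
    labels = {ex.label for ex in train_set}
    if None in labels or len(labels) < 2:
        raise ValueError("training set must contain both labels (0 and 1)")
    X, gc, y = _stack(train_set)
    model = EnhancerCNN(config)
    rng = np.random.default_rng(config.seed + 10_007)
    loss_log: list[float] = []
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            prob, cache = model.forward(X[idx], gc[idx], dropout_rng=rng)
            loss = _bce(prob, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch {lo // config.batch_size}: "
                    f"prob range [{prob.min()}, {prob.max()}]"
                )
            epoch_losses.append(loss)
            grads = model._backward(X[idx], prob, y[idx], cache)
            model._adam_step(grads)
        loss_log.append(float(np.mean(epoch_losses)))
    return model, loss_log


def predict_proba(
    model: EnhancerCNN, examples: list[EncodedExample], batch_size: int = 256
) -> list[tuple[str, float]]:
    """Probabilities in input order; evaluation is deterministic (no dropout)."""
    L = model.config.input_length
    for ex in examples:
        if ex.onehot.shape != (4, L):
            raise ValueError(
                f"example {ex.sequence_id!r} has shape {ex.onehot.shape}, "
                f"model expects (4, {L})"
            )
    out: list[tuple[str, float]] = []
    for lo in range(0, len(examples), batch_size):
        chunk = examples[lo : lo + batch_size]
        X, gc, _ = _stack(chunk)
        prob = model.predict(X, gc)
        out.extend((ex.sequence_id, float(p)) for ex, p in zip(chunk, prob))
    return out


def classify(probability: float, config: ClassifierConfig) -> str:
    """Bin a probability into strong / weak / non (lower edges inclusive)."""
    if probability >= config.strong_threshold:
        return CLASS_STRONG
    if probability >= config.weak_threshold:
        return CLASS_WEAK
    return CLASS_NON


# ---------------------------------------------------------------------------
# model artifact: single self-describing file (config + weights)
# ---------------------------------------------------------------------------


def save_model(model: EnhancerCNN, path) -> None:
    cfg = asdict(model.config)
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        **model.params,
    )


def load_model(path) -> EnhancerCNN:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    cfg = json.loads(bytes(data["__config__"]).decode())
    cfg["conv_blocks"] = [tuple(b) for b in cfg["conv_blocks"]]
    model = EnhancerCNN(ClassifierConfig(**cfg))
    for k in model.params:
        model.params[k] = data[k]
    return model
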