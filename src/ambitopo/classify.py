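"""Leave-one-subject-out CNN classification of topogram stacks.

Each fold holds out every image of one subject — the network never sees
the test subject — emulating a pre-trained decoder applied to a naive
user.  The default model is a small convolutional network (three conv/
pool blocks, a dense head, softmax cross-entropy, Adam), implemented in
numpy with fully seeded initialization and batching so that identical
seeds give identical runs.  A residual-block variant ("resnet") is
available for a deeper topology.  LA is class 0, HA class 1; HA is the
positive class for precision/recall.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .topomap import TopogramStack


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class LOSOSplit:
    test_subject: int
    train_subjects: tuple[int, ...]
    train_size: int
    test_size: int


def build_loso_splits(stacks: list[TopogramStack]) -> list[LOSOSplit]:
    """One split per subject; image counts come from the actual stacks."""
    if len(stacks) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    sizes = {}
    for s in stacks:
        if s.n_images == 0:
            raise ValueError(f"subject {s.subject_id} has zero images")
        if s.subject_id in sizes:
            raise ValueError(f"duplicate subject id {s.subject_id}")
        sizes[s.subject_id] = s.n_images
    subjects = sorted(sizes)
    total = sum(sizes.values())
    return [
        LOSOSplit(
            test_subject=sid,
            train_subjects=tuple(s for s in subjects if s != sid),
            train_size=total - sizes[sid],
            test_size=sizes[sid],
        )
        for sid in subjects
    ]


def image_fingerprints(stack: TopogramStack) -> set[str]:
    """Content hashes of every image (leakage audits)."""
    out = set()
    for ti in range(stack.n_trials):
        for ci in range(stack.n_clusters):
            out.add(hashlib.sha1(
                np.ascontiguousarray(stack.images[ti, ci]).tobytes()).hexdigest())
    return out


# ---------------------------------------------------------------------------
# numpy CNN layers


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H-k+1, W-k+1, C*k*k) patch matrix (valid conv)."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    win = win.transpose(0, 2, 3, 1, 4, 5)              # N,Ho,Wo,C,k,k
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win.reshape(n, ho, wo, -1))


class _Conv:
    """Valid 2-D convolution with bias (kernel k, stride 1)."""

    def __init__(self, rng, c_in, c_out, k=3):
        self.k = k
        self.W = _he_init(rng, (c_in * k * k, c_out), c_in * k * k)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]

    def forward(self, x):
        self.cols = _im2col(x, self.k)         # N,Ho,Wo,CKK
        out = self.cols @ self.W + self.b      # N,Ho,Wo,Cout
        self.x_shape = x.shape
        return out.transpose(0, 3, 1, 2)

    def backward(self, g):
        g = g.transpose(0, 2, 3, 1)            # N,Ho,Wo,Cout
        self.gW = np.tensordot(self.cols, g, axes=([0, 1, 2], [0, 1, 2]))
        self.gb = g.sum(axis=(0, 1, 2))
        gcols = g @ self.W.T                   # N,Ho,Wo,CKK
        n, c, h, w = self.x_shape
        k = self.k
        gx = np.zeros(self.x_shape)
        gcols = gcols.reshape(n, h - k + 1, w - k + 1, c, k, k)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + h - k + 1, j:j + w - k + 1] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gx

    @property
    def grads(self):
        return [self.gW, self.gb]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask


class _MaxPool2:
    """2x2 max pooling, stride 2 (even inputs trimmed if odd)."""

    params: list = []
    grads: list = []

    def forward(self, x):
        n, c, h, w = x.shape
        self.orig_shape = x.shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        x = x[:, :, :h2, :w2]
        self.x_shape = x.shape
        r = x.reshape(n, c, h2 // 2, 2, w2 // 2, 2)
        self.r = r
        out = r.max(axis=(3, 5))
        mask = (r == out[:, :, :, None, :, None])
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 // 2, w2 // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self.argmask = (flat & first).reshape(
            n, c, h2 // 2, w2 // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out

    def backward(self, g):
        gx = self.argmask * g[:, :, :, None, :, None]
        gx = gx.reshape(self.x_shape)
        if self.x_shape != self.orig_shape:
            out = np.zeros(self.orig_shape)
            out[:, :, :self.x_shape[2], :self.x_shape[3]] = gx
            return out
        return gx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.shape)


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW = self.x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    @property
    def grads(self):
        return [self.gW, self.gb]


class _ResBlock:
    """Two 3x3 same-padding convolutions with an identity shortcut."""

    def __init__(self, rng, c, k=3):
        self.c1 = _Conv(rng, c, c, k)
        self.r1 = _ReLU()
        self.c2 = _Conv(rng, c, c, k)
        self.r2 = _ReLU()
        self.pad = k // 2

    def _pad(self, x):
        p = self.pad
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def _unpad(self, g):
        p = self.pad
        return g[:, :, p:-p, p:-p]

    def forward(self, x):
        h = self.r1.forward(self.c1.forward(self._pad(x)))
        h = self.c2.forward(self._pad(h))
        return self.r2.forward(h + x)

    def backward(self, g):
        g = self.r2.backward(g)
        gh = self._unpad(self.c2.backward(g))
        gh = self.r1.backward(gh)
        gx = self._unpad(self.c1.backward(gh))
        return gx + g

    @property
    def params(self):
        return self.c1.params + self.c2.params

    @property
    def grads(self):
        return self.c1.grads + self.c2.grads


def _softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy, gradient wrt logits, class probabilities."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n, p


@dataclass
class CNNConfig:
    """Training configuration (architecture, optimizer, schedule)."""

    arch: str = "small"              # "small" | "resnet"
    conv_channels: tuple[int, ...] = (8, 16, 32)
    dense_units: int = 64
    kernel: int = 3
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 15
    seed: int = 0
    val_fraction: float = 0.15       # held-out slice of training subjects
    patience: int = 3                # early-stopping patience (epochs)


class SmallCNN:
    """Seeded numpy CNN for single-channel square images, two classes."""

    def __init__(self, image_size: int, config: CNNConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        layers: list = []
        c_in, size = 1, image_size
        for c_out in config.conv_channels:
            if size < config.kernel * 2:
                raise ValueError(
                    f"image size {image_size} too small for {len(config.conv_channels)} "
                    "conv/pool blocks; reduce blocks or enlarge images")
            layers += [_Conv(rng, c_in, c_out, config.kernel), _ReLU()]
            size = size - config.kernel + 1
            if config.arch == "resnet":
                layers.append(_ResBlock(rng, c_out, config.kernel))
            layers.append(_MaxPool2())
            size //= 2
            c_in = c_out
        layers.append(_Flatten())
        n_feat = c_in * size * size
        layers += [_Dense(rng, n_feat, config.dense_units), _ReLU(),
                   _Dense(rng, config.dense_units, 2)]
        self.layers = layers
        self._init_adam()

    def _init_adam(self):
        self._m = [np.zeros_like(p) for lay in self.layers for p in lay.params]
        self._v = [np.zeros_like(p) for lay in self.layers for p in lay.params]
        self._step = 0

    def _forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def _backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)

    def _adam_update(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._step += 1
        i = 0
        for lay in self.layers:
            for p, gr in zip(lay.params, lay.grads):
                self._m[i] = beta1 * self._m[i] + (1 - beta1) * gr
                self._v[i] = beta2 * self._v[i] + (1 - beta2) * gr**2
                mh = self._m[i] / (1 - beta1**self._step)
                vh = self._v[i] / (1 - beta2**self._step)
                p -= lr * mh / (np.sqrt(vh) + eps)
                i += 1

    def predict_proba(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        x = images[:, None, :, :] if images.ndim == 3 else images
        out = []
        for i in range(0, len(x), batch):
            logits = self._forward(x[i:i + batch])
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    def fit(self, images: np.ndarray, labels: np.ndarray,
            val_images: np.ndarray | None = None,
            val_labels: np.ndarray | None = None) -> list[dict]:
        """Mini-batch Adam training with optional early stopping.

        Returns the per-epoch log (loss, and validation accuracy when a
        validation set is supplied).
        """
        cfg = self.config
        x = images[:, None, :, :] if images.ndim == 3 else images
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(cfg.seed + 1)
        log = []
        best_val, best_state, since_best = -np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                logits = self._forward(x[idx])
                loss, g, _ = _softmax_xent(logits, y[idx])
                self._backward(g)
                self._adam_update(cfg.lr)
                losses.append(loss)
            entry = {"epoch": epoch, "loss": float(np.mean(losses))}
            if val_images is not None:
                p = self.predict_proba(val_images)
                acc = float(np.mean(p.argmax(axis=1) == val_labels))
                entry["val_accuracy"] = acc
                if acc > best_val + 1e-9:
                    best_val, since_best = acc, 0
                    best_state = [p.copy() for lay in self.layers for p in lay.params]
                else:
                    since_best += 1
            log.append(entry)
            if val_images is not None and since_best >= cfg.patience:
                break
        if best_state is not None:
            i = 0
            for lay in self.layers:
                for p in lay.params:
                    p[...] = best_state[i]
                    i += 1
        self.log = log
        return log


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvalReport:
    """Confusion counts and the standard metrics; HA is positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    level: str = "image"             # "image" | "trial"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    def to_dict(self) -> dict:
        return {"level": self.level, "tp": self.tp, "fp": self.fp, "tn": self.tn,
                "fn": self.fn, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall}


def confusion_report(y_true: np.ndarray, y_pred: np.ndarray, level: str = "image") -> EvalReport:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    return EvalReport(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        level=level,
    )


def train_cnn(split: LOSOSplit, stacks: list[TopogramStack],
              config: CNNConfig | None = None) -> tuple[SmallCNN, list[dict]]:
    """Train on the split's training subjects only.

    A validation slice (whole images sampled from the training subjects,
    never the test subject) drives early stopping.
    """
    config = config or CNNConfig()
    by_id = {s.subject_id: s for s in stacks}
    xs, ys = [], []
    for sid in split.train_subjects:
        imgs, lab, _ = by_id[sid].flat_images()
        xs.append(imgs)
        ys.append(lab)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    rng = np.random.default_rng(config.seed + split.test_subject)
    order = rng.permutation(len(x))
    n_val = int(round(config.val_fraction * len(x)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    model = SmallCNN(image_size=x.shape[-1], config=config)
    log = model.fit(x[tr_idx], y[tr_idx],
                    x[val_idx] if n_val else None,
                    y[val_idx] if n_val else None)
    return model, log


def evaluate(model: SmallCNN, split: LOSOSplit, stacks: list[TopogramStack],
             threshold: float = 0.5) -> dict:
    """Image-level metrics plus trial-level fusion (mean class probability
    across a trial's cluster images)."""
    by_id = {s.subject_id: s for s in stacks}
    stack = by_id[split.test_subject]
    imgs, lab, trial = stack.flat_images()
    if len(imgs) != split.test_size:
        raise ValueError("split/test stack size mismatch")
    proba = model.predict_proba(imgs)[:, 1]
    pred = (proba >= threshold).astype(int)
    image_rep = confusion_report(lab, pred, level="image")

    n_trials = stack.n_trials
    trial_proba = np.array([proba[trial == t].mean() for t in range(n_trials)])
    trial_true = (stack.labels == "HA").astype(int)
    trial_rep = confusion_report(trial_true, (trial_proba >= threshold).astype(int),
                                 level="trial")
    return {"test_subject": split.test_subject,
            "image": image_rep, "trial": trial_rep,
            "image_proba": proba}


def loso_evaluate(stacks: list[TopogramStack], config: CNNConfig | None = None,
                  ) -> "pd.DataFrame":
    """Run every LOSO fold; returns the per-fold metric table."""
    import pandas as pd

    config = config or CNNConfig()
    rows = []
    for split in build_loso_splits(stacks):
        model, log = train_cnn(split, stacks, config)
        rep = evaluate(model, split, stacks)
        rows.append({
            "test_subject": split.test_subject,
            "train_size": split.train_size,
            "test_size": split.test_size,
            "accuracy": rep["image"].accuracy,
            "precision": rep["image"].precision,
            "recall": rep["image"].recall,
            "trial_accuracy": rep["trial"].accuracy,
            "final_loss": log[-1]["loss"],
        })
    return pd.DataFrame(rows)
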