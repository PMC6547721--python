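"""Bidirectional LSTM classifier for per-event modification calling.

The classifier stacks three bidirectional LSTM layers over the ``w`` rows
of a feature window and maps the center time-step's concatenated
forward/backward hidden state through an affine layer to two logits
(unmodified, modified) and a softmax.  Each LSTM cell follows the standard
update

    v_j = f_i1 * f_i2 + v_{j-1} * f_f        (cell state)
    p_j = tanh(v_j) * f_p                     (output)

where ``f_i1 = tanh(.)`` is the input activation and ``f_i2``, ``f_f``,
``f_p`` are sigmoid input/forget/output gates, each an affine map of
``[x_j, p_{j-1}, 1]``.  Training minimizes the batch-averaged two-class
cross-entropy by Adam, with analytic backpropagation through time
implemented here in NumPy (verified against finite differences in the test
suite).

Training data is loaded as alternating chunks of positive and negative
windows — a small portion of each class at a time, the smaller class
cycled — which equalizes class exposure without resampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureWindow, WindowSet

__all__ = [
    "LstmParams",
    "ModelConfig",
    "Prediction",
    "lstm_cell",
    "cross_entropy",
    "BiLstmClassifier",
    "split_read_based",
    "split_region_based",
]

CHECKPOINT_FORMAT_VERSION = 1
ACCEPTED_W = (7, 11, 15, 21, 31, 51)
EPS = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class LstmParams:
    """Weights of one LSTM direction: input map ``W`` (D x 4H), recurrent
    map ``R`` (H x 4H) and bias ``b`` (4H), gate column order
    [input activation, input gate, forget gate, output gate]."""

    W: np.ndarray
    R: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        H = self.R.shape[0]
        if self.W.shape[1] != 4 * H or self.R.shape != (H, 4 * H) or self.b.shape != (4 * H,):
            raise ValueError(
                f"inconsistent LSTM shapes: W {self.W.shape}, R {self.R.shape}, "
                f"b {self.b.shape}"
            )

    @property
    def hidden_size(self) -> int:
        return self.R.shape[0]


def lstm_cell(
    x: np.ndarray, p_prev: np.ndarray, v_prev: np.ndarray, params: LstmParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step: returns (output ``p_j``, cell state ``v_j``).

    Accepts single vectors or batches (leading batch axis).
    """
    H = params.hidden_size
    x = np.asarray(x, dtype=np.float64)
    p_prev = np.asarray(p_prev, dtype=np.float64)
    v_prev = np.asarray(v_prev, dtype=np.float64)
    if x.shape[-1] != params.W.shape[0] or p_prev.shape[-1] != H or v_prev.shape[-1] != H:
        raise ValueError("lstm_cell: input/state shapes inconsistent with params")
    a = x @ params.W + p_prev @ params.R + params.b
    g = np.tanh(a[..., :H])          # input activation f_i1
    i = _sigmoid(a[..., H : 2 * H])  # input gate       f_i2
    f = _sigmoid(a[..., 2 * H : 3 * H])  # forget gate  f_f
    o = _sigmoid(a[..., 3 * H :])    # output gate      f_p
    v = g * i + v_prev * f
    p = np.tanh(v) * o
    return p, v


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Batch-mean two-class cross-entropy with an epsilon clamp.

    ``probs`` is (B, 2) softmax output in [unmodified, modified] order;
    ``labels`` is 0/1.
    """
    p = np.clip(np.asarray(probs, dtype=np.float64), EPS, 1.0)
    y = np.asarray(labels)
    pick = p[np.arange(len(y)), y.astype(np.int64)]
    return float(-np.log(pick).mean())


@dataclass
class ModelConfig:
    """Hyper-parameters of the window classifier."""

    w: int = 21
    hidden_size: int = 100
    n_layers: int = 3
    feature_mode: int = 7
    learning_rate: float = 1e-3
    batch_size: int = 256
    chunk_size: int = 2048
    max_steps: int = 1000
    seed: int = 0
    precision: str = "single"  # "single" (fast) or "double" (gradient checks)

    def __post_init__(self) -> None:
        if self.w % 2 == 0 or self.w < 1:
            raise ValueError(f"window width must be odd, got {self.w}")
        if self.w not in ACCEPTED_W:
            warnings.warn(
                f"window width {self.w} outside the usual set {ACCEPTED_W}",
                stacklevel=2,
            )
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.feature_mode not in (7, 57):
            raise ValueError("feature_mode must be 7 or 57")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")


@dataclass
class Prediction:
    """Per-event modification call."""

    p_mod: float
    label: int  # argmax: 1 modified, 0 unmodified
    contig: str | None = None
    ref_pos: int | None = None
    strand: str | None = None
    read_id: str | None = None


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class BiLstmClassifier:
    """Three-layer bidirectional LSTM with a 2-way softmax head."""

    def __init__(self, config: ModelConfig | None = None, **overrides):
        if config is None:
            config = ModelConfig(**overrides)
        elif overrides:
            config = ModelConfig(**{**asdict(config), **overrides})
        self.config = config
        self.dtype = np.float32 if config.precision == "single" else np.float64
        self._init_params(np.random.default_rng(config.seed))

    # --- parameters -----------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        H = self.config.hidden_size
        self.layers: list[tuple[LstmParams, LstmParams]] = []
        d_in = self.config.feature_mode
        for _ in range(self.config.n_layers):
            pair = []
            for _dir in range(2):
                s = 1.0 / np.sqrt(d_in + H)
                pair.append(
                    LstmParams(
                        rng.uniform(-s, s, (d_in, 4 * H)).astype(self.dtype),
                        rng.uniform(-s, s, (H, 4 * H)).astype(self.dtype),
                        np.zeros(4 * H, dtype=self.dtype),
                    )
                )
            self.layers.append(tuple(pair))
            d_in = 2 * H
        s = 1.0 / np.sqrt(2 * H)
        self.W_out = rng.uniform(-s, s, (2 * H, 2)).astype(self.dtype)
        self.b_out = np.zeros(2, dtype=self.dtype)

    def _param_list(self) -> list[np.ndarray]:
        out = []
        for fwd, bwd in self.layers:
            out += [fwd.W, fwd.R, fwd.b, bwd.W, bwd.R, bwd.b]
        out += [self.W_out, self.b_out]
        return out

    def zero_parameters(self) -> None:
        """Set every weight and bias to zero (diagnostic aid)."""
        for p in self._param_list():
            p[...] = 0.0

    # --- forward / backward ---------------------------------------------

    def _dir_forward(self, X: np.ndarray, lp: LstmParams, reverse: bool):
        B, T, _ = X.shape
        H = lp.hidden_size
        # input contribution for all time steps in one matmul
        AX = (X.reshape(B * T, -1) @ lp.W).reshape(B, T, 4 * H) + lp.b
        dt = X.dtype
        p = np.zeros((B, H), dt)
        v = np.zeros((B, H), dt)
        P = np.zeros((B, T, H), dt)
        # stacked per-step caches, indexed by processing order
        G = np.empty((T, B, H), dt)
        I = np.empty((T, B, H), dt)
        Fg = np.empty((T, B, H), dt)
        O = np.empty((T, B, H), dt)
        Vprev = np.empty((T, B, H), dt)
        TV = np.empty((T, B, H), dt)
        Pprev = np.empty((T, B, H), dt)
        order = range(T - 1, -1, -1) if reverse else range(T)
        for step, t in enumerate(order):
            a = AX[:, t] + p @ lp.R
            g = np.tanh(a[:, :H])
            i = _sigmoid(a[:, H : 2 * H])
            f = _sigmoid(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            G[step], I[step], Fg[step], O[step] = g, i, f, o
            Vprev[step], Pprev[step] = v, p
            v = g * i + v * f
            tv = np.tanh(v)
            TV[step] = tv
            p = tv * o
            P[:, t] = p
        cache = (list(order), G, I, Fg, O, Vprev, TV, Pprev)
        return P, cache

    def _dir_backward(self, dP: np.ndarray, X: np.ndarray, lp: LstmParams, cache):
        B, T, _ = X.shape
        H = lp.hidden_size
        order, G, I, Fg, O, Vprev, TV, Pprev = cache
        dt = X.dtype
        dA = np.empty((T, B, 4 * H), dt)
        dR = np.zeros_like(lp.R)
        dp_next = np.zeros((B, H), dt)
        dv_next = np.zeros((B, H), dt)
        for step in range(T - 1, -1, -1):
            t = order[step]
            g, i, f, o = G[step], I[step], Fg[step], O[step]
            tv = TV[step]
            dp = dP[:, t] + dp_next
            do = dp * tv
            dv = dp * o * (1 - tv * tv) + dv_next
            dv_next = dv * f
            da = dA[step]
            da[:, :H] = dv * i * (1 - g * g)
            da[:, H : 2 * H] = dv * g * i * (1 - i)
            da[:, 2 * H : 3 * H] = dv * Vprev[step] * f * (1 - f)
            da[:, 3 * H :] = do * o * (1 - o)
            dR += Pprev[step].T @ da
            dp_next = da @ lp.R.T
        # reorder steps back to time order for the batched matmuls
        dA_time = np.empty((B, T, 4 * H), dt)
        dA_time[:, order] = dA.transpose(1, 0, 2)
        flatA = dA_time.reshape(B * T, 4 * H)
        dW = X.reshape(B * T, -1).T @ flatA
        db = flatA.sum(axis=0)
        dX = (flatA @ lp.W.T).reshape(B, T, -1)
        return dX, dW, dR, db

    def forward_batch(self, X: np.ndarray, with_cache: bool = False):
        """Softmax probabilities (B, 2) in [unmodified, modified] order."""
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 2:
            X = X[None]
        B, T, D = X.shape
        if T != self.config.w or D != self.config.feature_mode:
            raise ValueError(
                f"window shape ({T}, {D}) does not match model "
                f"(w={self.config.w}, features={self.config.feature_mode})"
            )
        caches = []
        inp = X
        for fwd, bwd in self.layers:
            Pf, cf = self._dir_forward(inp, fwd, reverse=False)
            Pb, cb = self._dir_forward(inp, bwd, reverse=True)
            caches.append((inp, cf, cb))
            inp = np.concatenate([Pf, Pb], axis=2)
        center = T // 2
        h = inp[:, center]
        logits = h @ self.W_out + self.b_out
        probs = softmax(logits)
        if with_cache:
            return probs, (caches, h, center, B, T)
        return probs

    def backward_batch(
        self,
        probs: np.ndarray,
        labels: np.ndarray,
        cache,
        sample_weight: np.ndarray | None = None,
    ):
        """Gradients of the batch-mean cross-entropy, ordered as
        :meth:`_param_list`."""
        caches, h, center, B, T = cache
        y = np.asarray(labels, dtype=np.int64)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=np.float64)
            dlogits *= (w / w.mean())[:, None]
        dlogits /= B
        dW_out = h.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dh = dlogits @ self.W_out.T
        H = self.config.hidden_size
        dP_top = np.zeros((B, T, 2 * H), dtype=h.dtype)
        dP_top[:, center] = dh
        grads_rev = []
        dP = dP_top
        for (fwd, bwd), (inp, cf, cb) in zip(reversed(self.layers), reversed(caches)):
            dXf, dWf, dRf, dbf = self._dir_backward(dP[:, :, :H], inp, fwd, cf)
            dXb, dWb, dRb, dbb = self._dir_backward(dP[:, :, H:], inp, bwd, cb)
            grads_rev.append([dWf, dRf, dbf, dWb, dRb, dbb])
            dP = dXf + dXb
        grads = []
        for g6 in reversed(grads_rev):
            grads += g6
        grads += [dW_out, db_out]
        return grads

    # --- public API ------------------------------------------------------

    def forward(self, window: FeatureWindow) -> Prediction:
        """Deterministic per-window modification probability."""
        probs = self.forward_batch(window.matrix)[0]
        return Prediction(
            float(probs[1]), int(probs.argmax()),
            window.contig, window.ref_pos, window.strand, window.read_id,
        )

    def predict_proba(self, X: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        """Modification probability per window, computed in batches."""
        X = np.asarray(X)
        bs = batch_size or self.config.batch_size
        out = np.empty(len(X))
        for lo in range(0, len(X), bs):
            out[lo : lo + bs] = self.forward_batch(X[lo : lo + bs])[:, 1]
        return out

    def loss(self, probs: np.ndarray, labels: np.ndarray) -> float:
        return cross_entropy(probs, labels)

    def train(
        self,
        pos_windows: np.ndarray | WindowSet,
        neg_windows: np.ndarray | WindowSet,
        max_steps: int | None = None,
        class_weight: tuple[float, float] | None = None,
        log_every: int = 50,
    ) -> list[dict]:
        """Chunk-interleaved gradient training; returns the step history.

        Positive and negative windows are consumed as alternating chunks of
        ``config.chunk_size`` windows, the smaller class cycling until
        ``max_steps`` optimizer steps have been taken.  Reproducible given
        ``config.seed``.
        """
        X_pos = pos_windows.X if isinstance(pos_windows, WindowSet) else np.asarray(pos_windows)
        X_neg = neg_windows.X if isinstance(neg_windows, WindowSet) else np.asarray(neg_windows)
        if len(X_pos) == 0 or len(X_neg) == 0:
            raise ValueError("training requires windows of both classes")
        cfg = self.config
        steps_budget = max_steps if max_steps is not None else cfg.max_steps
        rng = np.random.default_rng(cfg.seed)
        opt = _Adam(self._param_list(), cfg.learning_rate)
        history: list[dict] = []

        def chunk_stream(X, rng_stream):
            while True:
                order = rng_stream.permutation(len(X))
                for lo in range(0, len(X), cfg.chunk_size):
                    yield X[order[lo : lo + cfg.chunk_size]]

        pos_stream = chunk_stream(X_pos, np.random.default_rng(rng.integers(2**31)))
        neg_stream = chunk_stream(X_neg, np.random.default_rng(rng.integers(2**31)))
        step = 0
        while step < steps_budget:
            cp, cn = next(pos_stream), next(neg_stream)
            Xc = np.concatenate([cp, cn])
            yc = np.concatenate(
                [np.ones(len(cp), np.int64), np.zeros(len(cn), np.int64)]
            )
            order = rng.permutation(len(Xc))
            for lo in range(0, len(Xc), cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                probs, cache = self.forward_batch(Xc[idx], with_cache=True)
                yb = yc[idx]
                wts = None
                if class_weight is not None:
                    wts = np.where(yb == 1, class_weight[1], class_weight[0])
                grads = self.backward_batch(probs, yb, cache, sample_weight=wts)
                loss = cross_entropy(probs, yb)
                opt.step(grads)
                step += 1
                if step % log_every == 0 or step == 1:
                    acc = float(((probs[:, 1] >= 0.5) == (yb == 1)).mean())
                    history.append({"step": step, "loss": loss, "accuracy": acc})
                if step >= steps_budget:
                    break
        return history

    # --- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{k}": p for k, p in enumerate(self._param_list())}
        meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "config": asdict(self.config)}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BiLstmClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format {meta.get('format_version')}"
                )
            model = cls(ModelConfig(**meta["config"]))
            for k, p in enumerate(model._param_list()):
                p[...] = z[f"param_{k}"]
        return model


def split_read_based(
    reads: Sequence,
    fraction: float = 0.9,
    seed: int = 0,
    classes: Sequence | None = None,
) -> tuple[list, list]:
    """Random disjoint train/test split over whole reads.

    ``classes`` (optional, e.g. positive/negative control of origin) makes
    the split honor the fraction per class.
    """
    rng = np.random.default_rng(seed)
    reads = list(reads)
    if classes is None:
        classes = [0] * len(reads)
    train: list = []
    test: list = []
    by_class: dict = {}
    for r, c in zip(reads, classes):
        by_class.setdefault(c, []).append(r)
    for c in sorted(by_class, key=str):
        group = by_class[c]
        order = rng.permutation(len(group))
        n_train = int(round(fraction * len(group)))
        train += [group[i] for i in order[:n_train]]
        test += [group[i] for i in order[n_train:]]
    return train, test


def split_region_based(
    windows: WindowSet, contig: str, lo: int, hi: int
) -> tuple[WindowSet, WindowSet]:
    """Hold out all windows centered in [lo, hi) of ``contig`` for testing."""
    in_region = (windows.contig.astype("U") == contig) & (windows.pos >= lo) & (windows.pos < hi)
    return windows.subset(~in_region), windows.subset(in_region)
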