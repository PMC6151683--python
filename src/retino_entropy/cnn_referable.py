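"""Small CNN for binary referable-DR detection on 100×100 inputs.

Architecture: four convolutional blocks with a shared 5×5 kernel size and
filter counts 32, 64, 64, 128; 2×2 max-pooling after each of the first three
blocks only; ReLU activation and a dropout layer in every block; then
flatten → fully connected (width 256, ReLU) → dropout → 2-logit
classification head trained with softmax cross-entropy.  Convolutions are
unpadded ("valid"), so the spatial path is
100 → 96 → 48 → 44 → 22 → 18 → 9 → 5.

The network is implemented directly on numpy: convolutions are lowered to
im2col + BLAS matmul in float32, gradients of the convolution are computed
as a full correlation with the rotated kernels (again via im2col), pooling
uses an argmax scatter, and optimisation is Adam.  Everything is
deterministic under a fixed seed.

Training follows a best-of-K selection rule: evaluation accuracy on the
held-out set is recorded after every iteration (an iteration is one epoch by
default) and the parameter snapshot of the best iteration — first index on
ties — is retained.  Selecting on the evaluation set leaks information from
it; an optional validation split avoids that, the default replicates the
best-of-K protocol.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# architecture and training configuration


@dataclass(frozen=True)
class ArchitectureSpec:
    kernel_size: int = 5
    conv_filters: tuple[int, ...] = (32, 64, 64, 128)
    pool_after: tuple[int, ...] = (1, 2, 3)  # 1-based block indices
    head_width: int = 256
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("architecture uses exactly 4 convolutional blocks")


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 200           # interpreted as epochs
    batch_size: int = 64
    learning_rate: float = 1e-3
    conv_dropout: float = 0.25
    head_dropout: float = 0.5
    seed: int = 0
    input_channels: int = 1         # 1 for entropy, 3 for original
    iteration_unit: str = "epoch"   # or "batch"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for r in (self.conv_dropout, self.head_dropout):
            if not 0.0 <= r < 1.0:
                raise ValueError(f"dropout rate {r} outside [0, 1)")
        if self.iteration_unit not in ("epoch", "batch"):
            raise ValueError(f"unknown iteration_unit {self.iteration_unit!r}")


@dataclass
class TrainHistory:
    eval_accuracy: list[float] = field(default_factory=list)

    @property
    def best_iteration(self) -> int:
        return select_best(self.eval_accuracy)


def select_best(eval_accuracy: list[float]) -> int:
    """Index of the best evaluation accuracy; first occurrence on ties."""
    if not eval_accuracy:
        raise ValueError("empty history")
    return int(np.argmax(eval_accuracy))


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) → (B·OH·OW, k·k·C) patch matrix for a valid convolution.

    Filled by k² contiguous slice copies (much faster than gathering a
    transposed sliding-window view); the flattened patch ordering (p, q, c)
    matches the (k, k, Cin, Cout) weight layout.
    """
    b, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((b, oh, ow, k, k, c), dtype=x.dtype)
    for p in range(k):
        for q in range(k):
            cols[:, :, :, p, q, :] = x[:, p:p + oh, q:q + ow, :]
    return cols.reshape(b * oh * ow, k * k * c)


class _Conv:
    """Valid 5×5 convolution lowered to BLAS GEMM, He-initialised.

    Two equivalent lowerings, picked by channel count: a patch-matrix
    (im2col) GEMM when c_in is small, and a per-tap accumulation — one
    (N, c_in) @ (c_in, c_out) GEMM per kernel offset — when c_in is large
    enough for the inner dimension to keep BLAS efficient.  The per-tap path
    avoids materialising the k²-fold patch matrix of the deep layers.
    """

    TAPS_MIN_CIN = 8

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.needs_input_grad = needs_input_grad
        self.W = rng.normal(0.0, scale, (k * k * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    @property
    def _use_taps(self) -> bool:
        return self.c_in >= self.TAPS_MIN_CIN

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        b, h, w, _ = x.shape
        oh, ow = h - k + 1, w - k + 1
        if self._use_taps:
            Wt = self.W.reshape(k, k, self.c_in, self.c_out)
            y = np.empty((b * oh * ow, self.c_out), dtype=np.float32)
            y[...] = self.b
            tap = np.empty((b, oh, ow, self.c_in), dtype=np.float32)
            for p in range(k):
                for q in range(k):
                    np.copyto(tap, x[:, p:p + oh, q:q + ow, :])
                    y += tap.reshape(-1, self.c_in) @ Wt[p, q]
            if train:
                self._cache = x
            return y.reshape(b, oh, ow, self.c_out)
        cols = _im2col(x, k)
        if train:
            self._cache = cols
            self._in_shape = x.shape
        return (cols @ self.W + self.b).reshape(b, oh, ow, self.c_out)

    def backward(self, dout: np.ndarray):
        k = self.k
        b, oh, ow, _ = dout.shape
        dflat = dout.reshape(b * oh * ow, self.c_out)
        self.db = dflat.sum(axis=0)
        if self._use_taps:
            x = self._cache
            Wt = self.W.reshape(k, k, self.c_in, self.c_out)
            self.dW = np.empty_like(Wt)
            dx = np.zeros_like(x) if self.needs_input_grad else None
            tap = np.empty((b, oh, ow, self.c_in), dtype=np.float32)
            for p in range(k):
                for q in range(k):
                    np.copyto(tap, x[:, p:p + oh, q:q + ow, :])
                    self.dW[p, q] = tap.reshape(-1, self.c_in).T @ dflat
                    if dx is not None:
                        dx[:, p:p + oh, q:q + ow, :] += (
                            dflat @ Wt[p, q].T).reshape(b, oh, ow, self.c_in)
            self.dW = self.dW.reshape(self.W.shape)
            self._cache = None
            return dx, [self.dW, self.db]
        cols = self._cache
        self.dW = cols.T @ dflat
        self._cache = None
        if not self.needs_input_grad:  # first layer: dx is never used
            return None, [self.dW, self.db]
        # dx = valid correlation of zero-padded dout with rotated kernels
        Wr = self.W.reshape(k, k, self.c_in, self.c_out)[::-1, ::-1]
        Wr = np.ascontiguousarray(Wr.transpose(0, 1, 3, 2)).reshape(
            k * k * self.c_out, self.c_in)
        pad = k - 1
        dpad = np.pad(dout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        dx = (_im2col(dpad, k) @ Wr).reshape(self._in_shape)
        return dx, [self.dW, self.db]


class _ReLU:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask, []

    def params(self):
        return []


class _MaxPool2:
    """2×2 max pooling, stride 2; ties route the gradient to the first max."""

    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, h // 2, w // 2, c, 4)
        if train:
            self._idx = xr.argmax(axis=-1)
            self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout):
        b, oh, ow, c = dout.shape
        dxr = np.zeros((b, oh, ow, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(b, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(self._shape), []

    def params(self):
        return []


class _Dropout:
    """Inverted dropout; identity at evaluation time."""

    n_params = 0

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout, []
        return dout * self._mask, []

    def params(self):
        return []


class _Flatten:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape), []

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx, [self.dW, self.db]


# ---------------------------------------------------------------------------
# model


class Model:
    """The referable-DR network: an ordered layer list plus bookkeeping."""

    def __init__(self, spec: ArchitectureSpec, input_channels: int,
                 input_size: int = 100, seed: int = 0,
                 conv_dropout: float = 0.25, head_dropout: float = 0.5):
        if input_channels not in (1, 3):
            raise ValueError(f"input_channels must be 1 or 3, got {input_channels}")
        self.spec = spec
        self.input_channels = input_channels
        self.input_size = input_size
        init_rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(init_rng.integers(2**31))

        k = spec.kernel_size
        layers: list = []
        size, c_in = input_size, input_channels
        for block, c_out in enumerate(spec.conv_filters, start=1):
            if size < k:
                raise ValueError(f"feature map {size} smaller than kernel {k}")
            layers.append(_Conv(k, c_in, c_out, init_rng,
                                needs_input_grad=block > 1))
            layers.append(_ReLU())
            size = size - k + 1
            if block in spec.pool_after:
                layers.append(_MaxPool2())
                size //= 2
            layers.append(_Dropout(conv_dropout, self._dropout_rng))
            c_in = c_out
        layers.append(_Flatten())
        flat = size * size * c_in
        layers.append(_Dense(flat, spec.head_width, init_rng))
        layers.append(_ReLU())
        layers.append(_Dropout(head_dropout, self._dropout_rng))
        layers.append(_Dense(spec.head_width, spec.n_classes, init_rng))
        self.layers = layers
        self.final_feature_size = size

    # -- audits ------------------------------------------------------------
    def layer_audit(self) -> dict[str, int]:
        counts = {"conv": 0, "pool": 0, "dropout": 0, "relu": 0, "dense": 0}
        for lay in self.layers:
            if isinstance(lay, _Conv):
                counts["conv"] += 1
            elif isinstance(lay, _MaxPool2):
                counts["pool"] += 1
            elif isinstance(lay, _Dropout):
                counts["dropout"] += 1
            elif isinstance(lay, _ReLU):
                counts["relu"] += 1
            elif isinstance(lay, _Dense):
                counts["dense"] += 1
        return counts

    def parameter_count(self) -> int:
        return sum(lay.n_params for lay in self.layers)

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=np.float32)
        if h.ndim != 4 or h.shape[1:] != (self.input_size, self.input_size,
                                          self.input_channels):
            raise ValueError(
                f"expected (B,{self.input_size},{self.input_size},"
                f"{self.input_channels}) input, got {h.shape}")
        for lay in self.layers:
            h = lay.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        d = dlogits
        for lay in reversed(self.layers):
            d, g = lay.backward(d)
            grads = g + grads
        return grads

    def parameters(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params()]

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p[...] = s


def build_model(spec: ArchitectureSpec | None = None, input_channels: int = 1,
                seed: int = 0, input_size: int = 100,
                conv_dropout: float = 0.25, head_dropout: float = 0.5) -> Model:
    """Construct the untrained referable-DR network."""
    return Model(spec or ArchitectureSpec(), input_channels,
                 input_size=input_size, seed=seed,
                 conv_dropout=conv_dropout, head_dropout=head_dropout)


def expected_parameter_count(input_channels: int, input_size: int = 100,
                             spec: ArchitectureSpec | None = None) -> int:
    """Closed-form parameter count: sum of k²·c_in·c_out + c_out over convs
    plus the two dense layers; kept independent of the layer objects."""
    spec = spec or ArchitectureSpec()
    k = spec.kernel_size
    total = 0
    size, c_in = input_size, input_channels
    for block, c_out in enumerate(spec.conv_filters, start=1):
        total += k * k * c_in * c_out + c_out
        size = size - k + 1
        if block in spec.pool_after:
            size //= 2
        c_in = c_out
    flat = size * size * c_in
    total += flat * spec.head_width + spec.head_width
    total += spec.head_width * spec.n_classes + spec.n_classes
    return total


# ---------------------------------------------------------------------------
# training


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def evaluate_accuracy(model: Model, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 128) -> float:
    """Fraction of correct argmax calls, computed in eval mode."""
    correct = 0
    for lo in range(0, len(x), batch_size):
        logits = model.forward(x[lo:lo + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == y[lo:lo + batch_size]).sum())
    return correct / len(x)


def train(model: Model, x_train: np.ndarray, y_train: np.ndarray,
          x_eval: np.ndarray, y_eval: np.ndarray,
          cfg: TrainConfig) -> tuple[list[np.ndarray], TrainHistory]:
    """Train with softmax cross-entropy and Adam; record per-iteration
    evaluation accuracy and return the best-iteration parameter snapshot.

    Returns ``(best_state, history)``; the model is left at its final
    iteration, load ``best_state`` to use the selected snapshot.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    x_train = np.asarray(x_train, dtype=np.float32)
    x_eval = np.asarray(x_eval, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_eval = np.asarray(y_eval, dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    history = TrainHistory()
    best_state: list[np.ndarray] | None = None
    best_acc = -1.0

    def one_batch(idx: np.ndarray) -> float:
        xb, yb = x_train[idx], y_train[idx]
        logits = model.forward(xb, train=True)
        probs = _softmax(logits)
        loss = float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean())
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at iteration {len(history.eval_accuracy)}: "
                f"loss={loss}, logit range [{logits.min()}, {logits.max()}]")
        dlogits = probs
        dlogits[np.arange(len(yb)), yb] -= 1.0
        dlogits /= len(yb)
        grads = model.backward(dlogits.astype(np.float32))
        opt.step(grads)
        return loss

    def record_eval() -> None:
        nonlocal best_state, best_acc
        acc = evaluate_accuracy(model, x_eval, y_eval)
        history.eval_accuracy.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_state = model.state_dict()

    if cfg.iteration_unit == "epoch":
        for _ in range(cfg.iterations):
            order = rng.permutation(len(x_train))
            for lo in range(0, len(order), cfg.batch_size):
                one_batch(order[lo:lo + cfg.batch_size])
            record_eval()
    else:  # one iteration = one mini-batch step
        order = rng.permutation(len(x_train))
        cursor = 0
        for _ in range(cfg.iterations):
            if cursor + cfg.batch_size > len(order):
                order = rng.permutation(len(x_train))
                cursor = 0
            one_batch(order[cursor:cursor + cfg.batch_size])
            cursor += cfg.batch_size
            record_eval()

    assert best_state is not None
    return best_state, history


# ---------------------------------------------------------------------------
# prediction


@dataclass
class PredictionSet:
    """Per-image referable-DR scores and binary calls."""

    ids: list[str]
    scores: np.ndarray      # referable-class probability in [0,1]
    calls: np.ndarray       # 1 iff score >= threshold
    threshold: float = 0.5


def predict(model: Model, ids: list[str], x: np.ndarray,
            threshold: float = 0.5, batch_size: int = 128) -> PredictionSet:
    """Score images with the trained model; call = 1 iff score >= threshold."""
    if len(ids) != len(x):
        raise ValueError(f"{len(ids)} ids for {len(x)} images")
    scores = np.empty(len(x), dtype=np.float64)
    for lo in range(0, len(x), batch_size):
        logits = model.forward(np.asarray(x[lo:lo + batch_size],
                                          dtype=np.float32), train=False)
        scores[lo:lo + len(logits)] = _softmax(logits)[:, 1]
    calls = (scores >= threshold).astype(np.int64)
    return PredictionSet(ids=list(ids), scores=scores, calls=calls,
                         threshold=threshold)


def snapshot_model(model: Model) -> Model:
    """Deep copy (used to keep the best-iteration snapshot usable)."""
    return copy.deepcopy(model)
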