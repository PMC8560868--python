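"""The five-block 3D CNN: construction, defining reference operations, training.

Architecture (for a 79 x 95 x 69 input): five blocks of
[3x3x3 conv (11 filters, stride 1, same padding) -> batch-norm -> ELU ->
2x2x2 max-pool (stride 2, ceil-mode)], then FC 300 -> FC 100 -> FC 3 ->
dropout(0.1) -> softmax.  Ceil-mode pooling maps n -> ceil(n/2), so the five
pools take 79 x 95 x 69 to 3 x 3 x 3 with 11 channels (297 features).

All layers are implemented directly in numpy with full backpropagation and an
Adam optimizer; the vectorised convolution is independently checked against
``conv3d_reference``, a literal nested-sum evaluation of the defining
convolution equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import ConfusionMatrix

__all__ = [
    "elu",
    "conv3d_reference",
    "output_shape",
    "ConvBlockSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "Model3DCNN",
    "build_model",
    "finalize_batchnorm",
    "train",
    "predict",
    "ArchitectureError",
]


class ArchitectureError(ValueError):
    """Specification violates the fixed architecture contract."""


# ---------------------------------------------------------------------------
# reference operations
# ---------------------------------------------------------------------------

def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x >= 0, alpha*(e^x - 1) otherwise.
    Continuous at 0; accepts scalars or arrays."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return out.item() if out.ndim == 0 else out


def conv3d_reference(input_block, kernel_weights, bias=0.0, activation=None):
    """Literal nested-sum 3D convolution at a single output position.

    ``input_block`` and ``kernel_weights`` have shape (M, P, Q, R) — M input
    feature maps and a P x Q x R kernel (single-map inputs may omit M).  Returns
    ``f(b + sum_m sum_p sum_q sum_r w[m,p,q,r] * x[m,p,q,r])`` evaluated with
    explicit Python loops; serves as the oracle for the vectorised layer.
    """
    x = np.asarray(input_block, dtype=np.float64)
    w = np.asarray(kernel_weights, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if w.ndim == 3:
        w = w[None]
    if x.shape != w.shape:
        raise ArchitectureError(f"window {x.shape} does not match kernel {w.shape}")
    acc = float(bias)
    m_n, p_n, q_n, r_n = w.shape
    for m in range(m_n):
        for p in range(p_n):
            for q in range(q_n):
                for r in range(r_n):
                    acc += w[m, p, q, r] * x[m, p, q, r]
    return activation(acc) if activation is not None else acc


def output_shape(
    input_shape: tuple[int, int, int], n_blocks: int = 5
) -> list[tuple[int, int, int]]:
    """Spatial shape after each conv+pool block.

    Same-padded stride-1 convolution preserves the spatial extent; the
    ceil-mode 2x2x2 pool maps n -> ceil(n/2).  Raises if any dimension would
    reach 0.
    """
    shapes = []
    cur = tuple(int(n) for n in input_shape)
    if any(n < 1 for n in cur):
        raise ArchitectureError(f"input dimensions must be positive, got {cur}")
    for _ in range(n_blocks):
        cur = tuple(math.ceil(n / 2) for n in cur)
        shapes.append(cur)
    return shapes


# ---------------------------------------------------------------------------
# architecture / training specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv block: 3x3x3 kernel, 11 filters, stride 1, same padding,
    followed by batch-norm, ELU and a ceil-mode 2x2x2 max-pool."""

    kernel: tuple[int, int, int] = (3, 3, 3)
    filters: int = 11
    stride: int = 1

    def __post_init__(self) -> None:
        if self.kernel != (3, 3, 3) or self.filters != 11 or self.stride != 1:
            raise ArchitectureError(
                "conv blocks are fixed at 3x3x3 kernel, 11 filters, stride 1"
            )


@dataclass(frozen=True)
class ArchitectureSpec:
    blocks: tuple[ConvBlockSpec, ...] = tuple(ConvBlockSpec() for _ in range(5))
    fc_sizes: tuple[int, int, int] = (300, 100, 3)
    dropout_rate: float = 0.1
    elu_alpha: float = 1.0
    input_shape: tuple[int, int, int] = (79, 95, 69)

    def __post_init__(self) -> None:
        if len(self.blocks) != 5:
            raise ArchitectureError("exactly five conv blocks required")
        if self.fc_sizes[-1] != 3:
            raise ArchitectureError("final FC layer must have 3 units (3 classes)")
        if not 0 <= self.dropout_rate < 1:
            raise ArchitectureError(f"dropout_rate {self.dropout_rate} outside [0, 1)")
        if self.elu_alpha <= 0:
            raise ArchitectureError("elu_alpha must be positive")
        output_shape(self.input_shape)  # raises if a dimension collapses

    @property
    def pooled_shapes(self) -> list[tuple[int, int, int]]:
        return output_shape(self.input_shape, len(self.blocks))

    @property
    def flattened_features(self) -> int:
        return self.blocks[-1].filters * int(np.prod(self.pooled_shapes[-1]))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults are the study's stated values
    (Adam, lr 0.001, batch 2, 30 epochs); the L2 coefficient is exposed."""

    learning_rate: float = 0.001
    batch_size: int = 2
    max_epochs: int = 30
    l2_lambda: float = 1e-4
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"


# ---------------------------------------------------------------------------
# layers (numpy, float32, explicit backprop)
# ---------------------------------------------------------------------------

_DT = np.float32


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    l2_mask: list[bool]  # True where weight decay applies

    def __init__(self):
        self.params, self.grads, self.l2_mask = [], [], []

    def forward(self, x, train):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3D(_Layer):
    """Same-padded stride-1 3D convolution via sliding-window matmul."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * int(np.prod(kernel))
        fan_out = c_out * int(np.prod(kernel))
        limit = math.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(c_out, c_in, *kernel)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.l2_mask = [True, False]

    def forward(self, x, train):
        n, c, d, h, w = x.shape
        kd, kh, kw = self.k
        pad = [(0, 0), (0, 0)] + [((k - 1) // 2, k // 2) for k in self.k]
        xp = np.pad(x, pad)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=(2, 3, 4))
        # (n, c, d, h, w, kd, kh, kw) -> (n*d*h*w, c*kd*kh*kw)
        xcol = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * d * h * w, c * kd * kh * kw
        )
        wmat = self.w.reshape(self.c_out, -1)
        y = xcol @ wmat.T + self.b
        self._cache = (xcol, x.shape)
        return np.ascontiguousarray(
            y.reshape(n, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, dy):
        xcol, xshape = self._cache
        n, c, d, h, w = xshape
        kd, kh, kw = self.k
        dymat = np.ascontiguousarray(dy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.grads[0][...] = (dymat.T @ xcol).reshape(self.w.shape)
        self.grads[1][...] = dymat.sum(axis=0)
        dxcol = (dymat @ self.w.reshape(self.c_out, -1)).reshape(
            n, d, h, w, c, kd, kh, kw
        )
        pd, ph, pw = (kd - 1) // 2, (kh - 1) // 2, (kw - 1) // 2
        dxp = np.zeros((n, c, d + kd - 1, h + kh - 1, w + kw - 1), dtype=_DT)
        for p in range(kd):
            for q in range(kh):
                for r in range(kw):
                    dxp[:, :, p : p + d, q : q + h, r : r + w] += dxcol[
                        :, :, :, :, :, p, q, r
                    ].transpose(0, 4, 1, 2, 3)
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class BatchNorm3D(_Layer):
    def __init__(self, c, eps=1e-5, momentum=0.9):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(c, dtype=_DT)
        self.beta = np.zeros(c, dtype=_DT)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.l2_mask = [False, False]

    @staticmethod
    def _bc(v):
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mu.astype(_DT))) * self._bc(inv.astype(_DT))
        self._cache = (xhat, inv)
        return self._bc(self.gamma) * xhat + self._bc(self.beta)

    def backward(self, dy):
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        g = self._bc((self.gamma * inv.astype(_DT)))
        return g * (
            dy
            - self._bc(dy.mean(axis=axes))
            - xhat * self._bc((dy * xhat).mean(axis=axes))
        )


class ELU(_Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        y = np.where(x >= 0, x, self.alpha * np.expm1(np.minimum(x, 0.0))).astype(_DT)
        self._cache = (x >= 0, y)
        return y

    def backward(self, dy):
        pos, y = self._cache
        return dy * np.where(pos, 1.0, y + self.alpha).astype(_DT)


class MaxPool3D(_Layer):
    """2x2x2 max-pool, stride 2, ceil-mode (trailing edge padded with -inf)."""

    def forward(self, x, train):
        n, c, d, h, w = x.shape
        do, ho, wo = math.ceil(d / 2), math.ceil(h / 2), math.ceil(w / 2)
        pad = [(0, 0), (0, 0), (0, 2 * do - d), (0, 2 * ho - h), (0, 2 * wo - w)]
        xp = np.pad(x, pad, constant_values=-np.inf)
        win = xp.reshape(n, c, do, 2, ho, 2, wo, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(n, c, do, ho, wo, 8)
        idx = win.argmax(axis=-1)
        self._cache = (idx, x.shape, (do, ho, wo))
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        idx, xshape, (do, ho, wo) = self._cache
        n, c, d, h, w = xshape
        dwin = np.zeros((n, c, do, ho, wo, 8), dtype=_DT)
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dxp = dwin.reshape(n, c, do, ho, wo, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dxp = dxp.reshape(n, c, 2 * do, 2 * ho, 2 * wo)
        return dxp[:, :, :d, :h, :w]


class Flatten(_Layer):
    def forward(self, x, train):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._cache)


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.l2_mask = [True, False]

    def forward(self, x, train):
        self._cache = x
        return x @ self.w + self.b

    def backward(self, dy):
        x = self._cache
        self.grads[0][...] = x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Dropout(_Layer):
    """Inverted dropout; placed after the last FC layer, before the softmax."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._cache = None
            return x
        mask = (self.rng.random(x.shape) >= self.rate).astype(_DT) / (1 - self.rate)
        self._cache = mask
        return x * mask

    def backward(self, dy):
        return dy if self._cache is None else dy * self._cache


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class Model3DCNN:
    """The assembled network; layer order per block is conv -> BN -> ELU -> pool,
    then flatten -> FC 300 -> FC 100 -> FC 3 -> dropout -> softmax."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        c_in = 1
        for block in arch.blocks:
            self.layers.append(Conv3D(c_in, block.filters, block.kernel, rng))
            self.layers.append(BatchNorm3D(block.filters))
            self.layers.append(ELU(arch.elu_alpha))
            self.layers.append(MaxPool3D())
            c_in = block.filters
        self.layers.append(Flatten())
        n_in = arch.flattened_features
        for n_out in arch.fc_sizes:
            self.layers.append(Dense(n_in, n_out, rng))
            n_in = n_out
        self.layers.append(Dropout(arch.dropout_rate, rng))

    # -- introspection ------------------------------------------------------
    def layer_output_shapes(self) -> list[tuple]:
        """Per-layer output shapes (channels-first, batch omitted)."""
        shapes = []
        c, spatial = 1, self.arch.input_shape
        for block, pooled in zip(self.arch.blocks, self.arch.pooled_shapes):
            c = block.filters
            shapes.append(("conv+bn+elu", (c, *spatial)))
            spatial = pooled
            shapes.append(("maxpool", (c, *spatial)))
        n = self.arch.flattened_features
        for i, n_out in enumerate(self.arch.fc_sizes, start=1):
            shapes.append((f"fc{i}", (n_out,)))
            n = n_out
        shapes.append(("dropout", (n,)))
        shapes.append(("softmax", (n,)))
        return shapes

    def num_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (n, 1, d, h, w)."""
        out = np.asarray(x, dtype=_DT)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, train=False))

    def loss_and_grads(self, x, labels, l2_lambda):
        """Cross-entropy (+ L2 on conv/FC weights) and parameter gradients."""
        n = x.shape[0]
        logits = self.forward(x, train=True)
        probs = _softmax(logits)
        eps = 1e-12
        ce = -np.mean(np.log(probs[np.arange(n), labels] + eps))
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits = (dlogits / n).astype(_DT)
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        l2 = 0.0
        if l2_lambda > 0:
            for layer in self.layers:
                for p, g, decayed in zip(layer.params, layer.grads, layer.l2_mask):
                    if decayed:
                        l2 += 0.5 * l2_lambda * float(np.sum(p.astype(np.float64) ** 2))
                        g += (l2_lambda * p).astype(_DT)
        return ce + l2, ce


def finalize_batchnorm(model: "Model3DCNN", records, class_order=None, batch: int = 8) -> None:
    """Replace batch-norm running statistics with exact activation statistics
    over the given (un-augmented) training volumes.

    Training mini-batches see augmented inputs, but validation and test
    volumes are clean; statistics accumulated during training therefore
    describe the wrong input domain.  This pass recomputes each batch-norm
    layer's inference mean/variance from clean training-subject volumes —
    the same domain the network sees at evaluation — using only training
    subjects.  Layers are finalized front to back so deeper statistics are
    computed under the already-finalized shallower ones.
    """
    x = np.stack([r.volume for r in records]).astype(_DT)[:, None]
    bn_layers = [l for l in model.layers if isinstance(l, BatchNorm3D)]
    for target in bn_layers:
        c = target.gamma.size
        s = np.zeros(c, dtype=np.float64)
        sq = np.zeros(c, dtype=np.float64)
        count = 0
        for start in range(0, x.shape[0], batch):
            out = x[start : start + batch]
            for layer in model.layers:
                if layer is target:
                    break
                out = layer.forward(out, train=False)
            s += out.astype(np.float64).sum(axis=(0, 2, 3, 4))
            sq += (out.astype(np.float64) ** 2).sum(axis=(0, 2, 3, 4))
            count += out.shape[0] * out.shape[2] * out.shape[3] * out.shape[4]
        mean = s / count
        target.running_mean = mean
        target.running_var = np.maximum(sq / count - mean**2, 0.0)


def build_model(arch: ArchitectureSpec | None = None, seed: int = 0) -> Model3DCNN:
    """Construct the network from an :class:`ArchitectureSpec` (validated
    against the fixed-architecture contract)."""
    return Model3DCNN(arch or ArchitectureSpec(), seed=seed)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, model, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = [
            (p, g, np.zeros_like(p, dtype=np.float64), np.zeros_like(p, dtype=np.float64))
            for layer in model.layers
            for p, g in zip(layer.params, layer.grads)
        ]

    def step(self):
        self.t += 1
        for p, g, m, v in self.slots:
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g.astype(np.float64) ** 2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DT)


def _stack(records, class_order) -> tuple[np.ndarray, np.ndarray]:
    idx = {lab: i for i, lab in enumerate(class_order)}
    x = np.stack([r.volume for r in records]).astype(_DT)[:, None]
    y = np.array([idx[r.label] for r in records], dtype=np.int64)
    return x, y


def train(model, train_records, val_records, cfg: TrainConfig, class_order):
    """Mini-batch Adam training; deterministic given ``cfg.seed``.

    ``class_order`` fixes the label -> output-unit mapping (the task's three
    classes).  Returns a per-epoch list of dicts with loss and accuracies.
    """
    if not train_records:
        raise ValueError("empty training set")
    for r in train_records:
        if r.label not in class_order:
            raise ValueError(f"label {r.label} outside task classes {class_order}")
    x_tr, y_tr = _stack(train_records, class_order)
    opt = _Adam(model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    log = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_records))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            total, _ce = model.loss_and_grads(x_tr[sel], y_tr[sel], cfg.l2_lambda)
            opt.step()
            losses.append(total)
        entry = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        entry["train_accuracy"] = _accuracy(model, x_tr, y_tr)
        if val_records:
            x_va, y_va = _stack(val_records, class_order)
            entry["val_accuracy"] = _accuracy(model, x_va, y_va)
        log.append(entry)
    return log


def _accuracy(model, x, y, batch=8) -> float:
    correct = 0
    for start in range(0, len(y), batch):
        p = model.predict_proba(x[start : start + batch])
        correct += int((p.argmax(axis=1) == y[start : start + batch]).sum())
    return correct / len(y)


def predict(model, records, class_order) -> ConfusionMatrix:
    """Argmax-of-softmax predictions tallied into a confusion matrix
    (rows = true class, columns = predicted)."""
    x, y = _stack(records, class_order)
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    batch = 8
    for start in range(0, len(y), batch):
        pred = model.predict_proba(x[start : start + batch]).argmax(axis=1)
        for t, p in zip(y[start : start + batch], pred):
            counts[t, p] += 1
    names = [getattr(lab, "value", str(lab)) for lab in class_order]
    return ConfusionMatrix(counts, names)
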