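"""The lightweight lead-flexible convolutional network.

Architecture (valid padding everywhere, L leads x W samples in, 20
sigmoid scores out):

1. a stem convolution with one 1x1 filter — a per-sample affine map
   shared across leads;
2. six convolve-normalize-pool blocks: a 1xk convolution with dilation 2
   (kernels 5,5,5 then 3,3,3; 16,16,32,32,64,64 output channels), batch
   normalization, a rectifier, and a 1x2 max-pool on the temporal axis
   only.  Each lead is filtered independently — the lead axis is never
   mixed here;
3. a 1x1 convolution with 128 filters projecting each lead's 64 features
   to 128 (default "per_lead" fusion), or a dense lead-spanning
   projection of the concatenated L x 64 features to 128 ("spanning"
   fusion);
4. a fully connected layer to 20 independent sigmoid units, one per
   diagnostic class.

With the default kernels the temporal receptive field is 344 samples
(3.44 s at 100 Hz) and an input window of exactly 344 samples collapses
to a single temporal position after block 6.

The layers implement their own forward/backward passes on NumPy arrays;
the lead axis is folded into the batch axis through the per-lead
sections, so batch-norm statistics pool over records, leads and time
exactly as a 2-D convolutional implementation with 1xk kernels would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Compute dtype for the network (single precision is ample for training).
DTYPE = np.float32

BLOCK_CHANNELS = (16, 16, 32, 32, 64, 64)
BLOCK_KERNELS = (5, 5, 5, 3, 3, 3)


@dataclass(frozen=True)
class ModelSpec:
    """Full hyperparameter description of the network for a lead count L."""

    n_leads: int = 12
    input_width: int = 344
    block_channels: tuple[int, ...] = BLOCK_CHANNELS
    block_kernels: tuple[int, ...] = BLOCK_KERNELS
    dilation: int = 2
    head_channels: int = 128
    n_classes: int = 20
    fusion: str = "per_lead"          # "per_lead" | "spanning"

    def __post_init__(self) -> None:
        if not 1 <= self.n_leads <= 12:
            raise ValueError("n_leads must be between 1 and 12")
        if len(self.block_channels) != len(self.block_kernels):
            raise ValueError("block_channels and block_kernels lengths differ")
        if self.fusion not in ("per_lead", "spanning"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")

    def effective_kernel(self, k: int) -> int:
        return self.dilation * (k - 1) + 1


def receptive_field(spec: ModelSpec) -> int:
    """Temporal receptive field (input samples) of the block-6 features.

    Closed-form accumulation: each valid convolution adds
    (k_eff - 1) * jump, each 1x2 pool adds jump and doubles it.
    """
    rf, jump = 1, 1
    for k in spec.block_kernels:
        rf += (spec.effective_kernel(k) - 1) * jump
        rf += jump            # pool kernel 2, stride 2
        jump *= 2
    return rf


def output_length(spec: ModelSpec, width: int) -> int:
    """Temporal positions remaining after block 6 for an input of ``width``.

    Returns 0 when the input is too narrow to be valid.
    """
    t = int(width)
    for k in spec.block_kernels:
        t -= spec.effective_kernel(k) - 1
        if t <= 0:
            return 0
        t //= 2
    return t


def minimum_width(spec: ModelSpec) -> int:
    """Smallest input width with a non-empty block-6 output.

    Walks the layer arithmetic backwards from one output position; for
    the default spec this equals the receptive field (344).
    """
    t = 1
    for k in reversed(spec.block_kernels):
        t *= 2
        t += spec.effective_kernel(k) - 1
    return t


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form learnable parameter count (must match the built network).

    Stem 1x1: 2.  Block i: k_i * c_{i-1} * c_i + c_i conv parameters plus
    2 * c_i batch-norm scale/shift (running statistics are not learnable).
    Default fusion: a per-lead 64->128 1x1 convolution then a dense layer
    over the concatenated L x 128 features; spanning fusion: a dense
    lead-spanning 64L -> 128 projection then 128 -> 20.
    """
    t_out = output_length(spec, spec.input_width)
    if t_out < 1:
        raise ValueError(
            f"input width {spec.input_width} below the minimum valid width "
            f"{minimum_width(spec)}"
        )
    total = 2
    c_prev = 1
    for c, k in zip(spec.block_channels, spec.block_kernels):
        total += k * c_prev * c + c     # conv weights + bias
        total += 2 * c                  # batch-norm gamma/beta
        c_prev = c
    h = spec.head_channels
    if spec.fusion == "per_lead":
        total += c_prev * h + h
        total += h * spec.n_leads * t_out * spec.n_classes + spec.n_classes
    else:
        total += c_prev * spec.n_leads * t_out * h + h
        total += h * spec.n_classes + spec.n_classes
    return total


# --------------------------------------------------------------------------
# layers (NumPy forward/backward)
# --------------------------------------------------------------------------


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Scale(Layer):
    """Per-sample affine map y = w x + b with scalar w, b (the 1x1 stem)."""

    def __init__(self) -> None:
        self.w = np.ones(1, dtype=DTYPE)
        self.b = np.zeros(1, dtype=DTYPE)
        self.gw = np.zeros(1, dtype=DTYPE)
        self.gb = np.zeros(1, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return self.w[0] * x + self.b[0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw[0] = float(np.sum(gy * self._x))
        self.gb[0] = float(np.sum(gy))
        return self.w[0] * gy

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]


class Conv1d(Layer):
    """Valid 1-D convolution (cross-correlation) with dilation."""

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int, rng) -> None:
        fan_in = c_in * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k, self.d = k, dilation

    def _t_out(self, t_in: int) -> int:
        k_eff = self.d * (self.k - 1) + 1
        t_out = t_in - k_eff + 1
        if t_out < 1:
            raise ValueError(
                f"input of width {t_in} too narrow for kernel {self.k} "
                f"with dilation {self.d}"
            )
        return t_out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # y[b,o,t] = sum_j w[:,:,j] @ x[b,:,t+j*d]: one batched matmul per tap
        t_out = self._t_out(x.shape[2])
        y = np.matmul(self.w[:, :, 0], x[:, :, :t_out])
        for j in range(1, self.k):
            y += np.matmul(self.w[:, :, j], x[:, :, j * self.d : j * self.d + t_out])
        y += self.b[None, :, None]
        if training:
            self._x = x
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        t_out = gy.shape[2]
        self.gb[...] = gy.sum(axis=(0, 2))
        gx = np.zeros_like(x)
        for j in range(self.k):
            sl = slice(j * self.d, j * self.d + t_out)
            # gw[:,:,j] = sum_b gy_b @ x_b[:, sl].T
            self.gw[:, :, j] = np.matmul(
                gy, x[:, :, sl].transpose(0, 2, 1)
            ).sum(axis=0)
            gx[:, :, sl] += np.matmul(self.w[:, :, j].T, gy)
        return gx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]


class BatchNorm1d(Layer):
    """Channel-wise batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.ggamma = np.zeros(c, dtype=DTYPE)
        self.gbeta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv[None, :, None]
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None]) * inv[None, :, None]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = gy.shape[0] * gy.shape[2]
        self.ggamma[...] = np.sum(gy * xhat, axis=(0, 2))
        self.gbeta[...] = np.sum(gy, axis=(0, 2))
        gy_mean = self.gbeta / m
        gyx_mean = self.ggamma / m
        gx = (
            self.gamma[None, :, None]
            * inv[None, :, None]
            * (gy - gy_mean[None, :, None] - xhat * gyx_mean[None, :, None])
        )
        return gx

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool1d(Layer):
    """1x2 max-pool, stride 2, temporal axis only (odd tail dropped)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, t = x.shape
        t2 = t // 2
        pairs = x[:, :, : 2 * t2].reshape(b, c, t2, 2)
        idx = pairs.argmax(axis=3)
        if training:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(pairs, idx[..., None], axis=3)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, t = self._shape
        t2 = t // 2
        gpairs = np.zeros((b, c, t2, 2), dtype=gy.dtype)
        np.put_along_axis(gpairs, self._idx[..., None], gy[..., None], axis=3)
        gx = np.zeros((b, c, t), dtype=gy.dtype)
        gx[:, :, : 2 * t2] = gpairs.reshape(b, c, 2 * t2)
        return gx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng) -> None:
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_out, n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw[...] = gy.T @ self._x
        self.gb[...] = gy.sum(axis=0)
        return gy @ self.w

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# --------------------------------------------------------------------------
# the assembled network
# --------------------------------------------------------------------------


class Network:
    """The assembled model: forward, backward and parameter access.

    Input arrays are (N, L, W); the output of :meth:`forward` is the
    (N, 20) array of pre-sigmoid logits (use :meth:`predict_proba` for
    class scores in (0, 1)).
    """

    def __init__(self, spec: ModelSpec, seed: int | None = 0) -> None:
        width = spec.input_width
        t_out = output_length(spec, width)
        if t_out < 1:
            raise ValueError(
                f"input width {width} below the minimum valid width "
                f"{minimum_width(spec)} for this spec"
            )
        self.spec = spec
        self.t_out = t_out
        rng = np.random.default_rng(seed)

        self.stem = Scale()
        self.blocks: list[list[Layer]] = []
        c_prev = 1
        for c, k in zip(spec.block_channels, spec.block_kernels):
            self.blocks.append(
                [
                    Conv1d(c_prev, c, k, spec.dilation, rng),
                    BatchNorm1d(c),
                    ReLU(),
                    MaxPool1d(),
                ]
            )
            c_prev = c
        self._c_feat = c_prev

        h, L, n_cls = spec.head_channels, spec.n_leads, spec.n_classes
        if spec.fusion == "per_lead":
            self.head_conv = Conv1d(c_prev, h, 1, 1, rng)
            self.head_relu = ReLU()
            self.fc = Dense(h * L * t_out, n_cls, rng)
        else:
            self.head_conv = None
            self.head_dense = Dense(c_prev * L * t_out, h, rng)
            self.head_relu = ReLU()
            self.fc = Dense(h, n_cls, rng)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self) -> list[Layer]:
        layers: list[Layer] = [self.stem]
        for block in self.blocks:
            layers.extend(block)
        if self.head_conv is not None:
            layers.extend([self.head_conv, self.head_relu, self.fc])
        else:
            layers.extend([self.head_dense, self.head_relu, self.fc])
        return layers

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    @property
    def n_parameters(self) -> int:
        """Trainable parameter count of the materialized arrays."""
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(weights):
            raise ValueError("weight list does not match this architecture")
        for p, w in zip(own, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def _feature_stack(self, x: np.ndarray, training: bool) -> np.ndarray:
        """Stem + six blocks on lead-folded input (N*L, 1, W) -> (N*L, 64, t)."""
        y = self.stem.forward(x, training)
        for block in self.blocks:
            for layer in block:
                y = layer.forward(y, training)
        return y

    def lead_features(self, x: np.ndarray) -> np.ndarray:
        """Pre-fusion per-lead features, eval mode: (N, L, 64, t_out).

        Up to this point each lead is filtered independently, so the
        feature block of lead i must not change when another lead does.
        """
        x = self._check_input(x)
        n, L, w = x.shape
        feats = self._feature_stack(x.reshape(n * L, 1, w), training=False)
        return feats.reshape(n, L, feats.shape[1], feats.shape[2])

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.spec.n_leads:
            raise ValueError(
                f"expected input of shape (N, {self.spec.n_leads}, W), "
                f"got {x.shape}"
            )
        if x.shape[2] != self.spec.input_width:
            raise ValueError(
                f"input width {x.shape[2]} does not match the spec width "
                f"{self.spec.input_width} (the crop width must equal the "
                "network receptive field)"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        n, L, w = x.shape
        self._n = n
        y = self._feature_stack(x.reshape(n * L, 1, w), training)
        if self.head_conv is not None:
            y = self.head_conv.forward(y, training)
            y = self.head_relu.forward(y, training)
            y = y.reshape(n, -1)
        else:
            y = y.reshape(n, -1)
            y = self.head_dense.forward(y, training)
            y = self.head_relu.forward(y, training)
        return self.fc.forward(y, training)

    def backward(self, glogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        g = self.fc.backward(glogits)
        n = self._n
        if self.head_conv is not None:
            g = g.reshape(n * self.spec.n_leads, self.spec.head_channels, self.t_out)
            g = self.head_relu.backward(g)
            g = self.head_conv.backward(g)
        else:
            g = self.head_relu.backward(g)
            g = self.head_dense.backward(g)
            g = g.reshape(n * self.spec.n_leads, self._c_feat, self.t_out)
        for block in reversed(self.blocks):
            for layer in reversed(block):
                g = layer.backward(g)
        self.stem.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class scores in (0, 1): one independent sigmoid per class."""
        return sigmoid(self.forward(x, training=False))


def build_network(spec: ModelSpec, seed: int | None = 0) -> Network:
    """Instantiate the network for ``spec`` with seeded initialization."""
    return Network(spec, seed=seed)


def describe(spec: ModelSpec) -> str:
    """Human-readable layer table with receptive field and parameter count."""
    lines = [
        f"Lead-flexible ECG network  (L={spec.n_leads}, W={spec.input_width}, "
        f"fusion={spec.fusion})",
        f"{'layer':<28}{'kernel':>8}{'dil':>5}{'ch out':>8}{'params':>10}",
    ]
    lines.append(f"{'stem conv 1x1':<28}{'1':>8}{'-':>5}{'1':>8}{2:>10}")
    c_prev = 1
    for i, (c, k) in enumerate(zip(spec.block_channels, spec.block_kernels), 1):
        p = k * c_prev * c + c + 2 * c
        lines.append(
            f"{f'block {i}: conv-bn-relu-pool':<28}{f'1x{k}':>8}"
            f"{spec.dilation:>5}{c:>8}{p:>10}"
        )
        c_prev = c
    t_out = output_length(spec, spec.input_width)
    h = spec.head_channels
    if spec.fusion == "per_lead":
        lines.append(
            f"{'head conv 1x1 (per lead)':<28}{'1x1':>8}{'-':>5}{h:>8}"
            f"{c_prev * h + h:>10}"
        )
        fc_p = h * spec.n_leads * t_out * spec.n_classes + spec.n_classes
    else:
        lines.append(
            f"{'head dense (lead-spanning)':<28}{'-':>8}{'-':>5}{h:>8}"
            f"{c_prev * spec.n_leads * t_out * h + h:>10}"
        )
        fc_p = h * spec.n_classes + spec.n_classes
    lines.append(
        f"{'output dense, 20 sigmoid':<28}{'-':>8}{'-':>5}{spec.n_classes:>8}"
        f"{fc_p:>10}"
    )
    lines.append("")
    lines.append(f"receptive field : {receptive_field(spec)} samples")
    lines.append(f"output length   : {t_out} temporal position(s)")
    lines.append(f"parameters      : {count_parameters(spec):,}")
    return "\n".join(lines)
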