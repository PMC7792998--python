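"""Two-branch encoder-decoder CNN for diffraction inversion.

Maps an oversampled diffraction modulus (n x n) to the particle's amplitude
and scaled-phase images (n/2 x n/2 each): a shared convolutional encoder
(3x3 conv + LRLU + BN blocks and separable 3x1 + 1x3 blocks, max-pooled per
level) whose bottleneck features are split equally between two independent
upsampling decoders, one per output channel.  All activations are leaky
ReLUs; the final convolution of each head stays leaky while training (so a
head whose pre-activation drifts all-negative keeps receiving gradient) and
is clipped to the nonnegative range at inference, so emitted amplitude and
scaled phase are always >= 0.

The training loss couples real and reciprocal space: mean squared error on
both heads (mean absolute error available via ``LossWeights.real_norm``)
plus a modulus-consistency term, the normalized quadratic misfit
between the Fourier modulus of the predicted complex image and the measured
input modulus.

The network, its backward pass and the Adam optimizer are implemented
directly on NumPy arrays (im2col convolutions, analytic FFT-loss gradient),
so training is CPU-only and fully deterministic given a seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .forward_model import cfft2, cifft2, crop_center, embed_centered
from .simulator import ComplexImage2D, Dataset, DiffractionPattern, unscale_phase

__all__ = [
    "ModelConfig",
    "LossWeights",
    "TrainedModel",
    "build_model",
    "count_parameters",
    "composite_loss",
    "train",
    "infer",
    "evaluate_on_split",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``depth`` pooling levels halve the input ``depth`` times; the decoders
    upsample ``depth - 1`` times, so each output is half the input size per
    dimension (one quarter of the pattern area), keeping the inversion
    overdetermined.
    """

    input_size: int = 64
    base_channels: int = 16
    depth: int = 3
    negative_slope: float = 0.1
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def output_size(self) -> int:
        return self.input_size // 2


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three loss terms (real amp, real phase, reciprocal).

    ``real_norm`` selects the real-space penalty: "l2" (mean squared error,
    the default) or "l1" (mean absolute error).  The targets are sparse —
    most amplitude pixels are zero at any given location — so the L1
    optimum for an untrained network is the near-zero per-pixel median,
    which starves the amplitude head; L2 regresses toward the mean and is
    well conditioned at every training scale.
    """

    w_amp: float = 1.0
    w_phase: float = 1.0
    w_recip: float = 1.0
    real_norm: str = "l2"

    def __post_init__(self) -> None:
        if min(self.w_amp, self.w_phase, self.w_recip) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_amp + self.w_phase + self.w_recip == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.real_norm not in ("l1", "l2"):
            raise ValueError("real_norm must be 'l1' or 'l2'")


# --------------------------------------------------------------------------
# layers (forward + hand-written backward)
# --------------------------------------------------------------------------

class Conv2D:
    """Same-padding stride-1 convolution with odd kernel (kh, kw).

    Arrays are channels-last (N, H, W, C); the convolution is evaluated as
    one matrix product per kernel tap on shifted views of the padded input,
    which avoids materialising an im2col buffer.
    """

    def __init__(self, cin: int, cout: int, kh: int, kw: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        fan_in = cin * kh * kw
        self.W = (rng.standard_normal((kh, kw, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.kh, self.kw = kh, kw
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._xp = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, H, W, _ = x.shape
        xp = self._pad(x)
        if train:
            self._xp = xp
            self._hw = (H, W)
        y = np.zeros((N, H, W, self.W.shape[-1]), dtype=x.dtype)
        for u in range(self.kh):
            for v in range(self.kw):
                y += xp[:, u : u + H, v : v + W, :] @ self.W[u, v]
        return y + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, (H, W) = self._xp, self._hw
        self._xp = None
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        gxp = np.zeros_like(xp)
        for u in range(self.kh):
            for v in range(self.kw):
                xs = xp[:, u : u + H, v : v + W, :]
                self.grads[0][u, v] = np.tensordot(xs, gy, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, u : u + H, v : v + W, :] += gy @ self.W[u, v].T
        self.grads[1][...] = gy.sum(axis=(0, 1, 2))
        return gxp[:, ph : ph + H, pw : pw + W, :]


class LeakyReLU:
    def __init__(self, negative_slope: float) -> None:
        self.alpha = negative_slope
        self.params, self.grads = [], []
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.alpha * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, gy, self.alpha * gy)
        self._mask = None
        return gx


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(0.0)


class HeadActivation:
    """Softplus output activation of the two heads.

    A plain-ReLU head whose pre-activation drifts uniformly negative is an
    absorbing state (zero gradient forever), and such mid-training head
    collapses were observed with some seeds.  A leaky head is no fix: the
    reciprocal loss term is invariant under an amplitude sign flip absorbed
    into the phase, so a sign-permitting amplitude can satisfy it while the
    inference-time clip destroys the image.  Softplus has strictly positive
    gradient everywhere, is exactly nonnegative, and behaves identically in
    training and inference.
    """

    def __init__(self) -> None:
        self.params, self.grads = [], []
        self._sig = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        if train:
            self._sig = 1.0 / (1.0 + np.exp(-x))
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._sig
        self._sig = None
        return gx


class BatchNorm2D:
    """Per-channel normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = gy.shape[0] * gy.shape[1] * gy.shape[2]
        self.grads[0][...] = (gy * xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma
        mean_g = gxhat.sum(axis=(0, 1, 2)) / m
        mean_gx = (gxhat * xhat).sum(axis=(0, 1, 2)) / m
        return inv * (gxhat - mean_g - xhat * mean_gx)


class MaxPool2:
    def __init__(self) -> None:
        self.params, self.grads = [], []
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(N, H // 2, W // 2, C, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        self._cache = None
        N, H, W, C = xshape
        flat = np.zeros((N, H // 2, W // 2, C, 4), dtype=gy.dtype)
        np.put_along_axis(flat, idx[..., None], gy[..., None], axis=-1)
        xr = flat.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(xr.reshape(N, H, W, C))


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        N, H, W, C = gy.shape
        return gy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def _conv_block(cin: int, cout: int, cfg: ModelConfig, rng, dtype) -> list:
    layers = [Conv2D(cin, cout, 3, 3, rng, dtype), LeakyReLU(cfg.negative_slope)]
    if cfg.batch_norm:
        layers.append(BatchNorm2D(cout, dtype))
    return layers


def _sep_block(cin: int, cout: int, cfg: ModelConfig, rng, dtype) -> list:
    layers = [
        Conv2D(cin, cout, 3, 1, rng, dtype),
        Conv2D(cout, cout, 1, 3, rng, dtype),
        LeakyReLU(cfg.negative_slope),
    ]
    if cfg.batch_norm:
        layers.append(BatchNorm2D(cout, dtype))
    return layers


# --------------------------------------------------------------------------
# the two-branch model
# --------------------------------------------------------------------------

class TwoBranchCNN:
    """Shared encoder, bottleneck split equally into two decoders."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        cfg, d = config, config.depth
        enc: list = []
        cin = 1
        for lvl in range(d):
            c = cfg.base_channels * 2**lvl
            enc += _conv_block(cin, c, cfg, rng, dtype)
            enc += _sep_block(c, c, cfg, rng, dtype)
            enc.append(MaxPool2())
            cin = c
        cb = cfg.base_channels * 2**d  # bottleneck channels, split in half
        enc += _conv_block(cin, cb, cfg, rng, dtype)
        self.encoder = enc
        self.split = cb // 2

        def make_decoder() -> list:
            dec: list = []
            c = cb // 2
            for _ in range(d - 1):
                dec.append(Upsample2())
                dec += _conv_block(c, max(c // 2, cfg.base_channels // 2), cfg, rng, dtype)
                c = max(c // 2, cfg.base_channels // 2)
                dec += _sep_block(c, c, cfg, rng, dtype)
            head = Conv2D(c, 1, 3, 3, rng, dtype)
            dec.append(head)
            dec.append(HeadActivation())
            return dec

        self.dec_amp = make_decoder()
        self.dec_phase = make_decoder()

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list:
        return self.encoder + self.dec_amp + self.dec_phase

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            p[...] = w
        # running BN statistics ride along with get/set via state below

    def get_state(self) -> dict:
        state = {"weights": self.get_weights(), "bn": []}
        for layer in self.layers():
            if isinstance(layer, BatchNorm2D):
                state["bn"].append((layer.running_mean.copy(), layer.running_var.copy()))
        return state

    def set_state(self, state: dict) -> None:
        self.set_weights(state["weights"])
        bns = [l for l in self.layers() if isinstance(l, BatchNorm2D)]
        for layer, (m, v) in zip(bns, state["bn"]):
            layer.running_mean[...] = m
            layer.running_var[...] = v

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, n, n) normalized moduli -> (amp, phase) each (N, n/2, n/2)."""
        h = x[..., None]  # channels-last
        for layer in self.encoder:
            h = layer.forward(h, train)
        ha, hp = h[..., : self.split], h[..., self.split :]
        for layer in self.dec_amp:
            ha = layer.forward(ha, train)
        for layer in self.dec_phase:
            hp = layer.forward(hp, train)
        return ha[..., 0], hp[..., 0]

    def backward(self, g_amp: np.ndarray, g_phase: np.ndarray) -> None:
        g_amp = np.ascontiguousarray(g_amp[..., None])
        g_phase = np.ascontiguousarray(g_phase[..., None])
        for layer in reversed(self.dec_amp):
            g_amp = layer.backward(g_amp)
        for layer in reversed(self.dec_phase):
            g_phase = layer.backward(g_phase)
        g = np.concatenate([g_amp, g_phase], axis=-1)
        for layer in reversed(self.encoder):
            g = layer.backward(g)


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> TwoBranchCNN:
    return TwoBranchCNN(config, seed=seed, dtype=dtype)


def count_parameters(model: TwoBranchCNN) -> int:
    return int(sum(p.size for p in model.parameters()))


# --------------------------------------------------------------------------
# composite loss (real + reciprocal space) with analytic gradients
# --------------------------------------------------------------------------

def _recip_term_and_grad(
    amp: np.ndarray, phase_scaled: np.ndarray, meas_modulus: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Modulus-consistency term for one sample, plus gradients.

    Both moduli are L2-normalized before comparison, so the term is
    insensitive to the overall intensity scale and vanishes exactly when
    the predicted complex image reproduces the measured modulus.
    """
    n = meas_modulus.shape[0]
    theta = 2 * np.pi * phase_scaled - np.pi
    z = amp * np.exp(1j * theta)
    Z = embed_centered(z, n)
    G = cfft2(Z)
    g = np.abs(G)
    ng = np.linalg.norm(g)
    nm = np.linalg.norm(meas_modulus)
    if ng == 0 or nm == 0:
        return 0.0, np.zeros_like(amp), np.zeros_like(phase_scaled)
    u = g / ng
    v = meas_modulus / nm
    r = u - v
    term = float((r**2).sum())
    # gradient through the normalization, the modulus and the DFT
    dg = (2.0 / ng) * (r - u * float((u * r).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        gG = np.where(g > 0, dg * G / g, 0.0)
    gZ = (n * n) * cifft2(gG)
    gz = crop_center(gZ, amp.shape[0])
    e = np.exp(-1j * theta)
    g_amp = np.real(e * gz)
    g_theta = amp * np.imag(e * gz)
    return term, g_amp, (2 * np.pi) * g_theta


def _loss_and_grads(
    pred_amp: np.ndarray,
    pred_phase: np.ndarray,
    true_amp: np.ndarray,
    true_phase: np.ndarray,
    meas_modulus: np.ndarray,
    weights: LossWeights,
) -> tuple[float, dict, np.ndarray, np.ndarray]:
    """Batched loss with gradients wrt both heads; arrays are (N, h, h)."""
    N = pred_amp.shape[0]
    npix = pred_amp[0].size
    d_amp = pred_amp - true_amp
    d_phase = pred_phase - true_phase
    if weights.real_norm == "l1":
        mae_amp = float(np.abs(d_amp).mean())
        mae_phase = float(np.abs(d_phase).mean())
        g_amp = weights.w_amp * np.sign(d_amp) / (npix * N)
        g_phase = weights.w_phase * np.sign(d_phase) / (npix * N)
    else:
        mae_amp = float((d_amp**2).mean())
        mae_phase = float((d_phase**2).mean())
        g_amp = weights.w_amp * 2.0 * d_amp / (npix * N)
        g_phase = weights.w_phase * 2.0 * d_phase / (npix * N)
    recip = 0.0
    if weights.w_recip > 0:
        for i in range(N):
            term, ga, gp = _recip_term_and_grad(
                pred_amp[i].astype(np.float64),
                pred_phase[i].astype(np.float64),
                meas_modulus[i].astype(np.float64),
            )
            recip += term
            g_amp[i] += weights.w_recip * ga / N
            g_phase[i] += weights.w_recip * gp / N
        recip /= N
    total = weights.w_amp * mae_amp + weights.w_phase * mae_phase + weights.w_recip * recip
    breakdown = {"amp": mae_amp, "phase": mae_phase, "recip": recip, "total": total}
    return total, breakdown, g_amp, g_phase


def composite_loss(
    pred_amp: np.ndarray,
    pred_phase_scaled: np.ndarray,
    true_amp: np.ndarray,
    true_phase_scaled: np.ndarray,
    input_modulus: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> tuple[float, dict]:
    """Scalar loss + per-term breakdown for a single sample (or batch)."""
    arrs = [np.asarray(a, dtype=float) for a in
            (pred_amp, pred_phase_scaled, true_amp, true_phase_scaled, input_modulus)]
    if arrs[0].ndim == 2:
        arrs = [a[None] for a in arrs]
    if not all(np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("loss inputs must be finite")
    total, breakdown, _, _ = _loss_and_grads(*arrs, weights)
    return total, breakdown


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """Weights + architecture + input-normalization spec + training history."""

    config: ModelConfig
    model: TwoBranchCNN
    normalization: str = "per_pattern_max_modulus"
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    loss_weights: LossWeights = field(default_factory=LossWeights)


def normalize_pattern(intensity: np.ndarray) -> np.ndarray:
    """Per-pattern max-normalized modulus: the network's physical input."""
    m = np.sqrt(np.asarray(intensity, dtype=np.float64))
    peak = m.max()
    if peak == 0:
        raise ValueError("empty pattern")
    return m / peak


def _dataset_arrays(dataset: Dataset, idx: np.ndarray):
    X = np.stack([normalize_pattern(dataset.samples[i].pattern.intensity) for i in idx])
    A = dataset.amplitudes(idx)
    P = dataset.phases_scaled(idx)
    return X.astype(np.float32), A.astype(np.float32), P.astype(np.float32)


def train(
    dataset: Dataset,
    config: ModelConfig,
    weights: LossWeights = LossWeights(),
    epochs: int = 30,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> TrainedModel:
    """Supervised training on the simulated corpus; keeps the best-validation
    weights.  Deterministic given the seed (pure NumPy arithmetic)."""
    if len(dataset.train_idx) == 0:
        raise ValueError("dataset has no training split")
    Xtr, Atr, Ptr = _dataset_arrays(dataset, dataset.train_idx)
    has_val = len(dataset.val_idx) > 0
    if has_val:
        Xva, Ava, Pva = _dataset_arrays(dataset, dataset.val_idx)

    model = build_model(config, seed=seed)
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    history = {"train_loss": [], "val_loss": []}
    best = None

    n = len(Xtr)
    for epoch in range(epochs):
        order = rng.permutation(n)
        running = 0.0
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            pa, pp = model.forward(Xtr[sel], train=True)
            loss, _, ga, gp = _loss_and_grads(
                pa, pp, Atr[sel], Ptr[sel], Xtr[sel], weights
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}; "
                    "reduce the learning rate"
                )
            model.backward(ga.astype(np.float32), gp.astype(np.float32))
            opt.step(model.gradients())
            running += loss * len(sel)
        history["train_loss"].append(running / n)

        if has_val:
            val = _eval_loss(model, Xva, Ava, Pva, weights, batch_size)
        else:
            val = history["train_loss"][-1]
        history["val_loss"].append(val)
        if best is None or val < best[0]:
            best = (val, model.get_state())

    model.set_state(best[1])
    return TrainedModel(config=config, model=model, history=history, loss_weights=weights)


def _eval_loss(model, X, A, P, weights, batch_size) -> float:
    total = 0.0
    for start in range(0, len(X), batch_size):
        sl = slice(start, start + batch_size)
        pa, pp = model.forward(X[sl], train=False)
        loss, _, _, _ = _loss_and_grads(pa, pp, A[sl], P[sl], X[sl], weights)
        total += loss * pa.shape[0]
    return total / len(X)


# --------------------------------------------------------------------------
# inference and evaluation
# --------------------------------------------------------------------------

def infer(
    trained: TrainedModel,
    pattern: DiffractionPattern,
    support_threshold: float = 0.05,
) -> tuple[ComplexImage2D, np.ndarray]:
    """Predict amplitude and phase for one pattern.

    Returns the complex image (phase unscaled to [-pi, pi], zeroed below the
    amplitude support threshold) and the raw scaled-phase map in [0, 1].
    """
    n = trained.config.input_size
    inten = np.asarray(pattern.intensity)
    if inten.shape != (n, n):
        raise ValueError(f"pattern shape {inten.shape} does not match input_size {n}")
    x = normalize_pattern(inten).astype(np.float32)[None]
    pa, pp = trained.model.forward(x, train=False)
    amp = np.clip(pa[0].astype(np.float64), 0.0, None)
    phase_scaled = np.clip(pp[0].astype(np.float64), 0.0, 1.0)
    # the raw scaled map is returned untouched (it is what the loss and the
    # real-space metrics are defined on); only the unscaled phase image is
    # masked to the predicted support
    support = amp >= support_threshold * amp.max() if amp.max() > 0 else amp > 0
    phase = unscale_phase(np.where(support, phase_scaled, 0.0), support)
    return ComplexImage2D(amplitude=amp, phase=phase), phase_scaled


def _chi2_modulus_of_image(image: ComplexImage2D, pattern: DiffractionPattern) -> float:
    from .baselines import chi2_modulus

    n = pattern.intensity.shape[0]
    G = cfft2(embed_centered(image.density, n))
    calc = np.abs(G)
    meas = pattern.modulus
    scale = np.linalg.norm(meas) / max(np.linalg.norm(calc), 1e-300)
    return chi2_modulus(calc * scale, meas)


def evaluate_on_split(
    trained: TrainedModel, dataset: Dataset, split: str = "val"
) -> dict:
    """Per-sample chi^2 table (modulus / amplitude / scaled phase) + Gamma means.

    CNN outputs live in the fixed centered training frame, so no ambiguity
    alignment is applied before comparison.
    """
    from .baselines import chi2_real, fit_gamma

    idx = {"val": dataset.val_idx, "train": dataset.train_idx}[split]
    rows = {"sample_id": [], "chi2_modulus": [], "chi2_amplitude": [], "chi2_phase": []}
    for i in idx:
        s = dataset.samples[i]
        image, phase_scaled = infer(trained, s.pattern)
        rows["sample_id"].append(int(i))
        rows["chi2_modulus"].append(_chi2_modulus_of_image(image, s.pattern))
        rows["chi2_amplitude"].append(chi2_real(image.amplitude, s.target_amplitude))
        rows["chi2_phase"].append(chi2_real(phase_scaled, s.target_phase_scaled))
    table = {k: np.asarray(v) for k, v in rows.items()}
    summary = {}
    for key in ("chi2_modulus", "chi2_amplitude", "chi2_phase"):
        vals = table[key]
        pos = vals[vals > 0]
        if len(pos) >= 10 and np.ptp(pos) > 0:
            summary[key + "_gamma_mean"] = fit_gamma(pos).mean
        summary[key + "_mean"] = float(vals.mean())
    table["summary"] = summary
    return table
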