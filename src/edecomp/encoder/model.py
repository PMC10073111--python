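"""Conv + transformer waveform encoder producing 8-dimensional embeddings.

A two-channel (ECG, PPG) 60-second 125-Hz input passes through a stack of
strided 1-D convolutions, transformer blocks with sinusoidal positional
encoding, mean pooling, and fully connected layers ending in an 8-unit
embedding layer (4 dimensions per modality by convention) topped by a
single-logit classification head.  Training minimises binary cross-entropy
against decompensation labels with Adam and a triangular cyclic learning
rate; after training the head is discarded and the embedding activations
feed the downstream gradient-boosted models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, bce_with_logits, conv1d, layer_norm, softmax

__all__ = ["EncoderConfig", "WaveformEncoder", "train_encoder", "extract_embeddings"]


@dataclass
class EncoderConfig:
    """Desk-scale defaults: a few minutes of CPU training.

    ``epochs`` defaults to the desk value 5; the full-scale setting is 60.
    The cyclic learning rate sweeps a triangle between ``lr_min`` and
    ``lr_max`` once per ``cycle_epochs`` epochs.
    """

    input_len: int = 7500  # 60 s x 125 Hz, per modality
    n_conv_layers: int = 4
    conv_channels: tuple = (16, 32, 64, 64)
    kernel_size: int = 15
    conv_stride: int = 2
    n_transformer_blocks: int = 2
    n_heads: int = 4
    model_dim: int = 64
    ff_dim: int = 128
    embedding_dim_per_modality: int = 4
    epochs: int = 5
    batch_size: int = 16
    lr_min: float = 1e-4
    lr_max: float = 1e-2
    cycle_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim_per_modality < 1:
            raise ValueError("embedding_dim_per_modality must be >= 1")
        if len(self.conv_channels) != self.n_conv_layers:
            raise ValueError("conv_channels length must equal n_conv_layers")
        if self.conv_channels[-1] != self.model_dim:
            raise ValueError("last conv channel count must equal model_dim")

    @property
    def embedding_dim(self) -> int:
        return 2 * self.embedding_dim_per_modality


def _sinusoidal_positions(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class WaveformEncoder:
    """The network; parameters are plain Tensors registered in ``params``."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        c = config

        def param(name: str, shape: tuple, scale: float) -> Tensor:
            t = Tensor(rng.normal(0.0, scale, shape), requires_grad=True)
            self.params[name] = t
            return t

        in_ch = 2
        for li, out_ch in enumerate(c.conv_channels):
            fan_in = in_ch * c.kernel_size
            param(f"conv{li}.w", (out_ch, in_ch, c.kernel_size),
                  np.sqrt(2.0 / fan_in))
            self.params[f"conv{li}.b"] = Tensor(
                np.zeros(out_ch), requires_grad=True
            )
            in_ch = out_ch
        d = c.model_dim
        for bi in range(c.n_transformer_blocks):
            for nm in ("q", "k", "v", "o"):
                param(f"block{bi}.{nm}", (d, d), np.sqrt(1.0 / d))
            param(f"block{bi}.ff1.w", (d, c.ff_dim), np.sqrt(2.0 / d))
            self.params[f"block{bi}.ff1.b"] = Tensor(np.zeros(c.ff_dim),
                                                     requires_grad=True)
            param(f"block{bi}.ff2.w", (c.ff_dim, d), np.sqrt(2.0 / c.ff_dim))
            self.params[f"block{bi}.ff2.b"] = Tensor(np.zeros(d),
                                                     requires_grad=True)
            for nm in ("ln1", "ln2"):
                self.params[f"block{bi}.{nm}.g"] = Tensor(np.ones(d),
                                                          requires_grad=True)
                self.params[f"block{bi}.{nm}.b"] = Tensor(np.zeros(d),
                                                          requires_grad=True)
        param("fc1.w", (d, 32), np.sqrt(2.0 / d))
        self.params["fc1.b"] = Tensor(np.zeros(32), requires_grad=True)
        param("emb.w", (32, c.embedding_dim), np.sqrt(2.0 / 32))
        self.params["emb.b"] = Tensor(np.zeros(c.embedding_dim),
                                      requires_grad=True)
        param("head.w", (c.embedding_dim, 1), np.sqrt(1.0 / c.embedding_dim))
        self.params["head.b"] = Tensor(np.zeros(1), requires_grad=True)
        self._pos_cache: dict[int, np.ndarray] = {}

    # -- forward ------------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def forward(self, x: np.ndarray) -> tuple[Tensor, Tensor]:
        """(B, 2, input_len) -> (logits (B,), embeddings (B, 8))."""
        c = self.config
        if x.ndim != 3 or x.shape[1] != 2 or x.shape[2] != c.input_len:
            raise ValueError(
                f"expected input of shape (B, 2, {c.input_len}), got {x.shape}"
            )
        p = self.params
        h = Tensor(x)
        pad = c.kernel_size // 2
        for li in range(c.n_conv_layers):
            h = conv1d(h, p[f"conv{li}.w"], p[f"conv{li}.b"],
                       stride=c.conv_stride, padding=pad).relu()
        tokens = h.transpose(0, 2, 1)  # (B, T, D)
        T = tokens.shape[1]
        if T not in self._pos_cache:
            self._pos_cache[T] = _sinusoidal_positions(T, c.model_dim)
        tokens = tokens + Tensor(self._pos_cache[T])
        for bi in range(c.n_transformer_blocks):
            tokens = self._block(tokens, bi)
        pooled = tokens.mean(axis=1)  # (B, D)
        hidden = (pooled @ p["fc1.w"] + p["fc1.b"]).relu()
        emb = hidden @ p["emb.w"] + p["emb.b"]
        logits = (emb @ p["head.w"] + p["head.b"]).reshape(-1)
        return logits, emb

    def _block(self, x: Tensor, bi: int) -> Tensor:
        c = self.config
        p = self.params
        d, H = c.model_dim, c.n_heads
        dh = d // H
        B, T, _ = x.shape
        normed = layer_norm(x, p[f"block{bi}.ln1.g"], p[f"block{bi}.ln1.b"])

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        q = heads(normed @ p[f"block{bi}.q"])
        k = heads(normed @ p[f"block{bi}.k"])
        v = heads(normed @ p[f"block{bi}.v"])
        att = softmax(q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh)))
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        x = x + ctx @ p[f"block{bi}.o"]
        normed = layer_norm(x, p[f"block{bi}.ln2.g"], p[f"block{bi}.ln2.b"])
        ff = (normed @ p[f"block{bi}.ff1.w"] + p[f"block{bi}.ff1.b"]).gelu()
        return x + ff @ p[f"block{bi}.ff2.w"] + p[f"block{bi}.ff2.b"]

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _cyclic_lr(epoch_frac: float, cfg: EncoderConfig) -> float:
    """Triangular cycle: lr_min -> lr_max -> lr_min per ``cycle_epochs``."""
    phase = (epoch_frac % cfg.cycle_epochs) / cfg.cycle_epochs
    tri = 1.0 - abs(2.0 * phase - 1.0)
    return cfg.lr_min + (cfg.lr_max - cfg.lr_min) * tri


def train_encoder(
    encoder: WaveformEncoder,
    x: np.ndarray,
    y: np.ndarray,
    config: EncoderConfig | None = None,
) -> list[float]:
    """Minimise BCE on labelled waveform windows; returns per-epoch losses.

    ``x`` has shape (n, 2, input_len); ``y`` is binary.  Training is
    refused when only one class is present.  Zero epochs leave the weights
    untouched.
    """
    cfg = config or encoder.config
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(encoder.params)
    n = len(y)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(steps_per_epoch):
            idx = order[s * cfg.batch_size : (s + 1) * cfg.batch_size]
            logits, _ = encoder.forward(x[idx])
            loss = bce_with_logits(logits, y[idx])
            loss.backward()
            lr = _cyclic_lr(epoch + s / steps_per_epoch, cfg)
            opt.step(lr)
            for p in encoder.params.values():
                p.grad = None
            epoch_loss += float(loss.data) * len(idx)
        trace.append(epoch_loss / n)
    return trace


def extract_embeddings(encoder: WaveformEncoder, x: np.ndarray) -> np.ndarray:
    """Embedding-layer activations, head discarded: (n, 8) array."""
    if x.ndim == 2:
        x = x[None]
    out = []
    bs = max(1, encoder.config.batch_size)
    for i in range(0, len(x), bs):
        _, emb = encoder.forward(x[i : i + bs])
        if not np.all(np.isfinite(emb.data)):
            raise FloatingPointError("non-finite activations in embedding layer")
        out.append(emb.data)
    return np.concatenate(out, axis=0)
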