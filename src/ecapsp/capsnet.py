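"""EcapsP: a capsule network with scalar-product self-attention routing.

The network stacks a 1-D convolutional front end (kernel-1 then kernel-9
convolutions with ReLU, dropout and batch normalisation), an optional
residual block, a depthwise-separable primary-capsule layer (60 capsules of
8 units by default), a single-pass self-attention routing layer producing
two 10-unit class capsules, and a three-layer fully connected reconstruction
decoder.  Capsule lengths are interpreted as class probabilities: capsule 1
is the phosphorylated class, capsule 0 the unphosphorylated class.

Ablation switches mirror the published comparisons: ``routing_mode``
(self-attention vs. iterative dynamic routing), ``decoder_mode``
(unconditional vs. masked reconstruction), ``loss_mode`` (cross-entropy vs.
margin loss) and ``use_shortcut`` (residual block on/off).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, conv1d, einsum, logsumexp, pad, unfold1d

EPS = 1e-9

ROUTING_MODES = ("self_attention", "dynamic")
DECODER_MODES = ("unconditional", "mask")
SQUASH_VARIANTS = ("exp", "classic")
LOSS_MODES = ("CEL", "ML")


class NumericalError(RuntimeError):
    """Raised when a forward stage produces NaN/Inf values."""


@dataclass
class NetworkConfig:
    """Architecture and ablation switches.

    Defaults follow the published architecture: 300 kernel-1 filters, 100
    kernel-9 filters, 50% dropout, 60 primary capsules of 8 units and two
    10-unit class capsules.
    """

    conv1_filters: int = 300
    conv1_kernel: int = 1
    conv2_filters: int = 100
    conv2_kernel: int = 9
    dropout_p: float = 0.5
    use_shortcut: bool = True
    n_primary: int = 60
    d_primary: int = 8
    n_digit: int = 2
    d_digit: int = 10
    routing_mode: str = "self_attention"
    decoder_mode: str = "unconditional"
    squash_variant: str = "exp"
    loss_mode: str = "CEL"
    recon_weight: float = 0.0005
    routing_iterations: int = 3
    primary_kernel: int = 9
    primary_stride: int = 2
    primary_pad: int = 2
    decoder_hidden: tuple[int, int] = (512, 1024)
    # margin-loss constants (original capsule-network convention)
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_ml: float = 0.5

    def __post_init__(self):
        if self.routing_mode not in ROUTING_MODES:
            raise ValueError(f"routing_mode must be one of {ROUTING_MODES}")
        if self.decoder_mode not in DECODER_MODES:
            raise ValueError(f"decoder_mode must be one of {DECODER_MODES}")
        if self.squash_variant not in SQUASH_VARIANTS:
            raise ValueError(f"squash_variant must be one of {SQUASH_VARIANTS}")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        for name in ("conv1_filters", "conv2_filters", "n_primary", "d_primary",
                     "n_digit", "d_digit"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decoder_hidden"] = list(self.decoder_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "decoder_hidden" in d:
            d["decoder_hidden"] = tuple(d["decoder_hidden"])
        return cls(**d)


# ---------------------------------------------------------------------------
# squash
# ---------------------------------------------------------------------------

def squash(s: Tensor | np.ndarray, variant: str = "exp", axis: int = -1) -> Tensor:
    """Compress capsule lengths into [0, 1) preserving direction.

    ``exp``:     scale = (1 - exp(-|s|)) / |s|
    ``classic``: scale = |s| / (1 + |s|^2)   (i.e. norm -> |s|^2/(1+|s|^2))
    The zero vector maps to the zero vector.
    """
    if variant not in SQUASH_VARIANTS:
        raise ValueError(f"unknown squash variant {variant!r}")
    s = s if isinstance(s, Tensor) else Tensor(s)
    r = ((s * s).sum(axis=axis, keepdims=True) + EPS).sqrt()
    if variant == "exp":
        scale = (1.0 - (-1.0 * r).exp()) / r
    else:
        scale = r / (1.0 + r * r)
    return s * scale


def capsule_norms(v: Tensor | np.ndarray, axis: int = -1) -> np.ndarray:
    data = v.data if isinstance(v, Tensor) else np.asarray(v)
    return np.sqrt((data ** 2).sum(axis=axis))


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def _check_finite(arr: np.ndarray, stage: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise NumericalError(f"non-finite values produced at stage {stage!r}")


def _softmax(x: Tensor, axis: int) -> Tensor:
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()


def attention_routing(u: Tensor, W: Tensor, B: Tensor,
                      squash_variant: str = "exp",
                      return_state: bool = False):
    """Single-pass scalar-product self-attention routing.

    Parameters
    ----------
    u : (batch, n_l, d_l) input capsules
    W : (n_l, n_next, d_l, d_next) affine vote map
    B : (n_l, n_next) learned coupling bias

    Steps: votes by affine transform; pairwise vote agreement scaled by
    sqrt(d_next); couplings by softmax over output capsules of the
    agreement totals; weighted vote sum with additive bias; squash.
    """
    d_next = W.shape[-1]
    u_hat = einsum("bnd,njde->bnje", u, W)
    _check_finite(u_hat.data, "votes")
    a = einsum("bnje,bmje->bnmj", u_hat, u_hat) * (1.0 / np.sqrt(d_next))
    _check_finite(a.data, "attention")
    logits = a.sum(axis=2)                      # (batch, n_l, n_next)
    c = _softmax(logits, axis=-1)
    s = einsum("bnje,bnj->bje", u_hat, c + B)
    _check_finite(s.data, "pre-activation")
    v = squash(s, variant=squash_variant)
    if return_state:
        state = {"u_hat": u_hat.data, "A": a.data, "C": c.data,
                 "s": s.data, "V": v.data}
        return v, state
    return v


def dynamic_routing(u: Tensor, W: Tensor, B: Tensor | None = None,
                    iterations: int = 3, squash_variant: str = "exp",
                    return_state: bool = False):
    """Classic routing-by-agreement (the dynamic-routing ablation baseline).

    The logits start at zero; each iteration softmaxes them into couplings,
    forms the weighted vote sum, squashes, and reinforces logits by the
    scalar product of votes with the output.  ``B`` is accepted for
    signature parity and ignored (the original algorithm has no bias).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    u_hat = einsum("bnd,njde->bnje", u, W)
    _check_finite(u_hat.data, "votes")
    batch, n_l, n_next, _ = u_hat.shape
    b_logits = Tensor(np.zeros((batch, n_l, n_next), dtype=u_hat.data.dtype))
    v = c = None
    for _ in range(iterations):
        c = _softmax(b_logits, axis=-1)
        s = einsum("bnje,bnj->bje", u_hat, c)
        v = squash(s, variant=squash_variant)
        b_logits = b_logits + einsum("bnje,bje->bnj", u_hat, v)
    _check_finite(v.data, "output")
    if return_state:
        return v, {"u_hat": u_hat.data, "C": c.data, "V": v.data}
    return v


def class_probabilities(v: Tensor | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lengths of the (positive, negative) class capsules.

    Capsule 1 holds the phosphorylated class.  The predicted label is the
    argmax of the two lengths; exact ties break toward the negative class.
    """
    norms = capsule_norms(v)
    return norms[..., 1], norms[..., 0]


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class EcapsPNet:
    """The full trainable network over encoded 33-residue peptides.

    Parameters
    ----------
    config : NetworkConfig
    input_dim : feature dimension D of the (33, D) encoded input (two-channel
        encodings are spliced to a single axis before they reach the network)
    seq_len : window length (33)
    seed : seeds the parameter initialisation
    """

    def __init__(self, config: NetworkConfig, input_dim: int,
                 seq_len: int = 33, seed: int = 0, dtype=np.float64):
        self.config = config
        self.input_dim = int(input_dim)
        self.seq_len = int(seq_len)
        self.dtype = dtype
        self.params: dict[str, Tensor] = {}
        self._bn_stats: dict[str, dict[str, np.ndarray]] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameter management --------------------------------------------
    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value.astype(self.dtype), requires_grad=True)
        self.params[name] = t
        return t

    def _he(self, rng, shape, fan_in) -> np.ndarray:
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    def _trunc_normal(self, rng, shape, std=0.05) -> np.ndarray:
        x = rng.standard_normal(shape) * std
        return np.clip(x, -2 * std, 2 * std)

    def _init_bn(self, name: str, channels: int, rng) -> None:
        self._param(f"{name}_gamma", np.ones(channels))
        self._param(f"{name}_beta", np.zeros(channels))
        self._bn_stats[name] = {"mean": np.zeros(channels, dtype=self.dtype),
                                "var": np.ones(channels, dtype=self.dtype)}

    def _init_params(self, rng) -> None:
        c = self.config
        if self.seq_len < max(c.conv1_kernel, c.conv2_kernel, c.primary_kernel):
            raise ValueError("input length shorter than a convolution kernel")
        D = self.input_dim
        self._param("conv1_w", self._he(rng, (D, c.conv1_kernel * c.conv1_filters),
                                        c.conv1_kernel * D))
        self._param("conv1_b", np.zeros(c.conv1_filters))
        self._init_bn("bn1", c.conv1_filters, rng)
        self._param("conv2_w", self._he(rng,
                                        (c.conv1_filters,
                                         c.conv2_kernel * c.conv2_filters),
                                        c.conv2_kernel * c.conv1_filters))
        self._param("conv2_b", np.zeros(c.conv2_filters))
        self._init_bn("bn2", c.conv2_filters, rng)
        if c.use_shortcut:
            fan = c.conv2_kernel * c.conv2_filters
            self._param("res1_w", self._he(rng, (c.conv2_filters, fan), fan))
            self._param("res1_b", np.zeros(c.conv2_filters))
            self._param("res2_w", self._he(rng, (c.conv2_filters, fan), fan))
            self._param("res2_b", np.zeros(c.conv2_filters))
        # primary capsules: depthwise then pointwise convolution
        self._param("dw_w", self._he(rng, (c.primary_kernel, c.conv2_filters),
                                     c.primary_kernel))
        self._param("dw_b", np.zeros(c.conv2_filters))
        L = self._primary_len()
        total = c.n_primary * c.d_primary
        if total % L != 0:
            raise ValueError(
                f"n_primary*d_primary={total} not divisible by the "
                f"{L} depthwise output positions; adjust the capsule geometry")
        pw_out = total // L
        self._param("pw_w", self._he(rng, (c.conv2_filters, pw_out),
                                     c.conv2_filters))
        self._param("pw_b", np.zeros(pw_out))
        # routing parameters
        self._param("W_route", self._trunc_normal(
            rng, (c.n_primary, c.n_digit, c.d_primary, c.d_digit)))
        self._param("B_route", np.zeros((c.n_primary, c.n_digit)))
        # decoder
        h1, h2 = c.decoder_hidden
        din = c.n_digit * c.d_digit
        dout = self.seq_len * D
        self._param("dec1_w", self._he(rng, (din, h1), din))
        self._param("dec1_b", np.zeros(h1))
        self._param("dec2_w", self._he(rng, (h1, h2), h1))
        self._param("dec2_b", np.zeros(h2))
        self._param("dec3_w", self._he(rng, (h2, dout), h2))
        self._param("dec3_b", np.zeros(dout))

    def _primary_len(self) -> int:
        c = self.config
        return (self.seq_len + 2 * c.primary_pad - c.primary_kernel) \
            // c.primary_stride + 1

    # -- layers -----------------------------------------------------------
    def _conv1d(self, x: Tensor, wname: str, kernel: int,
                padding: int | None = None) -> Tensor:
        """'same'-padded (default, odd kernels) stride-1 1-D convolution.

        Shift-GEMM formulation: one (B*L, C) x (C, k*F) matmul followed by a
        banded diagonal sum, avoiding im2col patch copies.  Weights are laid
        out (C_in, k*F) with kernel tap j in columns [j*F, (j+1)*F).
        """
        if padding is None:
            padding = (kernel - 1) // 2
        if padding:
            x = pad(x, ((0, 0), (padding, padding), (0, 0)))
        w = self.params[wname + "_w"]
        return conv1d(x, w, kernel) + self.params[wname + "_b"]

    def _depthwise(self, x: Tensor) -> Tensor:
        c = self.config
        if c.primary_pad:
            x = pad(x, ((0, 0), (c.primary_pad, c.primary_pad), (0, 0)))
        cols = unfold1d(x, c.primary_kernel, c.primary_stride)   # (B,L,k,C)
        return einsum("blkc,kc->blc", cols, self.params["dw_w"]) \
            + self.params["dw_b"]

    def _batchnorm(self, x: Tensor, name: str, training: bool,
                   momentum: float = 0.1) -> Tensor:
        gamma, beta = self.params[f"{name}_gamma"], self.params[f"{name}_beta"]
        stats = self._bn_stats[name]
        if training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 1), keepdims=True)
            stats["mean"] = (1 - momentum) * stats["mean"] + momentum * mu.data.reshape(-1)
            stats["var"] = (1 - momentum) * stats["var"] + momentum * var.data.reshape(-1)
            xhat = (x - mu) * ((var + 1e-5) ** -0.5)
        else:
            mu = Tensor(stats["mean"].reshape(1, 1, -1))
            var = Tensor(stats["var"].reshape(1, 1, -1))
            xhat = (x - mu) * ((var + 1e-5) ** -0.5)
        return xhat * gamma + beta

    def _dropout(self, x: Tensor, training: bool, rng) -> Tensor:
        p = self.config.dropout_p
        if not training or p == 0.0:
            return x
        mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
        return x * Tensor(mask)

    # -- stages -----------------------------------------------------------
    def conv_stack(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        """Kernel-1 and kernel-9 convolutions with ReLU, each followed by
        dropout and batch normalisation."""
        rng = rng or np.random.default_rng(0)
        h = self._conv1d(x, "conv1", self.config.conv1_kernel).relu()
        h = self._batchnorm(self._dropout(h, training, rng), "bn1", training)
        h = self._conv1d(h, "conv2", self.config.conv2_kernel).relu()
        h = self._batchnorm(self._dropout(h, training, rng), "bn2", training)
        return h

    def residual_block(self, x: Tensor) -> Tensor:
        """out = F(x) + x with F = conv9 -> ReLU -> conv9; identity when the
        shortcut ablation is off (the block is skipped entirely)."""
        if not self.config.use_shortcut:
            return x
        k = self.config.conv2_kernel
        f = self._conv1d(self._conv1d(x, "res1", k).relu(), "res2", k)
        return f + x

    def primary_caps(self, x: Tensor) -> Tensor:
        """Depthwise-separable convolution reshaped to squashed primary
        capsules of shape (batch, n_primary, d_primary)."""
        c = self.config
        h = self._depthwise(x)
        B, L, C = h.shape
        h = (h.reshape(B * L, C) @ self.params["pw_w"] + self.params["pw_b"])
        caps = h.reshape(B, c.n_primary, c.d_primary)
        return squash(caps, variant=c.squash_variant)

    def route(self, u: Tensor, return_state: bool = False):
        c = self.config
        if c.routing_mode == "self_attention":
            return attention_routing(u, self.params["W_route"],
                                     self.params["B_route"],
                                     squash_variant=c.squash_variant,
                                     return_state=return_state)
        return dynamic_routing(u, self.params["W_route"],
                               iterations=c.routing_iterations,
                               squash_variant=c.squash_variant,
                               return_state=return_state)

    def decode(self, v: Tensor, target: np.ndarray | None = None) -> Tensor:
        """Three-layer fully connected reconstruction of the encoded input.

        Unconditional mode flattens both class capsules; mask mode zeroes
        every capsule except the target (training) or predicted (inference)
        one before flattening.
        """
        c = self.config
        B = v.shape[0]
        if c.decoder_mode == "mask":
            if target is None:
                target = np.argmax(capsule_norms(v), axis=-1)
            mask = np.zeros((B, c.n_digit, 1), dtype=v.data.dtype)
            mask[np.arange(B), np.asarray(target, dtype=int)] = 1.0
            v = v * Tensor(mask)
        h = v.reshape(B, c.n_digit * c.d_digit)
        h = (h @ self.params["dec1_w"] + self.params["dec1_b"]).relu()
        h = (h @ self.params["dec2_w"] + self.params["dec2_b"]).relu()
        return h @ self.params["dec3_w"] + self.params["dec3_b"]

    def forward(self, x: np.ndarray, training: bool = False, rng=None,
                labels: np.ndarray | None = None):
        """Run the full pipeline.

        Returns ``(v, scores, recon)``: class capsules (batch, n_digit,
        d_digit), positive-class probabilities (batch,), and the flattened
        reconstruction.
        """
        xt = Tensor(np.asarray(x, dtype=self.dtype))
        if xt.ndim == 2:
            xt = xt.reshape(1, *xt.shape)
        h = self.conv_stack(xt, training=training, rng=rng)
        h = self.residual_block(h)
        u = self.primary_caps(h)
        v = self.route(u)
        target = labels if (training and labels is not None) else None
        recon = self.decode(v, target=target)
        return v, self.scores(v), recon

    def scores(self, v: Tensor | np.ndarray) -> np.ndarray:
        """Probability of the phosphorylated class: softmax over the two
        capsule lengths (matches the cross-entropy training objective)."""
        norms = capsule_norms(v)
        e = np.exp(norms - norms.max(axis=-1, keepdims=True))
        return (e[..., 1] / e.sum(axis=-1))

    # -- losses -----------------------------------------------------------
    def loss(self, v: Tensor, recon: Tensor, x: np.ndarray,
             labels: np.ndarray) -> Tensor:
        """Classification loss (cross-entropy or margin) plus weighted
        mean-squared reconstruction error."""
        c = self.config
        labels = np.asarray(labels, dtype=int)
        B = v.shape[0]
        norms = ((v * v).sum(axis=-1) + EPS).sqrt()     # (B, n_digit)
        if c.loss_mode == "CEL":
            logp = norms - logsumexp(norms, axis=-1, keepdims=True)
            onehot = np.zeros((B, c.n_digit))
            onehot[np.arange(B), labels] = 1.0
            cls = -1.0 * (logp * Tensor(onehot)).sum() * (1.0 / B)
        else:
            onehot = np.zeros((B, c.n_digit))
            onehot[np.arange(B), labels] = 1.0
            t = Tensor(onehot)
            pos_term = t * ((Tensor(np.full((B, c.n_digit), c.m_plus)) - norms).relu() ** 2)
            neg_term = (1.0 - t) * ((norms - Tensor(np.full((B, c.n_digit), c.m_minus))).relu() ** 2)
            cls = (pos_term + c.lambda_ml * neg_term).sum() * (1.0 / B)
        if c.recon_weight == 0.0:
            return cls
        flat = np.asarray(x, dtype=self.dtype).reshape(B, -1)
        diff = recon - Tensor(flat)
        mse = (diff * diff).mean()
        return cls + c.recon_weight * mse

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: t.data.copy() for k, t in self.params.items()}
        for name, st in self._bn_stats.items():
            d[f"{name}_running_mean"] = st["mean"].copy()
            d[f"{name}_running_var"] = st["var"].copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(d[k], dtype=self.dtype)
        for name, st in self._bn_stats.items():
            st["mean"] = np.asarray(d[f"{name}_running_mean"], dtype=self.dtype)
            st["var"] = np.asarray(d[f"{name}_running_var"], dtype=self.dtype)

    def save(self, path, extra: dict | None = None) -> None:
        meta = {"config": self.config.to_dict(), "input_dim": self.input_dim,
                "seq_len": self.seq_len, "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path) -> tuple["EcapsPNet", dict]:
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        net = cls(NetworkConfig.from_dict(meta["config"]),
                  input_dim=meta["input_dim"], seq_len=meta["seq_len"])
        net.load_state_dict(state)
        return net, meta.get("extra", {})

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()
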