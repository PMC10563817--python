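"""Dual-branch EEG classifier: transformer + CNN feature fusion with
channel/spatial attention filtering.

Architecture overview
---------------------
*Transformer (ViT-style) branch* — each 4-s time segment (19 channels x
window samples) is split per channel into fixed-length patches; every patch
is linearly embedded, given a within-channel positional embedding (shared
across channels, so the branch is equivariant to channel permutation), and
passed through a small pre-norm transformer encoder (multi-head scaled
dot-product attention + feed-forward blocks).  Tokens are mean-pooled per
channel and projected, yielding a (19, feature_dim) map.

*CNN branch* — the five band-filtered signals are stacked into a
(band, channel, time) array and passed through a small convolutional stack
(3x3 kernels, batch norm, ReLU, temporal pooling); the result is pooled over
time and projected per electrode row to (19, feature_dim).

*Fusion* — the branch maps are concatenated along the feature axis
(transformer block first), giving (19, 2 * feature_dim) — (19, 256) at the
default feature_dim of 128.

*Feature filter* — CBAM-style: a channel-attention weight vector (shared MLP
over global average- and max-pooled descriptors, sigmoid) rescales feature
channels, then a spatial-attention map (7x7 convolution over stacked
channel-wise average/max planes, sigmoid) rescales electrode positions.

*Classifier* — flatten, fully-connected, ReLU, fully-connected, softmax over
the three diagnostic classes (NC=0, FTD=1, AD=2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .constants import CLASS_NAMES
from .nn import Module, softmax

__all__ = [
    "AttentionConfig",
    "ModelConfig",
    "ClassProbabilities",
    "PatchEmbed",
    "MultiHeadAttention",
    "TransformerBlock",
    "ViTBranch",
    "CnnBranch",
    "ChannelAttention",
    "SpatialAttention",
    "FeatureFilter",
    "ClassifierHead",
    "DualBranchModel",
    "fuse_features",
    "cross_entropy",
    "VARIANTS",
]

VARIANTS = ("vit_cnn", "cnn_only", "vit_only", "cnn_cnn", "vit_vit")


@dataclass(frozen=True)
class AttentionConfig:
    """Transformer-branch hyperparameters."""

    n_heads: int = 4
    patch_len: int = 100
    embed_dim: int = 128
    encoder_depth: int = 2
    ffn_mult: int = 2

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture description; serialised alongside checkpoints."""

    n_channels: int = 19
    n_classes: int = 3
    feature_dim: int = 128
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    cnn_channels: tuple[int, ...] = (8, 16, 32)
    cnn_time_pool: int = 4
    cnn_time_downsample: int = 1
    cnn_norm: str = "none"  # or "instance"
    filter_reduction: int = 8
    spatial_kernel: int = 7
    use_filter: bool = True
    classifier_hidden: int = 64
    branches: str = "vit_cnn"

    def __post_init__(self):
        if isinstance(self.attention, dict):
            object.__setattr__(self, "attention", AttentionConfig(**self.attention))
        if isinstance(self.cnn_channels, list):
            object.__setattr__(self, "cnn_channels", tuple(self.cnn_channels))
        if self.branches not in VARIANTS:
            raise ValueError(f"unknown branch variant {self.branches!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnn_channels"] = list(self.cnn_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = AttentionConfig(**d["attention"])
        if "cnn_channels" in d:
            d["cnn_channels"] = tuple(d["cnn_channels"])
        return cls(**d)


@dataclass
class ClassProbabilities:
    """A simplex over (NC, FTD, AD) with its argmax hard label."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(CLASS_NAMES),):
            raise ValueError(f"expected {len(CLASS_NAMES)} class probabilities")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def hard_label(self) -> int:
        return int(np.argmax(self.probs))


# ---------------------------------------------------------------------------
# transformer branch
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Per-channel patching of a (B, channels, samples) segment.

    Each channel row is cut into ``samples / patch_len`` non-overlapping
    patches; every patch is flattened and linearly projected to the embedding
    dimension, giving ``channels * n_patches_per_channel`` tokens.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.proj = nn.Linear(cfg.patch_len, cfg.embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, W = x.shape
        p = self.cfg.patch_len
        if W % p != 0:
            raise ValueError(f"patch_len {p} does not divide segment length {W}")
        n_per_ch = W // p
        tokens = x.reshape(B, C * n_per_ch, p)
        return self.proj(tokens)  # (B, C * n_per_ch, embed)


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention with output projection.

    Each head computes ``softmax(q k^T / sqrt(d_head)) v`` on learned linear
    projections of the inputs; head outputs are concatenated and linearly
    projected back to the embedding dimension.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.embed_dim
        self.wq = nn.Linear(d, d, rng, bias=False)
        self.wk = nn.Linear(d, d, rng, bias=False)
        self.wv = nn.Linear(d, d, rng, bias=False)
        self.wo = nn.Linear(d, d, rng, bias=False)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
            raise ValueError("q/k/v dimension mismatch")
        cfg = self.cfg
        B, Lq, D = q.shape
        Lk = k.shape[-2]
        h, dh = cfg.n_heads, cfg.head_dim

        def split(t: Tensor, L: int) -> Tensor:
            # (B, L, D) -> (B, h, L, dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        qh = split(self.wq(q), Lq)
        kh = split(self.wk(k), Lk)
        vh = split(self.wv(v), Lk)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        weights = softmax(scores, axis=-1)  # rows sum to 1
        out = weights @ vh  # (B, h, Lq, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, Lq, h * dh)
        return self.wo(out)

    def attention_weights(self, q: Tensor, k: Tensor) -> np.ndarray:
        """Softmax-normalised attention matrix (B, heads, Lq, Lk), no grad."""
        cfg = self.cfg
        B, Lq, D = q.shape
        Lk = k.shape[-2]
        h, dh = cfg.n_heads, cfg.head_dim
        qh = self.wq(q).data.reshape(B, Lq, h, dh).transpose(0, 2, 1, 3)
        kh = self.wk(k).data.reshape(B, Lk, h, dh).transpose(0, 2, 1, 3)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)


class TransformerBlock(Module):
    """Pre-norm encoder block: MHA + feed-forward, each with residual."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.embed_dim
        self.ln1 = nn.LayerNorm(d)
        self.mha = MultiHeadAttention(cfg, rng)
        self.ln2 = nn.LayerNorm(d)
        self.ffn1 = nn.Linear(d, cfg.ffn_mult * d, rng)
        self.ffn2 = nn.Linear(cfg.ffn_mult * d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.mha(h, h, h)
        x = x + self.ffn2(self.ffn1(self.ln2(x)).relu())
        return x


class ViTBranch(Module):
    """Transformer encoder over per-channel patches, pooled per channel.

    The positional embedding indexes the within-channel patch position only
    and is shared across channels, so permuting input channels permutes the
    corresponding output rows.
    """

    def __init__(self, cfg: ModelConfig, window_samples: int, rng: np.random.Generator):
        super().__init__()
        att = cfg.attention
        if window_samples % att.patch_len != 0:
            raise ValueError(
                f"patch_len {att.patch_len} does not divide window of "
                f"{window_samples} samples"
            )
        self.cfg = cfg
        self.n_per_ch = window_samples // att.patch_len
        self.patch = PatchEmbed(att, rng)
        self.pos = Tensor(
            0.02 * rng.standard_normal((self.n_per_ch, att.embed_dim)),
            requires_grad=True,
        )
        self.blocks = [TransformerBlock(att, rng) for _ in range(att.encoder_depth)]
        self.norm = nn.LayerNorm(att.embed_dim)
        self.out_proj = nn.Linear(att.embed_dim, cfg.feature_dim, rng)

    def __call__(self, segments: Tensor) -> Tensor:
        B, C, W = segments.shape
        tokens = self.patch(segments)  # (B, C * n_per_ch, embed)
        pos_full = concat([self.pos] * C, axis=0)  # channel-agnostic positions
        tokens = tokens + pos_full
        for block in self.blocks:
            tokens = block(tokens)
        tokens = self.norm(tokens)
        per_channel = tokens.reshape(B, C, self.n_per_ch, -1).mean(axis=2)
        return self.out_proj(per_channel)  # (B, C, feature_dim)


class CnnBranch(Module):
    """Convolutional stack over the (band, channel, time) array.

    3x3 convolution blocks with ReLU and temporal pooling, then global
    temporal average pooling and a per-electrode-row projection to
    ``feature_dim`` features.  No normalisation layer by default: the class
    signal in band-decomposed EEG lives largely in the per-band signal
    *scale*, which per-example normalisation of the activation maps would
    erase; ``cnn_norm="instance"`` re-enables it for inputs where scale is
    a nuisance rather than the signal.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, n_bands: int = 5):
        super().__init__()
        self.cfg = cfg
        self.n_bands = n_bands
        chans = (n_bands,) + tuple(cfg.cnn_channels)
        self.convs = [
            nn.Conv2d(chans[i], chans[i + 1], (3, 3), rng, padding=(1, 1))
            for i in range(len(cfg.cnn_channels))
        ]
        if cfg.cnn_norm == "instance":
            self.bns = [nn.InstanceNorm2d(c) for c in cfg.cnn_channels]
        elif cfg.cnn_norm == "none":
            self.bns = [None] * len(cfg.cnn_channels)
        else:
            raise ValueError(f"unknown cnn_norm {cfg.cnn_norm!r}")
        self.out_proj = nn.Linear(cfg.cnn_channels[-1], cfg.feature_dim, rng)

    @staticmethod
    def _time_pool(x: Tensor, factor: int) -> Tensor:
        if factor <= 1:
            return x
        B, C, H, W = x.shape
        W2 = (W // factor) * factor
        if W2 == 0:
            return x
        x = x[:, :, :, :W2]
        return x.reshape(B, C, H, W2 // factor, factor).mean(axis=4)

    def __call__(self, bands: Tensor) -> Tensor:
        if bands.shape[1] != self.n_bands:
            raise ValueError(
                f"expected {self.n_bands} band planes, got {bands.shape[1]}"
            )
        x = self._time_pool(bands, self.cfg.cnn_time_downsample)
        for conv, bn in zip(self.convs, self.bns):
            x = conv(x)
            if bn is not None:
                x = bn(x)
            x = x.relu()
            x = self._time_pool(x, self.cfg.cnn_time_pool)
        x = x.mean(axis=3)  # (B, C_last, 19)
        x = x.transpose(0, 2, 1)  # (B, 19, C_last)
        return self.out_proj(x)  # (B, 19, feature_dim)


def fuse_features(f_vit: Tensor, f_cnn: Tensor) -> Tensor:
    """Feature-level fusion: concatenate branch maps along the feature axis.

    The transformer block occupies the first ``feature_dim`` channels, the
    CNN block the last; values pass through unmodified, so the fusion is
    lossless.  Two (19, 128) maps fuse to (19, 256).
    """
    f_vit, f_cnn = Tensor._wrap(f_vit), Tensor._wrap(f_cnn)
    if f_vit.shape[:-1] != f_cnn.shape[:-1]:
        raise ValueError(
            f"branch maps disagree on leading shape: {f_vit.shape} vs {f_cnn.shape}"
        )
    return concat([f_vit, f_cnn], axis=-1)


# ---------------------------------------------------------------------------
# feature filter (CBAM-style)
# ---------------------------------------------------------------------------

class ChannelAttention(Module):
    """Channel weights: sigmoid(MLP(avgpool) + MLP(maxpool)), shared MLP.

    Operates on a (B, C, H, W) map; pooling is global over (H, W); the MLP
    is two layers with a reduction-ratio bottleneck; every output weight
    lies in (0, 1).
    """

    def __init__(self, n_channels: int, rng: np.random.Generator, reduction: int = 8):
        super().__init__()
        hidden = max(1, n_channels // reduction)
        self.fc1 = nn.Linear(n_channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_channels, rng)

    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def __call__(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=(2, 3))  # (B, C)
        mx = f.max(axis=(2, 3))
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()  # (B, C)


class SpatialAttention(Module):
    """Spatial weights: sigmoid(conv7x7([channel-avg, channel-max])).

    The channel-wise average and maximum planes are stacked and convolved
    with a single zero-padded kernel, preserving the spatial extent.  On a
    19 x 1 electrode layout the 7x7 kernel degenerates to effective 7x1
    support via the zero padding.
    """

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("spatial kernel must be odd")
        pad = kernel // 2
        self.conv = nn.Conv2d(2, 1, (kernel, kernel), rng, padding=(pad, pad))

    def __call__(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=1, keepdims=True)  # (B, 1, H, W)
        mx = f.max(axis=1, keepdims=True)
        planes = concat([avg, mx], axis=1)
        return self.conv(planes).sigmoid()  # (B, 1, H, W)


class FeatureFilter(Module):
    """Channel attention then spatial attention applied to the fused map.

    ``F1 = M_c * F_fuse`` (weights broadcast over positions) and
    ``F2 = M_s * F1`` (weights broadcast over feature channels).  Because
    both weight fields lie in (0, 1), the filter is an element-wise
    contraction: ``|F2| <= |F_fuse|``.
    """

    def __init__(self, n_features: int, rng: np.random.Generator,
                 reduction: int = 8, kernel: int = 7):
        super().__init__()
        self.channel = ChannelAttention(n_features, rng, reduction)
        self.spatial = SpatialAttention(rng, kernel)

    def __call__(self, fused: Tensor) -> Tensor:
        # fused: (B, n_electrodes, n_features) -> conv layout (B, C, H, 1)
        B, H, C = fused.shape
        fmap = fused.transpose(0, 2, 1).reshape(B, C, H, 1)
        mc = self.channel(fmap).reshape(B, C, 1, 1)
        f1 = fmap * mc
        ms = self.spatial(f1)  # (B, 1, H, 1)
        f2 = f1 * ms
        return f2.reshape(B, C, H).transpose(0, 2, 1)  # (B, H, C)


class ClassifierHead(Module):
    """Flatten -> fully-connected -> ReLU -> fully-connected (logits)."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 hidden: int = 64, n_classes: int = 3):
        super().__init__()
        self.fc1 = nn.Linear(in_features, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_classes, rng)
        self.in_features = in_features

    def __call__(self, f: Tensor) -> Tensor:
        B = f.shape[0]
        x = f.reshape(B, -1)
        return self.fc2(self.fc1(x).relu())


def cross_entropy(probs, labels, eps: float = 1e-12):
    """Mean negative log-probability of the true class.

    ``probs`` may be a Tensor (training path, gradient flows) or an ndarray;
    an epsilon clamp inside the log guards against exactly-zero true-class
    probabilities.
    """
    labels = np.asarray(labels, dtype=int)
    if isinstance(probs, Tensor):
        if probs.shape[0] != labels.shape[0]:
            raise ValueError("batch sizes of probs and labels differ")
        p_true = probs[np.arange(labels.shape[0]), labels]
        return -((p_true + eps).log().mean())
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == 1:
        probs = probs[None, :]
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("batch sizes of probs and labels differ")
    p_true = probs[np.arange(labels.shape[0]), labels]
    return float(-np.mean(np.log(p_true + eps)))


class DualBranchModel(Module):
    """The full network: branch stack, fusion, optional filter, classifier."""

    def __init__(self, cfg: ModelConfig, window_samples: int, seed: int = 0,
                 n_bands: int = 5):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.window_samples = window_samples
        self.n_bands = n_bands
        kinds = {
            "vit_cnn": ("vit", "cnn"),
            "cnn_only": ("cnn",),
            "vit_only": ("vit",),
            "cnn_cnn": ("cnn", "cnn"),
            "vit_vit": ("vit", "vit"),
        }[cfg.branches]
        self.branch_kinds = kinds
        self.branch_modules = [
            ViTBranch(cfg, window_samples, rng) if kind == "vit"
            else CnnBranch(cfg, rng, n_bands)
            for kind in kinds
        ]
        fused_dim = cfg.feature_dim * len(kinds)
        if cfg.use_filter:
            self.filter = FeatureFilter(
                fused_dim, rng, cfg.filter_reduction, cfg.spatial_kernel
            )
        else:
            self.filter = None
        self.head = ClassifierHead(
            cfg.n_channels * fused_dim, rng, cfg.classifier_hidden, cfg.n_classes
        )

    # -- forward -----------------------------------------------------------
    def forward(self, segments, bands) -> Tensor:
        """Logits for a batch. ``segments``: (B, 19, W); ``bands``: (B, 5, 19, T)."""
        segments = Tensor._wrap(segments)
        bands = Tensor._wrap(bands)
        outs = [
            m(segments) if kind == "vit" else m(bands)
            for kind, m in zip(self.branch_kinds, self.branch_modules)
        ]
        if len(outs) == 2:
            fused = fuse_features(outs[0], outs[1])
        else:
            fused = outs[0]
        if self.filter is not None:
            fused = self.filter(fused)
        return self.head(fused)

    __call__ = forward

    def predict_proba(self, segments, bands) -> np.ndarray:
        """Class probabilities (B, 3) in eval mode (deterministic)."""
        was_training = self.training
        self.eval()
        logits = self.forward(segments, bands).data
        if was_training:
            self.train()
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def classify(self, segments, bands) -> list[ClassProbabilities]:
        return [ClassProbabilities(p) for p in self.predict_proba(segments, bands)]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint weights (.npz) with a self-describing JSON sidecar."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        meta = {
            "model_config": self.cfg.to_dict(),
            "window_samples": self.window_samples,
            "n_bands": self.n_bands,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DualBranchModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            ModelConfig.from_dict(meta["model_config"]),
            window_samples=meta["window_samples"],
            n_bands=meta["n_bands"],
        )
        with np.load(path if path.suffix else path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        model.eval()
        return model
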