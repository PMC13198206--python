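"""Dual-encoder classifier: two same-architecture single-channel encoders
(for the H and E views), feature averaging, and a linear+softmax head.

Two encoder architectures share one contract: a small 4-block convolutional
network for desk-scale runs and an 18-layer residual network matching the
full-scale configuration.  Optional 3-layer projection heads can be attached
for the contrastive-loss ablation; they are used only inside the contrastive
term, never by the classifier.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import Tensor, avg_pool2d

__all__ = [
    "SmallConvNet",
    "ResNet18Encoder",
    "ProjectionHead",
    "DualEncoder",
    "adapt_first_layer",
    "build_encoder",
    "save_checkpoint",
    "load_checkpoint",
]


def adapt_first_layer(kernels: np.ndarray) -> np.ndarray:
    """Collapse 3-input-channel first-layer kernels to 1 channel by summation.

    For a convolution this is exact: applying the summed kernels to a
    single-channel image equals applying the originals to that image
    replicated across the three channels.
    """
    kernels = np.asarray(kernels)
    if kernels.ndim != 4 or kernels.shape[1] != 3:
        raise ValueError(
            f"expected kernels of shape (F, 3, kh, kw); got {kernels.shape}"
        )
    return kernels.sum(axis=1, keepdims=True)


class SmallConvNet(nn.Module):
    """Desk-scale encoder: conv-relu-pool blocks, global average pool, linear."""

    def __init__(self, in_ch: int = 1, channels: tuple[int, ...] = (8, 16, 32, 64),
                 feature_dim: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.convs = [
            nn.Conv2d(c_in, c_out, kernel=3, rng=rng)
            for c_in, c_out in zip((in_ch,) + tuple(channels[:-1]), channels)
        ]
        self.head = nn.Linear(channels[-1], feature_dim, rng=rng)
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = avg_pool2d(conv(x).relu(), 2)
        x = x.mean(axis=(2, 3))  # global average pool -> (N, C)
        return self.head(x)


class _BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng)
        self.down = (
            nn.Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng)
            if (stride != 1 or in_ch != out_ch)
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).relu())
        skip = self.down(x) if self.down is not None else x
        return (y + skip).relu()


class ResNet18Encoder(nn.Module):
    """18-layer residual encoder (no batch normalization) with D = 512."""

    def __init__(self, in_ch: int = 1, feature_dim: int = 512,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stem = nn.Conv2d(in_ch, 64, kernel=7, stride=2, pad=3, rng=rng)
        blocks = []
        chans = [(64, 64, 1), (64, 128, 2), (128, 256, 2), (256, 512, 2)]
        for c_in, c_out, stride in chans:
            blocks.append(_BasicBlock(c_in, c_out, stride, rng))
            blocks.append(_BasicBlock(c_out, c_out, 1, rng))
        self.blocks = blocks
        self.head = nn.Linear(512, feature_dim, rng=rng)
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> Tensor:
        x = avg_pool2d(self.stem(x).relu(), 2)
        for block in self.blocks:
            x = block(x)
        x = x.mean(axis=(2, 3))
        return self.head(x)


class ProjectionHead(nn.Module):
    """3-layer perceptron used only inside the contrastive loss (ablation)."""

    def __init__(self, in_dim: int, hidden_dim: int = 128, out_dim: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(in_dim, hidden_dim, rng=rng)
        self.fc2 = nn.Linear(hidden_dim, hidden_dim, rng=rng)
        self.fc3 = nn.Linear(hidden_dim, out_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x).relu()).relu())


def build_encoder(name: str, feature_dim: int,
                  rng: np.random.Generator) -> nn.Module:
    if name == "small":
        return SmallConvNet(feature_dim=feature_dim, rng=rng)
    if name == "resnet18":
        return ResNet18Encoder(feature_dim=feature_dim, rng=rng)
    raise ValueError(f"unknown encoder architecture {name!r}")


class ForwardResult(NamedTuple):
    f_h: Tensor
    f_e: Tensor
    probs: Tensor
    z_h: Tensor | None = None
    z_e: Tensor | None = None


class DualEncoder(nn.Module):
    """Two disjointly parameterized encoders plus a shared classifier head.

    The classifier consumes the elementwise average of the two feature
    vectors, so exchanging ``f_h`` and ``f_e`` leaves its output unchanged.
    """

    def __init__(self, n_classes: int, encoder: str = "small",
                 feature_dim: int = 64, use_projection_heads: bool = False,
                 projection_hidden: int = 128, projection_dim: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        # independent child streams -> disjoint parameters, same architecture
        rng_h, rng_e, rng_c, rng_p = [
            np.random.default_rng(s) for s in rng.integers(0, 2**63 - 1, size=4)
        ]
        self.encoder_h = build_encoder(encoder, feature_dim, rng_h)
        self.encoder_e = build_encoder(encoder, feature_dim, rng_e)
        self.classifier = nn.Linear(feature_dim, n_classes, rng=rng_c,
                                    zero_init=True)
        self.proj_h = self.proj_e = None
        self.projection_hidden = projection_hidden
        self.projection_dim = projection_dim
        if use_projection_heads:
            self.proj_h = ProjectionHead(feature_dim, projection_hidden,
                                         projection_dim, rng=rng_p)
            self.proj_e = ProjectionHead(feature_dim, projection_hidden,
                                         projection_dim, rng=rng_p)
        self.n_classes = n_classes
        self.feature_dim = feature_dim
        self.encoder_name = encoder

    def forward(self, h_batch, e_batch) -> ForwardResult:
        """Run both encoders and the classifier.

        ``h_batch``/``e_batch``: arrays or Tensors of shape (N, 1, H, W).
        Returns features, class probabilities and (if enabled) projections.
        """
        h = Tensor.as_tensor(h_batch)
        e = Tensor.as_tensor(e_batch)
        if h.shape[0] != e.shape[0]:
            raise ValueError("H and E batches must be co-indexed")
        f_h = self.encoder_h(h)
        f_e = self.encoder_e(e)
        fused = (f_h + f_e) * 0.5
        probs = nn.softmax(self.classifier(fused), axis=1)
        z_h = self.proj_h(f_h) if self.proj_h is not None else None
        z_e = self.proj_e(f_e) if self.proj_e is not None else None
        return ForwardResult(f_h, f_e, probs, z_h, z_e)

    # -- checkpointing -------------------------------------------------------

    def config(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "encoder": self.encoder_name,
            "feature_dim": self.feature_dim,
            "use_projection_heads": self.proj_h is not None,
            "projection_hidden": self.projection_hidden,
            "projection_dim": self.projection_dim,
        }


def save_checkpoint(model: DualEncoder, path, meta: dict | None = None) -> None:
    """Write parameters (.npz) plus a JSON sidecar with architecture info."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = dict(model.config())
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[DualEncoder, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = DualEncoder(
        n_classes=meta["n_classes"],
        encoder=meta["encoder"],
        feature_dim=meta["feature_dim"],
        use_projection_heads=meta.get("use_projection_heads", False),
        projection_hidden=meta.get("projection_hidden", 128),
        projection_dim=meta.get("projection_dim", 64),
    )
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model, meta
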