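"""Feature-exposing classifiers for teacher/student training.

A :class:`FeatureClassifier` is any model whose forward pass yields both
class logits and the post-activation output of its last convolutional
block (the feature map both the consistency loss and Grad-CAM hook into).
The runnable architecture is ``tiny_reference`` — a small four-block CNN
with a pooled stem, sized for CPU experiments.  The names of common pretrained backbones are
recognized so configurations can be expressed, but since no pretrained
weights ship with this package, requesting them raises an explicit error
rather than silently training from random initialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

ARCHITECTURES = (
    "tiny_reference", "resnet50", "efficientnet_b0", "efficientnet_b1",
    "convnext_t", "convnext_s",
)

#: channel widths of the tiny reference net's conv blocks: three stride-2
#: stages plus one stride-1 stage that widens the receptive field enough to
#: cover a lesion together with its surrounding context
TINY_CHANNELS = (8, 16, 32, 32)


class UnsupportedArchitectureError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "tiny_reference"
    pretrained: bool = False
    dropout: bool = True
    n_classes: int = 5

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise UnsupportedArchitectureError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


class FeatureClassifier:
    """Backbone + pooled linear head, exposing the last conv feature map.

    ``forward`` returns ``(logits, feature_map)``; ``backward`` accepts
    gradients w.r.t. both and accumulates parameter gradients.  Once
    :func:`freeze` has been applied, forward passes always run in inference
    mode and the parameters are excluded from optimization.
    """

    def __init__(self, config: ModelConfig, backbone: nn.Sequential,
                 head: nn.Sequential, feature_channels: int):
        self.config = config
        self.backbone = backbone
        self.head = head
        self.feature_channels = feature_channels
        self.frozen = False
        self._fmap = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return self.backbone.params() + self.head.params()

    def grads(self) -> list[np.ndarray]:
        return self.backbone.grads() + self.head.grads()

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def state(self) -> list[np.ndarray]:
        """Copies of all learnable parameters (normalization layers are
        per-sample, so parameters fully determine behavior)."""
        return [p.copy() for p in self.params()]

    def load_state(self, arrs: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrs):
            p[...] = a

    def checksum(self) -> float:
        return float(sum(np.abs(a).sum() for a in self.state()))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        if x.ndim != 4:
            raise ValueError(f"expected a (N, C, H, W) batch, got shape {x.shape}")
        if self.frozen:
            train = False
        fmap = self.backbone.forward(x.astype(np.float32), train=train)
        logits = self.head.forward(fmap, train=train)
        self._fmap = fmap
        return logits, fmap

    def backward(self, dlogits: np.ndarray, dfmap: np.ndarray | None = None) -> np.ndarray:
        g = self.head.backward(dlogits)
        if dfmap is not None:
            g = g + dfmap
        return self.backbone.backward(g)

    def head_feature_gradient(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of a logit functional w.r.t. the feature map, computed
        through the head without touching accumulated parameter gradients."""
        saved = [g.copy() for g in self.head.grads()]
        g = self.head.backward(dlogits)
        for ref, s in zip(self.head.grads(), saved):
            ref[...] = s
        return g


def build_model(config: ModelConfig, seed: int = 0, in_channels: int = 3) -> FeatureClassifier:
    """Construct a :class:`FeatureClassifier` for ``config``.

    The head is a global-average pool, optional dropout (p = 0.5) directly
    before the classification layer, and a linear layer with
    ``config.n_classes`` outputs.  All parameters are trainable.
    """
    if config.architecture != "tiny_reference":
        if config.pretrained:
            raise UnsupportedArchitectureError(
                f"pretrained weights for {config.architecture!r} are not "
                "available in this installation; refusing to fall back to "
                "random initialization"
            )
        raise UnsupportedArchitectureError(
            f"architecture {config.architecture!r} requires a pretrained "
            "backbone which this installation does not provide; use "
            "'tiny_reference'"
        )
    rng = np.random.default_rng(seed)
    c1, c2, c3, c4 = TINY_CHANNELS
    backbone = nn.Sequential([
        nn.AvgPool2x2(),
        nn.Conv2d(in_channels, c1, k=3, stride=2, pad=1, rng=rng),
        nn.GroupNorm(c1, groups=4), nn.ReLU(),
        nn.Conv2d(c1, c2, k=3, stride=2, pad=1, rng=rng),
        nn.GroupNorm(c2, groups=8), nn.ReLU(),
        nn.Conv2d(c2, c3, k=3, stride=1, pad=1, rng=rng),
        nn.GroupNorm(c3, groups=8), nn.ReLU(),
        nn.Conv2d(c3, c4, k=3, stride=1, pad=1, rng=rng),
        nn.GroupNorm(c4, groups=8), nn.ReLU(),
    ])
    head_layers: list[nn.Layer] = [nn.GlobalAvgPool()]
    if config.dropout:
        head_layers.append(nn.Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))))
    head_layers.append(nn.Linear(c4, config.n_classes, rng=rng))
    return FeatureClassifier(config, backbone, nn.Sequential(head_layers), c4)


def forward_with_features(model: FeatureClassifier, batch: np.ndarray):
    """Inference-mode forward pass returning ``(logits, feature_map)``."""
    return model.forward(batch, train=False)


def freeze(model: FeatureClassifier) -> FeatureClassifier:
    """Fix the model's weights; later forwards run deterministically."""
    model.frozen = True
    return model


def feature_shape(model: FeatureClassifier, input_size: int, in_channels: int = 3):
    """Spatial/channel dims of the feature map for a given input size."""
    probe = np.zeros((1, in_channels, input_size, input_size), dtype=np.float32)
    _, fmap = model.forward(probe, train=False)
    return fmap.shape[1:]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FeatureClassifier, path, metadata: dict | None = None) -> None:
    arrs = {f"arr_{i}": a for i, a in enumerate(model.state())}
    meta = {"config": asdict(model.config), "frozen": model.frozen,
            "metadata": metadata or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrs)


def load_checkpoint(path, seed: int = 0, in_channels: int = 3) -> FeatureClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrs = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    model = build_model(ModelConfig(**meta["config"]), seed=seed, in_channels=in_channels)
    model.load_state(arrs)
    if meta["frozen"]:
        freeze(model)
    return model
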