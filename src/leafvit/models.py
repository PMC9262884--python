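"""Assembly of the eight lightweight classifiers from the two blocks.

Backbones (Fig.-style shorthand: I = conv block, II = transformer block):

====== =====================================================================
Model  Backbone
====== =====================================================================
1      I
2      I, I
3      patchify, II
4      patchify, II, II
5      Block III — I fused with (tokenizer, II) as one unit
6      I, tokenizer, II           (stacked version of 5)
7      Block IV — (patchify, II) fused with (tokens-to-grid, I) as one unit
8      patchify, II, tokens-to-grid, I   (stacked version of 7)
====== =====================================================================

All models share one classification head: pooling (global average by
default), two hidden dense layers with leaky ReLU and dropout, and a softmax
output.  Blocks III and IV are implemented as fused composites with the same
internals as their stacked counterparts; ``fused_filters`` /
``fused_proj_dim`` on the spec let the fused units be narrowed independently.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .blocks import (
    ConvBlock,
    ConvBlockConfig,
    Dense,
    Dropout,
    Flatten,
    GlobalAveragePool,
    LeakyReLU,
    PatchEmbed,
    PatchEmbedConfig,
    PatchExtract,
    TokensToGrid,
    TransformerBlock,
    TransformerBlockConfig,
)

__all__ = ["ModelSpec", "ClassifierOutput", "Model", "build_model",
           "save_checkpoint", "load_checkpoint", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1

_STANDARD_SIDES = (50, 100, 200)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the eight classifiers."""

    model_id: int
    input_side: int = 50
    n_classes: int = 3
    head_widths: tuple[int, int] = (64, 64)
    head_pooling: str = "global_average"  # or "flatten"
    head_dropout: float = 0.25
    conv: ConvBlockConfig = field(default_factory=ConvBlockConfig)
    transformer: TransformerBlockConfig = field(
        default_factory=TransformerBlockConfig)
    patch: PatchEmbedConfig = field(default_factory=PatchEmbedConfig)
    # width-override hook for the fused Blocks III / IV (models 5 and 7);
    # None means "same widths as the stacked equivalents".
    fused_filters: int | None = None
    fused_proj_dim: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.model_id <= 8:
            raise ValueError(f"model_id must be in 1..8, got {self.model_id}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(self.head_widths) != 2:
            raise ValueError("head_widths must have exactly two entries")
        if self.head_pooling not in ("global_average", "flatten"):
            raise ValueError("head_pooling must be 'global_average' or "
                             "'flatten'")
        if self.input_side not in _STANDARD_SIDES:
            warnings.warn(
                f"input_side {self.input_side} is outside the standard set "
                f"{_STANDARD_SIDES}; proceeding anyway", stacklevel=2)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @staticmethod
    def from_json(text: str) -> "ModelSpec":
        d = json.loads(text)
        d["conv"] = ConvBlockConfig(**d["conv"])
        tr = d["transformer"]
        tr["mlp_widths"] = tuple(tr["mlp_widths"])
        d["transformer"] = TransformerBlockConfig(**tr)
        d["patch"] = PatchEmbedConfig(**d["patch"])
        d["head_widths"] = tuple(d["head_widths"])
        return ModelSpec(**d)


@dataclass(frozen=True)
class ClassifierOutput:
    """Softmax probabilities and the arg-max class (ties -> lowest index)."""

    probabilities: np.ndarray
    predicted_class: int


class Model:
    """A built classifier: an ordered list of (block label, layer) pairs."""

    def __init__(self, spec: ModelSpec, layers: list, seed: int):
        self.spec = spec
        self.layers = layers  # list of (label, Layer)
        self.seed = seed

    # -- structure ---------------------------------------------------------

    def iter_primitives(self):
        """Yield (label, primitive layer) with composite blocks expanded."""
        for label, lyr in self.layers:
            if hasattr(lyr, "sublayers"):
                for sub in lyr.sublayers:
                    yield label, sub
            else:
                yield label, lyr

    def parameters(self):
        """Yield (layer, param name, array) over all trainable parameters."""
        for _, lyr in self.iter_primitives():
            for k in lyr.params:
                yield lyr, k, lyr.params[k]

    def n_params(self) -> int:
        return sum(int(v.size) for _, _, v in self.parameters())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{lyr.name}/{k}": v.copy()
                for lyr, k, v in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for lyr, k, v in self.parameters():
            key = f"{lyr.name}/{k}"
            if key not in weights:
                raise KeyError(f"checkpoint is missing parameter {key!r}")
            if weights[key].shape != v.shape:
                raise ValueError(f"shape mismatch for {key!r}")
            lyr.params[k] = weights[key].copy()

    def zero_grads(self) -> None:
        for _, lyr in self.iter_primitives():
            lyr.zero_grads()

    # -- forward -----------------------------------------------------------

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected images of shape (batch, side, side, 3)")
        s = self.spec.input_side
        if x.shape[1] != s or x.shape[2] != s:
            raise ValueError(
                f"model {self.spec.model_id} expects input side {s}, got "
                f"{x.shape[1]}x{x.shape[2]}")
        # inputs arrive in [0, 1]; centre to [-0.5, 0.5] before the backbone
        # (uncentred conv inputs couple first-layer gradient directions and
        # slow optimisation badly)
        return x - 0.5

    def forward(self, images: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch of images (no softmax)."""
        x = self._check_input(images)
        for _, lyr in self.layers:
            x = lyr.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for _, lyr in reversed(self.layers):
            d = lyr.backward(d)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        logits = self.forward(images, train=False)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=-1)

    def classify(self, images: np.ndarray) -> list[ClassifierOutput]:
        probs = self.predict_proba(images)
        return [ClassifierOutput(p, int(p.argmax())) for p in probs]

    # -- reporting ---------------------------------------------------------

    def summarize(self) -> str:
        """Layer table: label, name, output shape, parameter count."""
        from .complexity import count_flops

        rep = count_flops(self)
        buf = io.StringIO()
        hdr = f"Model {self.spec.model_id} @ {self.spec.input_side}px, " \
              f"{self.spec.n_classes} classes"
        buf.write(hdr + "\n")
        buf.write("-" * 72 + "\n")
        buf.write(f"{'block':<14}{'layer':<28}{'out shape':<16}{'params':>12}\n")
        shape = (self.spec.input_side, self.spec.input_side, 3)
        by_name = {e.name: e for e in rep.per_layer}
        for label, lyr in self.iter_primitives():
            shape = lyr.out_shape(shape)
            n = by_name[lyr.name].params if lyr.name in by_name else 0
            shp = "x".join(str(s) for s in shape)
            buf.write(f"{label:<14}{lyr.name:<28}{shp:<16}{n:>12,}\n")
        buf.write("-" * 72 + "\n")
        buf.write(f"{'total':<58}{rep.total_params:>14,}\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Instantiate one of the eight classifiers with seeded weights.

    The returned model's layer list is inspectable: ``model.layers`` holds
    (block label, layer) pairs in execution order, composite blocks expand
    through ``iter_primitives``.
    """
    rng = np.random.default_rng(seed)
    side = spec.input_side
    mid = spec.model_id
    layers: list = []
    shape = (side, side, 3)

    def add(label, lyr):
        nonlocal shape
        layers.append((label, lyr))
        shape = lyr.out_shape(shape)

    def add_conv(label, cfg):
        blk = ConvBlock(shape[-1], cfg, name=f"{label.lower().replace(' ', '_')}",
                        rng=rng)
        add(label, blk)

    def add_tokenizer(label, patch_cfg, proj_dim):
        pe = PatchExtract(patch_cfg.patch_side,
                          name=f"{label.lower().replace(' ', '_')}.patchify")
        n_tokens, patch_len = pe.out_shape(shape)
        add(label, pe)
        emb = PatchEmbed(patch_len, n_tokens, proj_dim,
                         positional=patch_cfg.positional,
                         name=f"{label.lower().replace(' ', '_')}.embed",
                         rng=rng)
        add(label, emb)

    def add_transformer(label, cfg):
        blk = TransformerBlock(cfg, name=f"{label.lower().replace(' ', '_')}",
                               rng=rng)
        add(label, blk)

    conv_cfg = spec.conv
    tr_cfg = spec.transformer
    patch_cfg = spec.patch

    # fused-block width overrides (models 5 and 7 only)
    fused_conv = conv_cfg if spec.fused_filters is None else ConvBlockConfig(
        filters=spec.fused_filters, kernel_side=conv_cfg.kernel_side,
        pool_side=conv_cfg.pool_side, leaky_slope=conv_cfg.leaky_slope)
    if spec.fused_proj_dim is None:
        fused_tr, fused_dim = tr_cfg, tr_cfg.proj_dim
    else:
        fused_dim = spec.fused_proj_dim
        fused_tr = TransformerBlockConfig(
            num_heads=tr_cfg.num_heads, proj_dim=fused_dim,
            mlp_widths=(tr_cfg.mlp_widths[0], fused_dim),
            mlp_activation=tr_cfg.mlp_activation, dropout=tr_cfg.dropout)

    if mid == 1:
        add_conv("Block I", conv_cfg)
    elif mid == 2:
        add_conv("Block I #1", conv_cfg)
        add_conv("Block I #2", conv_cfg)
    elif mid == 3:
        add_tokenizer("Patchify", patch_cfg, tr_cfg.proj_dim)
        add_transformer("Block II", tr_cfg)
    elif mid == 4:
        add_tokenizer("Patchify", patch_cfg, tr_cfg.proj_dim)
        add_transformer("Block II #1", tr_cfg)
        add_transformer("Block II #2", tr_cfg)
    elif mid == 5:  # Block III: conv -> tokenizer -> transformer, one unit
        add_conv("Block III", fused_conv)
        add_tokenizer("Block III", patch_cfg, fused_dim)
        add_transformer("Block III", fused_tr)
    elif mid == 6:
        add_conv("Block I", conv_cfg)
        add_tokenizer("Tokenizer", patch_cfg, tr_cfg.proj_dim)
        add_transformer("Block II", tr_cfg)
    elif mid == 7:  # Block IV: transformer -> grid -> conv, one unit
        add_tokenizer("Block IV", patch_cfg, fused_dim)
        add_transformer("Block IV", fused_tr)
        add("Block IV", TokensToGrid(name="block_iv.to_grid"))
        add_conv("Block IV", fused_conv)
    elif mid == 8:
        add_tokenizer("Patchify", patch_cfg, tr_cfg.proj_dim)
        add_transformer("Block II", tr_cfg)
        add("Bridge", TokensToGrid(name="bridge.to_grid"))
        add_conv("Block I", conv_cfg)

    # shared classification head
    if spec.head_pooling == "global_average":
        add("Head", GlobalAveragePool(name="head.gap"))
    else:
        add("Head", Flatten(name="head.flatten"))
    w1, w2 = spec.head_widths
    add("Head", Dense(shape[-1], w1, "head.dense1", rng))
    add("Head", LeakyReLU(conv_cfg.leaky_slope, "head.act1"))
    add("Head", Dropout(spec.head_dropout, "head.drop1"))
    add("Head", Dense(w1, w2, "head.dense2", rng))
    add("Head", LeakyReLU(conv_cfg.leaky_slope, "head.act2"))
    add("Head", Dropout(spec.head_dropout, "head.drop2"))
    add("Head", Dense(w2, spec.n_classes, "head.logits", rng))

    return Model(spec, layers, seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path) -> None:
    """Single-file checkpoint embedding the producing spec and a version."""
    arrays = model.get_weights()
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "seed": model.seed,
                       "spec": json.loads(model.spec.to_json())})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Model:
    """Rebuild the model recorded in a checkpoint and restore its weights."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')!r}")
        spec = ModelSpec.from_json(json.dumps(meta["spec"]))
        model = build_model(spec, seed=meta.get("seed", 0))
        model.set_weights({k: data[k] for k in data.files
                           if k != "__meta__"})
    return model
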