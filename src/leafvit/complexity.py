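"""Analytic per-layer FLOP and parameter accounting.

Counting convention (stated in every report header): one multiply-accumulate
is one FLOP; layer normalisation, softmax, activations and pooling are
counted as zero.  Per layer, for a per-sample input with N tokens of
dimension d (or a feature map of output size outH x outW):

* conv (k x k, C_in -> C_out):  outH * outW * k^2 * C_in * C_out
* dense (in -> out):            in * out, times N when applied token-wise
* attention (d, any head split): 3*N*d^2 (q,k,v) + N^2*d (scores)
                                 + N^2*d (weighted values) + N*d^2 (out proj)
* patch projection:             N * patch_len * d
* parameters: conv k^2*C_in*C_out + C_out; dense in*out + out; layer norm
  2*d; attention 4*(d^2 + d); positional table n_tokens*d; patch projection
  (patch_len + 1)*d.

These closed forms equal exhaustive multiply counts of naive nested-loop
implementations of the same layers (asserted in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .blocks import (
    Conv2D,
    Dense,
    LayerNorm,
    MultiHeadAttention,
    PatchEmbed,
)
from .models import Model, ModelSpec, build_model

__all__ = ["LayerCost", "ComplexityReport", "count_params", "count_flops",
           "compare_models", "EFFICIENTNETB0_GFLOPS", "CONVENTION"]

#: Published forward-pass cost of the EfficientNetB0 reference, used only as
#: a comparison constant (never computed here).
EFFICIENTNETB0_GFLOPS = 0.794

CONVENTION = ("1 multiply-accumulate = 1 FLOP; norms, softmax, activations "
              "and pooling counted as 0")


@dataclass(frozen=True)
class LayerCost:
    name: str
    flops: int
    params: int


@dataclass(frozen=True)
class ComplexityReport:
    """Per-layer costs plus totals; ``gflops = total_flops / 1e9``."""

    per_layer: tuple[LayerCost, ...]
    convention: str = CONVENTION

    @property
    def total_flops(self) -> int:
        return sum(e.flops for e in self.per_layer)

    @property
    def total_params(self) -> int:
        return sum(e.params for e in self.per_layer)

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def to_tsv(self) -> str:
        lines = [f"# convention: {self.convention}",
                 "layer\tflops\tparams"]
        lines += [f"{e.name}\t{e.flops}\t{e.params}" for e in self.per_layer]
        lines.append(f"TOTAL\t{self.total_flops}\t{self.total_params}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "convention": self.convention,
            "per_layer": [{"name": e.name, "flops": e.flops,
                           "params": e.params} for e in self.per_layer],
            "total_flops": self.total_flops,
            "total_params": self.total_params,
            "gflops": self.gflops,
        })


def _layer_cost(lyr, in_shape) -> tuple[int, int]:
    """(flops, params) of one primitive layer on a per-sample input shape."""
    if isinstance(lyr, Conv2D):
        oh, ow, _ = lyr.out_shape(in_shape)
        flops = oh * ow * lyr.k * lyr.k * lyr.c_in * lyr.c_out
        params = lyr.k * lyr.k * lyr.c_in * lyr.c_out + lyr.c_out
        return flops, params
    if isinstance(lyr, Dense):
        n = 1
        if len(in_shape) == 2:  # token-wise application
            n = in_shape[0]
        return n * lyr.d_in * lyr.d_out, lyr.d_in * lyr.d_out + lyr.d_out
    if isinstance(lyr, MultiHeadAttention):
        n, d = in_shape
        flops = 4 * n * d * d + 2 * n * n * d
        params = 4 * (d * d + d)
        return flops, params
    if isinstance(lyr, PatchEmbed):
        n, plen = in_shape
        flops = n * plen * lyr.dim
        params = (plen + 1) * lyr.dim
        if lyr.positional:
            params += lyr.n_tokens * lyr.dim
        return flops, params
    if isinstance(lyr, LayerNorm):
        return 0, 2 * lyr.dim
    return 0, 0


def _analyze(model: Model) -> ComplexityReport:
    side = model.spec.input_side
    shape = (side, side, 3)
    entries = []
    for _, lyr in model.iter_primitives():
        flops, params = _layer_cost(lyr, shape)
        entries.append(LayerCost(lyr.name, flops, params))
        shape = lyr.out_shape(shape)
    return ComplexityReport(tuple(entries))


def count_flops(model: Model, input_side: int | None = None
                ) -> ComplexityReport:
    """Analytic forward-pass cost of a built model.

    If ``input_side`` differs from the model's own, the model is rebuilt at
    that resolution (token counts and conv output sizes change with it).
    """
    if input_side is not None and input_side != model.spec.input_side:
        spec = ModelSpec(**{**_spec_dict(model.spec),
                            "input_side": input_side})
        model = build_model(spec, seed=model.seed)
    return _analyze(model)


def count_params(model: Model) -> ComplexityReport:
    """Per-layer trainable parameter counts (FLOPs included for free)."""
    return _analyze(model)


def _spec_dict(spec: ModelSpec) -> dict:
    return {
        "model_id": spec.model_id, "input_side": spec.input_side,
        "n_classes": spec.n_classes, "head_widths": spec.head_widths,
        "head_pooling": spec.head_pooling, "head_dropout": spec.head_dropout,
        "conv": spec.conv, "transformer": spec.transformer,
        "patch": spec.patch, "fused_filters": spec.fused_filters,
        "fused_proj_dim": spec.fused_proj_dim,
    }


def compare_models(specs: list[ModelSpec], sides: list[int]) -> list[dict]:
    """One row per (model, side) with gflops and parameter counts, plus a
    constant reference row for EfficientNetB0 at its published cost."""
    if not specs or not sides:
        raise ValueError("specs and sides must be nonempty")
    rows = []
    for spec in specs:
        for side in sides:
            s = ModelSpec(**{**_spec_dict(spec), "input_side": side})
            rep = _analyze(build_model(s, seed=0))
            rows.append({"model": f"Model {spec.model_id}", "side": side,
                         "gflops": rep.gflops, "params": rep.total_params})
    rows.append({"model": "EfficientNetB0 (published)", "side": None,
                 "gflops": EFFICIENTNETB0_GFLOPS, "params": None})
    return rows


def comparison_table(rows: list[dict]) -> str:
    out = [f"{'model':<28}{'side':>6}{'GFlops':>10}{'params':>12}"]
    for r in rows:
        side = "" if r["side"] is None else str(r["side"])
        params = "" if r["params"] is None else f"{r['params']:,}"
        out.append(f"{r['model']:<28}{side:>6}{r['gflops']:>10.3f}"
                   f"{params:>12}")
    return "\n".join(out)
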