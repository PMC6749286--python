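"""Segmentation model assembly.

Two architectures, both emitting per-pixel soil/crop/weed probabilities on a
grid four times coarser than the input:

* the *stationary* model — a classic U-Net with full 3x3 convolutions, four
  encoder levels plus a bottleneck, and a decoder that stops at 1/4 input
  resolution (accurate but heavy; trained in ensembles and used as the
  distillation teacher);
* the *mobile* model — a U-Net / MobileNet / DenseNet hybrid: a stride-2 stem,
  DenseNet-Mobile encoder blocks, nearest-neighbour upscaling instead of
  transposed convolutions, one skip connection, and a few separable residual
  units before the class head (cheap enough for small ARM boards).

Layer widths come from the width-multiplier schedules in
:mod:`weedseg.channel_schedule`: the stationary model scales its base widths
(64, 128, 256, 512) with the MobileNets rule; the mobile model derives its
stage widths (A, B, C) from bases (16, 32, 64) under either schedule.
"""

from __future__ import annotations

import copy as _copy
import io
import json
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from . import engine
from .blocks import BlockSpec, add_dense_mobile, add_separable_conv
from .channel_schedule import AlphaParams, channel_triple, f_mobilenet
from .netgraph import (
    INPUT_ID,
    GraphNode,
    NetworkGraph,
    TensorShape,
    graph_from_text,
    graph_to_text,
    propagate_shapes,
)

__all__ = [
    "StationaryConfig",
    "MobileConfig",
    "SegModel",
    "build_stationary",
    "build_mobile",
    "init_weights",
    "save_model",
    "load_model",
]

N_CLASSES = 3
OUTPUT_FACTOR = 4  # both architectures predict on a 4x-coarser grid


@dataclass(frozen=True)
class StationaryConfig:
    alpha: float = 1.0
    base_widths: Tuple[int, ...] = (64, 128, 256, 512)
    n_classes: int = N_CLASSES
    use_bn: bool = True

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")
        if list(self.base_widths) != sorted(set(self.base_widths)):
            raise ValueError("base_widths must be strictly increasing")
        if len(self.base_widths) != 4:
            raise ValueError("stationary model uses exactly 4 encoder widths")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class MobileConfig:
    alpha: float = 1.0
    channel_variant: Literal["mobilenet", "mod8"] = "mod8"
    block_variant: Literal["naive", "custom"] = "custom"
    n_residual: int = 2
    n_classes: int = N_CLASSES
    use_bn: bool = True

    def __post_init__(self) -> None:
        AlphaParams(self.alpha, self.channel_variant)  # validates both
        if self.block_variant not in ("naive", "custom"):
            raise ValueError(f"unknown block variant {self.block_variant!r}")
        if self.n_residual < 0:
            raise ValueError("n_residual must be >= 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _conv_bn_relu(nodes: List[GraphNode], inp: str, name: str, cin: int,
                  cout: int, stride: int = 1, use_bn: bool = True) -> str:
    nodes.append(GraphNode(name, "conv2d", (inp,), kernel=3, stride=stride,
                           in_channels=cin, out_channels=cout))
    cur = name
    if use_bn:
        nodes.append(GraphNode(f"{name}_bn", "batch_norm", (cur,),
                               in_channels=cout, out_channels=cout))
        cur = f"{name}_bn"
    nodes.append(GraphNode(f"{name}_relu", "relu", (cur,),
                           in_channels=cout, out_channels=cout))
    return f"{name}_relu"


def _head(nodes: List[GraphNode], inp: str, cin: int, n_classes: int) -> str:
    nodes.append(GraphNode("head_pw", "pointwise_conv2d", (inp,), kernel=1,
                           in_channels=cin, out_channels=n_classes))
    nodes.append(GraphNode("softmax", "softmax", ("head_pw",),
                           in_channels=n_classes, out_channels=n_classes))
    return "softmax"


def build_stationary(config: StationaryConfig) -> NetworkGraph:
    """U-Net: 4 encoder levels (two 3x3 convs each) + bottleneck at 1/16,
    decoder with two upscale+skip levels ending at 1/4, pointwise class head.

    Input height/width must be divisible by 16.
    """
    w = [f_mobilenet(b, config.alpha) for b in config.base_widths]
    nodes: List[GraphNode] = []
    bn = config.use_bn

    cur = _conv_bn_relu(nodes, INPUT_ID, "enc1a", 3, w[0], use_bn=bn)
    enc1 = _conv_bn_relu(nodes, cur, "enc1b", w[0], w[0], use_bn=bn)
    skips = []
    cur = enc1
    for lvl in range(2, 5):
        nodes.append(GraphNode(f"pool{lvl - 1}", "avg_pool2x2", (cur,),
                               in_channels=w[lvl - 2], out_channels=w[lvl - 2]))
        cur = _conv_bn_relu(nodes, f"pool{lvl - 1}", f"enc{lvl}a", w[lvl - 2],
                            w[lvl - 1], use_bn=bn)
        cur = _conv_bn_relu(nodes, cur, f"enc{lvl}b", w[lvl - 1], w[lvl - 1],
                            use_bn=bn)
        skips.append((cur, w[lvl - 1]))
    # bottleneck at 1/16
    nodes.append(GraphNode("pool4", "avg_pool2x2", (cur,),
                           in_channels=w[3], out_channels=w[3]))
    cur = _conv_bn_relu(nodes, "pool4", "bott_a", w[3], w[3], use_bn=bn)
    cur = _conv_bn_relu(nodes, cur, "bott_b", w[3], w[3], use_bn=bn)
    # decoder: 1/16 -> 1/8 (skip enc4) -> 1/4 (skip enc3)
    cur_ch = w[3]
    for d, (skip, skip_ch) in enumerate(reversed(skips[-2:]), start=1):
        nodes.append(GraphNode(f"up{d}", "upscale2x", (cur,),
                               in_channels=cur_ch, out_channels=cur_ch))
        nodes.append(GraphNode(f"dec{d}_cat", "concat", (f"up{d}", skip),
                               in_channels=cur_ch + skip_ch,
                               out_channels=cur_ch + skip_ch))
        cur = _conv_bn_relu(nodes, f"dec{d}_cat", f"dec{d}", cur_ch + skip_ch,
                            skip_ch, use_bn=bn)
        cur_ch = skip_ch
    out = _head(nodes, cur, cur_ch, config.n_classes)
    return NetworkGraph(nodes=nodes, output_nodes=(out,))


def build_mobile(config: MobileConfig) -> NetworkGraph:
    """Mobile hybrid: stride-2 stem to width A; two reducing and one
    non-reducing DenseNet-Mobile blocks with pointwise transitions to widths
    B, C, C; nearest-neighbour upscale + skip from the width-B stage; a few
    separable residual units; pointwise class head.  Total downsampling 4.

    Input height/width must be divisible by 8.
    """
    A, B, C = channel_triple(AlphaParams(config.alpha, config.channel_variant))
    g1, g2, g3 = max(1, B // 4), max(1, C // 4), max(1, C // 4)
    bn = config.use_bn
    nodes: List[GraphNode] = []

    stem = _conv_bn_relu(nodes, INPUT_ID, "stem", 3, A, stride=2, use_bn=bn)

    def block(inp: str, prefix: str, cin: int, growth: int, reduce: bool,
              trans_out: int) -> str:
        spec = BlockSpec(in_channels=cin, growth=growth, depthwise_layers=3,
                         reduce=reduce, variant=config.block_variant, use_bn=bn)
        out = add_dense_mobile(nodes, inp, prefix, spec)
        out_ch = cin + 3 * growth
        nodes.append(GraphNode(f"{prefix}trans", "pointwise_conv2d", (out,),
                               kernel=1, in_channels=out_ch, out_channels=trans_out))
        cur = f"{prefix}trans"
        if bn:
            nodes.append(GraphNode(f"{prefix}trans_bn", "batch_norm", (cur,),
                                   in_channels=trans_out, out_channels=trans_out))
            cur = f"{prefix}trans_bn"
        nodes.append(GraphNode(f"{prefix}trans_relu", "relu", (cur,),
                               in_channels=trans_out, out_channels=trans_out))
        return f"{prefix}trans_relu"

    b1 = block(stem, "b1_", A, g1, reduce=True, trans_out=B)   # 1/4, skip source
    b2 = block(b1, "b2_", B, g2, reduce=True, trans_out=C)     # 1/8
    b3 = block(b2, "b3_", C, g3, reduce=False, trans_out=C)    # 1/8

    nodes.append(GraphNode("dec_up", "upscale2x", (b3,), in_channels=C,
                           out_channels=C))
    nodes.append(GraphNode("dec_cat", "concat", ("dec_up", b1),
                           in_channels=C + B, out_channels=C + B))
    nodes.append(GraphNode("dec_pw", "pointwise_conv2d", ("dec_cat",), kernel=1,
                           in_channels=C + B, out_channels=B))
    cur = "dec_pw"
    if bn:
        nodes.append(GraphNode("dec_bn", "batch_norm", (cur,), in_channels=B,
                               out_channels=B))
        cur = "dec_bn"
    nodes.append(GraphNode("dec_relu", "relu", (cur,), in_channels=B,
                           out_channels=B))
    cur = "dec_relu"
    for r in range(config.n_residual):
        branch = add_separable_conv(nodes, cur, f"res{r}_", B, B, stride=1,
                                    use_bn=bn)
        nodes.append(GraphNode(f"res{r}_add", "add", (cur, branch),
                               in_channels=B, out_channels=B))
        cur = f"res{r}_add"
    out = _head(nodes, cur, B, config.n_classes)
    return NetworkGraph(nodes=nodes, output_nodes=(out,))


# ---------------------------------------------------------------------------
# SegModel: graph + weights
# ---------------------------------------------------------------------------

@dataclass
class SegModel:
    """A network graph with concrete weight values."""

    graph: NetworkGraph
    weights: Dict[str, np.ndarray]
    buffers: Dict[str, np.ndarray]
    meta: Dict = field(default_factory=dict)
    history: List[float] = field(default_factory=list)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Batch forward pass: (N,H,W,3) image -> (N,H/4,W/4,classes) probs."""
        acts, _ = engine.forward(self.graph, self.weights, self.buffers, x,
                                 training=training, keep=False)
        return acts[self.graph.output_nodes[-1]]

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Single image (H,W,3) float in [0,1] -> probability map (h,w,classes)."""
        return self.forward(image[None].astype(np.float32))[0]

    def copy(self) -> "SegModel":
        return SegModel(
            graph=self.graph,
            weights={k: v.copy() for k, v in self.weights.items()},
            buffers={k: v.copy() for k, v in self.buffers.items()},
            meta=_copy.deepcopy(self.meta),
            history=list(self.history),
        )

    def output_shape(self, input_shape: TensorShape) -> TensorShape:
        return propagate_shapes(self.graph, input_shape)[self.graph.output_nodes[-1]]


def init_weights(graph: NetworkGraph, seed: int, meta: Optional[Dict] = None) -> SegModel:
    """Deterministic fan-in-scaled random initialisation."""
    weights, buffers = engine.init_weights(graph, seed)
    return SegModel(graph=graph, weights=weights, buffers=buffers,
                    meta=dict(meta or {}, seed=int(seed)))


def save_model(model: SegModel, path: str) -> None:
    """Portable array-archive checkpoint (npz): weights, buffers, graph text."""
    arrays = {f"w:{k}": v for k, v in model.weights.items()}
    arrays.update({f"b:{k}": v for k, v in model.buffers.items()})
    arrays["graph_text"] = np.array(graph_to_text(model.graph))
    arrays["meta_json"] = np.array(json.dumps(model.meta))
    arrays["history"] = np.asarray(model.history, np.float64)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str) -> SegModel:
    with np.load(path, allow_pickle=False) as data:
        graph = graph_from_text(str(data["graph_text"]))
        meta = json.loads(str(data["meta_json"]))
        weights = {k[2:]: data[k] for k in data.files if k.startswith("w:")}
        buffers = {k[2:]: data[k] for k in data.files if k.startswith("b:")}
        history = [float(v) for v in data["history"]] if "history" in data.files else []
    return SegModel(graph=graph, weights=weights, buffers=buffers, meta=meta,
                    history=history)
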