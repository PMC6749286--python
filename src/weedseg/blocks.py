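"""Separable-convolution primitives and the DenseNet-Mobile block.

A DenseNet block stacks "stages" where every stage consumes the concatenation
of the block input and all earlier stage outputs, and contributes a fixed
number of new ("growth") channels; the block output concatenates everything.
Replacing each stage's full convolution with a depthwise 3x3 + pointwise 1x1
pair gives the *naive* DenseNet-Mobile block — but then each channel gets
depthwise-filtered again at every later stage that reads it.

The *custom* block computes one depthwise copy per channel, cached when the
channel is first needed, and lets every stage's pointwise conv read the cached
bank.  For resolution-reducing blocks the custom variant average-pools the
block input *before* any convolution, so the whole block runs at the reduced
resolution, whereas the naive block runs its dense stages at full resolution
and pools its output afterwards (the classic dense-block + transition-pool
layout).  Both variants emit ``in_channels + L * growth`` channels.

With depthwise kernels tied across stages (see :func:`tie_depthwise_weights`)
and identical pointwise weights, the naive and custom non-reducing blocks are
numerically identical — the redundancy the custom form removes is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Literal, Optional, Tuple

from .netgraph import INPUT_ID, GraphNode, NetworkGraph

__all__ = [
    "BlockSpec",
    "build_separable_conv",
    "build_dense_mobile_naive",
    "build_dense_mobile_custom",
    "build_dense_mobile",
    "tie_depthwise_weights",
    "depthwise_channel_load",
    "block_output_channels",
]


@dataclass(frozen=True)
class BlockSpec:
    """Configuration of one DenseNet-Mobile block.

    ``depthwise_layers`` is the number of growth stages (the reference block
    has 3); ``growth`` the channels each stage adds; ``reduce`` halves the
    spatial resolution; ``use_bn`` toggles batch normalisation after each
    pointwise conv.
    """

    in_channels: int
    growth: int
    depthwise_layers: int = 3
    reduce: bool = False
    variant: Literal["naive", "custom"] = "custom"
    use_bn: bool = True

    def __post_init__(self) -> None:
        if self.depthwise_layers < 1:
            raise ValueError("depthwise_layers must be >= 1")
        if self.growth < 1:
            raise ValueError("growth must be >= 1")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.variant not in ("naive", "custom"):
            raise ValueError(f"unknown block variant {self.variant!r}")


def block_output_channels(spec: BlockSpec) -> int:
    return spec.in_channels + spec.depthwise_layers * spec.growth


# ---------------------------------------------------------------------------
# Node-list builders.  Each helper appends nodes and returns the output id;
# the public functions wrap them into standalone NetworkGraph fragments whose
# input is the reserved id "input".
# ---------------------------------------------------------------------------

def add_separable_conv(
    nodes: List[GraphNode],
    inp: str,
    prefix: str,
    in_channels: int,
    out_channels: int,
    stride: int = 1,
    use_bn: bool = True,
) -> str:
    """Depthwise 3x3 -> [BN] -> ReLU -> pointwise 1x1 -> [BN] -> ReLU."""
    if stride not in (1, 2):
        raise ValueError(f"stride must be 1 or 2, got {stride}")
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be >= 1")
    dw = f"{prefix}dw"
    nodes.append(GraphNode(dw, "depthwise_conv2d", (inp,), kernel=3, stride=stride,
                           in_channels=in_channels, out_channels=in_channels))
    cur = dw
    if use_bn:
        nodes.append(GraphNode(f"{prefix}dw_bn", "batch_norm", (cur,),
                               in_channels=in_channels, out_channels=in_channels))
        cur = f"{prefix}dw_bn"
    nodes.append(GraphNode(f"{prefix}dw_relu", "relu", (cur,),
                           in_channels=in_channels, out_channels=in_channels))
    cur = f"{prefix}dw_relu"
    nodes.append(GraphNode(f"{prefix}pw", "pointwise_conv2d", (cur,), kernel=1,
                           in_channels=in_channels, out_channels=out_channels))
    cur = f"{prefix}pw"
    if use_bn:
        nodes.append(GraphNode(f"{prefix}pw_bn", "batch_norm", (cur,),
                               in_channels=out_channels, out_channels=out_channels))
        cur = f"{prefix}pw_bn"
    nodes.append(GraphNode(f"{prefix}pw_relu", "relu", (cur,),
                           in_channels=out_channels, out_channels=out_channels))
    return f"{prefix}pw_relu"


def _stage_tail(
    nodes: List[GraphNode], prefix: str, i: int, pw_in: str, in_ch: int,
    growth: int, use_bn: bool,
) -> str:
    """Pointwise conv to ``growth`` channels, then BN + ReLU."""
    pw = f"{prefix}s{i}_pw"
    nodes.append(GraphNode(pw, "pointwise_conv2d", (pw_in,), kernel=1,
                           in_channels=in_ch, out_channels=growth))
    cur = pw
    if use_bn:
        nodes.append(GraphNode(f"{prefix}s{i}_bn", "batch_norm", (cur,),
                               in_channels=growth, out_channels=growth))
        cur = f"{prefix}s{i}_bn"
    nodes.append(GraphNode(f"{prefix}s{i}_relu", "relu", (cur,),
                           in_channels=growth, out_channels=growth))
    return f"{prefix}s{i}_relu"


def add_dense_mobile_naive(
    nodes: List[GraphNode], inp: str, prefix: str, spec: BlockSpec
) -> str:
    """Naive block: stage i depthwise-filters concat(input, S1..S_{i-1}) anew.

    Reducing blocks run every stage at full resolution and 2x2-average-pool
    the concatenated output.
    """
    c0, g, L = spec.in_channels, spec.growth, spec.depthwise_layers
    feats: List[Tuple[str, int]] = [(inp, c0)]
    for i in range(1, L + 1):
        if len(feats) == 1:
            cat = feats[0][0]
        else:
            cat = f"{prefix}s{i}_cat"
            nodes.append(GraphNode(cat, "concat", tuple(f for f, _ in feats),
                                   in_channels=sum(c for _, c in feats),
                                   out_channels=sum(c for _, c in feats)))
        ch = sum(c for _, c in feats)
        dw = f"{prefix}s{i}_dw"
        nodes.append(GraphNode(dw, "depthwise_conv2d", (cat,), kernel=3, stride=1,
                               in_channels=ch, out_channels=ch))
        s_out = _stage_tail(nodes, prefix, i, dw, ch, g, spec.use_bn)
        feats.append((s_out, g))
    out = f"{prefix}out_cat"
    nodes.append(GraphNode(out, "concat", tuple(f for f, _ in feats),
                           in_channels=c0 + L * g, out_channels=c0 + L * g))
    if spec.reduce:
        nodes.append(GraphNode(f"{prefix}out_pool", "avg_pool2x2", (out,),
                               in_channels=c0 + L * g, out_channels=c0 + L * g))
        out = f"{prefix}out_pool"
    return out


def add_dense_mobile_custom(
    nodes: List[GraphNode], inp: str, prefix: str, spec: BlockSpec
) -> str:
    """Custom block: each channel is depthwise-filtered at most once.

    The depthwise copy of the block-input channels is computed before stage 1
    and each stage's new channels are filtered right after creation (lazily:
    the last stage's outputs feed no pointwise, so they get no depthwise
    node).  Reducing blocks pool the input first, so every convolution runs at
    the reduced resolution.
    """
    c0, g, L = spec.in_channels, spec.growth, spec.depthwise_layers
    if spec.reduce:
        nodes.append(GraphNode(f"{prefix}in_pool", "avg_pool2x2", (inp,),
                               in_channels=c0, out_channels=c0))
        inp = f"{prefix}in_pool"
    dw_in = f"{prefix}dw_in"
    nodes.append(GraphNode(dw_in, "depthwise_conv2d", (inp,), kernel=3, stride=1,
                           in_channels=c0, out_channels=c0))
    bank: List[Tuple[str, int]] = [(dw_in, c0)]
    feats: List[Tuple[str, int]] = [(inp, c0)]
    for i in range(1, L + 1):
        if len(bank) == 1:
            cat = bank[0][0]
        else:
            cat = f"{prefix}s{i}_cat"
            nodes.append(GraphNode(cat, "concat", tuple(f for f, _ in bank),
                                   in_channels=sum(c for _, c in bank),
                                   out_channels=sum(c for _, c in bank)))
        ch = sum(c for _, c in bank)
        s_out = _stage_tail(nodes, prefix, i, cat, ch, g, spec.use_bn)
        feats.append((s_out, g))
        if i < L:
            dw_i = f"{prefix}dw_s{i}"
            nodes.append(GraphNode(dw_i, "depthwise_conv2d", (s_out,), kernel=3,
                                   stride=1, in_channels=g, out_channels=g))
            bank.append((dw_i, g))
    out = f"{prefix}out_cat"
    nodes.append(GraphNode(out, "concat", tuple(f for f, _ in feats),
                           in_channels=c0 + L * g, out_channels=c0 + L * g))
    return out


def add_dense_mobile(nodes: List[GraphNode], inp: str, prefix: str,
                     spec: BlockSpec) -> str:
    if spec.variant == "naive":
        return add_dense_mobile_naive(nodes, inp, prefix, spec)
    return add_dense_mobile_custom(nodes, inp, prefix, spec)


def _fragment(nodes: List[GraphNode], out: str) -> NetworkGraph:
    return NetworkGraph(nodes=nodes, output_nodes=(out,))


def build_separable_conv(in_channels: int, out_channels: int, stride: int = 1,
                         use_bn: bool = True) -> NetworkGraph:
    nodes: List[GraphNode] = []
    out = add_separable_conv(nodes, INPUT_ID, "sep_", in_channels, out_channels,
                             stride, use_bn)
    return _fragment(nodes, out)


def build_dense_mobile_naive(spec: BlockSpec) -> NetworkGraph:
    if spec.variant != "naive":
        raise ValueError("spec.variant must be 'naive'")
    nodes: List[GraphNode] = []
    return _fragment(nodes, add_dense_mobile_naive(nodes, INPUT_ID, "", spec))


def build_dense_mobile_custom(spec: BlockSpec) -> NetworkGraph:
    if spec.variant != "custom":
        raise ValueError("spec.variant must be 'custom'")
    nodes: List[GraphNode] = []
    return _fragment(nodes, add_dense_mobile_custom(nodes, INPUT_ID, "", spec))


# ---------------------------------------------------------------------------
# Kernel tying and audits
# ---------------------------------------------------------------------------

def _naive_stage_dws(graph: NetworkGraph, prefix: str) -> List[GraphNode]:
    nmap = graph.node_map()
    dws = []
    i = 1
    while f"{prefix}s{i}_dw" in nmap:
        node = nmap[f"{prefix}s{i}_dw"]
        if node.kind != "depthwise_conv2d":
            raise ValueError(f"{node.id!r} is not a depthwise node")
        dws.append(node)
        i += 1
    if not dws:
        raise ValueError("graph is not a naive DenseNet-Mobile block "
                         f"(no '{prefix}s1_dw' node)")
    return dws


def tie_depthwise_weights(graph: NetworkGraph, prefix: str = "") -> NetworkGraph:
    """Share each channel's depthwise kernel across all naive-block stages.

    Every stage-i depthwise node (i >= 2) is given ``kernel_sources`` pointing
    at the node where each of its channels is filtered first: block-input
    channels at stage 1, stage-j output channels at stage j+1.  Stage 1 keeps
    its own kernels, so a one-stage block is untouched and re-tying is a
    no-op.  Only graphs built by :func:`build_dense_mobile_naive` qualify.
    """
    dws = _naive_stage_dws(graph, prefix)
    c0 = dws[0].in_channels
    growth = (dws[1].in_channels - c0) if len(dws) > 1 else 0
    replacements = {}
    for i, node in enumerate(dws[1:], start=2):
        sources: List[Tuple[str, int]] = [(f"{prefix}s1_dw", c) for c in range(c0)]
        for j in range(1, i):  # channels contributed by stage j
            owner = f"{prefix}s{j + 1}_dw"
            for t in range(growth):
                sources.append((owner, c0 + (j - 1) * growth + t))
        sources = sources[: node.in_channels]
        # a stage's own new channels are canonical in itself
        replacements[node.id] = replace(node, kernel_sources=tuple(sources))
    new_nodes = [replacements.get(n.id, n) for n in graph.nodes]
    return NetworkGraph(nodes=new_nodes, input_shape=graph.input_shape,
                        output_nodes=graph.output_nodes)


def depthwise_channel_load(graph: NetworkGraph) -> int:
    """Total depthwise filter applications = sum of depthwise input widths.

    In a custom block every channel a pointwise consumes is filtered exactly
    once, so the load equals the number of such distinct channels; the naive
    block re-filters early channels at every later stage.
    """
    return sum(n.in_channels for n in graph.nodes if n.kind == "depthwise_conv2d")
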