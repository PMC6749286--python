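"""Computational-graph description for convolutional networks.

A :class:`NetworkGraph` is an ordered, acyclic list of nodes; every node names
its inputs, which must appear earlier in the list (or be the reserved id
``"input"``).  The module only *describes and audits* structure: it propagates
tensor shapes and counts multiply-accumulate operations (MACs), the
hardware-independent proxy used to compare inference cost between
architectures.  Numeric execution and training live in :mod:`weedseg.engine`.

Conventions
-----------
* Shapes are ``(height, width, channels)``, origin top-left, no fractional
  sizes.
* All spatial convolutions use TensorFlow-style "same" padding, so a stride-1
  conv preserves spatial dims exactly and downsampling happens only through
  stride 2 or 2x2 average pooling; indivisible dims raise :class:`ShapeError`.
* ``upscale2x`` is nearest-neighbour duplication.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "TensorShape",
    "GraphNode",
    "NetworkGraph",
    "GraphError",
    "ShapeError",
    "propagate_shapes",
    "count_macs",
    "graph_to_text",
    "graph_from_text",
    "INPUT_ID",
]

INPUT_ID = "input"

OP_KINDS = (
    "conv2d",
    "depthwise_conv2d",
    "pointwise_conv2d",
    "avg_pool2x2",
    "upscale2x",
    "concat",
    "add",
    "batch_norm",
    "relu",
    "softmax",
)

_CONV_KINDS = ("conv2d", "depthwise_conv2d", "pointwise_conv2d")


class GraphError(ValueError):
    """Structurally invalid graph."""


class ShapeError(GraphError):
    """Shapes do not propagate (e.g. indivisible spatial dims)."""


@dataclass(frozen=True)
class TensorShape:
    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"TensorShape.{name} must be a positive integer, got {v!r}")

    def as_tuple(self) -> Tuple[int, int, int]:
        return (self.height, self.width, self.channels)


@dataclass(frozen=True)
class GraphNode:
    """One operation in the graph.

    ``kernel``/``stride`` apply to conv kinds and pooling only.  For
    ``depthwise_conv2d`` the output width is ``in_channels * depth_multiplier``.
    ``kernel_sources`` (optional, depthwise only) names, per input channel, the
    node and channel index whose depthwise kernel is shared — the mechanism
    behind tied-kernel blocks.
    """

    id: str
    kind: str
    inputs: Tuple[str, ...] = ()
    kernel: int = 3
    stride: int = 1
    in_channels: int = 0
    out_channels: int = 0
    depth_multiplier: int = 1
    kernel_sources: Optional[Tuple[Tuple[str, int], ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in OP_KINDS:
            raise GraphError(f"node {self.id!r}: unknown op kind {self.kind!r}")
        if self.kind in _CONV_KINDS:
            if self.kernel < 1 or self.kernel % 2 == 0:
                raise GraphError(f"node {self.id!r}: kernel must be odd positive, got {self.kernel}")
            if self.stride not in (1, 2):
                raise GraphError(f"node {self.id!r}: stride must be 1 or 2, got {self.stride}")
            if self.kind == "pointwise_conv2d" and self.kernel != 1:
                raise GraphError(f"node {self.id!r}: pointwise conv requires kernel=1")
            if self.kind == "depthwise_conv2d":
                if self.depth_multiplier < 1:
                    raise GraphError(f"node {self.id!r}: depth_multiplier must be >= 1")
                if self.out_channels != self.in_channels * self.depth_multiplier:
                    raise GraphError(
                        f"node {self.id!r}: depthwise out_channels must equal "
                        f"in_channels*depth_multiplier"
                    )


@dataclass
class NetworkGraph:
    """Ordered node list with a designated output set."""

    nodes: List[GraphNode] = field(default_factory=list)
    input_shape: Optional[TensorShape] = None
    output_nodes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = {INPUT_ID}
        for node in self.nodes:
            if node.id in seen:
                raise GraphError(f"duplicate node id {node.id!r}")
            for inp in node.inputs:
                if inp not in seen:
                    raise GraphError(
                        f"node {node.id!r} references {inp!r} before its definition"
                    )
            seen.add(node.id)
        for out in self.output_nodes:
            if out not in seen:
                raise GraphError(f"unknown output node {out!r}")

    def node_map(self) -> Dict[str, GraphNode]:
        return {n.id: n for n in self.nodes}

    def terminal(self) -> GraphNode:
        if not self.output_nodes:
            raise GraphError("graph has no output nodes")
        return self.node_map()[self.output_nodes[-1]]


def _conv_out_hw(h: int, w: int, stride: int, node_id: str) -> Tuple[int, int]:
    if stride == 1:
        return h, w
    if h % stride or w % stride:
        raise ShapeError(
            f"node {node_id!r}: spatial dims {h}x{w} not divisible by stride {stride}"
        )
    return h // stride, w // stride


def propagate_shapes(
    graph: NetworkGraph, input_shape: TensorShape
) -> Dict[str, TensorShape]:
    """Assign a :class:`TensorShape` to every node.

    Deterministic and total on valid graphs; raises :class:`ShapeError` naming
    the offending node otherwise.
    """
    shapes: Dict[str, TensorShape] = {INPUT_ID: input_shape}
    for node in graph.nodes:
        ins = [shapes[i] for i in node.inputs]
        if node.kind in _CONV_KINDS:
            (s,) = ins
            if node.in_channels and s.channels != node.in_channels:
                raise ShapeError(
                    f"node {node.id!r}: expected {node.in_channels} input channels, "
                    f"got {s.channels}"
                )
            h, w = _conv_out_hw(s.height, s.width, node.stride, node.id)
            shapes[node.id] = TensorShape(h, w, node.out_channels)
        elif node.kind == "avg_pool2x2":
            (s,) = ins
            if s.height % 2 or s.width % 2:
                raise ShapeError(
                    f"node {node.id!r}: cannot 2x2-pool odd dims {s.height}x{s.width}"
                )
            shapes[node.id] = TensorShape(s.height // 2, s.width // 2, s.channels)
        elif node.kind == "upscale2x":
            (s,) = ins
            shapes[node.id] = TensorShape(s.height * 2, s.width * 2, s.channels)
        elif node.kind == "concat":
            if not ins:
                raise ShapeError(f"node {node.id!r}: concat needs at least one input")
            hw = {(s.height, s.width) for s in ins}
            if len(hw) != 1:
                raise ShapeError(f"node {node.id!r}: concat inputs disagree spatially: {hw}")
            h, w = next(iter(hw))
            shapes[node.id] = TensorShape(h, w, sum(s.channels for s in ins))
        elif node.kind == "add":
            if len({s.as_tuple() for s in ins}) != 1:
                raise ShapeError(f"node {node.id!r}: add requires identical input shapes")
            shapes[node.id] = ins[0]
        elif node.kind in ("batch_norm", "relu", "softmax"):
            (s,) = ins
            shapes[node.id] = s
        else:  # pragma: no cover - OP_KINDS is closed
            raise GraphError(f"node {node.id!r}: unhandled kind {node.kind!r}")
    return shapes


def node_macs(node: GraphNode, out_shape: TensorShape, in_shape: TensorShape) -> int:
    """MACs attributed to a single node (zero for non-conv kinds)."""
    positions = out_shape.height * out_shape.width
    if node.kind == "conv2d":
        return positions * node.kernel ** 2 * in_shape.channels * node.out_channels
    if node.kind == "depthwise_conv2d":
        return positions * node.kernel ** 2 * in_shape.channels * node.depth_multiplier
    if node.kind == "pointwise_conv2d":
        return positions * in_shape.channels * node.out_channels
    return 0


def count_macs(graph: NetworkGraph, input_shape: TensorShape) -> int:
    """Total multiply-accumulates of one forward pass at ``input_shape``.

    Only convolution kinds contribute; pooling, scaling, concat, add,
    normalisation and activations are counted as free.
    """
    shapes = propagate_shapes(graph, input_shape)
    total = 0
    for node in graph.nodes:
        if node.kind in _CONV_KINDS:
            total += node_macs(node, shapes[node.id], shapes[node.inputs[0]])
    return total


# ---------------------------------------------------------------------------
# Text serialization (one node per line) for golden-file tests and checkpoints
# ---------------------------------------------------------------------------

def graph_to_text(graph: NetworkGraph) -> str:
    lines = []
    if graph.input_shape is not None:
        s = graph.input_shape
        lines.append(f"# input {s.height}x{s.width}x{s.channels}")
    lines.append("# id kind k s in out m <- inputs")
    for n in graph.nodes:
        src = ""
        if n.kernel_sources is not None:
            src = " src=" + ";".join(f"{nid}:{c}" for nid, c in n.kernel_sources)
        lines.append(
            f"{n.id} {n.kind} k={n.kernel} s={n.stride} in={n.in_channels} "
            f"out={n.out_channels} m={n.depth_multiplier}{src} <- {','.join(n.inputs)}"
        )
    lines.append("outputs " + ",".join(graph.output_nodes))
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(
    r"^(?P<id>\S+) (?P<kind>\S+) k=(?P<k>\d+) s=(?P<s>\d+) in=(?P<in>\d+) "
    r"out=(?P<out>\d+) m=(?P<m>\d+)(?: src=(?P<src>\S+))? <- (?P<inputs>.*)$"
)


def graph_from_text(text: str) -> NetworkGraph:
    nodes: List[GraphNode] = []
    outputs: Tuple[str, ...] = ()
    input_shape: Optional[TensorShape] = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# input "):
            h, w, c = (int(v) for v in line[len("# input "):].split("x"))
            input_shape = TensorShape(h, w, c)
            continue
        if line.startswith("#"):
            continue
        if line.startswith("outputs"):
            rest = line[len("outputs"):].strip()
            outputs = tuple(v for v in rest.split(",") if v)
            continue
        m = _NODE_RE.match(line)
        if m is None:
            raise GraphError(f"unparseable graph line: {line!r}")
        sources = None
        if m.group("src"):
            sources = tuple(
                (part.split(":")[0], int(part.split(":")[1]))
                for part in m.group("src").split(";")
            )
        nodes.append(
            GraphNode(
                id=m.group("id"),
                kind=m.group("kind"),
                inputs=tuple(v for v in m.group("inputs").split(",") if v),
                kernel=int(m.group("k")),
                stride=int(m.group("s")),
                in_channels=int(m.group("in")),
                out_channels=int(m.group("out")),
                depth_multiplier=int(m.group("m")),
                kernel_sources=sources,
            )
        )
    return NetworkGraph(nodes=nodes, input_shape=input_shape, output_nodes=outputs)


def concat_graphs(a: NetworkGraph, b: NetworkGraph) -> NetworkGraph:
    """Append ``b``'s nodes after ``a``'s (ids must not collide); ``b``'s
    references to ``input`` are rewired to ``a``'s terminal node.  Used by the
    MAC-additivity property tests."""
    term = a.output_nodes[-1] if a.output_nodes else INPUT_ID
    rewired = [
        replace(n, inputs=tuple(term if i == INPUT_ID else i for i in n.inputs))
        for n in b.nodes
    ]
    return NetworkGraph(
        nodes=list(a.nodes) + rewired,
        input_shape=a.input_shape,
        output_nodes=b.output_nodes,
    )
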