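"""Shared independent oracles and helpers for the test suite.

Everything here is deliberately naive (python loops, explicit counting) so it
cannot share a bug with the vectorised implementations it checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from weedseg import engine
from weedseg.blocks import (
    BlockSpec,
    build_dense_mobile_custom,
    build_dense_mobile_naive,
    tie_depthwise_weights,
)
from weedseg.metrics import CLASSES, IGNORE

# ---------------------------------------------------------------------------
# Brute-force metrics by per-pixel set enumeration
# ---------------------------------------------------------------------------

def brute_force_metrics(preds, labels, absent_class="one") -> Dict[str, float]:
    dice_terms: List[float] = []
    n_ew = n_pw = n_ew_pw = n_ec = n_ec_pw = 0
    for p, e in zip(preds, labels):
        p = np.asarray(p)
        e = np.asarray(e)
        for c in CLASSES:
            n_e = n_p = n_both = 0
            for r in range(e.shape[0]):
                for col in range(e.shape[1]):
                    if e[r, col] == IGNORE:
                        continue
                    in_e = e[r, col] == c
                    in_p = p[r, col] == c
                    n_e += in_e
                    n_p += in_p
                    n_both += in_e and in_p
            if n_e + n_p == 0:
                if absent_class == "one":
                    dice_terms.append(1.0)
            else:
                dice_terms.append(2.0 * n_both / (n_e + n_p))
        for r in range(e.shape[0]):
            for col in range(e.shape[1]):
                if e[r, col] == IGNORE:
                    continue
                ew = e[r, col] == 2
                pw = p[r, col] == 2
                ec = e[r, col] == 1
                n_ew += ew
                n_pw += pw
                n_ew_pw += ew and pw
                n_ec += ec
                n_ec_pw += ec and pw
    return {
        "e_dice": 100.0 * (1.0 - sum(dice_terms) / len(dice_terms)),
        "r_weed": 100.0 * n_ew_pw / n_ew if n_ew else float("nan"),
        "p_weed": 100.0 * n_ew_pw / n_pw if n_pw else float("nan"),
        "m_crop_as_weed": 100.0 * n_ec_pw / n_ec if n_ec else float("nan"),
    }


# ---------------------------------------------------------------------------
# Brute-force MAC counting: run the convolution arithmetic with explicit
# loops, incrementing a counter once per scalar multiply-accumulate
# ---------------------------------------------------------------------------

def counted_execution_macs(graph, input_shape) -> int:
    """Execute conv nodes of a (small!) graph with loops, counting MACs."""
    from weedseg.netgraph import propagate_shapes

    shapes = propagate_shapes(graph, input_shape)
    count = 0
    for node in graph.nodes:
        out = shapes[node.id]
        cin = shapes[node.inputs[0]].channels if node.inputs else 0
        if node.kind == "conv2d":
            for _pos in range(out.height * out.width):
                for _tap in range(node.kernel ** 2):
                    for _ci in range(cin):
                        for _co in range(node.out_channels):
                            count += 1
        elif node.kind == "depthwise_conv2d":
            for _pos in range(out.height * out.width):
                for _tap in range(node.kernel ** 2):
                    for _ci in range(cin):
                        for _m in range(node.depth_multiplier):
                            count += 1
        elif node.kind == "pointwise_conv2d":
            for _pos in range(out.height * out.width):
                for _ci in range(cin):
                    for _co in range(node.out_channels):
                        count += 1
    return count


# ---------------------------------------------------------------------------
# Naive(tied) vs custom block pairs with matched weights
# ---------------------------------------------------------------------------

def matched_block_pair(c0: int, growth: int, layers: int, seed: int,
                       use_bn: bool = True):
    """Build a tied naive block and a custom block with identical parameters.

    Returns ``(naive_graph, naive_weights, naive_buffers, custom_graph,
    custom_weights, custom_buffers)``; the pointwise/BN parameters are shared
    and the custom depthwise kernels are the canonical slices of the tied
    naive kernels, so the two blocks should compute the same function.
    """
    rng = np.random.default_rng(seed)
    gn = tie_depthwise_weights(build_dense_mobile_naive(
        BlockSpec(c0, growth, layers, variant="naive", use_bn=use_bn)))
    gc = build_dense_mobile_custom(
        BlockSpec(c0, growth, layers, variant="custom", use_bn=use_bn))
    wn, bn = engine.init_weights(gn, seed)
    for k in wn:
        wn[k] = rng.normal(0, 0.5, wn[k].shape).astype(np.float32)
    for k in bn:
        if k.endswith(".var"):
            bn[k] = (np.abs(rng.normal(size=bn[k].shape)) + 0.5).astype(np.float32)
        else:
            bn[k] = rng.normal(size=bn[k].shape).astype(np.float32)
    wc, bc = engine.init_weights(gc, seed + 1)
    wc["dw_in.W"] = wn["s1_dw.W"][:, :, :c0, :]
    for j in range(1, layers):
        wc[f"dw_s{j}.W"] = wn[f"s{j+1}_dw.W"][:, :, c0 + (j - 1) * growth : c0 + j * growth, :]
    for i in range(1, layers + 1):
        wc[f"s{i}_pw.W"] = wn[f"s{i}_pw.W"]
        wc[f"s{i}_pw.b"] = wn[f"s{i}_pw.b"]
        if use_bn:
            wc[f"s{i}_bn.gamma"] = wn[f"s{i}_bn.gamma"]
            wc[f"s{i}_bn.beta"] = wn[f"s{i}_bn.beta"]
            bc[f"s{i}_bn.mean"] = bn[f"s{i}_bn.mean"]
            bc[f"s{i}_bn.var"] = bn[f"s{i}_bn.var"]
    return gn, wn, bn, gc, wc, bc


def run_fragment(graph, weights, buffers, x: np.ndarray) -> np.ndarray:
    acts, _ = engine.forward(graph, weights, buffers, x, training=False, keep=False)
    return acts[graph.output_nodes[-1]]
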