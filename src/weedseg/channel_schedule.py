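"""Width-multiplier channel schedules.

The number of channels in every convolutional layer is scaled by a single
width multiplier ``alpha`` (dimensionless, > 0; 1.0 is the unscaled base
network).  Two schedules are supported:

* ``mobilenet`` — the MobileNets rule ``max(1, floor(x * alpha))``, which can
  produce any positive integer width.
* ``mod8`` — a quantised rule ``max(8, 8 * floor(x * alpha / 8))`` that keeps
  every width a positive multiple of 8.  Widths that are multiples of 8 map
  onto efficient tensor kernels on small ARM boards, so inference time becomes
  a monotone function of ``alpha`` instead of jumping around at awkward widths
  such as 15/31/62.

The mobile encoder widths are conventionally written as the triple
``(A, B, C) = (f(16), f(32), f(64))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

__all__ = [
    "AlphaParams",
    "ChannelTriple",
    "f_mobilenet",
    "f_mod8",
    "channel_triple",
    "BASE_TRIPLE",
]

Variant = Literal["mobilenet", "mod8"]

#: Base widths the (A, B, C) triple is derived from.
BASE_TRIPLE = (16, 32, 64)

# Guard against binary floating point landing a hair under an integer for
# alphas given as short decimals (e.g. 10 * 0.7 == 6.999...96).
_FLOOR_FUZZ = 1e-9


@dataclass(frozen=True)
class AlphaParams:
    """Width multiplier plus the schedule used to apply it."""

    alpha: float
    variant: Variant = "mod8"

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha!r}")
        if self.variant not in ("mobilenet", "mod8"):
            raise ValueError(f"unknown channel variant {self.variant!r}")


class ChannelTriple(NamedTuple):
    """Layer widths (A, B, C) derived from bases 16/32/64."""

    A: int
    B: int
    C: int


def _check_args(x: int, alpha: float) -> None:
    if not (isinstance(x, (int,)) and x >= 1):
        raise ValueError(f"base channel count must be a positive integer, got {x!r}")
    if not (alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha!r}")


def f_mobilenet(x: int, alpha: float) -> int:
    """MobileNets width rule: ``max(1, floor(x * alpha))``.

    Monotone non-decreasing in both arguments; never returns less than one
    channel.
    """
    _check_args(x, alpha)
    return max(1, math.floor(x * alpha + _FLOOR_FUZZ))


def f_mod8(x: int, alpha: float) -> int:
    """Multiple-of-8 width rule: ``max(8, 8 * floor(x * alpha / 8))``.

    The result is always a positive multiple of 8 and equals ``x`` at
    ``alpha == 1`` whenever ``x`` itself is a multiple of 8.
    """
    _check_args(x, alpha)
    return max(8, 8 * math.floor(x * alpha / 8 + _FLOOR_FUZZ))


_SCHEDULES = {"mobilenet": f_mobilenet, "mod8": f_mod8}


def channel_triple(params: AlphaParams) -> ChannelTriple:
    """Apply the selected schedule to the base widths 16, 32 and 64."""
    f = _SCHEDULES[params.variant]
    a, b, c = (f(x, params.alpha) for x in BASE_TRIPLE)
    return ChannelTriple(a, b, c)
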