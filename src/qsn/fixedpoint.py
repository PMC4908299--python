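"""Emulated two's-complement fixed-point arithmetic (Qm.n formats)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FixedPointFormat", "quantize", "FixedPointOverflowError"]


class FixedPointOverflowError(OverflowError):
    pass


@dataclass(frozen=True)
class FixedPointFormat:
    """total_bits two's-complement with frac_bits fractional bits.

    Representable range is [-2^(total-frac-1), 2^(total-frac-1) - 2^-frac].
    `truncate` rounding is two's-complement bit truncation, i.e. floor.
    """

    total_bits: int = 18
    frac_bits: int = 10
    rounding: str = "truncate"
    overflow: str = "saturate"

    def __post_init__(self):
        if not (2 <= self.frac_bits < self.total_bits <= 64):
            raise ValueError("need 2 <= frac_bits < total_bits <= 64")
        if self.rounding not in ("truncate", "nearest"):
            raise ValueError("rounding must be 'truncate' or 'nearest'")
        if self.overflow not in ("saturate", "error"):
            raise ValueError("overflow must be 'saturate' or 'error'")

    @property
    def scale(self) -> float:
        return float(2 ** self.frac_bits)

    @property
    def resolution(self) -> float:
        return 2.0 ** (-self.frac_bits)

    @property
    def max_value(self) -> float:
        return 2.0 ** (self.total_bits - self.frac_bits - 1) - self.resolution

    @property
    def min_value(self) -> float:
        return -(2.0 ** (self.total_bits - self.frac_bits - 1))


def quantize(x, fmt: FixedPointFormat):
    """Nearest representable value per the format's rounding/overflow policy.

    Idempotent and monotone; accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot quantize non-finite values")
    y = arr * fmt.scale
    y = np.floor(y + 0.5) if fmt.rounding == "nearest" else np.floor(y)
    y = y / fmt.scale
    over = (y > fmt.max_value) | (y < fmt.min_value)
    if np.any(over):
        if fmt.overflow == "error":
            raise FixedPointOverflowError(
                f"value outside representable range "
                f"[{fmt.min_value}, {fmt.max_value}]")
        y = np.clip(y, fmt.min_value, fmt.max_value)
    return y if y.ndim else float(y)
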