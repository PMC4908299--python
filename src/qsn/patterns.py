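"""+-1 pixel patterns for the associative-memory experiments.

The stored patterns of the original experiments are only available as
figures, so a seeded generator produces synthetic 16x16 +-1 patterns with a
bounded pairwise overlap as stand-ins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Pattern", "generate_patterns", "flip_pixels",
           "pattern_to_text", "pattern_from_text"]


@dataclass(frozen=True)
class Pattern:
    values: np.ndarray  # +-1 ints, length N
    label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=int)
        if not np.all(np.abs(v) == 1):
            raise ValueError("pattern entries must be +-1")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return self.values.size

    def grid(self) -> np.ndarray:
        side = math.isqrt(self.values.size)
        if side * side != self.values.size:
            raise ValueError("pattern length is not a perfect square")
        return self.values.reshape(side, side)

    def overlap(self, other) -> float:
        """Normalized inner product in [-1, 1]."""
        o = np.asarray(getattr(other, "values", other))
        return float(self.values @ o) / self.values.size


def generate_patterns(N: int = 256, count: int = 4, seed: int = 0,
                      max_pairwise_overlap: float = 0.25,
                      max_tries: int = 10000):
    """Seeded random +-1 patterns with all |pairwise overlap| bounded.

    Patterns are drawn one at a time; a draw that overlaps too strongly
    with any accepted pattern is rejected and redrawn.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Pattern] = []
    tries = 0
    while len(out) < count:
        if tries >= max_tries:
            raise RuntimeError(
                f"rejection budget exceeded after {max_tries} draws")
        tries += 1
        cand = rng.choice((-1, 1), size=N)
        if all(abs(float(cand @ p.values) / N) <= max_pairwise_overlap
               for p in out):
            out.append(Pattern(cand, label=f"pattern-{len(out) + 1}"))
    return out


def flip_pixels(pattern: Pattern, fraction: float, seed: int) -> Pattern:
    """Negate exactly round(fraction*N) distinct pixels, seeded."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    v = pattern.values.copy()
    k = int(round(fraction * v.size))
    idx = np.random.default_rng(seed).choice(v.size, size=k, replace=False)
    v[idx] = -v[idx]
    return Pattern(v, label=pattern.label)


def pattern_to_text(pattern: Pattern) -> str:
    """Grid rendering, '#' for +1 and '.' for -1, one row per line."""
    return "\n".join("".join("#" if x == 1 else "." for x in row)
                     for row in pattern.grid())


def pattern_from_text(text: str, label: str | None = None) -> Pattern:
    rows = [r.strip() for r in text.strip().splitlines() if r.strip()]
    vals = [1 if ch == "#" else -1 if ch == "." else None
            for r in rows for ch in r]
    if any(v is None for v in vals):
        raise ValueError("pattern text may contain only '#' and '.'")
    return Pattern(np.array(vals), label=label)
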