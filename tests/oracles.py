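"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy/scikit-image machinery so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def flood_fill(
    image: np.ndarray,
    seed: tuple[int, int],
    lo: float,
    hi: float,
    allowed: np.ndarray,
) -> set[tuple[int, int]]:
    """Explicit-stack 4-connected flood fill over in-window pixels."""
    n_rows, n_cols = image.shape
    r0, c0 = seed
    if not (allowed[r0, c0] and lo <= image[r0, c0] <= hi):
        return set()
    seen = {(r0, c0)}
    stack = [(r0, c0)]
    while stack:
        r, c = stack.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and (rr, cc) not in seen:
                if allowed[rr, cc] and lo <= image[rr, cc] <= hi:
                    seen.add((rr, cc))
                    stack.append((rr, cc))
    return seen


def disk_pixels(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    """Boolean disk by direct per-pixel distance enumeration."""
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                out[r, c] = True
    return out
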