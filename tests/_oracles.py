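"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: connected
components by breadth-first flood fill over hand-enumerated neighbour
offsets, and Benjamini-Hochberg by direct evaluation of every step-up
cutoff.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    max_l1 = {6: 1, 18: 2, 26: 3}[connectivity]
    return [
        off
        for off in product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0) and sum(abs(o) for o in off) <= max_l1
    ]


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[frozenset]:
    """All connected components of a 3-D boolean field as voxel-coordinate sets."""
    offsets = neighbour_offsets(connectivity)
    shape = binary.shape
    remaining = {tuple(c) for c in np.argwhere(binary)}
    components = []
    while remaining:
        start = remaining.pop()
        queue = deque([start])
        comp = {start}
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offsets:
                n = (i + di, j + dj, k + dk)
                if (
                    0 <= n[0] < shape[0]
                    and 0 <= n[1] < shape[1]
                    and 0 <= n[2] < shape[2]
                    and n in remaining
                ):
                    remaining.remove(n)
                    comp.add(n)
                    queue.append(n)
        components.append(frozenset(comp))
    return components


def bh_stepup_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """BH rejections by explicitly trying every cutoff rank."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    best = -1
    for i in range(m):  # largest i with p_(i) <= (i+1)/m * q
        if sorted_p[i] <= (i + 1) / m * q:
            best = i
    rejected = np.zeros(m, dtype=bool)
    if best >= 0:
        rejected[order[: best + 1]] = True
    return rejected
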