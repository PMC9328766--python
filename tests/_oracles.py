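"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (queue-based flood fill, per-pixel loops)
kept separate from the library so they share no code path with it.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    return offsets


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int, int]]]:
    """All connected components of a 3D boolean array as voxel-coordinate sets."""
    offsets = neighbor_offsets(connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    components: list[set[tuple[int, int, int]]] = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = {start}
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1] and 0 <= nx < mask.shape[2]:
                    if mask[nz, ny, nx] and not seen[nz, ny, nx]:
                        seen[nz, ny, nx] = True
                        comp.add((nz, ny, nx))
                        queue.append((nz, ny, nx))
        components.append(comp)
    return components


def brute_force_segment(
    volume: np.ndarray, threshold: float, min_voxels: int, connectivity: int
) -> np.ndarray:
    """Reference threshold + size filter: strict > threshold, keep size >= min_voxels."""
    fg = volume > threshold
    out = np.zeros_like(fg)
    for comp in flood_fill_components(fg, connectivity):
        if len(comp) >= min_voxels:
            for voxel in comp:
                out[voxel] = True
    return out


def brute_force_max_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel z-maximum via explicit loops."""
    _, ny, nx = stack.shape
    out = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            best = stack[0, y, x]
            for z in range(1, stack.shape[0]):
                if stack[z, y, x] > best:
                    best = stack[z, y, x]
            out[y, x] = best
    return out
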