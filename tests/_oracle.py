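"""Independent breadth-first flood-fill oracle for connectivity claims.

Pure-Python BFS over explicit neighbor offset lists; deliberately shares
no code with the scipy-based implementation it checks.
"""
from collections import deque

import numpy as np


def neighbor_offsets(ndim: int, connectivity: int):
    """Offset list for a named connectivity (4/8 in 2D, 6/18/26 in 3D)."""
    max_nonzero = {
        (2, 4): 1, (2, 8): 2,
        (3, 6): 1, (3, 18): 2, (3, 26): 3,
    }[(ndim, connectivity)]
    offsets = []

    def build(prefix):
        if len(prefix) == ndim:
            nonzero = sum(1 for p in prefix if p != 0)
            if 0 < nonzero <= max_nonzero:
                offsets.append(tuple(prefix))
            return
        for step in (-1, 0, 1):
            build(prefix + [step])

    build([])
    return offsets


def flood_fill(mask: np.ndarray, seed, connectivity: int) -> np.ndarray:
    """Boolean array of voxels reachable from ``seed`` through the mask."""
    mask = np.asarray(mask, dtype=bool)
    seed = tuple(int(c) for c in seed)
    visited = np.zeros(mask.shape, dtype=bool)
    if not mask[seed]:
        return visited
    offsets = neighbor_offsets(mask.ndim, connectivity)
    shape = mask.shape
    queue = deque([seed])
    visited[seed] = True
    while queue:
        voxel = queue.popleft()
        for offset in offsets:
            neighbor = tuple(v + o for v, o in zip(voxel, offset))
            if any(n < 0 or n >= s for n, s in zip(neighbor, shape)):
                continue
            if mask[neighbor] and not visited[neighbor]:
                visited[neighbor] = True
                queue.append(neighbor)
    return visited


def classify_by_flood_fill(mask: np.ndarray, center, connectivity: int):
    """(network, single) partition of the foreground: BFS from the center."""
    mask = np.asarray(mask, dtype=bool)
    network = flood_fill(mask, center, connectivity)
    return network, mask & ~network


def count_components(mask: np.ndarray, connectivity: int) -> int:
    """Number of connected foreground components, by repeated flood fill."""
    mask = np.asarray(mask, dtype=bool)
    remaining = mask.copy()
    n = 0
    while remaining.any():
        seed = tuple(int(c) for c in np.argwhere(remaining)[0])
        filled = flood_fill(remaining, seed, connectivity)
        remaining &= ~filled
        n += 1
    return n
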