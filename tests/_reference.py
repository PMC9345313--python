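"""Exhaustive per-voxel reference implementations used as oracles.

These deliberately avoid scipy/scikit-image machinery: connected
components by breadth-first search over explicit 26-neighbour offsets,
spans and overlaps by direct voxel set arithmetic, and bin assignment
by a literal loop over edges.  They are only feasible on tiny volumes.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_26 = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
]


def bfs_label(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components as sets of voxel index triples."""
    remaining = {tuple(v) for v in np.argwhere(mask)}
    components = []
    while remaining:
        seed = next(iter(remaining))
        remaining.discard(seed)
        comp = {seed}
        frontier = [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in OFFSETS_26:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components


def component_section_span(comp: set[tuple[int, int, int]]) -> int:
    return len({v[0] for v in comp})


def persistence_filter_reference(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    for comp in bfs_label(mask):
        if component_section_span(comp) >= 2:
            for v in comp:
                out[v] = True
    return out


def overlap_fraction_reference(
    comp: set[tuple[int, int, int]], other_mask: np.ndarray
) -> float:
    hits = sum(1 for v in comp if other_mask[v])
    return hits / len(comp)


def bin_assignment_reference(distance: float, edges) -> int:
    """Index of the half-open bin [lo, hi) containing ``distance``;
    -1 when the distance falls outside every bin."""
    for i in range(len(edges) - 1):
        if edges[i] <= distance < edges[i + 1]:
            return i
    return -1


def centroid_reference(comp: set[tuple[int, int, int]]) -> tuple[float, float, float]:
    arr = np.array(sorted(comp), dtype=float)
    return tuple(arr.mean(axis=0))
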