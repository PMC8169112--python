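"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by explicit enumeration (per-pixel
path following, per-permutation refits) and share no code with the library
implementations they check.
"""

from __future__ import annotations

import numpy as np

# Same documented move order as the library: up, down, left, right.
OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def brute_force_ascent_roots(values: np.ndarray, background: np.ndarray) -> dict:
    """Follow each non-background pixel's steepest-ascent path step by step.

    Returns a dict mapping (row, col) -> (row, col) of the terminal local
    peak.  A move is taken only when the best neighbor is strictly larger
    than the current pixel; among equal-valued best neighbors the first in
    the fixed scan order wins.  Background and out-of-bounds neighbors do
    not participate.
    """
    h, w = values.shape
    roots = {}
    for r0 in range(h):
        for c0 in range(w):
            if background[r0, c0]:
                continue
            r, c = r0, c0
            while True:
                best = None
                best_val = -np.inf
                for dr, dc in OFFSETS:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if background[rr, cc]:
                        continue
                    if values[rr, cc] > best_val:
                        best_val = values[rr, cc]
                        best = (rr, cc)
                if best is None or best_val <= values[r, c]:
                    break
                r, c = best
            roots[(r0, c0)] = (r, c)
    return roots


def brute_force_partition(values: np.ndarray, background: np.ndarray) -> set:
    """Clusters as a set of frozensets of pixel coordinates."""
    roots = brute_force_ascent_roots(values, background)
    clusters: dict = {}
    for pix, root in roots.items():
        clusters.setdefault(root, set()).add(pix)
    return {frozenset(v) for v in clusters.values()}


def brute_force_average_cluster_size(values: np.ndarray,
                                     background: np.ndarray) -> float:
    roots = brute_force_ascent_roots(values, background)
    return len(roots) / len(set(roots.values()))


def partition_from_labeling(label_map: np.ndarray) -> set:
    """Convert a label map (−1 = background) to the same set-of-sets form."""
    clusters: dict = {}
    for r, c in zip(*np.nonzero(label_map >= 0)):
        clusters.setdefault(label_map[r, c], set()).add((int(r), int(c)))
    return {frozenset(v) for v in clusters.values()}
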