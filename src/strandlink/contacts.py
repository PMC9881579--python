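"""Heavy-atom distance queries shared by clash screens and packing metrics."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum pairwise distance between two coordinate sets."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.inf
    tree = cKDTree(coords_b)
    d, _ = tree.query(coords_a, k=1)
    return float(d.min())

def count_contacts(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float) -> int:
    """Number of cross pairs within cutoff."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree = cKDTree(coords_b)
    return int(sum(len(x) for x in tree.query_ball_point(coords_a, cutoff)))

def close_pairs(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float):
    """Indices (i, j, d) of cross pairs within cutoff."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree = cKDTree(coords_b)
    out = []
    for i, neigh in enumerate(tree.query_ball_point(coords_a, cutoff)):
        for j in neigh:
            out.append((i, j, float(np.linalg.norm(coords_a[i] - coords_b[j]))))
    return out

def soft_sphere_repulsion(
    coords_a: np.ndarray, coords_b: np.ndarray,
    r_clash: float = 3.2, k: float = 100.0,
) -> float:
    """Quadratic soft-sphere repulsive score sum_k (r_clash - d)^2 over d < r_clash."""
    total = 0.0
    for _, _, d in close_pairs(coords_a, coords_b, r_clash):
        total += k * (r_clash - d) ** 2
    return total
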