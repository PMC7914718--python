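"""Membrane sensing-node geometry.

The cell membrane is sampled by 24 quasi-uniform unit directions: the
vertices of a rhombicuboctahedron projected onto the sphere.  Each octant
of the local frame contains exactly 3 of them, which defines the 8
contact "faces" of the cell: when another cell touches, the nearest
octant face loses its capacity to interact with the matrix.
"""

from __future__ import annotations

import itertools

import numpy as np

_PHI = 1.0 + np.sqrt(2.0)


def membrane_directions() -> np.ndarray:
    """Return the (24, 3) array of outward unit direction vectors.

    Vertices are all coordinate permutations of (+-1, +-1, +-(1+sqrt 2)),
    normalized.  Ordering is deterministic (sorted lexicographically).
    """
    verts = set()
    for perm in itertools.permutations((1.0, 1.0, _PHI)):
        for signs in itertools.product((-1.0, 1.0), repeat=3):
            verts.add(tuple(s * v for s, v in zip(signs, perm)))
    arr = np.array(sorted(verts))
    assert arr.shape == (24, 3)
    return arr / np.linalg.norm(arr, axis=1, keepdims=True)


#: Module-level constant: the 24 outward unit normals.
DIRECTIONS = membrane_directions()

#: Octant index (0..7) of each membrane node, from the sign pattern
#: (sx, sy, sz) -> 4*(sx>0) + 2*(sy>0) + (sz>0).
OCTANTS = (4 * (DIRECTIONS[:, 0] > 0).astype(int)
           + 2 * (DIRECTIONS[:, 1] > 0).astype(int)
           + (DIRECTIONS[:, 2] > 0).astype(int))


def octant_of(direction: np.ndarray) -> int:
    """Octant face index a given direction points into (ties go positive)."""
    d = np.asarray(direction, dtype=float)
    return int(4 * (d[0] >= 0) + 2 * (d[1] >= 0) + (d[2] >= 0))


def active_mask(blocked_octants) -> np.ndarray:
    """Boolean (24,) mask of nodes not belonging to any blocked octant face."""
    mask = np.ones(len(DIRECTIONS), dtype=bool)
    for o in blocked_octants:
        mask &= OCTANTS != o
    return mask


def max_angular_gap_deg() -> float:
    """Largest nearest-neighbour angular gap of the direction set, degrees."""
    cos = DIRECTIONS @ DIRECTIONS.T
    np.fill_diagonal(cos, -1.0)
    nearest = np.clip(cos.max(axis=1), -1.0, 1.0)
    return float(np.degrees(np.arccos(nearest)).max())
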