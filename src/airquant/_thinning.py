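"""Topology-preserving 3D thinning (sequential, distance-ordered).

Homotopic thinning for a 26-connected foreground over a 6-connected
background: border voxels are deleted one at a time, in increasing order of
the Euclidean distance transform (so the surviving curve stays medial),
and only when deletion provably preserves topology — the voxel must be a
*simple point* in the Bertrand-Malandain sense:

* exactly one 26-connected component of foreground in the 26-neighbourhood,
* exactly one 6-connected component of background in the 18-neighbourhood
  that is 6-adjacent to the centre.

Curve endpoints (voxels with a single foreground neighbour) are preserved,
so tubes reduce to their centrelines. Sequential deletion (re-checking the
neighbourhood at deletion time) makes total erasure impossible and the
result independent of any parallel-update schedule; ties in distance are
broken by flat voxel index for determinism.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = ["thin_3d"]

# 26-neighbourhood offsets (fixed order)
_N26 = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int8,
)
# indices into the 3x3x3 cube (flattened, centre=13)
_CUBE_OFF = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
    dtype=np.int8,
)
_IS_N18 = np.array([int(abs(o[0]) + abs(o[1]) + abs(o[2]) <= 2) for o in _CUBE_OFF], dtype=np.uint8)
_IS_N6 = np.array([int(abs(o[0]) + abs(o[1]) + abs(o[2]) == 1) for o in _CUBE_OFF], dtype=np.uint8)

# 26-adjacency between cube positions, and 6-adjacency, precomputed
_ADJ26 = np.zeros((27, 27), dtype=np.uint8)
_ADJ6 = np.zeros((27, 27), dtype=np.uint8)
for _i in range(27):
    for _j in range(27):
        d = np.abs(_CUBE_OFF[_i].astype(int) - _CUBE_OFF[_j].astype(int))
        if _i != _j and d.max() <= 1:
            _ADJ26[_i, _j] = 1
            if d.sum() == 1:
                _ADJ6[_i, _j] = 1


@njit(cache=True)
def _is_simple(cube: np.ndarray, adj26: np.ndarray, adj6: np.ndarray,
               is_n18: np.ndarray, is_n6: np.ndarray) -> bool:
    """Simple-point test on a flattened 3x3x3 neighbourhood (centre=13)."""
    # --- foreground: one 26-component in N26 (centre excluded) ---
    comp = np.full(27, -1, dtype=np.int8)
    n_fg = 0
    stack = np.empty(27, dtype=np.int8)
    for i in range(27):
        if i == 13 or cube[i] == 0 or comp[i] >= 0:
            continue
        n_fg += 1
        if n_fg > 1:
            return False
        top = 0
        stack[top] = i
        top += 1
        comp[i] = 0
        while top > 0:
            top -= 1
            u = stack[top]
            for v in range(27):
                if v != 13 and cube[v] == 1 and comp[v] < 0 and adj26[u, v] == 1:
                    comp[v] = 0
                    stack[top] = v
                    top += 1
    if n_fg != 1:
        return False
    # --- background: one 6-component in N18, 6-adjacent to centre ---
    comp_b = np.full(27, -1, dtype=np.int8)
    n_bg = 0
    for i in range(27):
        if i == 13 or is_n18[i] == 0 or cube[i] == 1 or comp_b[i] >= 0:
            continue
        if is_n6[i] == 0:
            continue  # seed components only from face neighbours
        n_bg += 1
        if n_bg > 1:
            return False
        top = 0
        stack[top] = i
        top += 1
        comp_b[i] = 0
        while top > 0:
            top -= 1
            u = stack[top]
            for v in range(27):
                if v != 13 and is_n18[v] == 1 and cube[v] == 0 and comp_b[v] < 0 and adj6[u, v] == 1:
                    comp_b[v] = 0
                    stack[top] = v
                    top += 1
    if n_bg != 1:
        return False
    # every background face-neighbour must belong to the one component
    for i in range(27):
        if is_n6[i] == 1 and cube[i] == 0 and comp_b[i] < 0:
            return False
    return True


@njit(cache=True)
def _thin_pass(obj: np.ndarray, candidates: np.ndarray,
               adj26: np.ndarray, adj6: np.ndarray,
               is_n18: np.ndarray, is_n6: np.ndarray) -> int:
    """Attempt sequential deletion of candidate voxels; return count."""
    nx, ny, nz = obj.shape
    cube = np.empty(27, dtype=np.uint8)
    n_deleted = 0
    for c in range(candidates.shape[0]):
        x, y, z = candidates[c, 0], candidates[c, 1], candidates[c, 2]
        if obj[x, y, z] == 0:
            continue
        # gather neighbourhood and count foreground neighbours
        k = 0
        n_nb = 0
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        cube[k] = obj[xx, yy, zz]
                    else:
                        cube[k] = 0
                    if cube[k] == 1 and k != 13:
                        n_nb += 1
                    k += 1
        if n_nb <= 1:
            continue  # endpoint (or isolated): preserve
        if _is_simple(cube, adj26, adj6, is_n18, is_n6):
            obj[x, y, z] = 0
            n_deleted += 1
    return n_deleted


def thin_3d(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Thin a 3D binary mask to a one-voxel-wide homotopic centreline.

    ``spacing`` weights the distance transform that orders deletions, so
    anisotropic grids still thin towards the medial axis in world mm.
    """
    obj = np.ascontiguousarray(mask.astype(np.uint8))
    if obj.ndim != 3:
        raise ValueError("thin_3d expects a 3D array")
    dt = ndimage.distance_transform_edt(obj, sampling=spacing)
    while True:
        border = obj.astype(bool) & ~ndimage.binary_erosion(
            obj.astype(bool), structure=ndimage.generate_binary_structure(3, 1)
        )
        cand = np.argwhere(border)
        if cand.size == 0:
            break
        d = dt[tuple(cand.T)]
        flat = np.ravel_multi_index(cand.T, obj.shape)
        order = np.lexsort((flat, d))
        cand = np.ascontiguousarray(cand[order])
        n = _thin_pass(obj, cand, _ADJ26, _ADJ6, _IS_N18, _IS_N6)
        if n == 0:
            break
    return obj.astype(bool)
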