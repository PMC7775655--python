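"""Independent brute-force oracles for the texture-matrix families.

Deliberately naive pure-Python loop implementations, kept separate from the
package so they share no code path with what they check. All operate on a
level grid (0 = outside mask, 1..Ng inside) and enumerate voxels/pairs
exhaustively.
"""

from __future__ import annotations

import numpy as np


def bf_glcm(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence counts by enumerating every voxel pair."""
    P = np.zeros((n_levels, n_levels))
    dx, dy, dz = direction
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                X, Y, Z = x + dx, y + dy, z + dz
                if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                    j = levels[X, Y, Z]
                    if j > 0:
                        P[i - 1, j - 1] += 1
                        P[j - 1, i - 1] += 1
    return P


def bf_ngtdm(levels: np.ndarray, n_levels: int):
    """(s, n) arrays by enumerating each voxel's 26-neighborhood."""
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                nbrs = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            X, Y, Z = x + dx, y + dy, z + dz
                            if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz \
                                    and levels[X, Y, Z] > 0:
                                nbrs.append(levels[X, Y, Z])
                if nbrs:
                    s[i - 1] += abs(i - sum(nbrs) / len(nbrs))
                    n[i - 1] += 1
    return s, n


def bf_glrlm(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts by walking every line of the grid in ``direction``."""
    nx, ny, nz = levels.shape
    rmax = max(levels.shape)
    P = np.zeros((n_levels, rmax))
    d = np.asarray(direction)
    starts = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                prev = np.array([x, y, z]) - d
                if not (0 <= prev[0] < nx and 0 <= prev[1] < ny and 0 <= prev[2] < nz):
                    starts.append((x, y, z))
    for sx, sy, sz in starts:
        line = []
        x, y, z = sx, sy, sz
        while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
            line.append(levels[x, y, z])
            x, y, z = x + d[0], y + d[1], z + d[2]
        run_val, run_len = None, 0
        for v in line + [None]:
            if v == run_val:
                run_len += 1
            else:
                if run_val not in (None, 0):
                    P[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, 1
    return P


def bf_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts by flood-filling 26-connected equal-level components."""
    nx, ny, nz = levels.shape
    visited = np.zeros_like(levels, dtype=bool)
    P = np.zeros((n_levels, int((levels > 0).sum())))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] == 0 or visited[x, y, z]:
                    continue
                lev = levels[x, y, z]
                stack, size = [(x, y, z)], 0
                visited[x, y, z] = True
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                X, Y, Z = cx + dx, cy + dy, cz + dz
                                if (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz
                                        and not visited[X, Y, Z]
                                        and levels[X, Y, Z] == lev):
                                    visited[X, Y, Z] = True
                                    stack.append((X, Y, Z))
                P[lev - 1, size - 1] += 1
    return P


def bf_gldm(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts by enumerating each voxel's 26-neighborhood."""
    nx, ny, nz = levels.shape
    P = np.zeros((n_levels, 27))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                dep = 0
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            X, Y, Z = x + dx, y + dy, z + dz
                            if (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz
                                    and levels[X, Y, Z] > 0
                                    and abs(int(levels[X, Y, Z]) - int(i)) <= alpha):
                                dep += 1
                P[i - 1, dep] += 1
    return P
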