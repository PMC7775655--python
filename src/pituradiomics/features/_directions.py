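"""Shared 3D neighborhood geometry for the texture-matrix families."""

from __future__ import annotations

import numpy as np


def unique_directions() -> list[tuple[int, int, int]]:
    """The 13 unique distance-1 3D directions (one of each ± pair)."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                first = next(v for v in d if v != 0)
                if first > 0:
                    dirs.append(d)
    assert len(dirs) == 13
    return dirs


DIRECTIONS_13 = unique_directions()

#: all 26 neighbor offsets
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Aligned views ``(center, neighbor)`` of ``arr`` under ``offset``.

    Both views have the same shape; ``neighbor[i] = arr[i + offset]`` for
    every index ``i`` where that is inside the grid.
    """
    sl_c, sl_n = [], []
    for o, n in zip(offset, arr.shape):
        if o >= 0:
            sl_c.append(slice(0, n - o))
            sl_n.append(slice(o, n))
        else:
            sl_c.append(slice(-o, n))
            sl_n.append(slice(0, n + o))
    return arr[tuple(sl_c)], arr[tuple(sl_n)]
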