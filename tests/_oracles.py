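"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> list:
    """Brute-force 3-D component extraction by BFS; returns voxel-index sets."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = set()
    comps = []
    coords = list(map(tuple, np.argwhere(mask)))
    coord_set = set(coords)
    for start in coords:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            i, j, k = queue.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in coord_set and nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        seen |= comp
        comps.append(comp)
    return comps
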