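"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the algorithms used by the package: cluster
labelling is union-find over explicitly enumerated neighbour pairs,
local thickness is an exhaustive largest-covering-inscribed-sphere search
over all candidate centres, and the connectivity index is evaluated
directly from the oracle's own component sizes.
"""

from __future__ import annotations

import numpy as np

# the 9 half-offsets of the 18-neighbourhood (faces + edges)
HALF_OFFSETS_18 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
]


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def label_clusters_oracle(mask: np.ndarray):
    """18-connected component sizes by union-find over neighbour pairs."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    n = coords.shape[0]
    if n == 0:
        return []
    index = -np.ones(mask.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    uf = _UnionFind(n)
    shape = np.array(mask.shape)
    for off in HALF_OFFSETS_18:
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_idx = index[tuple(nb[ok].T)]
        src = np.arange(n)[ok]
        for a, b in zip(src[nb_idx >= 0], nb_idx[nb_idx >= 0]):
            uf.union(int(a), int(b))
    roots = {}
    for i in range(n):
        r = uf.find(i)
        roots[r] = roots.get(r, 0) + 1
    return sorted(roots.values(), reverse=True)


def gamma_oracle(mask: np.ndarray) -> float:
    """Direct evaluation of the connectivity index from oracle components."""
    sizes = label_clusters_oracle(mask)
    total = sum(sizes)
    if total == 0:
        return float("nan")
    return sum(s * s for s in sizes) / total**2


def local_thickness_oracle(mask: np.ndarray) -> np.ndarray:
    """Exhaustive largest-covering-inscribed-sphere search (voxel units).

    For every pore voxel v: 2 * max{ r(c) : ||v − c|| < r(c) } over pore
    centres c, where r(c) is the distance from c to the nearest background
    voxel (the image border counts as background).
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    pore = np.argwhere(padded).astype(float)
    bg = np.argwhere(~padded).astype(float)
    out = np.zeros(padded.shape)
    if pore.size == 0:
        return out[1:-1, 1:-1, 1:-1]
    # radius of the maximal ball centred at each pore voxel
    r = np.empty(pore.shape[0])
    chunk = 2000
    for i in range(0, pore.shape[0], chunk):
        d2 = ((pore[i : i + chunk, None, :] - bg[None, :, :]) ** 2).sum(-1)
        r[i : i + chunk] = np.sqrt(d2.min(axis=1))
    values = np.zeros(pore.shape[0])
    for i in range(0, pore.shape[0], chunk):
        d2 = ((pore[i : i + chunk, None, :] - pore[None, :, :]) ** 2).sum(-1)
        covered = d2 < (r[None, :] ** 2) - 1e-9
        masked = np.where(covered, r[None, :], 0.0)
        values[i : i + chunk] = 2.0 * masked.max(axis=1)
    out[tuple(np.argwhere(padded).T)] = values
    return out[1:-1, 1:-1, 1:-1]
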