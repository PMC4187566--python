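"""Voxel-skeleton graph utilities shared by entrance detection and airway
segmentation: 26-connected adjacency over a skeletonized lumen, spur pruning,
rooted traversal, and junction-based generation numbering."""

from __future__ import annotations

import numpy as np

_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)
_STEP = np.linalg.norm(_OFFSETS, axis=1)


class SkeletonGraph:
    """A 26-connected graph over skeleton voxels.

    ``coords`` is (N, 3) voxel indices; adjacency is kept as flat arrays
    (neighbor indices + edge lengths in voxels) for speed.
    """

    def __init__(self, coords: np.ndarray, shape: tuple[int, int, int]):
        self.coords = np.asarray(coords, dtype=np.int64)
        self.shape = shape
        self._index = {}
        flat = np.ravel_multi_index(self.coords.T, shape)
        self._flat = flat
        self._lookup = dict(zip(flat.tolist(), range(len(flat))))
        nbrs: list[list[int]] = [[] for _ in range(len(flat))]
        lens: list[list[float]] = [[] for _ in range(len(flat))]
        for o, step in zip(_OFFSETS, _STEP):
            shifted = self.coords + o
            ok = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
            sf = np.ravel_multi_index(shifted[ok].T, shape)
            idx_ok = np.nonzero(ok)[0]
            for i, f in zip(idx_ok.tolist(), sf.tolist()):
                j = self._lookup.get(f)
                if j is not None:
                    nbrs[i].append(j)
                    lens[i].append(step)
        self.neighbors = [np.array(n, dtype=np.int64) for n in nbrs]
        self.edge_len = [np.array(l) for l in lens]

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors])

    def subgraph(self, keep: np.ndarray) -> "SkeletonGraph":
        return SkeletonGraph(self.coords[keep], self.shape)


def skeleton_graph(skel: np.ndarray) -> SkeletonGraph:
    coords = np.argwhere(skel)
    return SkeletonGraph(coords, skel.shape)


def prune_spurs(g: SkeletonGraph, min_len_vox: float, passes: int = 1) -> SkeletonGraph:
    """Remove leaf chains shorter than ``min_len_vox`` (arc length from the
    leaf to the nearest junction). Keeps isolated chains (whole components
    with no junction) intact. A single pass by default: alveolated airways
    carry a dense series of short side spurs, and repeated pruning would eat
    its way down the duct one inter-spur section per pass."""
    for _ in range(passes):
        deg = g.degrees
        junctions = deg >= 3
        if not junctions.any():
            return g
        remove = np.zeros(len(g), dtype=bool)
        for leaf in np.nonzero(deg == 1)[0]:
            chain = [leaf]
            length = 0.0
            prev, cur = -1, leaf
            ok = False
            while length < min_len_vox:
                nxt = [
                    (j, l)
                    for j, l in zip(g.neighbors[cur], g.edge_len[cur])
                    if j != prev
                ]
                if len(nxt) == 0:
                    break  # isolated chain end
                if len(nxt) > 1 or junctions[cur]:
                    ok = True  # reached a junction within min_len
                    break
                j, l = nxt[0]
                length += l
                prev, cur = cur, j
                if junctions[cur]:
                    ok = True
                    break
                chain.append(cur)
            if ok and length < min_len_vox:
                remove[chain] = True
        if not remove.any():
            return g
        g = g.subgraph(~remove)
    return g


def bfs_tree(g: SkeletonGraph, root: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Breadth-first spanning tree: (parent index, arc distance from root in
    voxels, visit order). Unreached nodes keep parent -2."""
    n = len(g)
    parent = np.full(n, -2, dtype=np.int64)
    dist = np.full(n, np.inf)
    parent[root] = -1
    dist[root] = 0.0
    order = [root]
    head = 0
    while head < len(order):
        u = order[head]
        head += 1
        for v, l in zip(g.neighbors[u], g.edge_len[u]):
            if parent[v] == -2:
                parent[v] = u
                dist[v] = dist[u] + l
                order.append(v)
    return parent, dist, np.array(order, dtype=np.int64)


def tree_children(parent: np.ndarray) -> list[list[int]]:
    ch: list[list[int]] = [[] for _ in range(len(parent))]
    for v, p in enumerate(parent):
        if p >= 0:
            ch[p].append(v)
    return ch


def root_to_leaf_paths(parent: np.ndarray) -> list[np.ndarray]:
    """All root→leaf node-index paths of a BFS tree."""
    ch = tree_children(parent)
    leaves = [
        v for v in range(len(parent)) if parent[v] != -2 and not ch[v]
    ]
    paths = []
    for leaf in leaves:
        path = [leaf]
        while parent[path[-1]] >= 0:
            path.append(int(parent[path[-1]]))
        paths.append(np.array(path[::-1], dtype=np.int64))
    return paths


def junction_generations(
    g: SkeletonGraph, parent: np.ndarray, order: np.ndarray
) -> np.ndarray:
    """Generation index per node: the number of branching vertices (tree
    degree >= 3) passed on the way from the root, the root edge being
    generation 0."""
    ch = tree_children(parent)
    gen = np.zeros(len(g), dtype=np.int64)
    for u in order:
        p = parent[u]
        if p < 0:
            gen[u] = 0
            continue
        gen[u] = gen[p] + (1 if len(ch[p]) >= 2 else 0)
    return gen


def select_root(
    g: SkeletonGraph, radius_vox: np.ndarray, z_max: int, face_margin: int = 3
) -> int:
    """Deterministic root: the largest-lumen-radius skeleton node near either
    z extreme of the skeleton — the lobar bronchus enters the volume along z.
    Thinning retracts the skeleton from an open tube end by about one tube
    radius, so the search band scales with the largest radius present (and
    is anchored to the skeleton itself, not the faces)."""
    z = g.coords[:, 0]
    band = max(face_margin, int(np.ceil(float(np.max(radius_vox)))) + 4)
    near = np.nonzero((z <= z.min() + band) | (z >= z.max() - band))[0]
    if len(near):
        return int(near[np.argmax(radius_vox[near])])
    return int(np.argmax(radius_vox))
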