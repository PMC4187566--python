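"""Conducting-airway segmentation behind segmentation stoppers.

To visualize and analyze the conducting airway tree separately from the
gas-exchange region, spherical segmentation stoppers are placed at the
acinar entrances; a gray-level threshold region growing from seed points
inside the conducting airways then floods the lumen but cannot pass the
stoppers, so the acini stay excluded. Growing runs on a downsampled grid
(factor 2 by default) to bound memory, the skeleton of the grown mask is
numbered by intralobar generation (root edge 0, +1 at every branching
vertex), and each entrance is annotated with the generation of its feeding
conducting airway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from ._skeleton import (
    bfs_tree,
    junction_generations,
    prune_spurs,
    select_root,
    skeleton_graph,
)
from .detect import AcinarEntrance
from .imaging import ImageStack

__all__ = [
    "StopperSet",
    "AirwaySegmentation",
    "place_stoppers",
    "region_grow",
    "assign_generations",
    "entrance_generations",
    "upsample_mask",
    "lumen_radius_map",
]


@dataclass
class StopperSet:
    """Spherical blockers at acinar entrances.

    ``spheres`` holds (center voxel (z, y, x), radius µm) pairs in native
    stack coordinates; ``source_labels`` the entrance labels they came from.
    """

    spheres: list[tuple[tuple[int, int, int], float]]
    source_labels: list[str]

    def __len__(self) -> int:
        return len(self.spheres)


@dataclass
class AirwaySegmentation:
    """Region-growing result on the (possibly downsampled) grid."""

    conducting_mask: np.ndarray  # bool, at downsampled resolution
    downsample_factor: int
    voxel_size: float  # native voxel size, µm
    seeds: list[tuple[int, int, int]]  # native coordinates
    stoppers: Optional[StopperSet] = None
    skeleton: Optional[nx.Graph] = None
    node_generation: Optional[np.ndarray] = None
    skeleton_coords: Optional[np.ndarray] = None  # downsampled coordinates

    @property
    def ds_voxel_size(self) -> float:
        return self.voxel_size * self.downsample_factor


def lumen_radius_map(
    stack: ImageStack, threshold: float
) -> np.ndarray:
    """Distance (µm) from each air voxel to the nearest tissue voxel: the
    local lumen radius along centerlines."""
    air = stack.voxels < threshold
    return ndi.distance_transform_edt(air) * stack.voxel_size


def place_stoppers(
    entrances: Sequence[Union[AcinarEntrance, tuple]],
    radius_map: np.ndarray,
    radius_factor: float = 1.5,
) -> StopperSet:
    """One stopper sphere per entrance, radius = ``radius_factor`` times the
    local lumen radius (which guarantees the sphere covers the full lumen
    cross-section at the entrance).

    ``radius_map`` is the air-distance map in µm (`lumen_radius_map`).
    Entrances lying outside the air phase are rejected by label.
    """
    if radius_factor < 1.0:
        raise ValueError("radius_factor must be >= 1 to occlude the lumen")
    spheres = []
    labels = []
    shape = radius_map.shape
    for k, e in enumerate(entrances):
        if isinstance(e, AcinarEntrance):
            pos, label = tuple(e.position), e.label
        else:
            pos, label = tuple(e), f"E{k + 1:04d}"
        if radius_map[pos] <= 0:
            raise ValueError(
                f"entrance {label} at {pos} lies outside the air phase"
            )
        # an entrance marked one voxel off the centerline would read an
        # undersized radius; take the largest radius in the immediate
        # neighborhood while keeping the marked center
        sl = tuple(
            slice(max(c - 1, 0), min(c + 2, dim)) for c, dim in zip(pos, shape)
        )
        r_local = float(radius_map[sl].max())
        spheres.append((pos, radius_factor * r_local))
        labels.append(label)
    return StopperSet(spheres=spheres, source_labels=labels)


def _downsample_min(vox: np.ndarray, f: int) -> np.ndarray:
    """Air-preserving downsampling: block minimum. Any native air voxel in a
    block keeps the block dark, so lumina are never pinched shut; conducting
    walls (several native voxels thick) survive, thin alveolar septa may
    not — behind the stoppers that cannot cause leaks into the acini."""
    nz, ny, nx_ = (s // f for s in vox.shape)
    c = vox[: nz * f, : ny * f, : nx_ * f]
    return c.reshape(nz, f, ny, f, nx_, f).min(axis=(1, 3, 5))


def _stopper_block(
    shape: tuple[int, int, int],
    stoppers: StopperSet,
    voxel_size: float,
    f: int,
) -> np.ndarray:
    """Voxels (downsampled grid) blocked by stopper spheres; conservative
    rasterization (any voxel whose center lies within radius + half a voxel
    diagonal is blocked)."""
    blocked = np.zeros(shape, dtype=bool)
    ds_size = voxel_size * f
    # center-rounding margin; the 1.5x radius factor supplies the
    # cross-section safety margin itself
    pad = 0.35 * ds_size
    for (cz, cy, cx), r_um in stoppers.spheres:
        c = np.array([cz, cy, cx]) / f
        r_vox = (r_um + pad) / ds_size
        lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, shape)
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        blocked[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= r_vox**2
    return blocked


def region_grow(
    stack: ImageStack,
    seeds: Sequence[tuple[int, int, int]],
    gray_threshold: float,
    stoppers: Optional[StopperSet] = None,
    downsample_factor: int = 2,
) -> AirwaySegmentation:
    """Gray-level threshold region growing from seeds, blocked by stoppers.

    6-connected flood over voxels darker than ``gray_threshold`` on the
    grid downsampled by ``downsample_factor``; the grown set never enters a
    stopper sphere (asserted by construction). Seeds must be air voxels and
    must not lie inside a stopper.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    f = downsample_factor
    seeds = [tuple(int(c) for c in s) for s in seeds]
    for s in seeds:
        if stack.voxels[s] >= gray_threshold:
            raise ValueError(f"seed {s} is not an air voxel below the threshold")
    ds = _downsample_min(stack.voxels, f) if f > 1 else stack.voxels
    air = ds < gray_threshold
    if stoppers is not None and len(stoppers):
        blocked = _stopper_block(air.shape, stoppers, stack.voxel_size, f)
        for s in seeds:
            sd = tuple(c // f for c in s)
            if blocked[sd]:
                raise ValueError(f"seed {s} lies inside a segmentation stopper")
        air &= ~blocked
    lab, _ = ndi.label(air, structure=ndi.generate_binary_structure(3, 1))
    seed_labels = {int(lab[tuple(c // f for c in s)]) for s in seeds}
    seed_labels.discard(0)
    if not seed_labels:
        raise ValueError("no seed lies in an air component after blocking")
    mask = np.isin(lab, sorted(seed_labels))
    return AirwaySegmentation(
        conducting_mask=mask,
        downsample_factor=f,
        voxel_size=stack.voxel_size,
        seeds=list(seeds),
        stoppers=stoppers,
    )


def upsample_mask(seg: AirwaySegmentation, shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbor upsampling of the grown mask back to native shape."""
    f = seg.downsample_factor
    up = np.repeat(
        np.repeat(np.repeat(seg.conducting_mask, f, axis=0), f, axis=1), f, axis=2
    )
    out = np.zeros(shape, dtype=bool)
    sz = tuple(min(a, b) for a, b in zip(up.shape, shape))
    out[: sz[0], : sz[1], : sz[2]] = up[: sz[0], : sz[1], : sz[2]]
    return out


def assign_generations(
    seg: AirwaySegmentation,
    root_voxel: Optional[tuple[int, int, int]] = None,
) -> AirwaySegmentation:
    """Skeletonize the conducting mask and number intralobar generations.

    The root edge (lobar bronchus at lobe entry) is generation 0; the
    generation increments by one at every branching vertex along any path.
    If no root voxel is given, the deterministic rule is the largest-radius
    skeleton point near a z extreme of the tree. The skeleton must be one
    connected component (the grown mask is seed-connected by construction).
    """
    mask = seg.conducting_mask
    if not mask.any():
        raise ValueError("empty conducting mask")
    ncomp = int(ndi.label(mask, ndi.generate_binary_structure(3, 1))[1])
    if ncomp > 1:
        raise ValueError(
            f"conducting mask has {ncomp} connected components; expected one"
        )
    radius = ndi.distance_transform_edt(mask)
    skel = skeletonize(mask)
    g = skeleton_graph(skel)
    ds_size = seg.ds_voxel_size
    # prune thinning artifacts at junction bulges and the short daughter
    # stubs left behind stoppers at dual entrances (their internal branch
    # point is not a conducting junction); real lateral branches lose about
    # one tube radius to end retraction and remain longer than this
    g = prune_spurs(g, 22.0 / ds_size)
    if len(g) == 0:
        raise ValueError("skeleton vanished after pruning")
    rad = radius[tuple(g.coords.T)]
    if root_voxel is not None:
        f = seg.downsample_factor
        rv = np.array([c // f for c in root_voxel])
        root = int(np.linalg.norm(g.coords - rv, axis=1).argmin())
    else:
        root = select_root(g, rad, mask.shape[0])
    parent, dist, order = bfs_tree(g, root)
    reached = parent != -2
    if not reached.all():
        g = g.subgraph(reached)
        rad = rad[reached]
        remap = -np.ones(len(reached), dtype=np.int64)
        remap[np.nonzero(reached)[0]] = np.arange(int(reached.sum()))
        root = int(remap[root])
        parent, dist, order = bfs_tree(g, root)
    gen = junction_generations(g, parent, order)

    graph = nx.Graph()
    for i, c in enumerate(g.coords):
        graph.add_node(
            i,
            z=int(c[0]),
            y=int(c[1]),
            x=int(c[2]),
            intralobar_generation=int(gen[i]),
        )
    for i in range(len(g)):
        p = parent[i]
        if p >= 0:
            graph.add_edge(int(p), i, intralobar_generation=int(gen[i]))
    seg.skeleton = graph
    seg.node_generation = gen
    seg.skeleton_coords = g.coords
    return seg


def entrance_generations(
    seg: AirwaySegmentation,
    entrances: Sequence[Union[AcinarEntrance, tuple]],
) -> list[int]:
    """Intralobar generation of the conducting edge feeding each entrance:
    the generation of the nearest conducting-skeleton point. Dual entrances
    sharing one transitional bronchiole inherit that bronchiole's
    generation (the internal branch point is not a conducting junction)."""
    if seg.skeleton_coords is None or seg.node_generation is None:
        raise ValueError("run assign_generations first")
    f = seg.downsample_factor
    out = []
    for e in entrances:
        pos = np.array(e.position if isinstance(e, AcinarEntrance) else e) / f
        i = int(np.linalg.norm(seg.skeleton_coords - pos, axis=1).argmin())
        out.append(int(seg.node_generation[i]))
    return out


def save_skeleton_graphml(seg: AirwaySegmentation, path: str | Path) -> None:
    if seg.skeleton is None:
        raise ValueError("run assign_generations first")
    nx.write_graphml(seg.skeleton, Path(path))
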