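"""Image-stack container, voxel-size degradation, and substack splitting.

Tomographic acquisitions arrive as 8-bit grayscale stacks with isometric
voxels of a few µm. Before counting, stacks are split along z into substacks
of 250–500 sections to bound memory; for the resolution study a stack is
degraded to coarser voxel sizes by bicubic interpolation, mimicking
acquisition at lower resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageStack",
    "Substack",
    "SubstackSet",
    "resample",
    "split_substacks",
    "concat_substacks",
    "read_stack",
    "write_stack",
]

SUBSTACK_DEPTH_RANGE = (250, 500)
#: remainder sections below this are appended to the previous substack
MIN_TAIL_SECTIONS = 50


@dataclass
class ImageStack:
    """3D 8-bit grayscale image stack with isometric voxels.

    ``voxels`` is indexed (z, y, x); ``voxel_size`` is the isometric voxel
    side length in µm; ``origin_index`` locates the stack inside a parent
    volume (0-based voxel indices), which keeps substack coordinates in
    parent-stack terms.
    """

    voxels: np.ndarray
    voxel_size: float
    origin_index: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != np.uint8:
            raise ValueError("voxels must be 8-bit (uint8)")
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 2:
            raise ValueError("voxels must be 3D with every dimension >= 2")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_sections(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Substack:
    """One z-slab of a parent stack, half-open section range [z_start, z_end)."""

    z_start: int
    z_end: int
    stack: ImageStack


@dataclass
class SubstackSet:
    """Substacks covering a parent stack along z, with a declared overlap."""

    substacks: list[Substack]
    overlap: int
    parent_shape: tuple[int, int, int]
    voxel_size: float

    def __iter__(self) -> Iterator[Substack]:
        return iter(self.substacks)

    def __len__(self) -> int:
        return len(self.substacks)

    @property
    def ranges(self) -> list[tuple[int, int]]:
        return [(s.z_start, s.z_end) for s in self.substacks]


def resample(stack: ImageStack, new_voxel_size: float) -> ImageStack:
    """Degrade a stack to a coarser voxel size by bicubic interpolation.

    Upsampling is rejected: only degradation to coarser voxels is meaningful
    when determining the minimal resolution required for counting. Bicubic
    interpolation per axis with reflect boundary handling (avoiding dark
    rims that could masquerade as airway walls), preceded by the Gaussian
    band-limiting prefilter matched to the size ratio — a coarser
    acquisition integrates over its larger detector element, so the
    prefilter is part of simulating it. Values are clipped back to
    [0, 255].
    """
    if new_voxel_size < stack.voxel_size:
        raise ValueError(
            f"upsampling requested ({stack.voxel_size} -> {new_voxel_size} µm); "
            "only degradation to coarser voxels is supported"
        )
    if new_voxel_size == stack.voxel_size:
        return ImageStack(stack.voxels.copy(), stack.voxel_size, stack.origin_index)
    zoom = stack.voxel_size / new_voxel_size
    shape = tuple(max(2, int(round(s * zoom))) for s in stack.voxels.shape)
    out = _sk_resize(
        stack.voxels.astype(np.float32),
        shape,
        order=3,
        mode="reflect",
        anti_aliasing=True,
        preserve_range=True,
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return ImageStack(out, new_voxel_size, stack.origin_index)


def split_substacks(
    stack: ImageStack,
    depth: int,
    overlap: int = 0,
    enforce_depth_range: bool = True,
) -> SubstackSet:
    """Split a stack along z into substacks of ``depth`` sections.

    Consecutive substacks share ``overlap`` sections. The final substack
    absorbs any remainder smaller than 50 sections instead of leaving a
    sliver. Depths outside the customary 250–500 sections are rejected unless
    ``enforce_depth_range=False`` (small stacks, tests).
    """
    lo, hi = SUBSTACK_DEPTH_RANGE
    if enforce_depth_range and not lo <= depth <= hi:
        raise ValueError(
            f"substack depth {depth} outside [{lo}, {hi}]; pass "
            "enforce_depth_range=False to override"
        )
    if overlap < 0 or depth < 2 * max(overlap, 1):
        raise ValueError("require depth >= 2*overlap and overlap >= 0")
    n = stack.n_sections
    step = depth - overlap
    starts = list(range(0, max(n - overlap, 1), step))
    # drop a trailing window that would start beyond the data
    starts = [s for s in starts if s < n]
    bounds: list[tuple[int, int]] = []
    for s in starts:
        e = min(s + depth, n)
        bounds.append((s, e))
    # tail tie-break: merge a sliver (<50 new sections) into the previous slab
    if len(bounds) > 1:
        s, e = bounds[-1]
        prev_s, prev_e = bounds[-2]
        if e - prev_e < MIN_TAIL_SECTIONS:
            bounds[-2] = (prev_s, e)
            bounds.pop()
    oz, oy, ox = stack.origin_index
    subs = [
        Substack(
            s,
            e,
            ImageStack(stack.voxels[s:e], stack.voxel_size, (oz + s, oy, ox)),
        )
        for s, e in bounds
    ]
    return SubstackSet(subs, overlap, stack.shape, stack.voxel_size)


def concat_substacks(subset: SubstackSet) -> ImageStack:
    """Reassemble the parent stack from an overlap-free substack set."""
    if subset.overlap != 0:
        raise ValueError("round-trip concatenation requires overlap == 0")
    parts = [s.stack.voxels for s in subset.substacks]
    out = np.concatenate(parts, axis=0)
    if out.shape != subset.parent_shape:
        raise ValueError("substacks do not tile the parent stack")
    first = subset.substacks[0].stack
    oz, oy, ox = first.origin_index
    return ImageStack(out, subset.voxel_size, (oz - subset.substacks[0].z_start, oy, ox))


def read_stack(path: str | Path, voxel_size: float) -> ImageStack:
    """Read a multi-page TIFF (or a directory of numbered TIFF sections,
    z ascending) as an ImageStack."""
    p = Path(path)
    if p.is_dir():
        pages = sorted(p.glob("*.tif")) + sorted(p.glob("*.tiff"))
        if not pages:
            raise FileNotFoundError(f"no TIFF sections in {p}")
        arr = np.stack([tifffile.imread(f) for f in pages])
    else:
        arr = tifffile.imread(p)
    if arr.ndim == 2:
        arr = arr[None]
    return ImageStack(arr.astype(np.uint8), voxel_size)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a single multi-page TIFF."""
    tifffile.imwrite(Path(path), stack.voxels, photometric="minisblack")
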