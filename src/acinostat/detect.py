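"""Automated counting of acinar entrances in 3D image stacks.

An acinar entrance is the locus where a transitional bronchiole's wall
changes abruptly from the thick conducting type to the thin gas-exchange
type, with the first alveoli appearing directly distal. The detector
operationalizes those two morphological criteria:

1. the airway lumen is segmented by thresholding and skeletonized, giving a
   1-D domain along which "sudden" is well defined;
2. wall thickness is profiled along every root-to-leaf path of the lumen
   skeleton (sub-voxel ray casting from the centerline through the nearest
   wall); a drop of at least ``thickness_drop_ratio`` within
   ``transition_window`` marks a candidate transition;
3. the candidate is confirmed if concave air pockets (alveoli and alveolated
   ducts, found as the morphological closing residue of the air phase) exist
   within ``alveolus_search_distance`` of it.

A branch point inside the transition zone whose vertex wall is still thick
produces one entrance per daughter; the two entrances are linked as a dual
pair. Counting over substacks attributes each entrance to the substack
containing its centroid and hands labels across boundaries so nothing is
counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from ._skeleton import (
    SkeletonGraph,
    bfs_tree,
    junction_generations,
    prune_spurs,
    root_to_leaf_paths,
    select_root,
    skeleton_graph,
)
from .imaging import ImageStack, SubstackSet, resample

__all__ = [
    "DetectParams",
    "AcinarEntrance",
    "CountResult",
    "ResolutionStudy",
    "tissue_mask",
    "wall_thickness_map",
    "detect_entrances",
    "count_acini",
    "minimal_resolution",
    "resolution_limit",
]

#: voxel size above which entrance counting is no longer reliable
RESOLUTION_LIMIT_UM = 3.6


@dataclass
class DetectParams:
    """Tunable operational definitions of the morphological criteria.

    All distances in µm. ``thickness_drop_ratio`` is the minimal proximal to
    distal wall-thickness ratio that counts as "sudden"; the transition must
    complete within ``transition_window`` of lumen arc length and show
    alveolar evidence within ``alveolus_search_distance`` distally.
    """

    tissue_threshold: Union[str, float] = "otsu"
    thickness_drop_ratio: float = 2.0
    transition_window: float = 40.0
    alveolus_search_distance: float = 60.0
    min_lumen_radius: float = 5.0
    closing_radius: float = 12.0
    min_evidence_volume: float = 5000.0
    spur_prune_length: float = 30.0
    dual_pair_arc: float = 42.0
    min_wall_proximal: float = 5.0
    max_distal_thickness: float = 8.0
    min_separation: float = 12.0

    def __post_init__(self) -> None:
        if self.thickness_drop_ratio < 2.0:
            raise ValueError("thickness_drop_ratio must be >= 2")
        for name in (
            "transition_window",
            "alveolus_search_distance",
            "min_lumen_radius",
            "closing_radius",
            "min_evidence_volume",
            "spur_prune_length",
            "dual_pair_arc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.tissue_threshold, str) and self.tissue_threshold <= 0:
            raise ValueError("tissue_threshold must be positive or 'otsu'")


@dataclass
class AcinarEntrance:
    """One detected acinar entrance."""

    position: tuple[int, int, int]  # (z, y, x) voxel, parent-stack coordinates
    label: str
    substack_index: int
    wall_thickness_proximal: float
    wall_thickness_distal: float
    dual_of: Optional[str] = None
    generation: Optional[int] = None
    lumen_radius: float = 0.0


@dataclass
class CountResult:
    """Entrance list plus the per-substack bookkeeping of one count."""

    entrances: list[AcinarEntrance]
    n_acini: int
    per_substack_counts: list[int]
    provenance: dict = field(default_factory=dict)


@dataclass
class ResolutionStudy:
    """Counts across a voxel-size ladder and the resulting resolution limit."""

    sizes: list[float]
    counts: list[int]
    limit: float
    anomaly: bool  # a count increased with coarser voxels


def _as_voxels(stack: Union[ImageStack, np.ndarray]) -> np.ndarray:
    return stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)


def resolve_threshold(
    stack: Union[ImageStack, np.ndarray], threshold: Union[str, float]
) -> float:
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        return float(threshold_otsu(_as_voxels(stack)))
    return float(threshold)


def tissue_mask(
    stack: Union[ImageStack, np.ndarray], threshold: Union[str, float] = "otsu"
) -> np.ndarray:
    """Binary tissue mask: voxels at or above the (possibly Otsu-resolved)
    grayscale threshold. Rejects stacks with an empty tissue or air class."""
    vox = _as_voxels(stack)
    thr = resolve_threshold(vox, threshold)
    mask = vox >= thr
    if mask.all():
        # Otsu returns the lower mode on two-valued data; use a strict
        # comparison so the air class survives
        mask = vox > thr
    if not mask.any():
        raise ValueError("empty tissue class: no voxel reaches the threshold")
    if mask.all():
        raise ValueError("empty air class: every voxel reaches the threshold")
    return mask


def wall_thickness_map(tissue: np.ndarray, voxel_size: float) -> np.ndarray:
    """Local thickness transform of a binary tissue mask, in µm.

    Each tissue voxel gets the diameter of the largest inscribed sphere that
    contains it (computed by propagating distance-transform maxima), the
    standard measure of local wall thickness.
    """
    tissue = np.asarray(tissue).astype(bool)
    if tissue.ndim != 3:
        raise ValueError("tissue mask must be 3D")
    edt = ndi.distance_transform_edt(tissue)
    out = np.zeros(tissue.shape, dtype=np.float32)
    rmax = int(np.floor(edt.max()))
    for r in range(rmax, 0, -1):
        centers = edt >= r
        if not centers.any():
            continue
        if r == 1:
            region = centers
        else:
            # a sphere of radius edt(c) centred at c stays inside the
            # tissue and covers voxels strictly closer than its radius
            reach = ndi.distance_transform_edt(~centers)
            region = reach <= r - 1e-3
        sel = region & tissue & (out == 0)
        out[sel] = 2 * r
    return out * voxel_size


def _closing_residue(tissue: np.ndarray, radius_vox: float) -> np.ndarray:
    """Air voxels swallowed by a morphological closing of the tissue with a
    ball of the given radius: concave pockets and narrow alveolated airways."""
    if radius_vox < 1:
        return np.zeros(tissue.shape, dtype=bool)
    d_air = ndi.distance_transform_edt(~tissue)
    dilated = d_air <= radius_vox
    d_in = ndi.distance_transform_edt(dilated)
    closed = d_in > radius_vox
    return closed & ~tissue


def _background_labels(lab: np.ndarray) -> set[int]:
    """Air components touching an x or y face are background: the lobe is
    surrounded by its airway-free cortex except where the bronchus enters
    along z."""
    edge = np.concatenate(
        [
            lab[:, 0].ravel(),
            lab[:, -1].ravel(),
            lab[:, :, 0].ravel(),
            lab[:, :, -1].ravel(),
        ]
    )
    return set(int(v) for v in np.unique(edge)) - {0}


def _wall_profile(
    gray: np.ndarray,
    coords: np.ndarray,
    directions: np.ndarray,
    threshold: float,
    voxel_size: float,
    radius_vox: Optional[np.ndarray] = None,
    probe_um: float = 30.0,
    step: float = 0.4,
    air_level: Optional[float] = None,
) -> np.ndarray:
    """Sub-voxel wall thickness (µm) for each skeleton voxel: march along the
    wall normal, find the up-crossing (wall entry) and the next down-crossing
    (wall exit) of the half-maximum gray level, interpolating both crossings
    linearly. Half-maximum crossings recover the true width of a blurred
    plateau, where the (class-imbalanced) segmentation threshold would not.

    The probing depth is ``probe_um`` beyond the wall entry (the march to the
    wall across the lumen does not count); walls with no exit within it are
    reported as ``probe_um``. If ``air_level`` is given, a down-crossing only
    counts as the wall's end when the profile then falls to that near-air
    level: shallow dips inside fused double walls (junction crevices) do not
    terminate the wall."""
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    lumen_reach = float(np.max(radius_vox)) if radius_vox is not None else 0.0
    kmax = int(np.ceil((lumen_reach + probe_um / voxel_size) / step)) + 3
    ts = np.arange(kmax) * step
    pts = coords[:, None, :] + directions[:, None, :] * ts[None, :, None]
    flat = pts.reshape(-1, 3).T
    vals = ndi.map_coordinates(
        gray.astype(np.float32), flat, order=1, mode="nearest"
    ).reshape(n, kmax)
    above = vals >= threshold
    out = np.zeros(n, dtype=np.float64)
    idx_all = np.arange(kmax)
    for i in range(n):
        a = above[i]
        entries = idx_all[1:][a[1:] & ~a[:-1]]
        if a[0]:
            entry = 0
        elif len(entries):
            entry = int(entries[0])
        else:
            out[i] = 0.0
            continue
        after = a[entry:]
        exits = np.nonzero(~after)[0]
        ex = None
        look = max(2, int(round(3.0 / voxel_size / step)))
        for e0 in exits:
            if e0 * step * voxel_size > probe_um:
                break
            cand = entry + int(e0)
            if air_level is None or vals[i, cand : cand + look].min() <= air_level:
                ex = cand
                break
        if ex is None:
            out[i] = probe_um  # thicker than the probing depth
            continue
        # linear sub-step refinement of both crossings
        if entry > 0:
            g0, g1 = vals[i, entry - 1], vals[i, entry]
            frac_in = (threshold - g0) / (g1 - g0) if g1 != g0 else 0.0
            t_in = ts[entry - 1] + frac_in * step
        else:
            t_in = 0.0
        g0, g1 = vals[i, ex - 1], vals[i, ex]
        frac_out = (threshold - g0) / (g1 - g0) if g1 != g0 else 0.0
        t_out = ts[ex - 1] + frac_out * step
        out[i] = max(t_out - t_in, 0.0) * voxel_size
    return out


def _detect_in_component(
    gray: np.ndarray,
    comp: np.ndarray,
    threshold: float,
    voxel_size: float,
    params: DetectParams,
    evidence_density: np.ndarray,
    z_offset: int,
    profile_level: Optional[float] = None,
    air_level: Optional[float] = None,
) -> list[dict]:
    """Run the path-scanning detector inside one lumen component (cropped)."""
    v = voxel_size
    radius_map = ndi.distance_transform_edt(comp)
    skel = skeletonize(comp)
    if not skel.any():
        return []
    g = skeleton_graph(skel)
    g = prune_spurs(g, params.spur_prune_length / v)
    if len(g) == 0:
        return []
    radius_vox = radius_map[tuple(g.coords.T)]
    root = select_root(g, radius_vox, comp.shape[0])
    parent, dist, order = bfs_tree(g, root)
    paths = root_to_leaf_paths(parent)
    ch_first = np.full(len(g), -1, dtype=np.int64)
    for node in range(len(g)):
        p_ = parent[node]
        if p_ >= 0 and ch_first[p_] < 0:
            ch_first[p_] = node

    # circumferential wall thickness: median over radial rays perpendicular
    # to the local centerline tangent. A single nearest-wall ray would read
    # near zero where it grazes the open mouth of a joining branch; the
    # median over the circumference is what an observer scrolling through
    # sections actually judges.
    tangents = np.zeros((len(g), 3))
    for node in range(len(g)):
        p_ = parent[node]
        nxt = ch_first[node]
        a_ = g.coords[p_] if p_ >= 0 else g.coords[node]
        b_ = g.coords[nxt] if nxt >= 0 else g.coords[node]
        t_ = b_ - a_
        nt = np.linalg.norm(t_)
        tangents[node] = t_ / nt if nt > 0 else (0.0, 0.0, 1.0)
    n_rays = 8
    angles = np.arange(n_rays) * (2 * np.pi / n_rays)
    level = profile_level if profile_level is not None else threshold
    # per-node orthonormal frame
    ref = np.where(
        np.abs(tangents[:, 0:1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
    )
    e1 = np.cross(tangents, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(tangents, e1)
    dirs_all = (
        np.cos(angles)[None, :, None] * e1[:, None, :]
        + np.sin(angles)[None, :, None] * e2[:, None, :]
    )
    coords_rep = np.repeat(g.coords.astype(np.float64), n_rays, axis=0)
    rad_rep = np.repeat(radius_vox, n_rays)
    w_all = _wall_profile(
        gray,
        coords_rep,
        dirs_all.reshape(-1, 3),
        level,
        v,
        radius_vox=rad_rep,
        air_level=air_level,
    ).reshape(len(g), n_rays)
    wall = np.median(w_all, axis=1)
    # resolvability floor: a width sampled at pitch v cannot be established
    # below about two voxels, so no wall may be judged thinner than that.
    # This is what ends reliable counting at coarse voxels: once 2 v exceeds
    # the gas-exchange wall bound, the thin distal wall can no longer be
    # recognized as thin.
    wall = np.maximum(wall, 2.0 * v)

    halfwin = max(3, int(round(0.35 * params.transition_window / v)))
    found: dict[int, dict] = {}
    ch_counts = np.zeros(len(g), dtype=np.int64)
    for node, p in enumerate(parent):
        if p >= 0:
            ch_counts[p] += 1
    for path in paths:
        w = wall[path]
        n = len(path)
        if n < 2 * halfwin + 1:
            continue
        for i in range(halfwin, n - halfwin):
            prox = float(np.median(w[i - halfwin : i]))
            # distal statistic: a low quantile over a longer window, robust
            # against the locally thick rims where alveolar cups meet the
            # duct wall just distal of the entrance
            distal_win = w[i + 1 : i + 1 + 2 * halfwin]
            distal = float(np.percentile(distal_win, 30))
            if prox < params.min_wall_proximal * 1.0:
                continue
            if distal > params.max_distal_thickness:
                continue  # distal wall not of gas-exchange thinness
            if prox < params.thickness_drop_ratio * max(distal, 1e-6):
                continue
            # localize the entrance at the steepest step of the profile
            # within the detection window (short medians on both sides)
            h3 = max(2, halfwin // 2)
            best_j, best_step = i, -np.inf
            for k in range(max(i - 2, h3), min(i + 2 * halfwin + 3, n - h3 - 1)):
                step_k = float(
                    np.median(w[k - h3 : k]) - np.median(w[k + 1 : k + 1 + h3])
                )
                if step_k > best_step:
                    best_step, best_j = step_k, k
            j = best_j
            node = int(path[j])
            if node not in found:
                vox = g.coords[node]
                evid = evidence_density[tuple(vox)]
                if evid < params.min_evidence_volume:
                    continue  # thickness drop without alveoli: no entrance
                found[node] = {
                    "node": node,
                    "position": (
                        int(vox[0]) + z_offset,
                        int(vox[1]),
                        int(vox[2]),
                    ),
                    "z_local": int(vox[0]),
                    "wall_proximal": prox,
                    "wall_distal": distal,
                    "lumen_radius": float(radius_vox[node] * v),
                }
            break  # everything distal of the first transition is acinar
    ents = list(found.values())

    # merge duplicates: the same transition can be crossed at slightly
    # different voxels by different root-leaf paths (dual-entrance pairs sit
    # farther apart than this and survive)
    merged: list[dict] = []
    for e in ents:
        pos = np.array(e["position"], dtype=float)
        dup = False
        for m in merged:
            if np.linalg.norm(pos - np.array(m["position"], float)) * v < params.min_separation:
                dup = True
                break
        if not dup:
            merged.append(e)
    ents = merged

    # dual pairing: the two entrances of a branched transitional bronchiole
    # sit just distal of its internal branch point, so their skeleton arc
    # separation is short; entrances of sibling unbranched transitional
    # bronchioles are separated by twice the conducting part and stay apart
    if len(ents) > 1:
        limit = 2 * params.dual_pair_arc / v
        narc = len(ents)
        arcs = np.full((narc, narc), np.inf)
        for a in range(narc):
            src = ents[a]["node"]
            darc = {src: 0.0}
            queue = [src]
            while queue:
                u = queue.pop()
                for vv, l in zip(g.neighbors[u], g.edge_len[u]):
                    nd = darc[u] + float(l)
                    if nd <= limit and nd < darc.get(vv, np.inf):
                        darc[vv] = nd
                        queue.append(vv)
            for b in range(narc):
                if b != a and ents[b]["node"] in darc:
                    arcs[a, b] = darc[ents[b]["node"]]
        pairs = sorted(
            ((arcs[a, b], a, b) for a in range(narc) for b in range(a + 1, narc)),
            key=lambda t: t[0],
        )
        taken: set[int] = set()
        for arc_ab, a, b in pairs:
            if arc_ab * v > 2 * params.dual_pair_arc:
                break
            if a in taken or b in taken:
                continue
            ents[a]["dual_partner"] = b
            ents[b]["dual_partner"] = a
            taken.update((a, b))
    return ents


def detect_entrances(
    stack: ImageStack,
    params: Optional[DetectParams] = None,
    provenance: Optional[dict] = None,
) -> list[AcinarEntrance]:
    """Detect acinar entrances in a stack (treated as one substack).

    The voxel size should be at or below the 3.6 µm reliability limit; above
    it a warning is recorded in the provenance (and emitted) but detection
    still runs.
    """
    params = params or DetectParams()
    prov = provenance if provenance is not None else {}
    ents = _detect_raw(stack, params, prov, z_offset=0)
    return _finalize_entrances([(0, ents)])[0]


def _detect_raw(
    stack: ImageStack,
    params: DetectParams,
    prov: dict,
    z_offset: int,
) -> list[dict]:
    v = stack.voxel_size
    if v > RESOLUTION_LIMIT_UM:
        msg = (
            f"voxel size {v:.2f} µm exceeds the {RESOLUTION_LIMIT_UM} µm "
            "reliability limit for acinus counting"
        )
        prov.setdefault("warnings", []).append(msg)
        warnings.warn(msg, stacklevel=3)
    thr = resolve_threshold(stack, params.tissue_threshold)
    prov["threshold"] = thr
    tis = stack.voxels >= thr
    if tis.all():
        tis = stack.voxels > thr  # two-valued data: Otsu hits the low mode
    if not tis.any() or tis.all():
        if tis.all():
            raise ValueError("empty air class: every voxel reaches the threshold")
        return []
    _st6 = ndi.generate_binary_structure(3, 1)

    def _lumen_components(t):
        lab_, n_ = ndi.label(~t, structure=_st6)
        bg_ = _background_labels(lab_)
        sizes_ = np.bincount(lab_.ravel())
        min_size = max(27, int((params.min_lumen_radius / v) ** 3))
        ids_ = [i for i in range(1, n_ + 1) if i not in bg_ and sizes_[i] >= min_size]
        return lab_, ids_

    lab, lumen_ids = _lumen_components(tis)
    if not lumen_ids:
        # marginally resolved walls can break at single spots and merge the
        # airway lumen into the background. Eroding the air phase narrows
        # such passages shut while the wide lumina stay connected, so the
        # component topology can be recovered; wall thickness itself is
        # always measured on the raw grayscale.
        for it in (1, 2):
            grown_tis = ndi.binary_dilation(tis, _st6, iterations=it)
            lab, lumen_ids = _lumen_components(grown_tis)
            if lumen_ids:
                prov.setdefault("warnings", []).append(
                    f"lumen separated from background only after eroding the "
                    f"air phase by {it} voxel(s): walls at the resolution limit"
                )
                break
    if not lumen_ids:
        return []
    air = lab > 0
    # half-maximum gray level for sub-voxel wall profiling; a wall only ends
    # where the profile returns near the air level
    air_mean = float(stack.voxels[air].mean())
    tis_mean = float(stack.voxels[tis].mean())
    level = 0.5 * (air_mean + tis_mean)
    air_level = air_mean + 0.25 * (tis_mean - air_mean)
    evid = _closing_residue(tis, params.closing_radius / v)
    # only pockets belonging to airway lumina count as alveolar evidence
    keep = np.isin(lab, lumen_ids)
    evid &= keep
    # local evidence volume within the search range, via a box average
    half = max(1, int(round(0.75 * params.alveolus_search_distance / v)))
    size = 2 * half + 1
    density = ndi.uniform_filter(evid.astype(np.float32), size=size)
    density = density * (size**3) * v**3  # -> µm³ of pocket air nearby

    ents: list[dict] = []
    objects = ndi.find_objects(lab)
    for lid in lumen_ids:
        sl = objects[lid - 1]
        pad = 2
        sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, lab.shape)
        )
        comp = lab[sl] == lid
        sub = _detect_in_component(
            stack.voxels[sl],
            comp,
            thr,
            v,
            params,
            density[sl],
            z_offset=z_offset + sl[0].start,
            profile_level=level,
            air_level=air_level,
        )
        for e in sub:
            e["position"] = (
                e["position"][0],
                e["position"][1] + sl[1].start,
                e["position"][2] + sl[2].start,
            )
        base = len(ents)
        for e in sub:
            if "dual_partner" in e:
                e["dual_partner"] += base
        ents.extend(sub)
    return ents


def _finalize_entrances(
    per_substack: list[tuple[int, list[dict]]]
) -> tuple[list[AcinarEntrance], list[int]]:
    """Assign labels and resolve dual partners across substacks."""
    entrances: list[AcinarEntrance] = []
    counts: list[int] = []
    for sub_idx, ents in per_substack:
        base = len(entrances)
        for k, e in enumerate(ents):
            entrances.append(
                AcinarEntrance(
                    position=e["position"],
                    label=f"A{base + k + 1:04d}",
                    substack_index=sub_idx,
                    wall_thickness_proximal=e["wall_proximal"],
                    wall_thickness_distal=e["wall_distal"],
                    lumen_radius=e.get("lumen_radius", 0.0),
                )
            )
        for k, e in enumerate(ents):
            if "dual_partner" in e and e["dual_partner"] is not None:
                p = e["dual_partner"]
                if 0 <= p < len(ents):
                    entrances[base + k].dual_of = entrances[base + p].label
        counts.append(len(ents))
    return entrances, counts


HALO_SECTIONS = 80


def count_acini(
    substacks: Union[SubstackSet, ImageStack],
    params: Optional[DetectParams] = None,
    parent: Optional[ImageStack] = None,
) -> CountResult:
    """Count acini over a substack set without double counting.

    Each substack is analyzed with a halo of context sections on both sides
    (the automated analogue of reporting labels of overlapping acini to the
    next substack); an entrance is attributed to the unique substack whose
    core z range contains its transition locus.
    """
    params = params or DetectParams()
    prov: dict = {"params": params.__dict__.copy()}
    if isinstance(substacks, ImageStack):
        ents = _detect_raw(substacks, params, prov, z_offset=0)
        entrances, counts = _finalize_entrances([(0, ents)])
        return CountResult(entrances, len(entrances), counts, prov)
    vsizes = {s.stack.voxel_size for s in substacks}
    if len(vsizes) > 1:
        raise ValueError(f"inconsistent voxel sizes across substacks: {vsizes}")
    if parent is None:
        from .imaging import concat_substacks

        parent = concat_substacks(substacks)
    halo = HALO_SECTIONS
    per_substack: list[tuple[int, list[dict]]] = []
    for k, s in enumerate(substacks):
        lo = max(s.z_start - halo, 0)
        hi = min(s.z_end + halo, parent.n_sections)
        ext = ImageStack(parent.voxels[lo:hi], parent.voxel_size)
        sub_prov: dict = {}
        ents = _detect_raw(ext, params, sub_prov, z_offset=lo)
        # sections shared with the previous substack belong to it: this is
        # the label hand-off that prevents double counting
        core_lo = s.z_start if k == 0 else s.z_start + substacks.overlap
        kept = [e for e in ents if core_lo <= e["position"][0] < s.z_end]
        # remap dual partner indices onto the kept subset
        index_map = {id(e): i for i, e in enumerate(kept)}
        for e in kept:
            p = e.get("dual_partner")
            if p is not None and 0 <= p < len(ents):
                e["dual_partner"] = index_map.get(id(ents[p]))
            elif "dual_partner" in e:
                e["dual_partner"] = None
        per_substack.append((k, kept))
        prov.setdefault("substacks", []).append(
            {"z_start": s.z_start, "z_end": s.z_end, **sub_prov}
        )
    entrances, counts = _finalize_entrances(per_substack)
    return CountResult(entrances, len(entrances), counts, prov)


def resolution_limit(sizes: Sequence[float], counts: Sequence[int]) -> float:
    """The largest voxel size whose count still equals the native count: one
    step better than the sizes where the count starts to decrease."""
    if len(sizes) != len(counts) or len(sizes) == 0:
        raise ValueError("sizes and counts must have equal nonzero length")
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be sorted ascending (native first)")
    native = counts[0]
    limit = sizes[0]
    for s, c in zip(sizes, counts):
        if c == native:
            limit = s
        else:
            break
    return float(limit)


def minimal_resolution(
    roi_stack: ImageStack,
    sizes: Sequence[float],
    params: Optional[DetectParams] = None,
    ground_truth_count: Optional[int] = None,
) -> ResolutionStudy:
    """Degrade a region of interest through a ladder of voxel sizes, recount
    at each, and report the minimal required resolution.

    ``sizes`` must be ascending and start at the stack's native voxel size.
    A count that increases with coarser voxels is flagged as an anomaly (not
    an exception).
    """
    params = params or DetectParams()
    sizes = [float(s) for s in sizes]
    if sizes != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    if abs(sizes[0] - roi_stack.voxel_size) > 1e-9:
        raise ValueError("first size must be the native voxel size")
    counts: list[int] = []
    for s in sizes:
        deg = resample(roi_stack, s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ents = detect_entrances(deg, params)
        counts.append(len(ents))
    anomaly = any(b > a for a, b in zip(counts, counts[1:]))
    limit = resolution_limit(sizes, counts)
    if ground_truth_count is not None and counts[0] != ground_truth_count:
        anomaly = True
    return ResolutionStudy(sizes=sizes, counts=counts, limit=limit, anomaly=anomaly)
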