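"""Synthetic lung-lobe phantoms with a known number of acini.

Real rat lobes are imaged at µm resolution and acinar entrances are counted
by eye; to validate an automated counter we need volumes in which the true
answer is known. This module grows a monopodial conducting airway tree
(a persistent main stem with lateral branches, the rodent pattern), attaches
exactly one transitional bronchiole to each path into an acinus, and
voxelizes it into an 8-bit absorption-contrast stack: bright tissue walls,
dark air. Conducting airways get thick walls; at every acinar entrance the
wall thickness drops abruptly to the thin gas-exchange value, the first
hemispherical alveoli appear directly distal, and the transition plane is a
slightly oblique ellipse. A configurable fraction of transitional
bronchioles contains a branch point inside the transition zone, producing
two acinar entrances that share one transitional bronchiole.

Ground truth (entrance voxel positions, acinus ids, conducting vs. acinar
lumen masks, per-branch generations) is carried alongside the rendered stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .imaging import ImageStack, write_stack

__all__ = [
    "TreeParams",
    "Branch",
    "Alveolus",
    "GroundTruthEntrance",
    "AirwayTreeSpec",
    "PhantomVolume",
    "GeometryError",
    "generate_airway_tree",
    "voxelize_tree",
    "generate_phantom",
    "save_phantom",
]

TISSUE_GRAY = 200
AIR_GRAY = 30
DEFAULT_VOXEL_BUDGET = 350_000_000


class GeometryError(ValueError):
    """The requested tree cannot be realized in the available geometry."""


@dataclass
class TreeParams:
    """Parameters of the synthetic airway tree.

    Lengths are µm. ``wall_thickness_conducting`` must exceed twice
    ``wall_thickness_acinar`` so the sudden wall-thickness transition at the
    acinar entrance stays detectable; entrance generations are confined to
    the intralobar range seen in rat lobes.
    """

    n_acini_target: int
    seed: int = 0
    monopodial_bias: float = 0.7
    generation_range_entrances: tuple[int, int] = (4, 15)
    dual_entrance_fraction: float = 0.15
    wall_thickness_conducting: float = 16.0
    wall_thickness_acinar: float = 6.0
    lumen_radius_root: float = 32.0
    radius_decay: float = 0.8
    cortex_thickness: float = 50.0
    alveolus_radius: float = 16.0
    # geometry of the grammar (all µm / degrees); exposed so phantoms are
    # fully described by their parameter set rather than buried constants
    segment_length: float = 50.0
    lateral_length: float = 90.0
    trb_conducting_length: float = 56.0
    trb_acinar_length: float = 26.0
    duct_length: float = 45.0
    lumen_radius_floor_conducting: float = 14.0
    lumen_radius_transitional: float = 11.0
    lumen_radius_duct: float = 9.0
    transition_tilt_deg: float = 15.0
    alveoli_per_acinus: int = 4
    clearance: float = 4.0

    def __post_init__(self) -> None:
        if self.n_acini_target < 1:
            raise ValueError("n_acini_target must be >= 1")
        if not 0 <= self.monopodial_bias <= 1:
            raise ValueError("monopodial_bias must be in [0, 1]")
        if not 0 <= self.dual_entrance_fraction <= 1:
            raise ValueError("dual_entrance_fraction must be in [0, 1]")
        gmin, gmax = self.generation_range_entrances
        if not (4 <= gmin <= gmax <= 25):
            raise ValueError("generation_range_entrances must lie within [4, 25]")
        if self.wall_thickness_conducting <= 2 * self.wall_thickness_acinar:
            raise ValueError(
                "wall_thickness_conducting must exceed 2x wall_thickness_acinar "
                "for the entrance transition to be detectable"
            )
        for name in (
            "wall_thickness_conducting",
            "wall_thickness_acinar",
            "lumen_radius_root",
            "cortex_thickness",
            "alveolus_radius",
            "segment_length",
            "lateral_length",
            "trb_conducting_length",
            "trb_acinar_length",
            "duct_length",
            "lumen_radius_floor_conducting",
            "lumen_radius_transitional",
            "lumen_radius_duct",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.radius_decay < 1:
            raise ValueError("radius_decay must be in (0, 1)")


@dataclass
class Branch:
    """A straight centerline segment of the tree.

    ``t_transition`` (transitional bronchioles and dual-entrance daughters
    only) is the arc position along the segment where the wall switches from
    the conducting to the acinar thickness; ``tilt_deg``/``tilt_azimuth``
    describe the oblique elliptical transition plane.
    """

    id: int
    parent_id: Optional[int]
    p0: np.ndarray
    p1: np.ndarray
    btype: str  # bronchus | bronchiole | terminal_bronchiole | transitional_bronchiole | alveolar_duct
    lumen_radius: float
    wall_thickness: float
    generation: int
    t_transition: Optional[float] = None
    wall_thickness_distal: Optional[float] = None
    tilt_deg: float = 0.0
    tilt_azimuth: float = 0.0
    capped: bool = False
    assembly: int = -1

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


@dataclass
class Alveolus:
    center: np.ndarray
    radius: float
    acinus_id: int


@dataclass
class GroundTruthEntrance:
    """A true acinar entrance: the locus where the conducting wall ends."""

    position_um: np.ndarray
    branch_id: int
    acinus_id: int
    generation: int
    lumen_radius: float
    dual_of: Optional[int] = None
    position: Optional[tuple[int, int, int]] = None  # voxel (z, y, x)


@dataclass
class AirwayTreeSpec:
    branches: list[Branch]
    entrances: list[GroundTruthEntrance]
    alveoli: list[Alveolus]
    params: TreeParams
    n_realized: int = 0

    def branch(self, bid: int) -> Branch:
        return self.branches[bid]

    @property
    def transitional_bronchioles(self) -> list[Branch]:
        return [b for b in self.branches if b.btype == "transitional_bronchiole"]


@dataclass
class PhantomVolume:
    """Rendered phantom: grayscale stack plus voxel-aligned ground truth."""

    stack: ImageStack
    tissue_mask: np.ndarray
    conducting_mask: np.ndarray
    acinar_mask: np.ndarray
    truth: list[GroundTruthEntrance]
    params: TreeParams
    tree: AirwayTreeSpec
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_acini(self) -> int:
        return len({e.acinus_id for e in self.truth})


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d."""
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, a))
    e2 = np.cross(d, e1)
    return e1, e2


def _tilted(d: np.ndarray, angle_deg: float, azimuth: float) -> np.ndarray:
    """Direction at ``angle_deg`` from d, at the given azimuth around it."""
    e1, e2 = _perp_frame(d)
    a = np.deg2rad(angle_deg)
    return _unit(
        np.cos(a) * d + np.sin(a) * (np.cos(azimuth) * e1 + np.sin(azimuth) * e2)
    )


def _seg_seg_dist(p0, p1, q0, q1) -> float:
    """Closest distance between segments [p0,p1] and [q0,q1]."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    if den > 1e-12:
        s = np.clip((b * e - c * d) / den, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(w + s * u - t * v))


def _point_seg_dist(p, q0, q1) -> float:
    v = q1 - q0
    c = v @ v
    t = np.clip(((p - q0) @ v) / c, 0.0, 1.0) if c > 1e-12 else 0.0
    return float(np.linalg.norm(p - (q0 + t * v)))


# ---------------------------------------------------------------------------
# tree construction


class _Builder:
    def __init__(self, params: TreeParams):
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.branches: list[Branch] = []
        self.entrances: list[GroundTruthEntrance] = []
        self.alveoli: list[Alveolus] = []
        # collision registry: (p0, p1, lumen_r, wall, assembly, conducting,
        # acinus_id); acinus_id is -1 for conducting structures
        self.capsules: list[
            tuple[np.ndarray, np.ndarray, float, float, int, bool, int]
        ] = []
        self.alv_capsules: list[tuple[np.ndarray, float, float, int, int]] = []
        self._acinus_id = 0
        self._assembly = 0
        # structures the current placement may legitimately touch (its host
        # stem); everything else keeps clearance
        self._exempt: tuple[int, ...] = ()

    # -- bookkeeping -------------------------------------------------------

    def _add_branch(self, **kw) -> Branch:
        b = Branch(id=len(self.branches), **kw)
        self.branches.append(b)
        return b

    GOLDEN = 2.399963  # golden-angle azimuth advance between laterals

    def _register(self, b: Branch, conducting: bool, trim: float = 0.0, acinus: int = -1):
        """Add a branch to the collision registry. ``trim`` drops the basal
        fraction of the capsule: a lateral legitimately fuses with its host
        stem around the junction, so only its outer part constrains others."""
        p0 = b.p0 + trim * (b.p1 - b.p0)
        self.capsules.append(
            (p0, b.p1, b.lumen_radius, b.wall_thickness, b.assembly, conducting, acinus)
        )

    def _clear_of_others(
        self,
        p0,
        p1,
        lumen_r: float,
        wall: float,
        assembly: int,
        conducting: bool,
        acinus: int = -1,
    ) -> bool:
        """True if the candidate tube keeps clearance from foreign structures.

        Walls of different airways may fuse without harm; what must never
        happen is one airway's air carving into another's wall, so the
        required centerline separation is r1 + r2 + max(w1, w2) + clearance.
        Each acinus is a closed unit: its airspace must stay separated from
        every other acinus and from all conducting airways; only structures
        of the same acinus may interpenetrate. Only the root may reach the
        z=0 face, so everything stays above a z floor.
        """
        if min(p0[0], p1[0]) - (lumen_r + wall) < 4.0:
            return False
        cl = self.p.clearance
        for q0, q1, r2, w2, asm, cond2, ac2 in self.capsules:
            # the host-stem exemption covers only conducting laterals, which
            # legitimately join their stem; acinar air must always clear it
            if conducting and (asm == assembly or asm in self._exempt):
                continue
            if not conducting and not cond2 and (ac2 == acinus or asm == assembly and ac2 < 0):
                continue
            if not conducting and cond2 and asm == assembly:
                continue
            if conducting and cond2:
                # conducting walls may fuse, but the seam between two
                # conducting lumina must stay thick enough not to mimic a
                # gas-exchange wall
                need = lumen_r + r2 + 8.0
            else:
                need = lumen_r + r2 + max(wall, w2) + cl
            if _seg_seg_dist(p0, p1, q0, q1) < need:
                return False
        for c, r2, w2, asm, ac2 in self.alv_capsules:
            if conducting:
                if asm == assembly or asm in self._exempt:
                    continue
            elif ac2 == acinus:
                continue
            need = lumen_r + r2 + max(wall, w2) + cl
            if _point_seg_dist(c, p0, p1) < need:
                return False
        return True

    def _alveolus_clear(
        self, center: np.ndarray, radius: float, assembly: int, acinus: int
    ) -> bool:
        if center[0] - radius < 4.0:
            return False
        cl = self.p.clearance
        w_a = self.p.wall_thickness_acinar
        for q0, q1, r2, w2, asm, cond2, ac2 in self.capsules:
            if cond2 and asm == assembly:
                continue
            if not cond2 and ac2 == acinus:
                continue
            need = radius + r2 + max(w_a, w2) + cl
            if _point_seg_dist(center, q0, q1) < need:
                return False
        for c, r2, w2, asm, ac2 in self.alv_capsules:
            if ac2 == acinus:
                continue
            need = radius + r2 + max(w_a, w2) + cl
            if np.linalg.norm(center - c) < need:
                return False
        return True

    def _radius(self, generation: int) -> float:
        p = self.p
        return max(
            p.lumen_radius_floor_conducting,
            p.lumen_radius_root * p.radius_decay**generation,
        )

    def _jitter(self, d: np.ndarray, sd_deg: float) -> np.ndarray:
        az = self.rng.uniform(0, 2 * np.pi)
        ang = abs(self.rng.normal(0, sd_deg))
        return _tilted(d, ang, az)

    # -- plan: how many transitional bronchioles at which generation --------

    def plan(self) -> list[dict]:
        """Allocate acini to transitional-bronchiole units and terminal
        bronchioles, and terminal bronchioles to junction depths on stems."""
        p = self.p
        gmin, gmax = p.generation_range_entrances
        rng = self.rng
        # units: one transitional bronchiole each, carrying 1 or 2 entrances
        units: list[int] = []
        remaining = p.n_acini_target
        while remaining > 0:
            if remaining >= 2 and rng.random() < p.dual_entrance_fraction:
                units.append(2)
                remaining -= 2
            else:
                units.append(1)
                remaining -= 1
        # stratified entrance generations: cycle through the shuffled range
        gens = []
        spread = np.arange(gmin, gmax + 1)
        while len(gens) < len(units):
            block = spread.copy()
            rng.shuffle(block)
            gens.extend(block.tolist())
        unit_gens = gens[: len(units)]
        # group same-generation units pairwise onto terminal bronchioles;
        # a paired TB branches (its children gain a generation), a single-TrB
        # TB does not, so pairs sit one junction shallower
        tbs: list[dict] = []
        bygen: dict[int, list[int]] = {}
        for u, g in zip(units, unit_gens):
            bygen.setdefault(g, []).append(u)
        for g in sorted(bygen):
            us = bygen[g]
            while len(us) >= 2:
                tbs.append({"depth": g - 1, "units": [us.pop(), us.pop()]})
            if us:
                tbs.append({"depth": g, "units": [us.pop()]})
        # assign TBs to junction slots on stems; spawn sub-stems on demand
        max_depth = gmax
        stems: list[dict] = [{"start": 1, "slots": {}, "host": None}]
        for _ in range(200):
            for s in stems:
                s["slots"] = {
                    d: occ for d, occ in s["slots"].items() if occ[0] == "stem"
                }
            unplaced = None
            order = sorted(range(len(tbs)), key=lambda i: tbs[i]["depth"])
            for i in order:
                d = tbs[i]["depth"]
                placed = False
                for si, s in enumerate(stems):
                    if s["start"] <= d <= max_depth and d not in s["slots"]:
                        s["slots"][d] = ("tb", i)
                        tbs[i]["stem"] = si
                        placed = True
                        break
                if not placed:
                    unplaced = d
                    break
            if unplaced is None:
                return self._finalize_plan(stems, tbs)
            # need another stem reaching depth `unplaced`: branch one off at
            # the deepest free junction shallower than it
            spot = None
            for si, s in enumerate(stems):
                for d in range(unplaced - 1, 0, -1):
                    if s["start"] <= d <= max_depth and d not in s["slots"]:
                        if spot is None or d > spot[1]:
                            spot = (si, d)
                        break
            if spot is None:
                raise GeometryError(
                    "cannot allocate the requested entrance generations: no free "
                    "junction left to branch an additional stem from"
                )
            si, d = spot
            stems[si]["slots"][d] = ("stem", len(stems))
            stems.append({"start": d + 1, "slots": {}, "host": (si, d)})
        raise GeometryError("stem allocation did not converge")

    @staticmethod
    def _finalize_plan(stems: list[dict], tbs: list[dict]) -> dict:
        for s in stems:
            occupied = list(s["slots"])
            s["last"] = max(occupied) if occupied else s["start"]
        return {"stems": stems, "tbs": tbs}

    # -- realization -------------------------------------------------------

    def build(self) -> AirwayTreeSpec:
        plan = self.plan()
        stems, tbs = plan["stems"], plan["tbs"]
        p = self.p
        # main stem starts at the lobe entry (hilum) and runs along +z
        pending = [0]
        built: set[int] = set()
        stem_geo: dict[int, dict] = {}
        while pending:
            si = pending.pop(0)
            s = stems[si]
            if s["host"] is None:
                origin = np.zeros(3)
                direction = np.array([1.0, 0.0, 0.0])  # (z, y, x): along +z
                parent_branch = None
            else:
                hsi, hd = s["host"]
                geo = stem_geo[hsi]
                origin = geo["junctions"][hd]
                hdir = geo["dirs"][hd]
                lateral = self.rng.random() < p.monopodial_bias
                lo, hi = (50.0, 90.0) if lateral else (25.0, 50.0)
                direction = None
                parent_branch = geo["in_branch"][hd]
                base_az = geo["azimuths"][hd]
                self._exempt = (-1 - hsi,)
                for k in range(80):
                    az = base_az + self.rng.normal(0, 0.3 + 0.08 * k)
                    cand = _tilted(hdir, self.rng.uniform(lo, hi), az)
                    if self._clear_of_others(
                        origin + cand * (p.segment_length * 0.8),
                        origin + cand * (p.segment_length * 2.5),
                        self._radius(s["start"]),
                        p.wall_thickness_conducting,
                        -1 - si,
                        True,
                    ):
                        direction = cand
                        break
                self._exempt = ()
                if direction is None:
                    raise GeometryError("cannot place a sub-stem without collisions")
            host_dir = None if s["host"] is None else stem_geo[s["host"][0]]["dirs"][s["host"][1]]
            self._build_stem(si, s, origin, direction, parent_branch, stem_geo, host_dir)
            built.add(si)
            for d, occ in s["slots"].items():
                if occ[0] == "stem" and occ[1] not in built:
                    pending.append(occ[1])
        for tb in tbs:
            geo = stem_geo[tb["stem"]]
            self._build_tb_assembly(tb, geo)
        n_real = len({e.acinus_id for e in self.entrances})
        return AirwayTreeSpec(
            branches=self.branches,
            entrances=self.entrances,
            alveoli=self.alveoli,
            params=p,
            n_realized=n_real,
        )

    def _build_stem(self, si, s, origin, direction, parent_branch, stem_geo, host_dir=None):
        """Lay the stem tube segment by segment; every junction depth from
        ``start`` to ``last`` gets a real branching vertex (terminal
        bronchiole, sub-stem, or a short conducting stub)."""
        p = self.p
        junctions: dict[int, np.ndarray] = {}
        dirs: dict[int, np.ndarray] = {}
        in_branch: dict[int, Branch] = {}
        azimuths: dict[int, float] = {}
        pos = origin.copy()
        d = direction.copy()
        prev = parent_branch
        az = self.rng.uniform(0, 2 * np.pi)
        first = True
        for depth in range(s["start"], s["last"] + 1):
            step = p.segment_length * self.rng.uniform(0.9, 1.1)
            if first and s["host"] is not None:
                # longer lead-in moves a sub-stem's first junction clear of
                # its host stem before laterals sprout from it
                step *= 2.2
            first = False
            nxt = pos + d * step
            gen = depth - 1
            btype = "bronchus" if gen <= 1 else "bronchiole"
            b = self._add_branch(
                parent_id=prev.id if prev is not None else None,
                p0=pos,
                p1=nxt,
                btype=btype,
                lumen_radius=self._radius(gen),
                wall_thickness=p.wall_thickness_conducting,
                generation=gen,
                assembly=-1 - si,
            )
            self._register(b, conducting=True, trim=0.45 if depth == s["start"] and s["host"] is not None else 0.0)
            junctions[depth] = nxt
            dirs[depth] = d
            in_branch[depth] = b
            az = az + self.GOLDEN + self.rng.normal(0, 0.2)
            azimuths[depth] = az
            prev = b
            pos = nxt
            if depth == s["start"] and host_dir is not None:
                # after the lead-in, a sub-stem bends to run alongside its
                # host (monopodial side-stem), keeping a clear lateral shell
                d = _unit(0.35 * d + 0.65 * host_dir)
            d = self._jitter(d, 4.0)
            if depth not in s["slots"]:
                # a stub must clear its host's wall by a recognizable length
                stub_len = b.lumen_radius + p.wall_thickness_conducting + 45.0
                self._build_stub(
                    b, nxt, dirs[depth], depth, -1 - si, azimuth=az, length=stub_len
                )
        # terminal continuation stub keeps the last junction a true branching
        # vertex and gives the stem a capped blind end
        self._build_stub(prev, pos, d, s["last"] + 1, -1 - si, length=45.0, axial=True)
        stem_geo[si] = {
            "junctions": junctions,
            "dirs": dirs,
            "in_branch": in_branch,
            "azimuths": azimuths,
        }

    def _build_stub(
        self, parent, pos, d, depth, stem_marker, azimuth=None, length=45.0, axial=False
    ):
        p = self.p
        self._assembly += 1
        asm = self._assembly
        self._exempt = (stem_marker,)
        try:
            for k in range(60):
                if axial:
                    cand = self._jitter(d, 6.0)
                else:
                    az = (
                        azimuth + self.rng.normal(0, 0.3 + 0.1 * k)
                        if azimuth is not None
                        else self.rng.uniform(0, 2 * np.pi)
                    )
                    cand = _tilted(d, self.rng.uniform(50, 90), az)
                end = pos + cand * (length if k < 30 else length * 0.6)
                r = p.lumen_radius_floor_conducting if k < 45 else 11.0
                if self._clear_of_others(
                    pos + cand * (length * 0.5), end,
                    r, p.wall_thickness_conducting, asm, True,
                ):
                    b = self._add_branch(
                        parent_id=parent.id,
                        p0=pos,
                        p1=end,
                        btype="bronchiole",
                        lumen_radius=r,
                        wall_thickness=p.wall_thickness_conducting,
                        generation=depth,
                        capped=True,
                        assembly=asm,
                    )
                    self._register(b, conducting=True, trim=0.4)
                    return
            raise GeometryError("cannot place a conducting stub without collisions")
        finally:
            self._exempt = ()

    def _build_tb_assembly(self, tb, geo):
        """Terminal bronchiole with 1–2 transitional bronchioles, their
        entrances, alveolar ducts, and alveoli. Retried as a whole on
        collision."""
        p = self.p
        depth = tb["depth"]
        origin = geo["junctions"][depth]
        hdir = geo["dirs"][depth]
        parent = geo["in_branch"][depth]
        last_err = None
        for _attempt in range(120):
            mark_b = len(self.branches)
            mark_e = len(self.entrances)
            mark_a = len(self.alveoli)
            mark_c = len(self.capsules)
            mark_ac = len(self.alv_capsules)
            mark_id = self._acinus_id
            self._assembly += 1
            self._exempt = (-1 - tb["stem"],)
            try:
                self._try_tb_assembly(
                    tb, origin, hdir, parent, depth, self._assembly,
                    geo["azimuths"][depth], _attempt,
                )
                self._exempt = ()
                return
            except GeometryError as err:
                last_err = err
                del self.branches[mark_b:]
                del self.entrances[mark_e:]
                del self.alveoli[mark_a:]
                del self.capsules[mark_c:]
                del self.alv_capsules[mark_ac:]
                self._acinus_id = mark_id
                self._exempt = ()
        raise GeometryError(
            f"cannot place a terminal-bronchiole assembly at depth {depth}: {last_err}"
        )

    def _try_tb_assembly(self, tb, origin, hdir, parent, depth, asm, base_az, attempt):
        p = self.p
        rng = self.rng
        az = base_az + rng.normal(0, 0.3 + 0.1 * attempt)
        tb_dir = _tilted(hdir, rng.uniform(50, 90), az)
        # two radial tiers double the packing capacity of the shell of
        # acini surrounding a stem
        tier = 1.0 if rng.random() < 0.5 else 1.9
        tb_len = p.lateral_length * tier * rng.uniform(0.9, 1.1)
        tb_end = origin + tb_dir * tb_len
        gen = depth
        r_tb = max(p.lumen_radius_floor_conducting, self._radius(gen))
        if not self._clear_of_others(
            origin + tb_dir * (tb_len * 0.35),
            tb_end,
            r_tb,
            p.wall_thickness_conducting,
            asm,
            True,
        ):
            raise GeometryError("terminal bronchiole collides")
        b_tb = self._add_branch(
            parent_id=parent.id,
            p0=origin,
            p1=tb_end,
            btype="terminal_bronchiole",
            lumen_radius=r_tb,
            wall_thickness=p.wall_thickness_conducting,
            generation=gen,
            assembly=asm,
        )
        self._register(b_tb, conducting=True, trim=0.4)
        units = tb["units"]
        if len(units) == 2:
            plane_az = rng.uniform(0, 2 * np.pi)
            angles = [rng.uniform(28, 45), rng.uniform(28, 45)]
            dirs = [
                _tilted(tb_dir, angles[0], plane_az),
                _tilted(tb_dir, angles[1], plane_az + np.pi),
            ]
            trb_gen = gen + 1
        else:
            dirs = [_tilted(tb_dir, rng.uniform(15, 30), rng.uniform(0, 2 * np.pi))]
            trb_gen = gen  # unbranched continuation: no new generation
        for n_entr, d_trb in zip(units, dirs):
            self._build_trb(b_tb, tb_end, d_trb, trb_gen, n_entr, asm)

    def _build_trb(self, parent, pos, d, gen, n_entrances, asm):
        p = self.p
        rng = self.rng
        r = p.lumen_radius_transitional
        lc = p.trb_conducting_length * rng.uniform(0.9, 1.1)
        if n_entrances == 1:
            la = p.trb_acinar_length * rng.uniform(0.9, 1.1)
            end = pos + d * (lc + la)
            if not self._clear_of_others(pos, end, r, p.wall_thickness_conducting, asm, True):
                raise GeometryError("transitional bronchiole collides")
            tilt_az = rng.uniform(0, 2 * np.pi)
            b = self._add_branch(
                parent_id=parent.id,
                p0=pos,
                p1=end,
                btype="transitional_bronchiole",
                lumen_radius=r,
                wall_thickness=p.wall_thickness_conducting,
                generation=gen,
                t_transition=lc,
                wall_thickness_distal=p.wall_thickness_acinar,
                tilt_deg=p.transition_tilt_deg,
                tilt_azimuth=tilt_az,
                assembly=asm,
            )
            self._register(b, conducting=True)
            aid = self._acinus_id
            self._acinus_id += 1
            self.entrances.append(
                GroundTruthEntrance(
                    position_um=pos + d * lc,
                    branch_id=b.id,
                    acinus_id=aid,
                    generation=gen,
                    lumen_radius=r,
                )
            )
            duct_dir = self._jitter(d, 8.0)
            self._build_duct(b, end, duct_dir, gen, aid, asm, first=True, entrance_t=la)
        else:
            # branched transitional bronchiole: the branch point sits inside
            # the transition zone, its vertex wall is still thick, and each
            # daughter carries its own acinar entrance just distal of it
            end = pos + d * lc
            if not self._clear_of_others(pos, end, r, p.wall_thickness_conducting, asm, True):
                raise GeometryError("transitional bronchiole collides")
            b = self._add_branch(
                parent_id=parent.id,
                p0=pos,
                p1=end,
                btype="transitional_bronchiole",
                lumen_radius=r,
                wall_thickness=p.wall_thickness_conducting,
                generation=gen,
                assembly=asm,
            )
            self._register(b, conducting=True)
            aids = (self._acinus_id, self._acinus_id + 1)
            self._acinus_id += 2
            plane_az = rng.uniform(0, 2 * np.pi)
            offs = r + p.wall_thickness_conducting + 6.0
            for k in range(2):
                dd = _tilted(d, rng.uniform(33, 48), plane_az + k * np.pi)
                dlen = p.duct_length * rng.uniform(0.9, 1.1) + offs
                dend = end + dd * dlen
                # the shared base at the branch point is legitimate; only the
                # part beyond the entrance must clear foreign structures
                if not self._clear_of_others(
                    end + dd * offs, dend, p.lumen_radius_duct,
                    p.wall_thickness_acinar, asm, False, acinus=aids[k],
                ):
                    raise GeometryError("dual daughter collides")
                daughter = self._add_branch(
                    parent_id=b.id,
                    p0=end,
                    p1=dend,
                    btype="alveolar_duct",
                    lumen_radius=p.lumen_radius_duct,
                    wall_thickness=p.wall_thickness_conducting,
                    generation=gen,
                    t_transition=offs,
                    wall_thickness_distal=p.wall_thickness_acinar,
                    capped=True,
                    assembly=asm,
                )
                self._register(daughter, conducting=False, trim=0.45, acinus=aids[k])
                self.entrances.append(
                    GroundTruthEntrance(
                        position_um=end + dd * offs,
                        branch_id=b.id,
                        acinus_id=aids[k],
                        generation=gen,
                        lumen_radius=p.lumen_radius_duct,
                        dual_of=aids[1 - k],
                    )
                )
                # alveoli face away from the sibling daughter so they never
                # carve into its still-conducting wall near the branch point
                away = dd - d * float(dd @ d)
                away /= np.linalg.norm(away)
                de1, de2 = _perp_frame(dd)
                az_away = float(np.arctan2(away @ de2, away @ de1))
                self._place_alveoli(
                    daughter,
                    aids[k],
                    t_from=offs + 0.9 * p.alveolus_radius,
                    az_center=az_away,
                    az_halfwidth=np.pi / 2,
                )

    def _build_duct(self, parent, pos, d, gen, acinus_id, asm, first=False, entrance_t=None):
        p = self.p
        dlen = p.duct_length * self.rng.uniform(0.9, 1.1)
        end = pos + d * dlen
        if not self._clear_of_others(
            pos, end, p.lumen_radius_duct, p.wall_thickness_acinar, asm, False,
            acinus=acinus_id,
        ):
            raise GeometryError("alveolar duct collides")
        b = self._add_branch(
            parent_id=parent.id,
            p0=pos,
            p1=end,
            btype="alveolar_duct",
            lumen_radius=p.lumen_radius_duct,
            wall_thickness=p.wall_thickness_acinar,
            generation=gen,
            capped=True,
            assembly=asm,
        )
        self._register(b, conducting=False, acinus=acinus_id)
        if first and entrance_t is not None:
            # the most proximal alveoli sit on the transitional bronchiole
            # itself, directly distal of the transition
            self._place_alveoli(parent, acinus_id, t_from=parent.t_transition + p.alveolus_radius * 0.9, n=2)
        self._place_alveoli(b, acinus_id)
        # terminal sac at the duct end
        sac = Alveolus(center=end, radius=p.alveolus_radius, acinus_id=acinus_id)
        self.alveoli.append(sac)
        self.alv_capsules.append(
            (end, p.alveolus_radius, p.wall_thickness_acinar, asm, acinus_id)
        )

    def _place_alveoli(
        self,
        b: Branch,
        acinus_id: int,
        t_from: float = 6.0,
        n: Optional[int] = None,
        az_center: Optional[float] = None,
        az_halfwidth: float = np.pi,
    ):
        p = self.p
        a = p.alveolus_radius
        n = p.alveoli_per_acinus if n is None else n
        d = b.direction
        e1, e2 = _perp_frame(d)
        t = t_from
        placed = 0
        az = (
            az_center + self.rng.uniform(-az_halfwidth, az_halfwidth)
            if az_center is not None
            else self.rng.uniform(0, 2 * np.pi)
        )
        golden = 2.399963 if az_center is None else az_halfwidth * 0.77
        while placed < n and t < b.length - 2.0:
            center = b.p0 + d * t + (np.cos(az) * e1 + np.sin(az) * e2) * b.lumen_radius
            ok = False
            for _ in range(12):
                if self._alveolus_clear(center, a, b.assembly, acinus_id):
                    ok = True
                    break
                az += golden
                center = b.p0 + d * t + (np.cos(az) * e1 + np.sin(az) * e2) * b.lumen_radius
            if ok:
                self.alveoli.append(Alveolus(center=center, radius=a, acinus_id=acinus_id))
                self.alv_capsules.append(
                    (center, a, p.wall_thickness_acinar, b.assembly, acinus_id)
                )
                placed += 1
            t += a * 1.2
            az += golden
            if az_center is not None:
                az = az_center + (az - az_center + az_halfwidth) % (
                    2 * az_halfwidth
                ) - az_halfwidth


def generate_airway_tree(params: TreeParams) -> AirwayTreeSpec:
    """Grow a seeded monopodial airway tree with the requested number of
    acinar entrances spread over the configured intralobar generations.

    Deterministic for a fixed parameter set. Raises :class:`GeometryError`
    when the tree cannot be embedded without collisions.
    """
    return _Builder(params).build()


# ---------------------------------------------------------------------------
# voxelization


class _Painter:
    def __init__(self, shape, origin_um, voxel_size):
        self.shape = shape
        self.origin = origin_um
        self.v = voxel_size

    def _subbox(self, lo_um, hi_um):
        lo = np.floor((lo_um - self.origin) / self.v).astype(int) - 1
        hi = np.ceil((hi_um - self.origin) / self.v).astype(int) + 2
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, self.shape)
        if np.any(hi <= lo):
            return None
        return tuple(slice(a, b) for a, b in zip(lo, hi))

    def segment_fields(self, p0, p1, reach):
        """Axial coordinate t (µm), radial distance (µm) and the radial
        offset vector components for every voxel near the segment."""
        lo = np.minimum(p0, p1) - reach
        hi = np.maximum(p0, p1) + reach
        sl = self._subbox(lo, hi)
        if sl is None:
            return None
        idx = np.indices([s.stop - s.start for s in sl], dtype=np.float32)
        coords = [
            (idx[k] + sl[k].start) * self.v + self.origin[k] for k in range(3)
        ]
        d = p1 - p0
        length = np.linalg.norm(d)
        dn = d / length
        rel = [coords[k] - p0[k] for k in range(3)]
        t = sum(rel[k] * dn[k] for k in range(3))
        tc = np.clip(t, 0.0, length)
        radial2 = sum((rel[k] - tc * dn[k]) ** 2 for k in range(3))
        return sl, t, np.sqrt(radial2), rel, dn, length

    def ball_fields(self, center, reach):
        sl = self._subbox(center - reach, center + reach)
        if sl is None:
            return None
        idx = np.indices([s.stop - s.start for s in sl], dtype=np.float32)
        coords = [
            (idx[k] + sl[k].start) * self.v + self.origin[k] for k in range(3)
        ]
        dist = np.sqrt(sum((coords[k] - center[k]) ** 2 for k in range(3)))
        return sl, dist


def _transition_cut(branch: Branch, t, rel, dn):
    """Oblique elliptical transition: the cut position varies with azimuth by
    tan(tilt)·(radial offset along the tilt azimuth)."""
    t0 = branch.t_transition
    if branch.tilt_deg <= 0:
        return t0 * np.ones_like(t)
    e1, e2 = _perp_frame(dn)
    ca, sa = np.cos(branch.tilt_azimuth), np.sin(branch.tilt_azimuth)
    axis = ca * e1 + sa * e2
    off = sum(rel[k] * axis[k] for k in range(3)) - 0.0
    return t0 + np.tan(np.deg2rad(branch.tilt_deg)) * off


def voxelize_tree(
    tree: AirwayTreeSpec,
    voxel_size: float,
    noise_sd: float = 10.0,
    seed: int = 0,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
) -> PhantomVolume:
    """Render a tree into an 8-bit grayscale stack with ground-truth masks.

    Tissue is bright (200), air dark (30), with clipped Gaussian noise.
    Conducting walls are rendered at their conducting thickness, acinar walls
    thin, alveoli as hemispherical outpocketings with thin shells. The
    conducting/acinar lumen split follows the (oblique) transition plane at
    every entrance. Identical tree + seed + voxel size give a bit-identical
    stack.
    """
    p = tree.params
    if voxel_size > p.wall_thickness_conducting / 2:
        raise ValueError(
            "voxel_size must not exceed half the conducting wall thickness "
            f"({p.wall_thickness_conducting / 2:.2f} µm) or conducting walls "
            "would not be resolvable"
        )
    margin = p.cortex_thickness
    pts = []
    for b in tree.branches:
        reach = b.lumen_radius + max(b.wall_thickness, p.wall_thickness_conducting)
        pts.append(b.p0 - reach)
        pts.append(b.p1 + reach)
    for a in tree.alveoli:
        reach = a.radius + p.wall_thickness_acinar
        pts.append(a.center - reach)
        pts.append(a.center + reach)
    pts = np.array(pts)
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    lo[0] = 0.0  # the root enters the volume at the z=0 face (hilum)
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    if int(np.prod(shape)) > voxel_budget:
        raise ValueError(
            f"phantom volume {tuple(int(s) for s in shape)} exceeds the voxel "
            f"budget of {voxel_budget} voxels"
        )
    shape = tuple(int(s) for s in shape)
    origin = lo
    painter = _Painter(shape, origin, voxel_size)

    wall = np.zeros(shape, dtype=bool)
    lumen_cond = np.zeros(shape, dtype=bool)
    lumen_acin = np.zeros(shape, dtype=bool)

    # pass 1: walls
    for b in tree.branches:
        reach = b.lumen_radius + max(b.wall_thickness, b.wall_thickness_distal or 0)
        f = painter.segment_fields(b.p0, b.p1, reach + voxel_size)
        if f is None:
            continue
        sl, t, rad, rel, dn, length = f
        inside = (t >= 0) & (t <= length)
        if b.t_transition is None:
            w = b.wall_thickness
            m = inside & (rad > b.lumen_radius) & (rad <= b.lumen_radius + w)
        else:
            cut = _transition_cut(b, t, rel, dn)
            w_prox, w_dist = b.wall_thickness, b.wall_thickness_distal
            m = inside & (rad > b.lumen_radius) & (
                ((t < cut) & (rad <= b.lumen_radius + w_prox))
                | ((t >= cut) & (rad <= b.lumen_radius + w_dist))
            )
        wall[sl] |= m
        if b.capped:
            fb = painter.ball_fields(b.p1, b.lumen_radius + b.wall_thickness + voxel_size)
            if fb is not None:
                slb, dist = fb
                w_end = (
                    b.wall_thickness_distal
                    if b.wall_thickness_distal is not None
                    else b.wall_thickness
                )
                wall[slb] |= dist <= b.lumen_radius + w_end
        # junction sphere closes the wedge gap where jointed cylinders meet
        fb = painter.ball_fields(b.p0, b.lumen_radius + b.wall_thickness + voxel_size)
        if fb is not None:
            slb, dist = fb
            wall[slb] |= dist <= b.lumen_radius + b.wall_thickness
    # thick branch-point vertex of dual-entrance transitional bronchioles
    children: dict[int, list[Branch]] = {}
    for b in tree.branches:
        if b.parent_id is not None:
            children.setdefault(b.parent_id, []).append(b)
    for b in tree.branches:
        if b.btype == "transitional_bronchiole" and len(children.get(b.id, [])) == 2:
            fb = painter.ball_fields(
                b.p1, b.lumen_radius + b.wall_thickness + voxel_size
            )
            if fb is not None:
                slb, dist = fb
                wall[slb] |= dist <= b.lumen_radius + b.wall_thickness
    for a in tree.alveoli:
        fb = painter.ball_fields(a.center, a.radius + p.wall_thickness_acinar + voxel_size)
        if fb is not None:
            slb, dist = fb
            wall[slb] |= dist <= a.radius + p.wall_thickness_acinar

    # pass 2: carve lumens (air wins over any wall painted across it)
    for b in tree.branches:
        f = painter.segment_fields(b.p0, b.p1, b.lumen_radius + voxel_size)
        if f is None:
            continue
        sl, t, rad, rel, dn, length = f
        inside = (t >= 0) & (t <= length) & (rad <= b.lumen_radius)
        if b.t_transition is None:
            if b.btype == "alveolar_duct":
                lumen_acin[sl] |= inside
            else:
                lumen_cond[sl] |= inside
        else:
            cut = _transition_cut(b, t, rel, dn)
            lumen_cond[sl] |= inside & (t < cut)
            lumen_acin[sl] |= inside & (t >= cut)
        # lumen sphere at the proximal node completes the joint
        fb = painter.ball_fields(b.p0, b.lumen_radius + voxel_size)
        if fb is not None:
            slb, dist = fb
            ball = dist <= b.lumen_radius
            proximal_acinar = b.btype == "alveolar_duct" and b.t_transition is None
            if proximal_acinar:
                lumen_acin[slb] |= ball
            else:
                lumen_cond[slb] |= ball
    for a in tree.alveoli:
        fb = painter.ball_fields(a.center, a.radius + voxel_size)
        if fb is not None:
            slb, dist = fb
            lumen_acin[slb] |= dist <= a.radius

    lumen = lumen_cond | lumen_acin
    tissue = wall & ~lumen
    lumen_cond &= ~lumen_acin  # acinar wins the sliver where both were carved

    # watertightness: boolean composition of shells can leave sub-voxel
    # pinholes at seams (e.g., where an alveolar shell meets a wall edge);
    # seal any outside-air voxel face-adjacent to the lumen
    from scipy import ndimage as _ndi

    outside_air = ~tissue & ~lumen
    pinholes = (
        _ndi.binary_dilation(lumen, _ndi.generate_binary_structure(3, 1))
        & outside_air
    )
    pinholes[0] = False  # the root opening at the z=0 face stays open
    tissue |= pinholes

    rng = np.random.default_rng(seed)
    gray = np.where(tissue, float(TISSUE_GRAY), float(AIR_GRAY))
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, size=shape)
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)

    truth = []
    for e in tree.entrances:
        vox = np.rint((e.position_um - origin) / voxel_size).astype(int)
        vox = np.minimum(np.maximum(vox, 0), np.array(shape) - 1)
        truth.append(
            GroundTruthEntrance(
                position_um=e.position_um,
                branch_id=e.branch_id,
                acinus_id=e.acinus_id,
                generation=e.generation,
                lumen_radius=e.lumen_radius,
                dual_of=e.dual_of,
                position=tuple(int(c) for c in vox),
            )
        )

    return PhantomVolume(
        stack=ImageStack(gray, voxel_size),
        tissue_mask=tissue,
        conducting_mask=lumen_cond,
        acinar_mask=lumen_acin,
        truth=truth,
        params=p,
        tree=tree,
        origin_um=origin,
    )


def generate_phantom(
    params: TreeParams,
    voxel_size: float = 2.35,
    noise_sd: float = 10.0,
    noise_seed: Optional[int] = None,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
) -> PhantomVolume:
    """Grow a tree and render it in one step (noise seed defaults to the
    tree seed)."""
    tree = generate_airway_tree(params)
    return voxelize_tree(
        tree,
        voxel_size,
        noise_sd=noise_sd,
        seed=params.seed if noise_seed is None else noise_seed,
        voxel_budget=voxel_budget,
    )


def save_phantom(ph: PhantomVolume, outdir: str | Path) -> None:
    """Write the stack as multi-page TIFF plus a ground-truth JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(ph.stack, out / "phantom.tif")
    meta = {
        "voxel_size_um": ph.stack.voxel_size,
        "n_acini": ph.n_acini,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(ph.params).items()
        },
        "entrances": [
            {
                "acinus_id": e.acinus_id,
                "position_zyx": list(e.position),
                "generation": e.generation,
                "dual_of": e.dual_of,
            }
            for e in ph.truth
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
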