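"""Stereological estimators for acinar numbers and volumes.

The counting method yields the exact number of acini in one lung lobe
(typically the right middle lobe, RML). Scaling that count to the whole lung
and to the other lobes uses parenchymal volumes: per-lobe water-displacement
volumes multiplied by per-lobe parenchyma volume densities. The acinar
airspace volume additionally uses the volume density of airspace within
parenchyma. A Cavalieri point-counting estimator measures lobe volume on the
tomographic stack itself, which — compared against fresh water displacement —
quantifies embedding shrinkage.

Volume conventions: lobe volumes in mL, acinar volumes in µL
(1 mL = 1000 µL), image dimensions in µm (1 mL = 1e12 µm³).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "LobeRecord",
    "EstimateSet",
    "PARENCHYMA_DENSITY",
    "AIRSPACE_DENSITY",
    "cavalieri_volume",
    "shrinkage_pct",
    "acinar_volumes",
    "estimate_total_acini",
    "estimate_lobe_acini",
    "matching_accuracy",
]

ML_PER_UM3 = 1e-12
UL_PER_ML = 1e3

#: Volume density of parenchyma per lobe (point counting, ATS guidelines):
#: right upper lobe, right middle lobe, right lower lobe, cardiac lobe, left lung.
PARENCHYMA_DENSITY: Mapping[str, float] = {
    "RUL": 0.888,
    "RML": 0.839,
    "RLL": 0.843,
    "LC": 0.865,
    "LL": 0.862,
}

#: Volume density of airspace within parenchyma (single global value).
AIRSPACE_DENSITY = 0.658

LOBES = tuple(PARENCHYMA_DENSITY)


@dataclass
class LobeRecord:
    """Per-lobe measurements feeding the estimators.

    Parameters
    ----------
    lobe : one of RUL, RML, RLL, LC, LL.
    v_wd : fresh lobe volume by water displacement [mL]. All scaling
        calculations use water-displacement volumes so that embedding
        shrinkage cannot bias them.
    d_parenchyma : volume density of parenchyma in the lobe (fraction).
    d_airspace : volume density of airspace within parenchyma (fraction).
    v_cavalieri : optional lobe volume measured on the tomographic dataset
        by the Cavalieri principle [mL]; used only for shrinkage.
    n_counted : optional exhaustively counted number of acini in the lobe.
    """

    lobe: str
    v_wd: float
    d_parenchyma: Optional[float] = None
    d_airspace: float = AIRSPACE_DENSITY
    v_cavalieri: Optional[float] = None
    n_counted: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}; expected one of {LOBES}")
        if self.d_parenchyma is None:
            self.d_parenchyma = PARENCHYMA_DENSITY[self.lobe]
        if not 0 < self.d_parenchyma <= 1:
            raise ValueError("d_parenchyma must be in (0, 1]")
        if not 0 < self.d_airspace <= 1:
            raise ValueError("d_airspace must be in (0, 1]")
        if self.v_wd <= 0:
            raise ValueError("v_wd must be positive")
        if self.v_cavalieri is not None and self.v_cavalieri <= 0:
            raise ValueError("v_cavalieri must be positive")

    @property
    def v_parenchyma(self) -> float:
        """Parenchymal volume [mL]."""
        return self.v_wd * self.d_parenchyma


@dataclass
class EstimateSet:
    """Derived quantities for one lung: acinar volumes and scaled counts."""

    v_acinar_airspace_ul: float
    v_acinar_mean_ul: float
    n_total_lung: int
    n_estimated_per_lobe: dict[str, int] = field(default_factory=dict)
    matching_accuracy_pct: dict[str, float] = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cavalieri_volume(
    mask: np.ndarray,
    voxel_size: float,
    section_period: int,
    grid_spacing: float,
    seed: Optional[int] = None,
    offsets: Optional[tuple[float, float, float]] = None,
) -> float:
    """Cavalieri volume estimate of a binary structure in a voxel grid [mL].

    A systematic uniform random point grid with spacing ``grid_spacing`` (µm)
    is laid over every ``section_period``-th section; the estimate is
    V = ΣP · a(p) · t with a(p) = grid_spacing² and t = section_period ·
    voxel_size.

    Parameters
    ----------
    mask : 3D boolean array (z, y, x); True voxels belong to the structure.
    voxel_size : isometric voxel side length [µm].
    section_period : take every k-th section.
    grid_spacing : point grid spacing [µm]; must be >= voxel_size.
    seed : seeds the uniform random grid offset.
    offsets : explicit (z, y, x) offsets in voxels, overriding ``seed``;
        z offset in [0, section_period), y/x in [0, grid_spacing/voxel_size).
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if grid_spacing < voxel_size:
        raise ValueError("grid_spacing must be >= voxel_size")
    if section_period < 1:
        raise ValueError("section_period must be >= 1")
    g = grid_spacing / voxel_size  # grid spacing in voxels
    if offsets is None:
        rng = np.random.default_rng(seed)
        offsets = (
            float(rng.uniform(0, section_period)),
            float(rng.uniform(0, g)),
            float(rng.uniform(0, g)),
        )
    oz, oy, ox = offsets
    nz, ny, nx = mask.shape
    zs = np.arange(int(oz), nz, section_period)
    ys = np.rint(np.arange(oy, ny, g)).astype(int)
    xs = np.rint(np.arange(ox, nx, g)).astype(int)
    ys = ys[ys < ny]
    xs = xs[xs < nx]
    hits = int(mask[np.ix_(zs, ys, xs)].sum())
    if hits == 0:
        raise ValueError(
            "no grid points hit the structure; use a finer grid_spacing or "
            "section_period"
        )
    v_um3 = hits * grid_spacing**2 * (section_period * voxel_size)
    return v_um3 * ML_PER_UM3


def shrinkage_pct(v_wd: float, v_cavalieri: float) -> float:
    """Volume shrinkage 100·(1 − V_cavalieri/V_wd) between the fresh lobe
    (water displacement) and the embedded, scanned lobe (Cavalieri) [%].

    A negative value (swelling) is returned but flagged with a warning.
    """
    if v_wd <= 0 or v_cavalieri <= 0:
        raise ValueError("volumes must be positive")
    s = 100.0 * (1.0 - v_cavalieri / v_wd)
    if s < 0:
        warnings.warn(
            f"negative shrinkage ({s:.2f}%): Cavalieri volume exceeds "
            "water-displacement volume (swelling?)",
            stacklevel=2,
        )
    return s


def acinar_volumes(rec: LobeRecord) -> tuple[float, float]:
    """Mean acinar airspace volume and mean acinar volume of a counted lobe [µL].

    airspace: V_wd · d_airspace / n_counted;
    mean (tissue + airspace): V_wd · d_parenchyma / n_counted.
    """
    if not rec.n_counted:
        raise ValueError(f"lobe {rec.lobe}: n_counted missing")
    v_air = rec.v_wd * rec.d_airspace / rec.n_counted * UL_PER_ML
    v_mean = rec.v_wd * rec.d_parenchyma / rec.n_counted * UL_PER_ML
    return v_air, v_mean


def estimate_total_acini(counted: LobeRecord, all_lobes: Sequence[LobeRecord]) -> int:
    """Total acini per lung: the counted lobe's acini per parenchymal volume
    scaled by the total parenchymal lung volume, rounded half-up."""
    if not counted.n_counted:
        raise ValueError("counted lobe must carry n_counted")
    if counted.lobe not in {r.lobe for r in all_lobes}:
        raise ValueError(f"counted lobe {counted.lobe} absent from all_lobes")
    total_parenchyma = sum(r.v_parenchyma for r in all_lobes)
    return _round_half_up(counted.n_counted / counted.v_parenchyma * total_parenchyma)


def estimate_lobe_acini(target: LobeRecord, v_acinar_mean_ref: float) -> int:
    """Acini in a lobe from its parenchymal volume and a reference mean
    acinar volume [µL], rounded half-up."""
    if v_acinar_mean_ref <= 0:
        raise ValueError("v_acinar_mean_ref must be positive")
    return _round_half_up(target.v_parenchyma * UL_PER_ML / v_acinar_mean_ref)


def matching_accuracy(estimated: float, counted: float) -> float:
    """Estimated over counted number of acini, as a percentage."""
    if counted <= 0:
        raise ValueError("counted must be positive")
    return 100.0 * estimated / counted
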