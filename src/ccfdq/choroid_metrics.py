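"""Choroidal thickness measurement and sector annotation.

Choroidal thickness (CT) is the axial distance between the outer border of
Bruch's membrane (BM) and the inner border of the sclera, sampled at five
points per eye: the sub-foveal center (cCT) and the center of each corner
square.  An optional tilt correction multiplies the axial gap by the cosine
of the local BM inclination (plane fit over a 5 px radius), approximating a
measurement perpendicular to the surface tangent; it is off by default
since at macular scale the correction is below measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, Sector


@dataclass
class CTSurfaces:
    """Paired depth maps (um) bounding the choroid, aligned to the en-face grid."""

    bm_outer_depth: np.ndarray
    sclera_inner_depth: np.ndarray
    fovea_center_px: tuple[float, float]
    pitch_um: float = 6000.0 / 1024.0

    def __post_init__(self) -> None:
        self.bm_outer_depth = np.asarray(self.bm_outer_depth, dtype=np.float64)
        self.sclera_inner_depth = np.asarray(self.sclera_inner_depth, dtype=np.float64)
        if self.bm_outer_depth.shape != self.sclera_inner_depth.shape:
            raise ValueError("boundary surfaces must share a shape")
        if not np.all(self.sclera_inner_depth > self.bm_outer_depth):
            raise ValueError("inner sclera must lie below the outer BM border everywhere")


@dataclass(frozen=True)
class CTSample:
    location: str  # "fovea" or "sector-1".."sector-4"
    ct_um: float

    def __post_init__(self) -> None:
        if self.ct_um <= 0:
            raise ValueError("choroidal thickness must be positive")


def _bm_tilt_cos(surfaces: CTSurfaces, row: int, col: int, radius_px: int = 5) -> float:
    """cos of the BM inclination from a least-squares plane over a disk patch."""
    h, w = surfaces.bm_outer_depth.shape
    r0, r1 = max(0, row - radius_px), min(h, row + radius_px + 1)
    c0, c1 = max(0, col - radius_px), min(w, col + radius_px + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    keep = (rr - row) ** 2 + (cc - col) ** 2 <= radius_px**2
    y = surfaces.bm_outer_depth[rr[keep], cc[keep]]
    # plane z = a*row_um + b*col_um + c; slopes are um of depth per um lateral
    x_um = np.column_stack(
        [rr[keep] * surfaces.pitch_um, cc[keep] * surfaces.pitch_um, np.ones(keep.sum())]
    )
    coef, *_ = np.linalg.lstsq(x_um, y, rcond=None)
    a, b = coef[0], coef[1]
    return 1.0 / np.sqrt(1.0 + a * a + b * b)


def measure_ct(
    surfaces: CTSurfaces,
    point_px: tuple[float, float],
    location: str = "sector",
    tilt_correction: bool = False,
) -> CTSample:
    """CT at one point: axial sclera-BM gap, optionally tilt-corrected."""
    row, col = int(round(point_px[0])), int(round(point_px[1]))
    h, w = surfaces.bm_outer_depth.shape
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError("measurement point lies outside the raster")
    ct = float(surfaces.sclera_inner_depth[row, col] - surfaces.bm_outer_depth[row, col])
    if ct <= 0:
        raise ValueError("non-positive choroidal thickness at the measurement point")
    if tilt_correction:
        ct *= _bm_tilt_cos(surfaces, row, col)
    return CTSample(location=location, ct_um=ct)


def _flag_from_mask(mask: BinaryMask | np.ndarray | None, sector: Sector) -> bool:
    """A sector is positive iff at least one mask pixel lies inside it."""
    if mask is None:
        return False
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    return bool(pixels[sector.slice()].any())


def annotate_sectors(
    records: list[dict],
    sectors: list[Sector],
    lcv: BinaryMask | np.ndarray | dict | None = None,
    drusen: BinaryMask | np.ndarray | dict | None = None,
) -> list[dict]:
    """Attach binary LCV / drusen flags to sector records.

    Flags may come as rasters (any-pixel-inside rule, matching the
    "drusen of any size" convention) or as precomputed per-sector
    dictionaries keyed by sector index.
    """
    by_index = {s.index: s for s in sectors}
    out = []
    for rec in records:
        sector = by_index.get(rec["sector"])
        if sector is None:
            raise ValueError(f"record references unknown sector {rec['sector']}")
        rec = dict(rec)
        for name, source in (("lcv", lcv), ("drusen", drusen)):
            if isinstance(source, dict):
                rec[name] = bool(source[rec["sector"]])
            else:
                rec[name] = _flag_from_mask(source, sector)
        out.append(rec)
    return out
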