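"""Core data containers shared across the pipeline.

The unit of every image operation is an :class:`EnFaceImage`: a square
grayscale en-face projection of a choriocapillaris (CC) slab with a known
physical pixel pitch.  Binary rasters (vessel exclusions, large-choroidal-
vessel and drusen annotations, sector windows) are carried as
:class:`BinaryMask`.  Quantification results flow through
:class:`FDComponent` (one connected flow-deficit region) and
:class:`SectorRecord` (one 1x1 mm corner square), which is the row type of
the statistical layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Laterality = Literal["OD", "OS"]
ImageKind = Literal["angio", "structural"]
Orientation = Literal["nasal", "temporal"]


@dataclass(frozen=True)
class SlabSpec:
    """Depth window of the en-face projection, relative to the RPE-fit line.

    ``offset_um`` is the distance below the RPE-fit reference at which the
    slab starts, ``thickness_um`` its axial extent.  The two settings used
    throughout are 10 um @ 31 um and 20 um @ 29 um.
    """

    offset_um: float
    thickness_um: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("slab thickness must be positive")
        if self.offset_um < 0:
            raise ValueError("slab offset must be non-negative")


SLAB_10_AT_31 = SlabSpec(offset_um=31.0, thickness_um=10.0)
SLAB_20_AT_29 = SlabSpec(offset_um=29.0, thickness_um=20.0)


@dataclass
class EnFaceImage:
    """A 2-D grayscale en-face slab image with physical pixel pitch.

    Intensities are stored normalized to [0, 1] (by the source dtype's full
    range, not the per-image maximum, so thresholds stay portable across
    scans).
    """

    pixels: np.ndarray
    pitch_um: float
    laterality: Laterality
    kind: ImageKind
    slab: SlabSpec = SLAB_10_AT_31

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("en-face image must be a square 2-D array")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError("intensities must be normalized to [0, 1]")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.kind not in ("angio", "structural"):
            raise ValueError(f"unknown image kind {self.kind!r}")

    @property
    def size_px(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray, kind: ImageKind | None = None) -> "EnFaceImage":
        return EnFaceImage(
            pixels=pixels,
            pitch_um=self.pitch_um,
            laterality=self.laterality,
            kind=self.kind if kind is None else kind,
            slab=self.slab,
        )


MaskSemantics = Literal["vessel-exclusion", "lcv", "drusen", "sector", "fd"]


@dataclass
class BinaryMask:
    """A boolean raster aligned to an image grid, with a semantics label."""

    pixels: np.ndarray
    semantics: MaskSemantics

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FDComponent:
    """One connected flow-deficit region (a 'particle')."""

    id: int
    pixel_count: int
    area_um2: float
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("a component has at least one pixel")


@dataclass(frozen=True)
class Sector:
    """One 1x1 mm corner square: pixel bounds plus its topographic label.

    ``rows`` / ``cols`` are half-open intervals; ``orientation`` is nasal or
    temporal depending on laterality (the vertical position is recorded in
    ``position`` but not modelled).
    """

    index: int  # 1..4
    rows: tuple[int, int]
    cols: tuple[int, int]
    orientation: Orientation
    position: Literal["superior", "inferior"]

    @property
    def center_px(self) -> tuple[float, float]:
        return (
            (self.rows[0] + self.rows[1] - 1) / 2.0,
            (self.cols[0] + self.cols[1] - 1) / 2.0,
        )

    @property
    def side_px(self) -> int:
        return self.rows[1] - self.rows[0]

    def slice(self) -> tuple[slice, slice]:
        return slice(*self.rows), slice(*self.cols)


@dataclass
class SectorRecord:
    """Measurements of one corner square of one eye."""

    eye_id: str
    group: str
    sector: int
    orientation: Orientation
    fd_percent: float
    ct_um: float
    lcv: bool
    drusen: bool
    valid_px: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fd_percent <= 100.0:
            raise ValueError("FD% must lie in [0, 100]")
        if self.valid_px <= 0:
            raise ValueError("a sector record needs at least one valid pixel")


@dataclass
class Masked:
    """An array with a per-pixel validity channel.

    Excluded (invalid) pixels are never counted as flow deficit nor in any
    denominator downstream.
    """

    data: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape:
            raise ValueError("data and validity channel must share a shape")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())
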