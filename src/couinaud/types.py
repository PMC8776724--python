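"""Core domain containers shared across the package.

All world coordinates are in millimetres, RAS+ convention (x → patient
right, y → anterior, z → superior), matching the native NIfTI frame.
Voxel grids carry a 4x4 affine mapping voxel index (i, j, k, 1) to world
(x, y, z, 1); the absolute determinant of its 3x3 block is the voxel
volume in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "SEGMENT_CODES",
    "SEGMENT_NAMES",
    "LiverMask",
    "LandmarkSet",
    "SegmentLabelMap",
    "QuantMap",
    "QuantSlice",
    "SegmentStats",
    "SegmentReport",
    "voxel_volume_mm3",
]

#: The eight anatomical landmarks that define the intersegmental planes.
LANDMARK_NAMES = (
    "ivc_superior",
    "ivc_inferior",
    "middle_hepatic_vein",
    "gallbladder_fossa",
    "right_hepatic_vein",
    "umbilical_fissure",
    "right_portal_vein",
    "left_portal_vein",
)

#: Integer label codes for the nine Couinaud segments.  Segments 4a/4b are
#: encoded as 41/42 so the labelmap stays a single-integer NIfTI volume.
SEGMENT_CODES = (1, 2, 3, 41, 42, 5, 6, 7, 8)

SEGMENT_NAMES = {
    1: "1",
    2: "2",
    3: "3",
    41: "4a",
    42: "4b",
    5: "5",
    6: "6",
    7: "7",
    8: "8",
}


class CouinaudError(Exception):
    """Base class for errors raised by this package."""


class NonVolumeImageError(CouinaudError):
    """The NIfTI image is not a 3D volume."""


class EmptyMaskError(CouinaudError):
    """The liver mask contains no foreground voxel."""


class LandmarkSchemaError(CouinaudError):
    """The landmark file is missing/adding names or violates the schema."""


class DegenerateGeometryError(CouinaudError):
    """A geometric construction is undefined (coincident points, etc.)."""


def voxel_volume_mm3(affine: np.ndarray) -> float:
    """Voxel volume in mm^3: |det| of the affine's 3x3 block."""
    return float(abs(np.linalg.det(np.asarray(affine, dtype=float)[:3, :3])))


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) <= 0.0:
        raise ValueError("affine 3x3 block is singular")
    return affine


@dataclass
class LiverMask:
    """Binary liver mask on a voxel grid with a voxel-to-world affine."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise NonVolumeImageError(
                f"mask grid must be 3D, got {self.grid.ndim}D"
            )
        self.grid = (self.grid > 0).astype(np.uint8)
        self.affine = _check_affine(self.affine)
        if not self.grid.any():
            raise EmptyMaskError("liver mask has no foreground voxel")

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.affine)

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


@dataclass
class LandmarkSet:
    """The eight named landmark points, world millimetres.

    ``points`` maps each name in :data:`LANDMARK_NAMES` to a length-3
    array.  The IVC superior/inferior pair must be distinct so the IVC
    axis is well defined.
    """

    points: dict
    space: str = "RAS"

    def __post_init__(self) -> None:
        names = set(self.points)
        missing = [n for n in LANDMARK_NAMES if n not in names]
        extra = sorted(names - set(LANDMARK_NAMES))
        if missing:
            raise LandmarkSchemaError(f"missing landmark: {missing[0]}")
        if extra:
            raise LandmarkSchemaError(f"unknown landmark: {extra[0]}")
        pts = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(self.points[name], dtype=float)
            if p.shape != (3,):
                raise LandmarkSchemaError(
                    f"landmark {name} must have 3 coordinates"
                )
            if not np.all(np.isfinite(p)):
                raise LandmarkSchemaError(f"non-finite coordinate in {name}")
            pts[name] = p
        if np.array_equal(pts["ivc_superior"], pts["ivc_inferior"]):
            raise DegenerateGeometryError(
                "ivc_superior equals ivc_inferior: IVC axis undefined"
            )
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Apply a rigid transform x -> R x + t to every landmark."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return LandmarkSet(
            points={n: R @ p + t for n, p in self.points.items()},
            space=self.space,
        )


@dataclass
class SegmentLabelMap:
    """Per-voxel Couinaud segment codes (0 = background)."""

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise NonVolumeImageError(
                f"labelmap grid must be 3D, got {self.grid.ndim}D"
            )
        self.grid = self.grid.astype(np.int16)
        self.affine = _check_affine(self.affine)
        codes = set(np.unique(self.grid).tolist())
        allowed = {0, *SEGMENT_CODES}
        bad = codes - allowed
        if bad:
            raise ValueError(f"labelmap contains invalid codes: {sorted(bad)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.affine)


@dataclass
class QuantSlice:
    """One 2D slice of a quantitative map with its own affine.

    The slice affine maps pixel index (i, j, 0, 1) to world mm.  The third
    affine column is the slice normal scaled by the slice spacing; the
    physical slab half-width is ``thickness / 2`` about the slice plane.
    """

    values: np.ndarray
    affine: np.ndarray
    thickness_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("slice values must be 2D")
        self.affine = _check_affine(self.affine)
        if not self.thickness_mm > 0:
            raise ValueError("slice thickness must be positive")

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]

    @property
    def normal(self) -> np.ndarray:
        n = self.affine[:3, 2]
        return n / np.linalg.norm(n)


@dataclass
class QuantMap:
    """Sparse multislice quantitative map (cT1 in ms or PDFF in %)."""

    modality: str
    slices: list

    VALID_MODALITIES = ("cT1", "PDFF")

    def __post_init__(self) -> None:
        if self.modality not in self.VALID_MODALITIES:
            raise ValueError(
                f"modality must be one of {self.VALID_MODALITIES}, "
                f"got {self.modality!r}"
            )
        if len(self.slices) < 1:
            raise ValueError("quantitative map needs at least one slice")
        for s in self.slices:
            finite = s.values[np.isfinite(s.values)]
            if self.modality == "cT1" and np.any(finite < 0):
                raise ValueError("cT1 values must be non-negative")
            if self.modality == "PDFF" and (
                np.any(finite < 0) or np.any(finite > 100)
            ):
                raise ValueError("PDFF values must lie in [0, 100]")


@dataclass
class SegmentStats:
    """Per-segment volumetry and optional quantitative-map medians."""

    code: int
    voxel_count: int
    volume_ml: float
    volume_fraction: float
    median_ct1_ms: Optional[float] = None
    ct1_voxel_count: int = 0
    median_pdff_pct: Optional[float] = None
    pdff_voxel_count: int = 0


@dataclass
class SegmentReport:
    """Volumetry (and map statistics) for the nine segments + whole liver.

    Segment volumes are voxel counts times the voxel volume, so the
    whole-liver volume equals the sum of segment volumes exactly and the
    volume fractions sum to one.
    """

    segments: dict
    total_voxel_count: int
    total_volume_ml: float
    whole_liver_median_ct1_ms: Optional[float] = None
    whole_liver_ct1_voxel_count: int = 0
    whole_liver_median_pdff_pct: Optional[float] = None
    whole_liver_pdff_voxel_count: int = 0
    voxel_volume_mm3: Optional[float] = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_CODES if c not in self.segments]
        if missing:
            raise ValueError(f"report missing segment codes: {missing}")
        nseg = sum(s.voxel_count for s in self.segments.values())
        if nseg != self.total_voxel_count:
            raise ValueError(
                "segment voxel counts do not sum to the whole-liver count"
            )
        frac = sum(s.volume_fraction for s in self.segments.values())
        if self.total_voxel_count > 0 and abs(frac - 1.0) > 1e-9:
            raise ValueError(f"volume fractions sum to {frac}, not 1")

    def volume_ml(self, code: int) -> float:
        return self.segments[code].volume_ml
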