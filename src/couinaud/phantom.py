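"""Synthetic liver phantoms: masks, landmarks, quantitative maps, pairs.

The phantom is a geometric stand-in for a liver, not an anatomically
realistic one: an ellipsoid (optionally with a smooth, seed-controlled
radial perturbation) voxelized on a grid with the typical reconstructed
resolution of 1.2 x 1.2 x 3.0 mm.  Landmarks are placed at fixed
anatomy-shaped fractions of the ellipsoid semi-axes (IVC axis along a
posterior-midline vertical chord, hepatic-vein points superior, the
gallbladder fossa anterior-inferior, the umbilical fissure
left-anterior-inferior, portal points mid-height), so every generated
set is valid input for plane construction and ground-truth segment
volumes are computable by supersampled labeling.  Quantitative maps are
generated with per-segment constant values plus Gaussian noise in the
acquisition geometry of the respective modality (cT1: 5 axial slices,
8 mm thick with a 12 mm gap; PDFF: 5 contiguous 20 mm slices).

All randomness is behind explicit integer seeds; no global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import build_planes
from .partition import classify_points
from .types import (
    SEGMENT_CODES,
    LandmarkSet,
    LiverMask,
    QuantMap,
    QuantSlice,
    SegmentLabelMap,
)

__all__ = [
    "PhantomSpec",
    "make_phantom_mask",
    "place_landmarks",
    "make_quantmap",
    "simulate_pairs",
    "true_segment_volumes",
]

#: Landmark placement as fractions of the semi-axes relative to the
#: ellipsoid centre (RAS: +x right, +y anterior, +z superior).
_LANDMARK_FRACTIONS = {
    "ivc_inferior": (0.0, -1 / 6, -2 / 3),
    "ivc_superior": (0.0, -1 / 6, 2 / 3),
    "middle_hepatic_vein": (0.0, 0.0, 8 / 15),
    "gallbladder_fossa": (0.0, 2 / 3, -8 / 15),
    "right_hepatic_vein": (4 / 9, 0.0, 2 / 5),
    "umbilical_fissure": (-5 / 18, 3 / 4, -7 / 15),
    "right_portal_vein": (1 / 3, 1 / 6, -1 / 15),
    "left_portal_vein": (-2 / 9, 1 / 12, 0.0),
}

#: Acquisition geometry per modality: (slice count, thickness mm, spacing mm).
MAP_GEOMETRY = {
    "cT1": (5, 8.0, 20.0),   # 8 mm thick, 12 mm gap
    "PDFF": (5, 20.0, 20.0),  # contiguous 20 mm slabs
}

#: Default per-segment map constants: healthy-range cT1 (ms) and PDFF (%),
#: distinct per segment so recovery of each median is checkable.
DEFAULT_CT1_MS = {1: 700.0, 2: 720.0, 3: 740.0, 41: 760.0, 42: 780.0,
                  5: 800.0, 6: 820.0, 7: 840.0, 8: 860.0}
DEFAULT_PDFF_PCT = {1: 2.0, 2: 3.0, 3: 4.0, 41: 5.0, 42: 6.0,
                    5: 7.0, 6: 8.0, 7: 9.0, 8: 10.0}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic liver.

    The defaults give a liver-sized ellipsoid (analytic volume about
    1.70 L) at the typical reconstructed voxel size.  ``perturb_amplitude``
    is the relative amplitude of a smooth random radial perturbation
    (0 = exact ellipsoid); ``map_noise_sd`` has map units (ms or %).
    """

    semi_axes_mm: tuple = (90.0, 60.0, 75.0)
    center_mm: tuple = (0.0, 10.0, 50.0)
    voxel_size_mm: tuple = (1.2, 1.2, 3.0)
    margin_mm: float = 12.0
    seed: int = 0
    perturb_amplitude: float = 0.0
    map_values: dict = field(default_factory=lambda: {
        "cT1": dict(DEFAULT_CT1_MS), "PDFF": dict(DEFAULT_PDFF_PCT)})
    map_noise_sd: dict = field(default_factory=lambda: {
        "cT1": 50.0, "PDFF": 1.0})

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


def _perturbation(spec: PhantomSpec):
    """Smooth random radial field p(u) on unit directions, |p| <= amplitude.

    A seeded linear + quadratic form of the direction vector: low order,
    hence smooth, and deterministic for a fixed seed.
    """
    amp = spec.perturb_amplitude
    if amp == 0.0:
        return lambda u: np.zeros(u.shape[0])
    rng = np.random.default_rng(spec.seed)
    g = rng.normal(size=3)
    H = rng.normal(size=(3, 3))
    H = (H + H.T) / 2.0
    scale = np.abs(g).sum() + np.abs(H).sum()  # bound |g.u + u'Hu| <= scale

    def p(u: np.ndarray) -> np.ndarray:
        raw = u @ g + np.einsum("ij,jk,ik->i", u, H, u)
        return amp * raw / scale

    return p


def make_phantom_mask(spec: PhantomSpec) -> LiverMask:
    """Voxelize the (perturbed) ellipsoid by centre inclusion."""
    a = np.asarray(spec.semi_axes_mm, dtype=float)
    c = np.asarray(spec.center_mm, dtype=float)
    vox = np.asarray(spec.voxel_size_mm, dtype=float)
    lo = c - a - spec.margin_mm
    hi = c + a + spec.margin_mm
    shape = np.ceil((hi - lo) / vox).astype(int)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vox)
    affine[:3, 3] = lo + vox / 2.0  # voxel (0,0,0) centre

    idx = np.indices(shape, dtype=float)
    world = idx.reshape(3, -1).T * vox + (lo + vox / 2.0)
    grid = _inside(world, spec).reshape(tuple(shape))

    fg = np.argwhere(grid)
    if fg.size and (fg.min() == 0 or np.any(fg.max(axis=0) == shape - 1)):
        warnings.warn("ellipsoid clipped by the phantom grid", stacklevel=2)
    return LiverMask(grid=grid.astype(np.uint8), affine=affine)


def _inside(world: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Membership test for world-mm points, including the perturbation."""
    a = np.asarray(spec.semi_axes_mm, dtype=float)
    c = np.asarray(spec.center_mm, dtype=float)
    rel = (world - c) / a
    r = np.linalg.norm(rel, axis=1)
    if spec.perturb_amplitude == 0.0:
        return r <= 1.0
    p = _perturbation(spec)
    u = np.zeros_like(rel)
    nz = r > 0
    u[nz] = rel[nz] / r[nz, None]
    return r <= 1.0 + p(u)


def place_landmarks(spec: PhantomSpec, mask: LiverMask | None = None
                    ) -> LandmarkSet:
    """Canonical anatomy-shaped landmark placement for the phantom."""
    a = np.asarray(spec.semi_axes_mm, dtype=float)
    c = np.asarray(spec.center_mm, dtype=float)
    points = {
        name: (c + np.asarray(frac) * a).tolist()
        for name, frac in _LANDMARK_FRACTIONS.items()
    }
    return LandmarkSet(points=points)


def make_quantmap(spec: PhantomSpec, labels: SegmentLabelMap,
                  modality: str) -> QuantMap:
    """Generate a multislice map over the labelled phantom.

    Five axial slices in the modality's acquisition geometry, centred on
    the liver's axial extent.  Pixel values are the per-segment constant
    plus Gaussian noise; pixels off the liver are missing (NaN).
    """
    if modality not in MAP_GEOMETRY:
        raise ValueError(f"unknown modality: {modality!r}")
    n_slices, thickness, spacing = MAP_GEOMETRY[modality]
    consts = spec.map_values[modality]
    noise_sd = spec.map_noise_sd[modality]
    rng = np.random.default_rng(spec.seed + (0 if modality == "cT1" else 1))

    fg = np.argwhere(labels.grid > 0)
    if fg.size == 0:
        raise ValueError("labelmap has no foreground")
    A, t = labels.affine[:3, :3], labels.affine[:3, 3]
    z_world = fg @ A[2] + t[2]
    z_lo, z_hi = float(z_world.min()), float(z_world.max())
    if (z_hi - z_lo) < thickness:
        warnings.warn("liver thinner than one slab", stacklevel=2)
    z_mid = (z_lo + z_hi) / 2.0
    slice_z = z_mid + (np.arange(n_slices) - (n_slices - 1) / 2.0) * spacing

    nx, ny = labels.grid.shape[:2]
    inv = np.linalg.inv(labels.affine)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    slices = []
    for z in slice_z:
        # pixel grid shares the volume's in-plane geometry at height z
        affine = labels.affine.copy()
        shift = (z - labels.affine[2, 3]) / labels.affine[2, 2]
        affine[:3, 3] = labels.affine[:3, 3] + shift * labels.affine[:3, 2]
        affine[:3, 2] = labels.affine[:3, 2] / labels.affine[2, 2] * spacing

        k = np.rint((z - t[2]) / A[2, 2]).astype(int)
        k = np.clip(k, 0, labels.grid.shape[2] - 1)
        seg = labels.grid[ii, jj, k]
        values = np.full((nx, ny), np.nan)
        for code in SEGMENT_CODES:
            m = seg == code
            if not m.any():
                continue
            v = consts[code] + rng.normal(0.0, noise_sd, size=int(m.sum()))
            if modality == "PDFF":
                v = np.clip(v, 0.0, 100.0)
            else:
                v = np.maximum(v, 0.0)
            values[m] = v
        slices.append(QuantSlice(values=values, affine=affine,
                                 thickness_mm=thickness))
    return QuantMap(modality=modality, slices=slices)


def simulate_pairs(true_values, bias_pct: float, sd_pct: float, n: int,
                   seed: int) -> pd.DataFrame:
    """Paired measurements under a proportional-error repeatability model.

    For each of n subjects, reading A is the true value and reading B is
    the truth scaled by 1 - (bias_pct + eps)/100 with eps ~ Normal(0,
    sd_pct), emulating two acquisitions of the same subject.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if sd_pct < 0:
        raise ValueError("sd_pct must be non-negative")
    truths = np.broadcast_to(np.asarray(true_values, dtype=float), (n,))
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sd_pct, size=n) if sd_pct > 0 else np.zeros(n)
    value_b = truths * (1.0 - (bias_pct + eps) / 100.0)
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "value_a": truths,
        "value_b": value_b,
    })


def true_segment_volumes(spec: PhantomSpec, landmarks: LandmarkSet,
                         caudate_radius_mm: float = 30.0,
                         factor: int = 3, chunk_slabs: int = 8) -> dict:
    """Independent volumetry oracle by supersampled analytic labeling.

    Points on a grid ``factor`` times finer than the phantom voxel grid
    are tested against the analytic ellipsoid (not the voxelized mask)
    and classified; each point carries voxel_volume / factor^3.  Returns
    volumes in mL per segment code plus ``"whole_liver"``.
    """
    planes = build_planes(landmarks, caudate_radius_mm=caudate_radius_mm)
    a = np.asarray(spec.semi_axes_mm, dtype=float)
    c = np.asarray(spec.center_mm, dtype=float)
    vox = np.asarray(spec.voxel_size_mm, dtype=float)
    fine = vox / factor
    lo = c - a - spec.margin_mm
    hi = c + a + spec.margin_mm
    shape = np.ceil((hi - lo) / fine).astype(int)
    cell_ml = float(np.prod(fine)) / 1000.0

    counts = {code: 0 for code in SEGMENT_CODES}
    xs = lo[0] + fine[0] * (np.arange(shape[0]) + 0.5)
    ys = lo[1] + fine[1] * (np.arange(shape[1]) + 0.5)
    for k0 in range(0, shape[2], chunk_slabs):
        zs = lo[2] + fine[2] * (np.arange(k0, min(k0 + chunk_slabs, shape[2]))
                                + 0.5)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        inside = _inside(pts, spec)
        if not inside.any():
            continue
        codes = classify_points(pts[inside], planes)
        for code in SEGMENT_CODES:
            counts[code] += int(np.count_nonzero(codes == code))
    volumes = {code: counts[code] * cell_ml for code in SEGMENT_CODES}
    volumes["whole_liver"] = sum(volumes[c] for c in SEGMENT_CODES)
    return volumes
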