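"""Slab resampling of sparse multislice maps and per-segment medians.

Quantitative maps (cT1, PDFF) are acquired as a handful of thick axial
slices (cT1: 8 mm thick with a 12 mm gap; PDFF: 20 mm thick), while the
segment labelmap lives on a dense 3D grid.  A shared scanner world frame
is assumed — no registration step.  A volume voxel centre falling within
+/- thickness/2 of a slice plane (measured along the slice normal, closed
interval) receives that slice's nearest in-plane pixel value; voxel
centres in the inter-slice gaps or outside the slice field of view are
missing (NaN).  Where slabs overlap, the nearer slice plane wins, ties
going to the earlier slice.  Per-segment summaries use the median, which
is robust and does not invent values the scanner never measured.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import QuantMap, SegmentLabelMap, SEGMENT_CODES

__all__ = ["resample_to_grid", "segment_medians", "attach_map_statistics"]


def resample_to_grid(qmap: QuantMap, labels: SegmentLabelMap,
                     chunk_voxels: int = 2_000_000) -> np.ndarray:
    """Map slice values onto the labelmap grid; NaN marks missing voxels.

    Only foreground (labelled) voxels are filled; background stays NaN.
    """
    out = np.full(labels.grid.size, np.nan)
    fg = np.flatnonzero(labels.grid.ravel())
    if fg.size == 0:
        return out.reshape(labels.grid.shape)

    ijk = np.column_stack(np.unravel_index(fg, labels.grid.shape)).astype(float)
    A, t = labels.affine[:3, :3], labels.affine[:3, 3]

    any_hit = False
    for start in range(0, fg.size, chunk_voxels):
        sl = slice(start, start + chunk_voxels)
        world = ijk[sl] @ A.T + t
        n = world.shape[0]
        best_dist = np.full(n, np.inf)
        values = np.full(n, np.nan)
        for s in qmap.slices:
            normal = s.normal
            dist = np.abs((world - s.origin) @ normal)
            in_slab = dist <= s.thickness_mm / 2.0
            # strict < keeps the earlier slice on exact ties
            cand = in_slab & (dist < best_dist)
            if not np.any(cand):
                continue
            inv = np.linalg.inv(s.affine)
            pix = world[cand] @ inv[:3, :3].T + inv[:3, 3]
            ii = np.rint(pix[:, 0]).astype(int)
            jj = np.rint(pix[:, 1]).astype(int)
            inb = (ii >= 0) & (ii < s.values.shape[0]) \
                & (jj >= 0) & (jj < s.values.shape[1])
            idx = np.flatnonzero(cand)[inb]
            values[idx] = s.values[ii[inb], jj[inb]]
            best_dist[idx] = dist[idx]
        out[fg[sl]] = values
        any_hit = any_hit or bool(np.any(np.isfinite(values)))

    if not any_hit:
        warnings.warn(
            "quantitative map does not overlap the labelled volume: "
            "all values missing",
            stacklevel=2,
        )
    return out.reshape(labels.grid.shape)


def segment_medians(values: np.ndarray, labels: SegmentLabelMap,
                    min_voxels: int = 10) -> dict:
    """Median of non-missing map values per segment and whole liver.

    Returns ``{code: (median | None, n_voxels)}`` plus a ``"whole_liver"``
    entry.  Segments with fewer than ``min_voxels`` non-missing values
    report ``None`` (unstable median).  Even-count medians are the
    midpoint of the two central values.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != labels.grid.shape:
        raise ValueError("value array shape does not match labelmap")
    out = {}
    whole = values[(labels.grid > 0) & np.isfinite(values)]
    out["whole_liver"] = (
        float(np.median(whole)) if whole.size >= min_voxels else None,
        int(whole.size),
    )
    for code in SEGMENT_CODES:
        v = values[(labels.grid == code) & np.isfinite(values)]
        out[code] = (
            float(np.median(v)) if v.size >= min_voxels else None,
            int(v.size),
        )
    return out


def attach_map_statistics(report, qmap: QuantMap, labels: SegmentLabelMap,
                          min_voxels: int = 10):
    """Fill a SegmentReport's median fields for one modality in place."""
    med = segment_medians(resample_to_grid(qmap, labels), labels,
                          min_voxels=min_voxels)
    if qmap.modality == "cT1":
        for code in SEGMENT_CODES:
            report.segments[code].median_ct1_ms = med[code][0]
            report.segments[code].ct1_voxel_count = med[code][1]
        report.whole_liver_median_ct1_ms = med["whole_liver"][0]
        report.whole_liver_ct1_voxel_count = med["whole_liver"][1]
    else:
        for code in SEGMENT_CODES:
            report.segments[code].median_pdff_pct = med[code][0]
            report.segments[code].pdff_voxel_count = med[code][1]
        report.whole_liver_median_pdff_pct = med["whole_liver"][0]
        report.whole_liver_pdff_voxel_count = med["whole_liver"][1]
    return report
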