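"""On-disk formats: NIfTI volumes, landmark JSON, reports, pairs tables.

World convention is fixed to RAS+ (the native NIfTI frame); files in
other conventions must be reoriented upstream.  Landmarks live in a JSON
file with world-mm coordinates so they are decoupled from any one image
grid::

    {"space": "RAS", "units": "mm",
     "landmarks": {"ivc_superior": [x, y, z], ...}}  # all eight names

Quantitative maps are stored as a thin 3D stack (one file per modality)
whose affine gives the slice plane geometry; the physical slab thickness
(which can be smaller than the slice spacing when slices have gaps) is
recorded in the NIfTI ``descrip`` header field.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    LANDMARK_NAMES,
    SEGMENT_CODES,
    SEGMENT_NAMES,
    LandmarkSet,
    LiverMask,
    NonVolumeImageError,
    QuantMap,
    QuantSlice,
    SegmentLabelMap,
    SegmentReport,
    SegmentStats,
    LandmarkSchemaError,
)

__all__ = [
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "read_labelmap",
    "write_labelmap",
    "read_quantmap",
    "write_quantmap",
    "write_report",
    "read_report",
    "read_pairs",
    "write_pairs",
]


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    return nib.load(str(path))


def read_mask(path) -> LiverMask:
    """Read a binary liver mask from a NIfTI-1/2 volume.

    Any voxel value > 0 is foreground.  The affine is taken from the
    header (RAS+ world convention).
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise NonVolumeImageError(
            f"expected a 3D volume, got {data.ndim}D: {path}"
        )
    return LiverMask(grid=data, affine=img.affine)


def write_mask(mask: LiverMask, path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_landmarks(path) -> LandmarkSet:
    """Read the eight-landmark JSON file (world mm, RAS)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("space", "units", "landmarks"):
        if key not in doc:
            raise LandmarkSchemaError(f"landmark file missing key: {key}")
    if doc["units"] != "mm":
        raise LandmarkSchemaError(
            f"landmark units must be 'mm', got {doc['units']!r}"
        )
    return LandmarkSet(points=doc["landmarks"], space=doc["space"])


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    doc = {
        "space": landmarks.space,
        "units": "mm",
        "landmarks": {n: landmarks[n].tolist() for n in LANDMARK_NAMES},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_labelmap(path) -> SegmentLabelMap:
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise NonVolumeImageError(
            f"expected a 3D labelmap, got {data.ndim}D: {path}"
        )
    return SegmentLabelMap(grid=data.astype(np.int16), affine=img.affine)


def write_labelmap(labels: SegmentLabelMap, path) -> None:
    img = nib.Nifti1Image(labels.grid.astype(np.int16), labels.affine)
    nib.save(img, str(path))


def write_quantmap(qmap: QuantMap, path) -> None:
    """Write a multislice map as a thin 3D stack.

    All slices must share in-plane geometry and be evenly spaced along a
    common normal (the phantom generator guarantees this).
    """
    s0 = qmap.slices[0]
    stack = np.stack([s.values for s in qmap.slices], axis=2)
    affine = s0.affine.copy()
    img = nib.Nifti1Image(stack.astype(np.float64), affine)
    img.header["descrip"] = f"modality={qmap.modality};thickness_mm={s0.thickness_mm}".encode()
    nib.save(img, str(path))


def read_quantmap(path, modality: str | None = None) -> QuantMap:
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise NonVolumeImageError(
            f"expected a 3D slice stack, got {data.ndim}D: {path}"
        )
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    meta = dict(item.split("=", 1) for item in descrip.split(";")
                if "=" in item)
    if modality is None:
        if "modality" not in meta:
            raise ValueError(
                f"cannot determine map modality from header of {path}; "
                "pass modality explicitly"
            )
        modality = meta["modality"]
    thickness = float(meta.get("thickness_mm", abs(img.affine[:3, 2] @ img.affine[:3, 2]) ** 0.5))
    slices = []
    for k in range(data.shape[2]):
        affine = img.affine.copy()
        affine[:3, 3] = img.affine[:3, 3] + k * img.affine[:3, 2]
        slices.append(QuantSlice(values=data[:, :, k], affine=affine,
                                 thickness_mm=thickness))
    return QuantMap(modality=modality, slices=slices)


_REPORT_COLUMNS = [
    "segment",
    "voxel_count",
    "volume_ml",
    "volume_fraction",
    "median_ct1_ms",
    "ct1_voxel_count",
    "median_pdff_pct",
    "pdff_voxel_count",
]


def _report_rows(report: SegmentReport) -> list[dict]:
    rows = []
    for code in SEGMENT_CODES:
        s = report.segments[code]
        rows.append({
            "segment": SEGMENT_NAMES[code],
            "voxel_count": s.voxel_count,
            "volume_ml": s.volume_ml,
            "volume_fraction": s.volume_fraction,
            "median_ct1_ms": s.median_ct1_ms,
            "ct1_voxel_count": s.ct1_voxel_count,
            "median_pdff_pct": s.median_pdff_pct,
            "pdff_voxel_count": s.pdff_voxel_count,
        })
    rows.append({
        "segment": "whole_liver",
        "voxel_count": report.total_voxel_count,
        "volume_ml": report.total_volume_ml,
        "volume_fraction": 1.0 if report.total_voxel_count else 0.0,
        "median_ct1_ms": report.whole_liver_median_ct1_ms,
        "ct1_voxel_count": report.whole_liver_ct1_voxel_count,
        "median_pdff_pct": report.whole_liver_median_pdff_pct,
        "pdff_voxel_count": report.whole_liver_pdff_voxel_count,
    })
    return rows


def write_report(report: SegmentReport, path) -> None:
    """Write a segment report as JSON (``path``) and CSV (same stem).

    The CSV has one row per segment in fixed code order plus a final
    whole-liver row; the JSON additionally carries the parameter audit
    block (plane geometry, caudate radius, tool version).
    """
    path = Path(path)
    doc = {
        "segments": _report_rows(report),
        "voxel_volume_mm3": report.voxel_volume_mm3,
        "parameters": report.parameters,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_REPORT_COLUMNS)
        writer.writeheader()
        for row in _report_rows(report):
            writer.writerow(row)


def read_report(path) -> SegmentReport:
    """Read back a JSON segment report written by :func:`write_report`."""
    with open(path) as fh:
        doc = json.load(fh)
    name_to_code = {v: k for k, v in SEGMENT_NAMES.items()}
    segments = {}
    total = None
    for row in doc["segments"]:
        if row["segment"] == "whole_liver":
            total = row
            continue
        code = name_to_code[row["segment"]]
        segments[code] = SegmentStats(
            code=code,
            voxel_count=row["voxel_count"],
            volume_ml=row["volume_ml"],
            volume_fraction=row["volume_fraction"],
            median_ct1_ms=row["median_ct1_ms"],
            ct1_voxel_count=row["ct1_voxel_count"] or 0,
            median_pdff_pct=row["median_pdff_pct"],
            pdff_voxel_count=row["pdff_voxel_count"] or 0,
        )
    if total is None:
        raise ValueError(f"report {path} has no whole_liver row")
    return SegmentReport(
        segments=segments,
        total_voxel_count=total["voxel_count"],
        total_volume_ml=total["volume_ml"],
        whole_liver_median_ct1_ms=total["median_ct1_ms"],
        whole_liver_ct1_voxel_count=total["ct1_voxel_count"] or 0,
        whole_liver_median_pdff_pct=total["median_pdff_pct"],
        whole_liver_pdff_voxel_count=total["pdff_voxel_count"] or 0,
        voxel_volume_mm3=doc.get("voxel_volume_mm3"),
        parameters=doc.get("parameters", {}),
    )


def read_pairs(path) -> pd.DataFrame:
    """Read a paired-measurement CSV with columns id, value_a, value_b."""
    df = pd.read_csv(path)
    required = {"id", "value_a", "value_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"pairs table {path} missing columns: {sorted(missing)}"
        )
    return df


def write_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
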