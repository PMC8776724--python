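"""Future-liver-remnant (FLR) computation for resection planning.

FLR% is the fraction of total liver volume left after removing a set of
Couinaud segments.  Safe lower limits depend on parenchymal health:
20% for a healthy liver, 30% with steatosis, 40% with fibrosis or
cirrhosis.  These thresholds are a configurable map, not hard-coded
clinical advice.  "Segment 4" in a plan expands to {4a, 4b}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import SEGMENT_CODES, SEGMENT_NAMES, SegmentReport

__all__ = [
    "DEFAULT_THRESHOLDS",
    "CANONICAL_RESECTIONS",
    "ResectionPlan",
    "FLRResult",
    "parse_segment_codes",
    "flr_percent",
    "enumerate_plans",
]

#: Safe lower FLR limits (%) by parenchymal status.
DEFAULT_THRESHOLDS = {
    "healthy": 20.0,
    "steatosis": 30.0,
    "fibrosis_cirrhosis": 40.0,
}

#: Built-in catalogue of named resections (removed segment codes).
CANONICAL_RESECTIONS = {
    "right_hepatectomy": frozenset({5, 6, 7, 8}),
    "extended_right_hepatectomy": frozenset({1, 41, 42, 5, 6, 7, 8}),
    "left_hepatectomy": frozenset({2, 3, 41, 42}),
    "left_lateral_sectionectomy": frozenset({2, 3}),
    "segmentectomy_5_8": frozenset({5, 8}),
    "segmentectomy_5": frozenset({5}),
    "segmentectomy_6": frozenset({6}),
    "segmentectomy_2": frozenset({2}),
}

_NAME_TO_CODE = {v: k for k, v in SEGMENT_NAMES.items()}
_NAME_TO_CODE["4"] = None  # sentinel: expands to 4a + 4b


def parse_segment_codes(tokens) -> frozenset:
    """Parse segment names ('1', '4a', '8', ... or '4') into label codes."""
    codes: set[int] = set()
    for tok in tokens:
        tok = str(tok).strip()
        if tok == "4":
            codes.update({41, 42})
            continue
        if tok in _NAME_TO_CODE and _NAME_TO_CODE[tok] is not None:
            codes.add(_NAME_TO_CODE[tok])
            continue
        try:
            code = int(tok)
        except ValueError as exc:
            raise ValueError(f"unknown segment: {tok!r}") from exc
        if code not in SEGMENT_CODES:
            raise ValueError(f"unknown segment code: {code}")
        codes.add(code)
    return frozenset(codes)


@dataclass
class ResectionPlan:
    """Segments to remove plus the parenchymal status of the remnant."""

    removed: frozenset
    parenchyma_status: str = "healthy"

    def __post_init__(self) -> None:
        self.removed = frozenset(self.removed)
        bad = self.removed - set(SEGMENT_CODES)
        if bad:
            raise ValueError(f"unknown segment codes in plan: {sorted(bad)}")
        if self.parenchyma_status not in DEFAULT_THRESHOLDS:
            raise ValueError(
                f"unknown parenchyma status: {self.parenchyma_status!r} "
                f"(expected one of {sorted(DEFAULT_THRESHOLDS)})"
            )


@dataclass
class FLRResult:
    flr_percent: float
    threshold_percent: float
    adequate: bool
    remnant_volume_ml: float
    total_volume_ml: float
    removed: frozenset = field(default_factory=frozenset)


def flr_percent(report: SegmentReport, plan: ResectionPlan,
                thresholds: dict | None = None) -> FLRResult:
    """FLR% = 100 x (total - removed) / total, judged against the
    status-specific safe lower limit."""
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    total = report.total_volume_ml
    if not total > 0:
        raise ValueError("total liver volume is zero: FLR undefined")
    removed_ml = sum(report.volume_ml(c) for c in plan.removed)
    remnant = total - removed_ml
    flr = 100.0 * remnant / total
    thr = float(thresholds[plan.parenchyma_status])
    return FLRResult(
        flr_percent=flr,
        threshold_percent=thr,
        adequate=flr >= thr,
        remnant_volume_ml=remnant,
        total_volume_ml=total,
        removed=plan.removed,
    )


def enumerate_plans(report: SegmentReport, status: str = "healthy",
                    thresholds: dict | None = None,
                    catalogue: dict | None = None) -> pd.DataFrame:
    """FLR% and adequacy for every named resection in the catalogue."""
    catalogue = dict(CANONICAL_RESECTIONS if catalogue is None else catalogue)
    rows = []
    for name, removed in catalogue.items():
        res = flr_percent(report, ResectionPlan(removed, status), thresholds)
        rows.append({
            "resection": name,
            "removed_segments": ",".join(
                SEGMENT_NAMES[c] for c in sorted(removed)
            ),
            "flr_percent": res.flr_percent,
            "remnant_volume_ml": res.remnant_volume_ml,
            "threshold_percent": res.threshold_percent,
            "adequate": res.adequate,
        })
    return pd.DataFrame(rows).sort_values(
        "flr_percent", ascending=False, ignore_index=True
    )
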