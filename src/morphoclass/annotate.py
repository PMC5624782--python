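"""Overlap bookkeeping: peaks vs enhancer-reporter tiles and TSS proximity,
plus the combined machine/human-readable pipeline report.

All percentages are computed as 100 * count / denominator and rounded
half-up to one decimal, matching conventional table formatting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval, Peak, overlaps

__all__ = [
    "TileAnnotation",
    "percentage",
    "tile_overlap_summary",
    "tss_proximity_summary",
    "report",
]

ACTIVITIES = ("active_early", "active_late", "inactive")


@dataclass(frozen=True)
class TileAnnotation:
    """A reporter tile with its measured activity call."""

    interval: GenomicInterval
    activity: str  # active_early / active_late / inactive
    patterned: bool = False

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"activity must be one of {ACTIVITIES}")
        if self.patterned and self.activity != "active_early":
            raise ValueError("patterned tiles must be active_early")


def percentage(count: float, total: float) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(
        Decimal(100 * count / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def tile_overlap_summary(
    peaks: Sequence[Peak],
    classes: Sequence[str],
    tiles: Sequence[TileAnnotation],
) -> pd.DataFrame:
    """Peak/tile overlap counts stratified by tile activity.

    Per activity stratum (plus a total row): tiles overlapping >= 1 peak,
    peaks overlapping >= 1 tile, and the number of peaks/tiles in a
    one-to-one ("single") overlap.  A peak overlapping two tiles contributes
    two tile overlaps but is not a single-overlap peak.
    """
    labels = np.asarray(classes, dtype=object)
    if labels.shape != (len(peaks),):
        raise ValueError("one class label per peak required")
    pairs = overlaps(peaks, [t.interval for t in tiles])
    rows = []
    for stratum in ACTIVITIES + ("total",):
        keep = [
            (pi, ti)
            for pi, ti in pairs
            if stratum == "total" or tiles[ti].activity == stratum
        ]
        peak_hits: dict[int, int] = {}
        tile_hits: dict[int, int] = {}
        for pi, ti in keep:
            peak_hits[pi] = peak_hits.get(pi, 0) + 1
            tile_hits[ti] = tile_hits.get(ti, 0) + 1
        single_pairs = [
            (pi, ti)
            for pi, ti in keep
            if peak_hits[pi] == 1 and tile_hits[ti] == 1
        ]
        rows.append(
            {
                "stratum": stratum,
                "n_tiles_overlapping": len(tile_hits),
                "n_peaks_overlapping": len(peak_hits),
                "n_single_overlap": len(single_pairs),
                "pct_peaks_overlapping": percentage(len(peak_hits), len(peaks)),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def tss_proximity_summary(
    peaks: Sequence[Peak],
    classes: Sequence[str],
    tss: Sequence[tuple[str, int]],
    window: int = 500,
) -> pd.DataFrame:
    """Per-class counts of peaks within ``window`` bp of a TSS point.

    Distance is point-to-interval (0 when the TSS falls inside the peak) and
    the window boundary is inclusive.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    labels = np.asarray(classes, dtype=object)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss:
        by_chrom.setdefault(chrom, [])
    tmp: dict[str, list[int]] = {}
    for chrom, pos in tss:
        tmp.setdefault(chrom, []).append(pos)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in tmp.items()}
    near = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        positions = by_chrom.get(p.chrom)
        if positions is None or positions.size == 0:
            continue
        j = np.searchsorted(positions, p.start)
        candidates = positions[max(0, j - 1) : j + 2]
        for pos in candidates:
            if pos < p.start:
                dist = p.start - pos
            elif pos >= p.end:
                dist = pos - (p.end - 1)
            else:
                dist = 0
            if dist <= window:
                near[i] = True
                break
    rows = []
    for klass in pd.unique(labels):
        mask = labels == klass
        count = int(np.sum(near & mask))
        rows.append(
            {
                "class": str(klass),
                "n_near_tss": count,
                "class_size": int(mask.sum()),
                "pct": percentage(count, int(mask.sum())),
            }
        )
    rows.append(
        {
            "class": "total",
            "n_near_tss": int(near.sum()),
            "class_size": len(peaks),
            "pct": percentage(int(near.sum()), len(peaks)),
        }
    )
    return pd.DataFrame(rows).set_index("class")


def report(
    class_sizes: dict[str, int] | None = None,
    filter_provenance: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
    dependence_by_class: pd.DataFrame | None = None,
    quantification: pd.DataFrame | None = None,
    tile_summary: pd.DataFrame | None = None,
    tss_summary: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the stage outputs into one JSON-serialisable report.

    Sections for stages that were not run are omitted with a notice; all
    percentages are recomputed from counts at assembly time.  When
    ``out_dir`` is given, report.json and per-section TSVs are written.
    """
    sections: dict = {}
    notices: list[str] = []
    if class_sizes is not None:
        total = sum(class_sizes.values())
        sections["classes"] = {
            "sizes": dict(class_sizes),
            "total": total,
            "percentages": {
                k: percentage(v, total) for k, v in class_sizes.items() if total
            },
        }
    else:
        notices.append("classification stage missing: classes section omitted")
    pairs = [
        ("filter", filter_provenance),
        ("motif_enrichment", enrichment),
        ("dependence_by_class", dependence_by_class),
        ("quantification", quantification),
        ("tiles", tile_summary),
        ("tss", tss_summary),
    ]
    for name, frame in pairs:
        if frame is None:
            notices.append(f"{name} stage missing: section omitted")
        else:
            sections[name] = json.loads(frame.reset_index().to_json(orient="records"))
    out = {"sections": sections, "notices": notices}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(out, fh, indent=2, default=str)
        for name, frame in pairs:
            if frame is not None:
                frame.to_csv(out_dir / f"report_{name}.tsv", sep="\t")
    return out
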