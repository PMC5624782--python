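"""Region x sample read-count matrices with sample metadata and CPM scaling."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval, Peak

__all__ = ["Sample", "CountMatrix", "read_count_table", "write_count_table", "cpm"]


@dataclass(frozen=True)
class Sample:
    """Sample metadata: display label, biological condition, replicate index."""

    label: str
    condition: str = ""
    replicate: int = 1


@dataclass
class CountMatrix:
    """Non-negative integer read counts over regions x samples.

    ``library_sizes`` default to column sums over the supplied regions; when
    set explicitly they must be at least the column sums (regions are a
    subset of the library).
    """

    regions: list
    samples: list[Sample]
    counts: np.ndarray
    library_sizes: np.ndarray | None = None
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int):
                raise ValueError("counts must be integers")
            self.counts = as_int.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if self.library_sizes is None:
            self.library_sizes = colsums.astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if self.library_sizes.shape != (len(self.samples),):
                raise ValueError("library_sizes must have one entry per sample")
            if (self.library_sizes <= 0).any():
                raise ValueError("library_sizes must be positive")
            if (self.library_sizes < colsums).any():
                raise ValueError("library_sizes cannot be below column sums over regions")
        if not self.region_ids:
            self.region_ids = [
                r.id if isinstance(r, Peak) else f"region_{i}"
                for i, r in enumerate(self.regions)
            ]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def columns(self, condition: str) -> np.ndarray:
        """Column indices of samples belonging to ``condition``."""
        idx = np.array([i for i, s in enumerate(self.samples) if s.condition == condition])
        if idx.size == 0:
            raise ValueError(f"no samples with condition {condition!r}")
        return idx

    def subset_regions(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return CountMatrix(
            [self.regions[i] for i in idx],
            list(self.samples),
            self.counts[idx],
            self.library_sizes.copy(),
            [self.region_ids[i] for i in idx],
        )

    def cpm(self) -> np.ndarray:
        return cpm(self)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chrom": [(r.chrom if isinstance(r, Peak) else r.chrom) for r in self.regions],
            "start": [r.start for r in self.regions],
            "end": [r.end for r in self.regions],
            "id": self.region_ids,
        }
        frame = pd.DataFrame(data)
        for j, s in enumerate(self.samples):
            frame[s.label] = self.counts[:, j]
        return frame


def cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million: ``count * 1e6 / library_size`` per sample column."""
    libs = counts.library_sizes.astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive for CPM")
    return counts.counts * (1e6 / libs)


def read_count_table(
    path: str | Path,
    sample_sheet: str | Path | None = None,
    library_sizes: Sequence[int] | None = None,
) -> CountMatrix:
    """Read a TSV count table: chrom/start/end/id columns then one column per sample.

    An optional sample sheet (TSV with columns label, condition, replicate)
    attaches metadata; otherwise conditions are parsed from labels of the
    form ``condition_rep`` when possible.
    """
    frame = pd.read_csv(path, sep="\t")
    coord_cols = ["chrom", "start", "end"]
    for col in coord_cols:
        if col not in frame.columns:
            raise ValueError(f"count table must have a {col!r} column")
    has_id = "id" in frame.columns
    sample_cols = [c for c in frame.columns if c not in coord_cols + ["id"]]
    raw = frame[sample_cols].to_numpy()
    if not np.allclose(raw, np.rint(raw)) or (raw < 0).any():
        raise ValueError("counts must be non-negative integers")
    regions = [
        GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        for row in frame.itertuples()
    ]
    region_ids = [str(x) for x in frame["id"]] if has_id else []
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t")
        meta = {str(r.label): Sample(str(r.label), str(r.condition), int(r.replicate))
                for r in sheet.itertuples()}
        samples = [meta.get(c, Sample(c)) for c in sample_cols]
    else:
        samples = []
        for c in sample_cols:
            cond, _, rep = c.rpartition("_")
            samples.append(Sample(c, cond or c, int(rep) if rep.isdigit() else 1))
    return CountMatrix(regions, samples, np.rint(raw).astype(np.int64),
                       None if library_sizes is None else np.asarray(library_sizes),
                       region_ids)


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)
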