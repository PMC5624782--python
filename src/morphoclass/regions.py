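"""Genomic intervals, peaks, binned coverage tracks, and BED/bedGraph I/O.

All coordinates are 0-based, half-open (BED convention).  Chromosome names
are opaque strings; no genome build is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "Track",
    "read_bed",
    "write_bed",
    "overlaps",
    "resize_center",
    "binned_coverage",
    "write_bedgraph",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A peak region: an interval plus identifier and summit offset.

    The summit is an absolute genomic coordinate of maximum signal and must
    lie inside the interval.
    """

    interval: GenomicInterval
    id: str
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def anchor(self) -> int:
        """Summit if defined, otherwise the interval midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


def validate_peak_ids(peaks: Sequence[Peak]) -> None:
    ids = [p.id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("peak ids must be unique within a peak set")


@dataclass
class Track:
    """Per-chromosome binned signal values at fixed bin width."""

    chrom: str
    bin_width: int = 10
    values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def span(self) -> int:
        return len(self.values) * self.bin_width

    def value_at(self, position: int) -> float:
        """Value of the bin containing ``position``; 0.0 outside the track."""
        idx = position // self.bin_width
        if 0 <= idx < len(self.values):
            return float(self.values[idx])
        raise IndexError(f"position {position} outside track extent {self.span}")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving file order.

    Raises a ``ValueError`` naming the offending line on malformed input.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED3 (or BED6 with a name column when given)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None or iv.strand != ".":
                name = names[i] if names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _as_interval(x) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def overlaps(a: Sequence, b: Sequence, min_overlap: int = 1) -> list[tuple[int, int]]:
    """Index pairs ``(i, j)`` where ``a[i]`` overlaps ``b[j]`` by >= min_overlap bases.

    Accepts intervals or peaks.  Overlap requires the same chromosome;
    half-open semantics, so ``[0,10)`` and ``[10,20)`` do not overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for j, item in enumerate(b):
        iv = _as_interval(item)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, item in enumerate(a):
        iv = _as_interval(item)
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def resize_center(items: Sequence, width: int, anchor: str = "midpoint") -> list[GenomicInterval]:
    """Resize intervals/peaks to ``width`` bases centred on an anchor point.

    ``anchor`` is ``"summit"`` (peaks only; falls back to midpoint when the
    summit is undefined) or ``"midpoint"``.  For even widths the anchor
    occupies the left-of-centre base (output = ``[a - width//2, a + width -
    width//2)``), a deterministic tie-break.  Starts are clipped at 0 while
    preserving the requested width.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if anchor not in ("summit", "midpoint"):
        raise ValueError("anchor must be 'summit' or 'midpoint'")
    out = []
    for item in items:
        if anchor == "summit" and isinstance(item, Peak):
            a = item.anchor
        else:
            a = _as_interval(item).midpoint
        iv = _as_interval(item)
        start = a - width // 2
        if start < 0:
            start = 0
        out.append(GenomicInterval(iv.chrom, start, start + width, iv.strand))
    return out


def binned_coverage(
    fragments: Sequence[GenomicInterval],
    bin_width: int = 10,
    normalize_cpm: bool = False,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, Track]:
    """Per-chromosome binned coverage: each bin counts overlapping fragments.

    A fragment increments every bin it overlaps by >= 1 bp.  With
    ``normalize_cpm`` values are scaled by 1e6 / total fragment count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    fragments = list(fragments)
    if normalize_cpm and not fragments:
        raise ValueError("cannot CPM-normalize an empty fragment set")
    spans: dict[str, int] = dict(chrom_lengths or {})
    for f in fragments:
        spans[f.chrom] = max(spans.get(f.chrom, 0), f.end)
    tracks = {
        chrom: Track(chrom, bin_width, np.zeros(-(-length // bin_width)))
        for chrom, length in spans.items()
    }
    for f in fragments:
        first = f.start // bin_width
        last = (f.end - 1) // bin_width  # end is exclusive
        tracks[f.chrom].values[first : last + 1] += 1
    if normalize_cpm:
        scale = 1e6 / len(fragments)
        for t in tracks.values():
            t.values *= scale
    return tracks


def write_bedgraph(tracks: dict[str, Track], path: str | Path) -> None:
    """Write tracks as bedGraph, omitting zero bins."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            nz = np.nonzero(t.values)[0]
            for idx in nz:
                start = int(idx) * t.bin_width
                fh.write(f"{chrom}\t{start}\t{start + t.bin_width}\t{t.values[idx]:g}\n")
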