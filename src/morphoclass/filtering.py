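"""Peak-list refinement: ATAC/ChIP ratio permutation filter, euchromatic
restriction, and common-peak intersection.

Peaks whose accessibility-to-binding ratio looks like a randomly chosen open
region of the genome (rather than a genuine binding site) are retained; the
hyper-open outliers — typically highly transcribed promoters that produce
false-positive ChIP signal — are discarded.  The ratio threshold is derived
from a permutation test against sampled open regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix, cpm
from .regions import GenomicInterval, Peak, overlaps

__all__ = [
    "RatioFilterResult",
    "atac_chip_ratio",
    "permutation_ratio_filter",
    "euchromatic_filter",
    "common_peaks",
    "DEFAULT_EUCHROMATIC",
]

logger = logging.getLogger(__name__)

DEFAULT_EUCHROMATIC = frozenset({"chr2L", "chr2R", "chr3L", "chr3R", "chr4", "chrX"})


@dataclass
class RatioFilterResult:
    """Per-peak ratio/p-value provenance and the derived discard threshold."""

    ratio: np.ndarray  # ATAC CPM / ChIP CPM per peak (nan when undefined)
    p: np.ndarray  # empirical openness p-value per peak
    threshold: float
    kept: np.ndarray  # bool per peak

    def to_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"ratio": self.ratio, "p_open": self.p, "kept": self.kept}
        )
        if ids is not None:
            frame.index = list(ids)
        return frame


def atac_chip_ratio(
    chip: CountMatrix, atac: CountMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak ratio of replicate-mean ATAC CPM to replicate-mean ChIP CPM.

    Returns (ratio, atac_cpm_mean).  Peaks with zero ChIP CPM get a NaN
    ratio and are excluded from threshold derivation downstream.
    """
    if chip.n_regions != atac.n_regions:
        raise ValueError("chip and atac matrices must cover the same regions")
    for r1, r2 in zip(chip.regions, atac.regions):
        a = r1.interval if isinstance(r1, Peak) else r1
        b = r2.interval if isinstance(r2, Peak) else r2
        if (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end):
            raise ValueError("chip and atac matrices must list regions in the same order")
    chip_cpm = cpm(chip).mean(axis=1)
    atac_cpm = cpm(atac).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(chip_cpm > 0, atac_cpm / chip_cpm, np.nan)
    return ratio, atac_cpm


def permutation_ratio_filter(
    peaks: Sequence[Peak],
    chip: CountMatrix,
    atac: CountMatrix,
    open_region_atac_cpm: Sequence[float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> RatioFilterResult:
    """Discard peaks that are more open than random open regions of the genome.

    For each peak, the empirical p-value is the add-one-corrected fraction
    of ``n_perm`` sampled open regions whose ATAC CPM is at least the
    peak's.  The ratio threshold t is the largest ATAC/ChIP ratio among
    peaks whose openness is unexceptional (p >= alpha); peaks with ratio
    above t are discarded.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    open_vals = np.asarray(open_region_atac_cpm, dtype=float)
    if open_vals.size == 0:
        raise ValueError("open_region_atac_cpm must be non-empty")
    rng = np.random.default_rng(seed)
    if open_vals.size >= n_perm:
        sampled = rng.choice(open_vals, size=n_perm, replace=False)
    else:
        logger.warning(
            "only %d open regions available; sampling with replacement", open_vals.size
        )
        sampled = rng.choice(open_vals, size=n_perm, replace=True)
    ratio, atac_cpm = atac_chip_ratio(chip, atac)
    sampled_sorted = np.sort(sampled)
    n_ge = n_perm - np.searchsorted(sampled_sorted, atac_cpm, side="left")
    p = (1.0 + n_ge) / (1.0 + n_perm)
    defined = ~np.isnan(ratio)
    eligible = defined & (p >= alpha)
    if not eligible.any():
        raise ValueError("no peak has unexceptional openness; cannot derive a threshold")
    threshold = float(np.max(ratio[eligible]))
    kept = defined & (ratio <= threshold)
    return RatioFilterResult(ratio=ratio, p=p, threshold=threshold, kept=kept)


def euchromatic_filter(
    peaks: Sequence[Peak], allowed: frozenset[str] | set[str] = DEFAULT_EUCHROMATIC
) -> list[Peak]:
    """Keep peaks on the allowed (euchromatic) chromosomes, preserving order."""
    if not allowed:
        raise ValueError("allowed chromosome set must be non-empty")
    return [p for p in peaks if p.chrom in allowed]


def common_peaks(peak_sets: Sequence[Sequence[Peak]], min_sets: int) -> list[Peak]:
    """Merge peaks supported by at least ``min_sets`` of the input sets.

    Support means >= 1 bp overlap.  Overlapping peaks are union-merged into
    a single region whose summit is taken from the first supporting peak of
    the highest-priority (earliest) input set.
    """
    if not peak_sets:
        raise ValueError("peak_sets must be non-empty")
    if not 1 <= min_sets <= len(peak_sets):
        raise ValueError("min_sets must lie in [1, number of sets]")
    tagged: list[tuple[GenomicInterval, int, Peak]] = []
    for si, pset in enumerate(peak_sets):
        for p in pset:
            tagged.append((p.interval, si, p))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    merged: list[Peak] = []
    cluster: list[tuple[GenomicInterval, int, Peak]] = []
    counter = 0

    def flush() -> None:
        nonlocal counter
        if not cluster:
            return
        support = len({si for _, si, _ in cluster})
        if support >= min_sets:
            start = min(iv.start for iv, _, _ in cluster)
            end = max(iv.end for iv, _, _ in cluster)
            best = min(cluster, key=lambda t: t[1])[2]
            merged.append(
                Peak(
                    GenomicInterval(cluster[0][0].chrom, start, end),
                    f"common_{counter:05d}",
                    best.summit,
                )
            )
            counter += 1

    cur_chrom, cur_end = None, -1
    for iv, si, p in tagged:
        if iv.chrom != cur_chrom or iv.start >= cur_end:
            flush()
            cluster = [(iv, si, p)]
            cur_chrom, cur_end = iv.chrom, iv.end
        else:
            cluster.append((iv, si, p))
            cur_end = max(cur_end, iv.end)
    flush()
    return merged
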