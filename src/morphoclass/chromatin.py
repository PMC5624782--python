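"""ATAC-side analysis: fragment-size mixture model, open-fragment selection,
differential accessibility with dependence labels, Fisher class enrichment,
motif accessibility scores, and nucleosome-motif overlap.

Fragment lengths are modelled as a two-component mixture: sub-nucleosomal
fragments from open chromatin follow an exponential law, nucleosome-
protected fragments a Gaussian around the nucleosomal wrap length.  The
mixture is fitted by EM; the fitted open-class weight and the <=100 bp
cutoff together select the open-chromatin fragment subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix
from .diffbind import bh_fdr, exact_test_matrix, estimate_common_dispersion
from .regions import GenomicInterval, Peak, Track, overlaps, resize_center

__all__ = [
    "FragmentSizeModel",
    "FragmentSizeMixture",
    "AccessibilityCall",
    "AccessibilityModel",
    "AccessibilityResults",
    "select_open_fragments",
    "fit_fragment_mixture",
    "fisher_class_enrichment",
    "motif_accessibility_scores",
    "nucleosome_motif_overlap",
    "occupancy_track",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentSizeModel:
    """Fitted mixture: open weight w, exponential rate, Gaussian mean/sd."""

    w: float
    rate: float
    mean: float
    sd: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: tuple = ()

    def open_fraction_below(self, cutoff: float) -> float:
        """Model-implied fraction of fragments at or below the cutoff."""
        p_exp = stats.expon.cdf(cutoff, scale=1.0 / self.rate)
        p_nuc = stats.norm.cdf(cutoff, self.mean, self.sd)
        return float(self.w * p_exp + (1.0 - self.w) * p_nuc)


class FragmentSizeMixture:
    """EM model for ATAC fragment lengths: w*Exp(rate) + (1-w)*N(mean, sd).

    >>> model = FragmentSizeMixture(lengths)
    >>> fit = model.fit()
    >>> fit.w, fit.rate, fit.mean, fit.sd
    """

    def __init__(self, lengths: Sequence[float]) -> None:
        lengths = np.asarray(lengths, dtype=float)
        if lengths.size < 100:
            raise ValueError("at least 100 fragment lengths are required")
        if (lengths < 1).any():
            raise ValueError("fragment lengths must be >= 1")
        self.lengths = lengths

    def _init_params(self) -> tuple[float, float, float, float]:
        """Quantile heuristics: short fragments seed the exponential, long
        fragments the Gaussian."""
        x = self.lengths
        short = x[x < 150]
        long_ = x[x >= 150]
        w = float(short.size) / x.size if short.size and long_.size else 0.5
        rate = 1.0 / float(short.mean()) if short.size else 1.0 / 60.0
        mean = float(long_.mean()) if long_.size else float(np.percentile(x, 90))
        sd = float(long_.std()) if long_.size > 1 else max(1.0, 0.15 * mean)
        return min(max(w, 0.01), 0.99), rate, mean, max(sd, 1.0)

    def fit(
        self,
        init: tuple[float, float, float, float] | None = None,
        tol: float = 1e-8,
        max_iter: int = 2000,
    ) -> FragmentSizeModel:
        """Maximum-likelihood EM fit; converges when the log-likelihood gain
        drops below ``tol``.  Degenerate data trigger a floored sd and a
        warning rather than failure."""
        x = self.lengths
        w, rate, mean, sd = init if init is not None else self._init_params()
        prev = -np.inf
        loglik = prev
        converged = False
        trace: list[float] = []
        it = 0
        for it in range(1, max_iter + 1):
            log_open = np.log(w) + stats.expon.logpdf(x, scale=1.0 / rate)
            log_nuc = np.log1p(-w) + stats.norm.logpdf(x, mean, sd)
            m = np.maximum(log_open, log_nuc)
            log_tot = m + np.log(np.exp(log_open - m) + np.exp(log_nuc - m))
            loglik = float(log_tot.sum())
            trace.append(loglik)
            resp = np.exp(log_open - log_tot)  # open-class responsibility
            n_open = resp.sum()
            n_nuc = x.size - n_open
            w = float(np.clip(n_open / x.size, 1e-10, 1 - 1e-10))
            rate = float(n_open / np.sum(resp * x)) if n_open > 0 else rate
            if n_nuc > 0:
                mean = float(np.sum((1 - resp) * x) / n_nuc)
                var = float(np.sum((1 - resp) * (x - mean) ** 2) / n_nuc)
                if var < 1e-6:
                    logger.warning("degenerate nucleosomal component; flooring sd")
                    var = 1e-6
                sd = np.sqrt(var)
            if loglik - prev < tol and it > 1:
                converged = True
                break
            prev = loglik
        return FragmentSizeModel(w, rate, mean, sd, loglik, it, converged, tuple(trace))


def fit_fragment_mixture(
    lengths: Sequence[float],
    init: tuple[float, float, float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FragmentSizeModel:
    """Functional wrapper around :class:`FragmentSizeMixture`."""
    return FragmentSizeMixture(lengths).fit(init=init, tol=tol, max_iter=max_iter)


def select_open_fragments(
    fragments: Sequence[GenomicInterval], cutoff: int = 100
) -> list[GenomicInterval]:
    """Fragments with length <= cutoff (inclusive): the open-chromatin subset."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return [f for f in fragments if len(f) <= cutoff]


@dataclass(frozen=True)
class AccessibilityCall:
    """One peak's differential-accessibility result for one mutant contrast."""

    peak_id: str
    contrast: str
    logfc: float  # positive = higher in wild type
    q: float
    dependent: bool  # reduced in the mutant at the FDR threshold

    def __post_init__(self) -> None:
        if self.dependent and not (self.q <= 0.05 and self.logfc > 0):
            raise ValueError("dependent flag requires q <= 0.05 and reduced accessibility")


class AccessibilityModel:
    """Differential accessibility between wild type and a mutant genotype.

    The count matrix covers peaks plus background regions (the background
    regions stabilise FDR adjustment exactly as the noise regions do for
    binding).  ``fit`` reuses the NB exact test at common dispersion.
    """

    def __init__(
        self,
        counts: CountMatrix,
        wildtype: str,
        mutant: str,
        is_background: np.ndarray | None = None,
    ) -> None:
        self.counts = counts
        self.wildtype = wildtype
        self.mutant = mutant
        self.is_background = (
            np.zeros(counts.n_regions, dtype=bool)
            if is_background is None
            else np.asarray(is_background, dtype=bool)
        )

    def fit(self, alpha: float = 0.05, dispersion: float | None = None) -> "AccessibilityResults":
        phi = (
            estimate_common_dispersion(self.counts, [self.wildtype, self.mutant]).phi
            if dispersion is None
            else float(dispersion)
        )
        tab = exact_test_matrix(self.counts, self.wildtype, self.mutant, phi)
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        tab["dependent"] = (tab["q"] <= alpha) & (tab["logfc"] > 0)
        tab.loc[self.is_background, "dependent"] = False
        return AccessibilityResults(self, tab, phi, alpha)


class AccessibilityResults:
    def __init__(self, model: AccessibilityModel, table: pd.DataFrame,
                 dispersion: float, alpha: float) -> None:
        self.model = model
        self.table = table
        self.dispersion = dispersion
        self.alpha = alpha

    @property
    def dependent(self) -> np.ndarray:
        """Dependence flags for the peak (non-background) regions."""
        return self.table["dependent"].to_numpy()[~self.model.is_background]

    def calls(self) -> list[AccessibilityCall]:
        contrast = f"{self.model.wildtype}_vs_{self.model.mutant}"
        mask = ~self.model.is_background
        return [
            AccessibilityCall(
                peak_id=idx,
                contrast=contrast,
                logfc=float(row.logfc),
                q=float(row.q),
                dependent=bool(row.dependent),
            )
            for idx, row in self.table[mask].iterrows()
        ]

    def summary(self) -> str:
        n_peak = int((~self.model.is_background).sum())
        n_dep = int(self.dependent.sum())
        return (
            f"Differential accessibility {self.model.wildtype} vs {self.model.mutant}\n"
            f"peaks: {n_peak}, background regions: "
            f"{int(self.model.is_background.sum())}\n"
            f"common dispersion: {self.dispersion:.4f}\n"
            f"dependent peaks (reduced in mutant, FDR <= {self.alpha:g}): "
            f"{n_dep} ({100.0 * n_dep / n_peak:.1f}%)"
        )


def fisher_class_enrichment(
    class_labels: Sequence[str], dependence_flags: Sequence[bool]
) -> pd.DataFrame:
    """Per-class 2x2 Fisher's exact test of dependence enrichment.

    Table per class: {in class, not in class} x {dependent, not dependent}.
    Two-sided p via the exact conditional (hypergeometric) test; the odds
    ratio is ad/bc with the Haldane half-count correction when a cell is 0.
    """
    labels = np.asarray(class_labels, dtype=object)
    flags = np.asarray(dependence_flags, dtype=bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags must align")
    if labels.size == 0:
        raise ValueError("no peaks given")
    rows = []
    for klass in pd.unique(labels):
        in_class = labels == klass
        if not in_class.any():
            raise ValueError(f"empty class {klass!r}")
        a = int(np.sum(in_class & flags))
        b = int(np.sum(in_class & ~flags))
        c = int(np.sum(~in_class & flags))
        d = int(np.sum(~in_class & ~flags))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({"class": str(klass), "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": float(orr), "p": float(p)})
    return pd.DataFrame(rows).set_index("class")


def motif_accessibility_scores(
    tracks: dict[str, Track],
    motifs: pd.DataFrame,
    peaks: Sequence[Peak],
) -> pd.DataFrame:
    """Accessibility score per motif: the value of the 10 bp coverage bin
    containing the motif midpoint; per-peak scores average over the peak's
    motifs.  Motifs outside the track extent are excluded (logged).

    ``motifs`` needs columns peak_id / start / end (genomic coordinates).
    """
    peak_by_id = {p.id: p for p in peaks}
    per_peak: dict[str, list[float]] = {}
    n_skipped = 0
    for row in motifs.itertuples():
        peak = peak_by_id.get(row.peak_id)
        if peak is None:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        track = tracks.get(peak.chrom)
        try:
            score = track.value_at(mid) if track is not None else None
        except IndexError:
            score = None
        if score is None:
            n_skipped += 1
            continue
        per_peak.setdefault(row.peak_id, []).append(score)
    if n_skipped:
        logger.warning("%d motifs outside track extent were excluded", n_skipped)
    rows = [
        {"peak_id": pid, "mean_score": float(np.mean(v)), "n_motifs": len(v)}
        for pid, v in per_peak.items()
    ]
    return pd.DataFrame(rows, columns=["peak_id", "mean_score", "n_motifs"]).set_index(
        "peak_id"
    )


def _widen_dyads(dyads: Sequence[tuple[str, int]], widen: int) -> list[GenomicInterval]:
    """Centre a window of ``widen`` bases on each dyad point.  Even widths are
    symmetric; odd widths put the extra base on the right."""
    half = widen // 2
    return [
        GenomicInterval(chrom, max(0, pos - half), max(0, pos - half) + widen)
        for chrom, pos in dyads
    ]


def nucleosome_motif_overlap(
    dyads: Sequence[tuple[str, int]],
    motifs: pd.DataFrame,
    peaks: Sequence[Peak],
    widen: int = 160,
) -> pd.DataFrame:
    """Per-peak fraction of motifs not covered by a widened nucleosome dyad.

    Dyad points are widened to ``widen`` bases; a motif overlapping any
    widened dyad by >= 1 bp is nucleosome-associated, otherwise open.  Peaks
    without motifs are excluded.  Returns open_fraction and counts per peak.
    """
    nuc = _widen_dyads(dyads, widen)
    motif_ivs = [
        GenomicInterval(
            str(getattr(row, "chrom", None) or _peak_chrom(peaks, row.peak_id)),
            int(row.start),
            int(row.end),
        )
        for row in motifs.itertuples()
    ]
    associated = np.zeros(len(motif_ivs), dtype=bool)
    for i, _ in overlaps(motif_ivs, nuc):
        associated[i] = True
    table: dict[str, list[int]] = {}
    for k, row in enumerate(motifs.itertuples()):
        table.setdefault(row.peak_id, [0, 0])
        table[row.peak_id][0] += 1
        table[row.peak_id][1] += int(associated[k])
    rows = []
    for pid, (total, assoc) in table.items():
        rows.append(
            {
                "peak_id": pid,
                "n_motifs": total,
                "n_associated": assoc,
                "open_fraction": (total - assoc) / total,
            }
        )
    return pd.DataFrame(
        rows, columns=["peak_id", "n_motifs", "n_associated", "open_fraction"]
    ).set_index("peak_id")


def _peak_chrom(peaks: Sequence[Peak], peak_id: str) -> str:
    for p in peaks:
        if p.id == peak_id:
            return p.chrom
    raise KeyError(peak_id)


def occupancy_track(
    dyads: Sequence[tuple[str, int]],
    weights: Sequence[float] | None = None,
    bin_width: int = 10,
    widen: int = 147,
    aggregate: str = "max",
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, Track]:
    """Nucleosome occupancy per bin from widened dyads.

    Each dyad is widened to ``widen`` bases (odd widths add the extra base
    on the right) and contributes its weight (default 1, an occupancy
    probability) to every bin it overlaps; overlapping nucleosomes combine
    by max (default) or sum.
    """
    if aggregate not in ("max", "sum"):
        raise ValueError("aggregate must be 'max' or 'sum'")
    w = np.ones(len(dyads)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(dyads),):
        raise ValueError("one weight per dyad is required")
    if ((w < 0) | (w > 1)).any():
        raise ValueError("weights must lie in [0, 1]")
    ivs = _widen_dyads(dyads, widen)
    spans: dict[str, int] = dict(chrom_lengths or {})
    for iv in ivs:
        spans[iv.chrom] = max(spans.get(iv.chrom, 0), iv.end)
    tracks = {
        chrom: Track(chrom, bin_width, np.zeros(-(-length // bin_width)))
        for chrom, length in spans.items()
    }
    for iv, weight in zip(ivs, w):
        first = iv.start // bin_width
        last = (iv.end - 1) // bin_width
        vals = tracks[iv.chrom].values
        if aggregate == "sum":
            vals[first : last + 1] += weight
        else:
            seg = vals[first : last + 1]
            np.maximum(seg, weight, out=seg)
    return tracks
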