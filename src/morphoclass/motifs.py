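"""PWM construction and scanning, per-peak motif counts, and permutation
tests for motif enrichment between sensitivity classes and for group score
differences.

Scanning uses log-odds scores against a background letter distribution with
the conventional min-score threshold semantics: a hit requires

    score >= score_min + threshold_frac * (score_max - score_min)

where score_min/score_max are the per-column minimal/maximal attainable
log-odds sums.  ``N`` bases score as background (zero log-odds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import Peak

__all__ = [
    "PWM",
    "MotifHit",
    "EnrichmentResult",
    "build_pwm",
    "read_jaspar",
    "scan_pwm",
    "motif_counts_per_peak",
    "class_enrichment_permutation",
    "group_difference_permutation",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASES = "ACGT"


@dataclass
class PWM:
    """Position weight matrix: 4 x L letter probabilities plus background."""

    name: str
    matrix: np.ndarray  # 4 x L, columns sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("matrix must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.background[::-1])


@dataclass(frozen=True)
class MotifHit:
    """A PWM match: position (0-based offset of the match start), strand,
    raw log-odds score, and the score on the normalized (min..max) scale."""

    peak_id: str
    offset: int
    strand: str
    score: float
    score_fraction: float


@dataclass(frozen=True)
class EnrichmentResult:
    klass: str
    motif: str
    observed: float  # mean per-peak motif count in the class
    null_mean: float
    fold: float
    p: float
    n_perm: int


def build_pwm(consensus: str, pseudo_weight: float = 0.01, name: str | None = None) -> PWM:
    """PWM from an IUPAC consensus: matched letters share 1 - 3*eps mass."""
    consensus = consensus.upper()
    cols = []
    for letter in consensus:
        if letter not in _IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r}")
        allowed = _IUPAC[letter]
        eps = pseudo_weight
        col = np.full(4, eps)
        remaining = 1.0 - eps * (4 - len(allowed))
        for b in allowed:
            col[_BASES.index(b)] = remaining / len(allowed)
        cols.append(col)
    return PWM(name or consensus, np.column_stack(cols))


def read_jaspar(path, pseudo_weight: float = 0.01) -> list[PWM]:
    """Read PWMs from a JASPAR-format plain-text count matrix file.

    Counts are converted to letter probabilities with ``pseudo_weight``
    added per letter before normalization.
    """
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            counts += pseudo_weight
            out.append(PWM(m.name or m.matrix_id, counts / counts.sum(axis=0)))
    return out


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / unknown
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for i, b in enumerate(_BASES):
        codes[arr == ord(b)] = i
    return codes


def _scores_all_offsets(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Log-odds score at every offset (vectorized sliding window)."""
    lo = np.vstack([pwm.log_odds, np.zeros(pwm.length)])  # N row scores 0
    L = pwm.length
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo[windows, np.arange(L)].sum(axis=1)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_frac: float = 0.8,
    both_strands: bool = True,
    peak_id: str = "",
) -> list[MotifHit]:
    """All PWM hits in a sequence at the given normalized-score threshold.

    Offsets refer to the forward strand start of the matched window on both
    strands.  Sequences shorter than the motif yield no hits.
    """
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must lie in (0, 1]")
    codes = _encode(sequence)
    span = pwm.max_score - pwm.min_score
    cutoff = pwm.min_score + threshold_frac * span
    hits: list[MotifHit] = []
    strands = [("+", pwm), ("-", pwm.reverse_complement())] if both_strands else [("+", pwm)]
    for strand, mat in strands:
        scores = _scores_all_offsets(codes, mat)
        for off in np.nonzero(scores >= cutoff - 1e-12)[0]:
            s = float(scores[off])
            frac = (s - pwm.min_score) / span if span > 0 else 1.0
            hits.append(MotifHit(peak_id, int(off), strand, s, float(frac)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def motif_counts_per_peak(
    peaks: Sequence[Peak],
    hits: dict[str, list[MotifHit]] | pd.DataFrame,
    motif_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Integer hit counts per peak and motif.

    ``hits`` maps motif name to hit lists whose offsets are peak-relative
    (hits carry the peak id), or is a frame with columns peak_id / motif.
    Hits are assigned by midpoint containment upstream; overlapping hits on
    opposite strands both count.
    """
    if isinstance(hits, pd.DataFrame):
        table = hits[["peak_id", "motif"]]
    else:
        rows = [
            {"peak_id": h.peak_id, "motif": motif}
            for motif, hlist in hits.items()
            for h in hlist
        ]
        table = pd.DataFrame(rows, columns=["peak_id", "motif"])
    motifs = list(motif_names) if motif_names is not None else sorted(
        table["motif"].unique()
    )
    out = pd.DataFrame(0, index=[p.id for p in peaks], columns=motifs, dtype=np.int64)
    if len(table):
        grouped = table.groupby(["peak_id", "motif"]).size()
        for (pid, motif), n in grouped.items():
            if pid in out.index and motif in out.columns:
                out.loc[pid, motif] = n
    return out


def class_enrichment_permutation(
    counts_per_peak: pd.DataFrame,
    class_labels: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Motif enrichment of each class relative to the whole peak list.

    The statistic is the mean per-peak motif count within the class; the
    null resamples same-size subsets of all peaks.  Two-sided p with the
    add-one correction.
    """
    import warnings

    labels = np.asarray(class_labels, dtype=object)
    if len(labels) != len(counts_per_peak):
        raise ValueError("one class label per peak is required")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    rng = np.random.default_rng(seed)
    values = counts_per_peak.to_numpy(dtype=float)
    n = len(labels)
    results = []
    for klass in pd.unique(labels):
        members = np.nonzero(labels == klass)[0]
        size = members.size
        if size > n:
            raise ValueError("class larger than the peak set")
        if size < 2:
            raise ValueError(f"class {klass!r} has fewer than 2 peaks")
        draws = np.empty((n_perm, values.shape[1]))
        for b in range(n_perm):
            draws[b] = values[rng.choice(n, size=size, replace=False)].mean(axis=0)
        for mj, motif in enumerate(counts_per_peak.columns):
            obs = float(values[members, mj].mean())
            null = draws[:, mj]
            mu = float(null.mean())
            p = (1.0 + np.sum(np.abs(null - mu) >= abs(obs - mu) - 1e-12)) / (1.0 + n_perm)
            fold = obs / mu if mu > 0 else np.inf
            results.append(
                EnrichmentResult(str(klass), str(motif), obs, mu, fold, float(p), n_perm)
            )
    return results


def group_difference_permutation(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    side: str = "one_sided",
    exact: bool = False,
) -> float:
    """Permutation p-value for mean(A) - mean(B) under label shuffles.

    One-sided by default (how often a shuffled difference is at least the
    observed one); add-one corrected, so the floor is 1/(1+n_perm).  With
    ``exact`` the full set of label assignments is enumerated instead
    (feasible only for small groups) and the p-value is the exact fraction
    of assignments with a difference at least the observed one.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be > 0")
    if side not in ("one_sided", "two_sided"):
        raise ValueError("side must be 'one_sided' or 'two_sided'")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    n_a, n_b = a.size, b.size
    if exact:
        from itertools import combinations

        total = 0
        hits = 0
        csum = pooled.sum()
        for combo in combinations(range(n_a + n_b), n_a):
            sa = pooled[list(combo)].sum()
            diff = sa / n_a - (csum - sa) / n_b
            total += 1
            if side == "one_sided":
                hits += diff >= observed - 1e-12
            else:
                hits += abs(diff) >= abs(observed) - 1e-12
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_perm:
        chunk = min(20_000, n_perm - done)
        mat = rng.permuted(np.tile(pooled, (chunk, 1)), axis=1)
        diffs = mat[:, :n_a].mean(axis=1) - mat[:, n_a:].mean(axis=1)
        if side == "one_sided":
            hits += int(np.sum(diffs >= observed - 1e-12))
        else:
            hits += int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
        done += chunk
    return (1.0 + hits) / (1.0 + n_perm)
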