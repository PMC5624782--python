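"""Differential binding between uniform morphogen concentrations.

The statistical core of the pipeline: CPM scaling, a common-dispersion
negative-binomial exact test between conditions (the edgeR-style test for
small replicate counts), Benjamini-Hochberg FDR, a four-class
concentration-sensitivity decision table, and noise-region z-score
normalization.

The model: region counts are NB distributed with variance = mean + phi *
mean^2 (phi = common dispersion shared by all regions).  For a two-group
comparison the replicate counts are first scaled to a common library size;
conditional on the total s = a + b of the two group sums, the null
distribution of the group-A sum is known exactly (a sum of i.i.d. NB
variables is NB), and the two-sided p-value is the probability of all
outcomes no more likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix

__all__ = [
    "NormalizationStats",
    "ExactTestResult",
    "SensitivityCall",
    "DispersionModel",
    "CLASSES",
    "estimate_common_dispersion",
    "nb_exact_test",
    "exact_test_matrix",
    "bh_fdr",
    "classify_sensitivity",
    "zscore_normalize",
    "BindingSensitivityModel",
    "SensitivityResults",
]

CLASSES = ("CS-I", "CS-II", "CS-III", "Insensitive", "Unclassified")


@dataclass(frozen=True)
class NormalizationStats:
    """Mean/sd of CPM over noise regions, used for z-score display scaling."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class ExactTestResult:
    """One pairwise exact test: log2 fold change (positive = higher in A),
    two-sided exact p, and (once adjusted) BH q."""

    logfc: float
    p: float
    q: float | None = None


@dataclass(frozen=True)
class DispersionModel:
    """Common NB dispersion phi >= 0 (variance = mu + phi * mu^2)."""

    phi: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class SensitivityCall:
    """Per-region contrasts (high-med, high-low, med-low) and assigned class."""

    high_vs_med: ExactTestResult
    high_vs_low: ExactTestResult
    med_vs_low: ExactTestResult
    klass: str


def _equalize_libraries(counts: np.ndarray, libs: np.ndarray) -> np.ndarray:
    """Scale each column to the geometric-mean library size, rounding half-to-even."""
    libs = np.asarray(libs, dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    target = np.exp(np.mean(np.log(libs)))
    return np.rint(counts * (target / libs)).astype(np.int64)


def estimate_common_dispersion(
    counts: CountMatrix, groups: Sequence[str] | None = None
) -> DispersionModel:
    """Method-of-moments common dispersion pooled across regions.

    After library equalization, each region/group with replication
    contributes its sample mean m and variance v; since var = m + phi*m^2,
    phi is estimated by pooling (v - m) against m^2 over all contributions
    and flooring at 0.
    """
    if counts.n_samples < 2:
        raise ValueError("dispersion is unidentifiable from a single sample")
    if groups is None:
        groups = sorted({s.condition for s in counts.samples})
    eq = _equalize_libraries(counts.counts, counts.library_sizes)
    num = 0.0
    den = 0.0
    for g in groups:
        cols = counts.columns(g)
        if cols.size < 2:
            continue
        block = eq[:, cols].astype(float)
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        keep = m > 0
        num += float(np.sum(v[keep] - m[keep]))
        den += float(np.sum(m[keep] ** 2))
    if den == 0.0:
        raise ValueError("no replicated groups with nonzero counts")
    return DispersionModel(max(0.0, num / den))


def _conditional_pmf(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Null conditional pmf of the group-A sum given total s.

    Group sums are NB with sizes n_a/phi and n_b/phi and means proportional
    to replicate numbers (Poisson when phi == 0, giving a binomial
    conditional law).  Returned vector is over x = 0..s and sums to 1.
    """
    x = np.arange(s + 1)
    if s == 0:
        return np.ones(1)
    if phi == 0.0:
        logf = stats.binom.logpmf(x, s, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        mu_a = s * n_a / (n_a + n_b)
        mu_b = s - mu_a
        logf = stats.nbinom.logpmf(x, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
            s - x, r_b, r_b / (r_b + mu_b)
        )
        logf -= logf.max()
    f = np.exp(logf)
    return f / f.sum()


def _two_sided_tail(f: np.ndarray, a: int) -> float:
    """Sum of probabilities of outcomes no more likely than the observed one."""
    return float(f[f <= f[a] * (1.0 + 1e-12)].sum())


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    dispersion: float,
    lib_a: Sequence[int] | None = None,
    lib_b: Sequence[int] | None = None,
) -> ExactTestResult:
    """Exact NB test between two replicate groups at common dispersion.

    Counts are scaled to a common library size, summed within groups, and
    the two-sided conditional p computed by enumeration over the total.
    The log2 fold change uses a pseudo-count of 0.5 per group (never used
    for the p-value) and is positive when group A is higher per replicate.
    """
    a_arr = np.asarray(counts_a, dtype=float)
    b_arr = np.asarray(counts_b, dtype=float)
    if (a_arr < 0).any() or (b_arr < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = len(a_arr), len(b_arr)
    all_counts = np.concatenate([a_arr, b_arr])[None, :]
    libs = (
        np.concatenate([np.asarray(lib_a, dtype=float), np.asarray(lib_b, dtype=float)])
        if lib_a is not None and lib_b is not None
        else np.ones(n_a + n_b)
    )
    eq = _equalize_libraries(all_counts, libs)[0]
    a = int(eq[:n_a].sum())
    b = int(eq[n_a:].sum())
    s = a + b
    p = 1.0 if s == 0 else _two_sided_tail(_conditional_pmf(s, n_a, n_b, dispersion), a)
    logfc = float(np.log2((a + 0.5) / n_a) - np.log2((b + 0.5) / n_b))
    return ExactTestResult(logfc=logfc, p=p)


def exact_test_matrix(
    counts: CountMatrix, cond_a: str, cond_b: str, dispersion: float
) -> pd.DataFrame:
    """Vectorized exact tests for all regions between two conditions.

    Regions sharing a total s share the same null conditional law, so the
    pmf is computed once per distinct total.  Returns a frame with columns
    ``logfc`` (positive = higher in ``cond_a``) and ``p``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    cols_a = counts.columns(cond_a)
    cols_b = counts.columns(cond_b)
    n_a, n_b = cols_a.size, cols_b.size
    eq = _equalize_libraries(
        counts.counts[:, np.concatenate([cols_a, cols_b])],
        counts.library_sizes[np.concatenate([cols_a, cols_b])],
    )
    a = eq[:, :n_a].sum(axis=1)
    b = eq[:, n_a:].sum(axis=1)
    s = a + b
    p = np.ones(len(s))
    for total in np.unique(s):
        if total == 0:
            continue
        f = _conditional_pmf(int(total), n_a, n_b, dispersion)
        order = np.argsort(f, kind="stable")
        csum = np.cumsum(f[order])
        # tail(a) = sum of f over outcomes with f <= f[a]; rank via sorted pmf
        rank = np.empty(total + 1, dtype=np.int64)
        rank[order] = np.arange(total + 1)
        # outcomes tied with f[a] must all be included
        fs = f[order]
        idx = np.searchsorted(fs, fs * (1.0 + 1e-12), side="right") - 1
        tail_by_outcome = csum[idx]
        sel = s == total
        p[sel] = tail_by_outcome[rank[a[sel]]]
    p = np.clip(p, 0.0, 1.0)
    logfc = np.log2((a + 0.5) / n_a) - np.log2((b + 0.5) / n_b)
    return pd.DataFrame({"logfc": logfc, "p": p}, index=counts.region_ids)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sig_decrease(q: float, logfc: float, alpha: float) -> bool:
    """Significant reduction at the lower concentration: q <= alpha and the
    higher-concentration group is the larger one (positive logFC)."""
    return q <= alpha and logfc > 0


def _sig_increase(q: float, logfc: float, alpha: float) -> bool:
    return q <= alpha and logfc < 0


def classify_sensitivity(
    high_vs_med: ExactTestResult,
    high_vs_low: ExactTestResult,
    med_vs_low: ExactTestResult,
    alpha: float = 0.05,
) -> str:
    """Assign a concentration-sensitivity class from the three contrasts.

    Decision table, evaluated in order:

    1. any significant *increase* at a lower concentration -> Unclassified
    2. reduced high->med and high->low                      -> CS-I
    3. reduced high->low and med->low                       -> CS-II
    4. reduced high->low only                               -> CS-III
    5. nothing significant                                  -> Insensitive
    6. any residual pattern                                 -> Unclassified
    """
    for res in (high_vs_med, high_vs_low, med_vs_low):
        if res.q is None:
            raise ValueError("contrasts must carry BH-adjusted q values")
    hm, hl, ml = high_vs_med, high_vs_low, med_vs_low
    if any(_sig_increase(r.q, r.logfc, alpha) for r in (hm, hl, ml)):
        return "Unclassified"
    dec_hm = _sig_decrease(hm.q, hm.logfc, alpha)
    dec_hl = _sig_decrease(hl.q, hl.logfc, alpha)
    dec_ml = _sig_decrease(ml.q, ml.logfc, alpha)
    if dec_hm and dec_hl:
        return "CS-I"
    if dec_hl and dec_ml:
        return "CS-II"
    if dec_hl and not dec_hm and not dec_ml:
        return "CS-III"
    if not (dec_hm or dec_hl or dec_ml):
        return "Insensitive"
    return "Unclassified"


def zscore_normalize(values: np.ndarray, stats_: NormalizationStats) -> np.ndarray:
    """z = (value - mu) / sigma with mu/sigma taken over noise regions."""
    return (np.asarray(values, dtype=float) - stats_.mu) / stats_.sigma


def noise_normalization_stats(cpm_values: np.ndarray) -> NormalizationStats:
    """Normalization stats from one sample's noise-region CPM values."""
    sigma = float(np.std(cpm_values))
    if sigma == 0:
        raise ValueError("noise-region CPM has zero spread")
    return NormalizationStats(mu=float(np.mean(cpm_values)), sigma=sigma)


_CONTRASTS = (("high", "med"), ("high", "low"), ("med", "low"))


def _classify_vectorized(tables: dict[str, pd.DataFrame], alpha: float) -> np.ndarray:
    """Array form of :func:`classify_sensitivity` (same decision table)."""
    dec = {}
    inc = {}
    for name, tab in tables.items():
        q = tab["q"].to_numpy()
        lf = tab["logfc"].to_numpy()
        dec[name] = (q <= alpha) & (lf > 0)
        inc[name] = (q <= alpha) & (lf < 0)
    hm, hl, ml = dec["high_vs_med"], dec["high_vs_low"], dec["med_vs_low"]
    any_inc = inc["high_vs_med"] | inc["high_vs_low"] | inc["med_vs_low"]
    classes = np.full(hm.shape, "Unclassified", dtype=object)
    none_sig = ~(hm | hl | ml)
    classes[~any_inc & none_sig] = "Insensitive"
    classes[~any_inc & hl & ~hm & ~ml] = "CS-III"
    classes[~any_inc & hl & ml & ~hm] = "CS-II"
    classes[~any_inc & hm & hl] = "CS-I"
    return classes


class BindingSensitivityModel:
    """Concentration-sensitivity model over a peak + noise-region count matrix.

    Parameters
    ----------
    counts
        Count matrix whose samples carry conditions named by
        ``condition_order`` (highest concentration first).
    condition_order
        The three uniform-concentration condition labels, high/med/low.
    is_noise
        Boolean mask over regions marking the non-peak noise regions.  Noise
        regions take part in FDR adjustment (and provide display
        normalization) but receive no class.
    """

    def __init__(
        self,
        counts: CountMatrix,
        condition_order: tuple[str, str, str] = ("high", "med", "low"),
        is_noise: np.ndarray | None = None,
    ) -> None:
        if len(condition_order) != 3:
            raise ValueError("exactly three concentration conditions are required")
        self.counts = counts
        self.condition_order = tuple(condition_order)
        self.is_noise = (
            np.zeros(counts.n_regions, dtype=bool)
            if is_noise is None
            else np.asarray(is_noise, dtype=bool)
        )
        if self.is_noise.shape != (counts.n_regions,):
            raise ValueError("is_noise must have one flag per region")

    def fit(self, alpha: float = 0.05, dispersion: float | None = None) -> "SensitivityResults":
        """Run the three pairwise exact tests, BH-adjust each contrast across
        all regions (peaks plus noise), and classify the peaks."""
        high, med, low = self.condition_order
        phi = (
            estimate_common_dispersion(self.counts).phi
            if dispersion is None
            else float(dispersion)
        )
        name_map = {"high": high, "med": med, "low": low}
        tables = {}
        for ca, cb in _CONTRASTS:
            tab = exact_test_matrix(self.counts, name_map[ca], name_map[cb], phi)
            tab["q"] = bh_fdr(tab["p"].to_numpy())
            tables[f"{ca}_vs_{cb}"] = tab
        classes = _classify_vectorized(tables, alpha)
        classes[self.is_noise] = "noise"
        return SensitivityResults(self, tables, classes, phi, alpha)


class SensitivityResults:
    """Fitted results: per-contrast tests, classes, dispersion, class sizes."""

    def __init__(self, model, tables, classes, dispersion, alpha) -> None:
        self.model = model
        self.tables = tables
        self.classes = classes
        self.dispersion = dispersion
        self.alpha = alpha

    @property
    def class_sizes(self) -> dict[str, int]:
        mask = ~self.model.is_noise
        vals, counts_ = np.unique(self.classes[mask], return_counts=True)
        sizes = {k: 0 for k in CLASSES}
        sizes.update(dict(zip(vals.tolist(), counts_.tolist())))
        return sizes

    def to_frame(self) -> pd.DataFrame:
        """Per-region table of logFC/p/q per contrast plus assigned class."""
        out = pd.DataFrame(index=self.model.counts.region_ids)
        for name, tab in self.tables.items():
            out[f"logfc_{name}"] = tab["logfc"].to_numpy()
            out[f"p_{name}"] = tab["p"].to_numpy()
            out[f"q_{name}"] = tab["q"].to_numpy()
        out["class"] = self.classes
        return out

    def summary(self) -> str:
        sizes = self.class_sizes
        n_peaks = int((~self.model.is_noise).sum())
        lines = [
            "Concentration-sensitivity classification",
            "========================================",
            f"regions tested: {self.model.counts.n_regions} "
            f"({n_peaks} peaks, {int(self.model.is_noise.sum())} noise)",
            f"common dispersion: {self.dispersion:.4f}",
            f"FDR threshold:     {self.alpha:g}",
            "",
            "class sizes:",
        ]
        for k in CLASSES:
            pct = 100.0 * sizes[k] / n_peaks if n_peaks else 0.0
            lines.append(f"  {k:<13}{sizes[k]:>6}  ({pct:.1f}%)")
        return "\n".join(lines)

    def plot_classes(self, ax=None):
        """Bar chart of class sizes (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = self.class_sizes
        ax.bar(list(sizes.keys()), list(sizes.values()))
        ax.set_ylabel("peaks")
        ax.set_title("concentration-sensitivity classes")
        return ax
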