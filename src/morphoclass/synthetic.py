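"""Synthetic worlds with the statistical structure the pipeline assumes.

The generator plants ground truth for every downstream stage: peaks with a
known concentration-sensitivity class whose ChIP means follow a Hill dose
response at three uniform morphogen concentrations; NB-distributed counts at
a common dispersion; ATAC counts across wild-type and mutant genotypes with
planted accessibility-dependence labels; fragment lengths from an
exponential + Gaussian mixture; consensus motifs planted into random
background sequence; nucleosome dyads over motifs of closed peaks; and
reporter-tile / TSS annotations with class-correlated activity.

Class dose-response design.  Each class gets a Hill midpoint K (nM) and
exponent n chosen so the planted class exhibits its defining contrast
pattern at the simulated depth: CS-I (K above the medium concentration,
cooperative) loses binding at both medium and low; CS-II (K below the
medium concentration, cooperative) is saturated by the medium level and
loses binding only at low; Insensitive (tiny K) is saturated everywhere.
CS-III regions are modelled as weakly bound, non-cooperative targets
(n = 1, intermediate K, lower signal weight), mirroring the observation
that the weakest-effect class also shows the weakest binding; their
defining pattern (a reduction detectable only between the extreme
concentrations) is intrinsically a borderline-power regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix, Sample
from .regions import GenomicInterval, Peak

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "occupancy",
    "generate_world",
    "simulate_chip_counts",
    "simulate_atac_counts",
    "simulate_fragments",
    "simulate_motifs_and_sequence",
    "simulate_nucleosomes_and_annotations",
    "write_fasta",
]

CLASS_NAMES = ("CS-I", "CS-II", "CS-III", "Insensitive")

MOTIF_CONSENSUS = {"bcd_strong": "TAATCC", "bcd_weak": "TAAGCC", "zld": "CAGGTAG"}

# dm3-style euchromatic chromosome arms (opaque names, truncated lengths)
DEFAULT_CHROM_LENGTHS = {
    "chr2L": 23_000_000,
    "chr2R": 21_000_000,
    "chr3L": 24_000_000,
    "chr3R": 27_000_000,
    "chr4": 1_300_000,
    "chrX": 22_000_000,
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic world; defaults mirror the study conditions."""

    # peaks and classes
    n_peaks: dict[str, int] = field(
        default_factory=lambda: {k: 250 for k in CLASS_NAMES}
    )
    peak_width_median: float = 500.0
    peak_width_sigma: float = 0.35  # lognormal sigma of widths

    # uniform morphogen concentrations (nM), low/med/high
    concentrations: tuple[float, float, float] = (12.58, 98.84, 242.61)
    hill_k: dict[str, float] = field(
        default_factory=lambda: {"CS-I": 160.0, "CS-II": 30.0, "CS-III": 80.0,
                                 "Insensitive": 1.0}
    )
    hill_n: dict[str, float] = field(
        default_factory=lambda: {"CS-I": 3.0, "CS-II": 3.0, "CS-III": 1.5,
                                 "Insensitive": 1.0}
    )

    # ChIP count model
    dispersion: float = 0.05
    depth: float = 1e6
    # expected fraction of the library captured per fully occupied peak
    signal_weight: dict[str, float] = field(
        default_factory=lambda: {"CS-I": 2e-4, "CS-II": 2e-4, "CS-III": 1e-5,
                                 "Insensitive": 2e-4}
    )
    weight_sigma: float = 0.25  # lognormal spread of per-peak weights
    noise_weight: float = 5e-6  # per noise region, concentration independent

    # ATAC model
    atac_weight: float = 2e-4
    atac_fold_change: float = 4.0  # accessibility reduction in dependent mutants
    background_weight: float = 2e-5
    frac_open: float = 0.6
    exp_rate: float = 1.0 / 60.0
    nuc_mean: float = 200.0
    nuc_sd: float = 30.0

    # region bookkeeping
    n_noise_regions: int = 50_000
    n_background_regions: int = 25_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )

    # planted annotation structure
    motif_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "CS-I": {"bcd_strong": 3.0, "bcd_weak": 2.0, "zld": 1.0},
            "CS-II": {"bcd_strong": 2.5, "bcd_weak": 2.0, "zld": 1.0},
            "CS-III": {"bcd_strong": 1.0, "bcd_weak": 1.0, "zld": 1.0},
            "Insensitive": {"bcd_strong": 0.5, "bcd_weak": 0.5, "zld": 3.0},
        }
    )
    dependence_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "CS-I": {"bcd": 0.33, "zld": 0.45},
            "CS-II": {"bcd": 0.32, "zld": 0.45},
            "CS-III": {"bcd": 0.06, "zld": 0.45},
            "Insensitive": {"bcd": 0.01, "zld": 0.45},
        }
    )
    tile_active_fraction: dict[str, float] = field(
        default_factory=lambda: {"CS-I": 0.73, "CS-II": 0.74, "CS-III": 0.52,
                                 "Insensitive": 0.5}
    )
    tile_overlap_fraction: float = 0.3  # fraction of peaks covered by a tile
    n_extra_tiles: int = 1000
    tile_width: int = 2000
    background_tile_active_fraction: float = 0.085
    tss_near_fraction: float = 0.3  # fraction of peaks with a TSS within window
    tss_window: int = 500
    n_extra_tss: int = 2000

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_open <= 1.0:
            raise ValueError("frac_open must lie in [0, 1]")
        for name, val in (("exp_rate", self.exp_rate), ("nuc_mean", self.nuc_mean),
                          ("nuc_sd", self.nuc_sd), ("depth", self.depth)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for k in self.n_peaks:
            if k not in CLASS_NAMES:
                raise ValueError(f"unknown class label {k!r}")


@dataclass
class SyntheticWorld:
    """Ground-truth container for one synthetic experiment."""

    config: SyntheticConfig
    chrom_lengths: dict[str, int]
    peaks: list[Peak]
    true_class: np.ndarray  # per peak
    bcd_dependent: np.ndarray  # per peak, bool
    zld_dependent: np.ndarray
    signal_weight: np.ndarray  # per peak expected library fraction at occupancy 1
    atac_weight: np.ndarray
    noise_regions: list[GenomicInterval]
    background_regions: list[GenomicInterval]
    tss: list[tuple[str, int]]
    tiles: list[GenomicInterval]
    tile_activity: np.ndarray  # per tile: active_early / active_late / inactive
    # populated by simulate_motifs_and_sequence
    sequences: dict[str, str] = field(default_factory=dict)
    planted_motifs: pd.DataFrame | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def class_indices(self, klass: str) -> np.ndarray:
        return np.nonzero(self.true_class == klass)[0]


def occupancy(c, k, n):
    """Hill occupancy ``c**n / (k**n + c**n)``, strictly increasing in c."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0) or k <= 0:
        raise ValueError("concentration and K must be positive")
    if np.any(np.asarray(n) < 1):
        raise ValueError("Hill exponent must be >= 1")
    ratio = (np.asarray(c, dtype=float) / k) ** n
    out = ratio / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    """Deterministic child generator for one sub-stage of the world."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_lengths: dict[str, int], widths: np.ndarray
) -> list[GenomicInterval]:
    """Place intervals of given widths without overlap, spread across chroms.

    Per chromosome, starts are drawn by the stick-breaking construction:
    sorted uniforms over the length minus the total width budget, shifted by
    the cumulative widths, which guarantees disjointness.
    """
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    assignment = rng.choice(len(chroms), size=len(widths), p=probs)
    out: list[GenomicInterval | None] = [None] * len(widths)
    for ci, chrom in enumerate(chroms):
        idx = np.nonzero(assignment == ci)[0]
        if idx.size == 0:
            continue
        w = widths[idx]
        slack = chrom_lengths[chrom] - int(w.sum())
        if slack <= 0:
            raise ValueError(f"chromosome {chrom} too small for requested regions")
        gaps = np.sort(rng.uniform(0, slack, size=idx.size)).astype(np.int64)
        starts = gaps + np.concatenate([[0], np.cumsum(w[:-1])])
        for j, i in enumerate(idx):
            out[i] = GenomicInterval(chrom, int(starts[j]), int(starts[j] + w[j]))
    return out  # type: ignore[return-value]


def _sample_outside_peaks(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    peaks: list[Peak],
    widths: np.ndarray,
) -> list[GenomicInterval]:
    """Sample regions of the given widths that do not overlap any peak."""
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        ivs = sorted((p.start, p.end) for p in peaks if p.chrom == chrom)
        starts_by_chrom[chrom] = np.array([s for s, _ in ivs])
        ends_by_chrom[chrom] = np.array([e for _, e in ivs])
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out: list[GenomicInterval] = []
    need = len(widths)
    wpool = np.asarray(widths, dtype=np.int64)
    attempts = 0
    while len(out) < need:
        attempts += 1
        if attempts > 200:
            raise ValueError("could not place regions outside peaks")
        m = need - len(out)
        ci = rng.choice(len(chroms), size=m, p=probs)
        w = wpool[len(out) : len(out) + m]
        for k in range(m):
            chrom = chroms[ci[k]]
            start = int(rng.integers(0, chrom_lengths[chrom] - int(w[k])))
            end = start + int(w[k])
            ps, pe = starts_by_chrom[chrom], ends_by_chrom[chrom]
            j = np.searchsorted(ps, end)
            if j > 0 and pe[j - 1] > start:
                continue  # overlaps a peak; redraw on a later pass
            out.append(GenomicInterval(chrom, start, end))
    return out


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Build the full ground-truth world (deterministic given the seed)."""
    rng = _rng(config, 0)
    labels = [k for k in CLASS_NAMES for _ in range(config.n_peaks.get(k, 0))]
    n = len(labels)
    widths = np.maximum(
        50,
        np.rint(
            config.peak_width_median
            * np.exp(rng.normal(0.0, config.peak_width_sigma, size=n))
        ),
    ).astype(np.int64)
    intervals = _place_nonoverlapping(rng, config.chrom_lengths, widths)
    # keep class labels attached to their intervals but emit coordinate order
    perm = sorted(range(n), key=lambda i: (intervals[i].chrom, intervals[i].start))
    peaks = []
    true_class = []
    for rank, i in enumerate(perm):
        iv = intervals[i]
        summit = int(rng.integers(iv.start + len(iv) // 4, iv.end - len(iv) // 4))
        peaks.append(Peak(iv, f"peak_{rank:05d}", summit))
        true_class.append(labels[i])
    true_class = np.array(true_class, dtype=object)

    dep_rng = _rng(config, 1)
    bcd_dep = np.zeros(n, dtype=bool)
    zld_dep = np.zeros(n, dtype=bool)
    for i, klass in enumerate(true_class):
        fr = config.dependence_fractions[klass]
        bcd_dep[i] = dep_rng.uniform() < fr["bcd"]
        zld_dep[i] = dep_rng.uniform() < fr["zld"]

    w_rng = _rng(config, 2)
    signal_w = np.array(
        [
            config.signal_weight[k] * np.exp(w_rng.normal(0.0, config.weight_sigma))
            for k in true_class
        ]
    )
    atac_w = config.atac_weight * np.exp(w_rng.normal(0.0, config.weight_sigma, size=n))

    reg_rng = _rng(config, 3)
    noise_w = np.maximum(
        50,
        np.rint(config.peak_width_median
                * np.exp(reg_rng.normal(0.0, config.peak_width_sigma,
                                        size=config.n_noise_regions))),
    ).astype(np.int64)
    noise_regions = _sample_outside_peaks(reg_rng, config.chrom_lengths, peaks, noise_w)
    bg_w = np.maximum(
        50,
        np.rint(config.peak_width_median
                * np.exp(reg_rng.normal(0.0, config.peak_width_sigma,
                                        size=config.n_background_regions))),
    ).astype(np.int64)
    background_regions = _sample_outside_peaks(reg_rng, config.chrom_lengths, peaks, bg_w)

    ann_rng = _rng(config, 4)
    tss: list[tuple[str, int]] = []
    near = ann_rng.uniform(size=n) < config.tss_near_fraction
    for i, peak in enumerate(peaks):
        if near[i]:
            offset = int(ann_rng.integers(-config.tss_window, config.tss_window + 1))
            pos = max(0, peak.anchor + offset)
            tss.append((peak.chrom, pos))
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for ci in ann_rng.choice(len(chroms), size=config.n_extra_tss, p=probs):
        tss.append((chroms[ci], int(ann_rng.integers(0, config.chrom_lengths[chroms[ci]]))))

    tiles: list[GenomicInterval] = []
    activity: list[str] = []
    covered = ann_rng.uniform(size=n) < config.tile_overlap_fraction
    for i, peak in enumerate(peaks):
        if not covered[i]:
            continue
        start = max(0, peak.anchor - int(ann_rng.integers(0, config.tile_width)))
        tiles.append(GenomicInterval(peak.chrom, start, start + config.tile_width))
        if ann_rng.uniform() < config.tile_active_fraction[true_class[i]]:
            activity.append("active_early")
        else:
            activity.append("active_late" if ann_rng.uniform() < 0.5 else "inactive")
    extra_w = np.full(config.n_extra_tiles, config.tile_width, dtype=np.int64)
    for iv in _sample_outside_peaks(ann_rng, config.chrom_lengths, peaks, extra_w):
        tiles.append(iv)
        if ann_rng.uniform() < config.background_tile_active_fraction:
            activity.append("active_early")
        else:
            activity.append("active_late" if ann_rng.uniform() < 0.3 else "inactive")

    return SyntheticWorld(
        config=config,
        chrom_lengths=dict(config.chrom_lengths),
        peaks=peaks,
        true_class=true_class,
        bcd_dependent=bcd_dep,
        zld_dependent=zld_dep,
        signal_weight=signal_w,
        atac_weight=atac_w,
        noise_regions=noise_regions,
        background_regions=background_regions,
        tss=tss,
        tiles=tiles,
        tile_activity=np.array(activity, dtype=object),
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with variance = mean + phi * mean^2 (Poisson when phi == 0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mean * phi))


def simulate_chip_counts(
    world: SyntheticWorld, n_replicates: int = 3
) -> tuple[CountMatrix, np.ndarray]:
    """ChIP counts at the three uniform concentrations over peaks + noise regions.

    Peak means are depth * weight * Hill occupancy at each concentration;
    noise regions have concentration-independent low means.  Returns the
    count matrix (conditions named low/med/high) and the noise-region mask.
    """
    cfg = world.config
    if cfg.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = _rng(cfg, 10)
    c_low, c_med, c_high = cfg.concentrations
    cond_conc = [("low", c_low), ("med", c_med), ("high", c_high)]
    occ = np.empty((world.n_peaks, 3))
    for i, klass in enumerate(world.true_class):
        for j, (_, c) in enumerate(cond_conc):
            occ[i, j] = occupancy(c, cfg.hill_k[klass], cfg.hill_n[klass])
    noise_mean = cfg.depth * cfg.noise_weight * np.exp(
        rng.normal(0.0, cfg.weight_sigma, size=cfg.n_noise_regions)
    )
    samples = []
    columns = []
    for j, (cond, _) in enumerate(cond_conc):
        peak_means = cfg.depth * world.signal_weight * occ[:, j]
        means = np.concatenate([peak_means, noise_mean])
        for rep in range(1, n_replicates + 1):
            samples.append(Sample(f"{cond}_{rep}", cond, rep))
            columns.append(_nb_draw(rng, means, cfg.dispersion))
    counts = np.column_stack(columns)
    regions = list(world.peaks) + list(world.noise_regions)
    ids = [p.id for p in world.peaks] + [
        f"noise_{i:05d}" for i in range(cfg.n_noise_regions)
    ]
    is_noise = np.array([False] * world.n_peaks + [True] * cfg.n_noise_regions)
    return CountMatrix(regions, samples, counts, None, ids), is_noise


GENOTYPES = ("WT", "bcd-", "zld-", "uBcd_low", "uBcd_med", "uBcd_high")


def simulate_atac_counts(
    world: SyntheticWorld,
    genotypes: tuple[str, ...] = ("WT", "bcd-", "zld-"),
    n_replicates: int = 3,
) -> tuple[CountMatrix, np.ndarray]:
    """ATAC counts over peaks + background regions for the given genotypes.

    Dependent peaks lose a configured fold of accessibility in the matching
    mutant; in uniform-morphogen genotypes the accessibility of
    morphogen-dependent peaks scales with Hill occupancy at that line's
    concentration.  Returns the count matrix and the background-region mask.
    """
    cfg = world.config
    for g in genotypes:
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype {g!r}")
    rng = _rng(cfg, 11)
    c_by_line = dict(zip(("uBcd_low", "uBcd_med", "uBcd_high"), cfg.concentrations))
    base = cfg.depth * world.atac_weight
    bg_mean = cfg.depth * cfg.background_weight * np.exp(
        rng.normal(0.0, cfg.weight_sigma, size=cfg.n_background_regions)
    )
    reduction = 1.0 / cfg.atac_fold_change
    samples = []
    columns = []
    for g in genotypes:
        means = base.copy()
        if g == "bcd-":
            means[world.bcd_dependent] *= reduction
        elif g == "zld-":
            means[world.zld_dependent] *= reduction
        elif g.startswith("uBcd"):
            c = c_by_line[g]
            for i in np.nonzero(world.bcd_dependent)[0]:
                klass = world.true_class[i]
                occ = occupancy(c, cfg.hill_k[klass], cfg.hill_n[klass])
                means[i] *= reduction + (1.0 - reduction) * occ
        all_means = np.concatenate([means, bg_mean])
        for rep in range(1, n_replicates + 1):
            samples.append(Sample(f"{g}_{rep}", g, rep))
            columns.append(_nb_draw(rng, all_means, cfg.dispersion))
    counts = np.column_stack(columns)
    regions = list(world.peaks) + list(world.background_regions)
    ids = [p.id for p in world.peaks] + [
        f"background_{i:05d}" for i in range(cfg.n_background_regions)
    ]
    is_background = np.array([False] * world.n_peaks + [True] * cfg.n_background_regions)
    return CountMatrix(regions, samples, counts, None, ids), is_background


def simulate_fragments(
    config: SyntheticConfig,
    n_fragments: int,
    world: SyntheticWorld | None = None,
) -> tuple[np.ndarray, list[GenomicInterval]]:
    """Fragment lengths from w*Exp(rate) + (1-w)*Normal(mean, sd), floored at 1.

    When a world is given, open-class (exponential) fragments are placed
    inside accessible peaks and nucleosomal fragments uniformly at random;
    otherwise all fragments land on a single synthetic chromosome.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    rng = _rng(config, 12)
    is_open = rng.uniform(size=n_fragments) < config.frac_open
    lengths = np.empty(n_fragments)
    lengths[is_open] = rng.exponential(1.0 / config.exp_rate, size=int(is_open.sum()))
    lengths[~is_open] = rng.normal(
        config.nuc_mean, config.nuc_sd, size=int((~is_open).sum())
    )
    lengths = np.maximum(1, np.rint(lengths)).astype(np.int64)
    intervals: list[GenomicInterval] = []
    if world is not None and world.n_peaks > 0:
        open_targets = [
            p for i, p in enumerate(world.peaks) if not world.bcd_dependent[i]
        ] or list(world.peaks)
        chroms = list(world.chrom_lengths)
        for i in range(n_fragments):
            ln = int(lengths[i])
            if is_open[i]:
                p = open_targets[int(rng.integers(0, len(open_targets)))]
                lo = p.start
                hi = max(lo + 1, p.end - ln)
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                lo, hi = 0, world.chrom_lengths[chrom] - ln
                p = None
            start = int(rng.integers(lo, hi))
            chrom = p.chrom if p is not None else chrom
            intervals.append(GenomicInterval(chrom, start, start + ln))
    else:
        chrom, span = "chrS", 10_000_000
        starts = rng.integers(0, span, size=n_fragments)
        intervals = [
            GenomicInterval(chrom, int(s), int(s) + int(ln))
            for s, ln in zip(starts, lengths)
        ]
    return lengths, intervals


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def simulate_motifs_and_sequence(world: SyntheticWorld) -> pd.DataFrame:
    """Random-background peak sequences with exact consensus motifs planted.

    Per-peak motif counts are Poisson with the class-specific expected
    counts; instances are placed at non-colliding offsets (error after 100
    failed attempts) on a random strand.  Sequences are stored on the world
    keyed by peak id; the returned frame records every planted instance.
    """
    cfg = world.config
    rng = _rng(cfg, 13)
    bases = np.array(list("ACGT"))
    records = []
    for i, peak in enumerate(world.peaks):
        width = len(peak.interval)
        seq = rng.integers(0, 4, size=width)
        occupied = np.zeros(width, dtype=bool)
        klass = world.true_class[i]
        for motif, expected in cfg.motif_bias[klass].items():
            consensus = MOTIF_CONSENSUS[motif]
            m = len(consensus)
            for _ in range(rng.poisson(expected)):
                placed = False
                for _attempt in range(100):
                    off = int(rng.integers(0, width - m))
                    if occupied[off : off + m].any():
                        continue
                    strand = "+" if rng.uniform() < 0.5 else "-"
                    inst = consensus if strand == "+" else _revcomp(consensus)
                    seq[off : off + m] = [("ACGT".index(b)) for b in inst]
                    occupied[off : off + m] = True
                    records.append(
                        {
                            "peak_id": peak.id,
                            "motif": motif,
                            "offset": off,
                            "start": peak.start + off,
                            "end": peak.start + off + m,
                            "strand": strand,
                            "class": klass,
                        }
                    )
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"could not place motif {motif} in {peak.id} after 100 attempts"
                    )
        world.sequences[peak.id] = "".join(bases[seq])
    world.planted_motifs = pd.DataFrame(
        records,
        columns=["peak_id", "motif", "offset", "start", "end", "strand", "class"],
    )
    return world.planted_motifs


def simulate_nucleosomes_and_annotations(
    world: SyntheticWorld, genotype: str = "bcd-"
) -> list[tuple[str, int]]:
    """Nucleosome dyads for one genotype: dyads are planted over the motifs
    of peaks that are closed in that genotype (e.g. morphogen-dependent peaks
    in the mutant), plus scattered background dyads outside peaks."""
    if world.planted_motifs is None:
        raise ValueError("run simulate_motifs_and_sequence first")
    cfg = world.config
    rng = _rng(cfg, 14)
    if genotype == "bcd-":
        closed = world.bcd_dependent
    elif genotype == "zld-":
        closed = world.zld_dependent
    elif genotype == "WT":
        closed = np.zeros(world.n_peaks, dtype=bool)
    else:
        raise ValueError(f"unknown genotype {genotype!r}")
    closed_ids = {world.peaks[i].id for i in np.nonzero(closed)[0]}
    dyads: list[tuple[str, int]] = []
    id_to_peak = {p.id: p for p in world.peaks}
    for row in world.planted_motifs.itertuples():
        if row.peak_id not in closed_ids or row.motif == "zld":
            continue
        peak = id_to_peak[row.peak_id]
        mid = (row.start + row.end) // 2
        dyads.append((peak.chrom, mid + int(rng.integers(-40, 41))))
    widths = np.full(2000, 1, dtype=np.int64)
    for iv in _sample_outside_peaks(rng, world.chrom_lengths, world.peaks, widths):
        dyads.append((iv.chrom, iv.start))
    return dyads


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
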