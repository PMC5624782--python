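"""Western-blot concentration estimation: relative band intensities to
absolute nuclear morphogen concentrations.

The chain: a literature total of ~1.5e8 molecules per embryo partitions
between nucleus and cytoplasm at ~4:1 with a cytoplasm:nucleus volume ratio
of ~9, giving a nuclear fraction of 4/(4+9) ~ 0.31.  Spread over 6000
cortical nuclei that is ~7,750 molecules per nucleus for a wild-type dose.
An optical calibration point (8 nM corresponding to 690 molecules) converts
molecules to nM at 8/690 = 0.011594203 nM/molecule.  A transgenic line's
dose is its Western band intensity (normalized to a loading control)
relative to wild type; molecules scale linearly with that relative level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ConcentrationModel",
    "WesternMeasurement",
    "nuclear_fraction",
    "molecules_per_nucleus",
    "nm_per_molecule",
    "estimate_nuclear_concentration",
    "relative_level_from_western",
]


def nuclear_fraction(k: float = 4.0, v: float = 9.0, rounded: bool = True) -> float:
    """Nuclear fraction k/(k+v) of total protein.

    ``k`` is the nuclear:cytoplasmic partition ratio and ``v`` the
    cytoplasm:nucleus volume ratio.  The published arithmetic uses the
    2-decimal rounding (0.31 rather than 4/13); pass ``rounded=False`` for
    the exact value.
    """
    if k <= 0 or v <= 0:
        raise ValueError("partition and volume ratios must be positive")
    frac = k / (k + v)
    return round(frac, 2) if rounded else frac


def molecules_per_nucleus(
    total: float = 1.5e8, fraction: float | None = None, n_nuclei: int = 6000
) -> float:
    """Molecules per nucleus: total * nuclear fraction / number of nuclei."""
    if fraction is None:
        fraction = nuclear_fraction()
    if total <= 0 or not 0 < fraction < 1 or n_nuclei <= 0:
        raise ValueError("total, fraction and n_nuclei must be positive (fraction in (0,1))")
    return total * fraction / n_nuclei


def nm_per_molecule(ref_nm: float = 8.0, ref_molecules: float = 690.0) -> float:
    """nM per molecule from the optical calibration point, to 9 decimals."""
    if ref_nm <= 0 or ref_molecules <= 0:
        raise ValueError("reference values must be positive")
    return round(ref_nm / ref_molecules, 9)


@dataclass(frozen=True)
class ConcentrationModel:
    """Constants of the molecules-to-nM conversion chain with derived values."""

    total_molecules_per_embryo: float = 1.5e8
    partition_ratio: float = 4.0  # nuclear : cytoplasmic
    volume_ratio: float = 9.0  # cytoplasm : nucleus
    n_nuclei: int = 6000
    ref_nm: float = 8.0
    ref_molecules: float = 690.0
    use_rounded_fraction: bool = True

    def __post_init__(self) -> None:
        for name in ("total_molecules_per_embryo", "partition_ratio", "volume_ratio",
                     "n_nuclei", "ref_nm", "ref_molecules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def nuclear_fraction(self) -> float:
        return nuclear_fraction(
            self.partition_ratio, self.volume_ratio, rounded=self.use_rounded_fraction
        )

    @property
    def total_nuclear_molecules(self) -> float:
        """Total molecules in all nuclei combined (~4.6e7 with defaults)."""
        return self.total_molecules_per_embryo * self.nuclear_fraction

    @property
    def molecules_per_nucleus(self) -> float:
        return molecules_per_nucleus(
            self.total_molecules_per_embryo, self.nuclear_fraction, self.n_nuclei
        )

    @property
    def nm_per_molecule(self) -> float:
        return nm_per_molecule(self.ref_nm, self.ref_molecules)


def estimate_nuclear_concentration(
    relative_level: float, model: ConcentrationModel | None = None
) -> tuple[int, float]:
    """(molecules per nucleus, nM) for a line at the given relative dose.

    Molecules are rounded to an integer before the nM conversion; nM is
    reported to two decimals, matching the published table arithmetic.
    """
    if relative_level <= 0:
        raise ValueError("relative_level must be positive")
    model = model or ConcentrationModel()
    molecules = round(relative_level * model.molecules_per_nucleus)
    nm = round(molecules * model.nm_per_molecule, 2)
    return int(molecules), nm


@dataclass(frozen=True)
class WesternMeasurement:
    """One lane: target band and loading-control band intensities."""

    label: str
    band_intensity: float
    control_intensity: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.band_intensity <= 0 or self.control_intensity <= 0:
            raise ValueError("band intensities must be positive")

    @property
    def normalized(self) -> float:
        return self.band_intensity / self.control_intensity


def relative_level_from_western(
    measurements: Sequence[WesternMeasurement], wild_type: str
) -> dict[str, float]:
    """Per-sample dose relative to wild type.

    Each lane is normalized to its loading control; replicate normalized
    levels are averaged per label after division by the wild-type mean
    normalized level.
    """
    by_label: dict[str, list[float]] = {}
    for m in measurements:
        by_label.setdefault(m.label, []).append(m.normalized)
    if wild_type not in by_label:
        raise ValueError(f"wild-type label {wild_type!r} missing from measurements")
    wt = sum(by_label[wild_type]) / len(by_label[wild_type])
    return {
        label: sum(v / wt for v in values) / len(values)
        for label, values in by_label.items()
    }


def concentration_table(
    relative_levels: dict[str, float], model: ConcentrationModel | None = None
) -> pd.DataFrame:
    """Published-style table: relative level, molecules/nucleus, nM per line."""
    model = model or ConcentrationModel()
    rows = []
    for label, level in relative_levels.items():
        molecules, nm = estimate_nuclear_concentration(level, model)
        rows.append(
            {"line": label, "relative_level": level, "molecules": molecules, "nM": nm}
        )
    return pd.DataFrame(rows, columns=["line", "relative_level", "molecules", "nM"])
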