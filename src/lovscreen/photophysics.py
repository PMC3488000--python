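"""Relative quantum yield and holoprotein-fraction calculations.

Two quantities characterise a purified flavin-binding fluorescent
protein sample:

* the **relative fluorescence quantum yield**, estimated against free
  FMN as a standard of known quantum yield (0.27):

      QY_sample = (F_sample / A_sample) / (F_std / A_std) * QY_std

  where ``F`` is the integrated 470-600 nm emission and ``A`` the
  absorbance at the 450 nm excitation band.  Measurements over a
  concentration series are aggregated as the mean of per-sample ``F/A``
  before the ratio is formed; and

* the **holoprotein fraction**: Beer-Lambert inversion of the 450 nm
  absorbance with the FMN molar absorptivity (12 500 /M/cm) gives the
  concentration of FMN-bound (fluorescent) holoprotein, which over the
  Bradford total protein concentration yields f_holo.  Apoprotein does
  not absorb at 450 nm, and free FMN in purified preparations is taken
  as negligible, so the 450 nm band reports holoprotein alone.

No refractive-index correction is applied to the quantum-yield ratio:
sample and standard are measured in the same aqueous buffer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import EmissionSpectrum

__all__ = [
    "FMN_QUANTUM_YIELD",
    "FMN_MOLAR_ABSORPTIVITY",
    "PhotophysicsSample",
    "QYStandard",
    "QYEstimate",
    "HoloFraction",
    "Measurement",
    "InconsistentMeasurementError",
    "integrate_emission",
    "quantum_yield",
    "holoprotein_concentration",
    "holo_fraction",
    "holo_fraction_series",
    "fold_with_error",
    "round_sig",
]

#: Fluorescence quantum yield of free FMN, the reference standard.
FMN_QUANTUM_YIELD = 0.27

#: Molar absorptivity of FMN at 450 nm, in 1/(M cm).
FMN_MOLAR_ABSORPTIVITY = 12_500.0


class InconsistentMeasurementError(ValueError):
    """Absorbance and total-protein readings cannot both be right."""


@dataclass(frozen=True)
class PhotophysicsSample:
    """One paired emission/absorbance/total-protein measurement.

    ``integrated_emission`` is the trapezoidal integral of the 470-600
    nm emission scan (a.u. * nm); ``absorbance_450`` is dimensionless;
    ``total_protein_conc`` is molar (from a Bradford assay) and may be
    omitted when only a quantum yield is wanted; ``path_length_cm`` is
    the cuvette path length.
    """

    integrated_emission: float
    absorbance_450: float
    total_protein_conc: float | None = None
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.absorbance_450 < 0:
            raise ValueError("absorbance cannot be negative")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")


@dataclass(frozen=True)
class QYStandard:
    """A reference concentration series with known quantum yield."""

    samples: tuple[PhotophysicsSample, ...]
    known_qy: float = FMN_QUANTUM_YIELD

    def __post_init__(self) -> None:
        if not 0.0 < self.known_qy <= 1.0:
            raise ValueError("known quantum yield must lie in (0, 1]")
        if not self.samples:
            raise ValueError("standard series is empty")


@dataclass(frozen=True)
class QYEstimate:
    value: float
    sd: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("quantum yield cannot be negative")


@dataclass(frozen=True)
class HoloFraction:
    """Holoprotein concentration and bound fraction of one preparation."""

    c_holo: float
    f_holo: float
    sd: float
    epsilon: float = FMN_MOLAR_ABSORPTIVITY


@dataclass(frozen=True)
class Measurement:
    """A scalar with a standard-deviation uncertainty."""

    value: float
    sd: float = 0.0


def integrate_emission(
    spectrum: EmissionSpectrum, interval: tuple[float, float] = (470.0, 600.0)
) -> float:
    """Trapezoidal integral of the emission over ``interval`` (a.u. * nm)."""
    lo, hi = interval
    wl = spectrum.wavelengths
    if lo < wl[0] or hi > wl[-1] or lo >= hi:
        raise ValueError(f"interval {interval} outside scan [{wl[0]}, {wl[-1]}]")
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise ValueError("interval covers fewer than two grid points")
    return float(np.trapezoid(spectrum.intensities[mask], wl[mask]))


def _emission_per_absorbance(samples: Sequence[PhotophysicsSample]) -> np.ndarray:
    ratios = []
    for sample in samples:
        if sample.absorbance_450 <= 0:
            raise ValueError("absorbance must be positive for a quantum yield")
        ratios.append(sample.integrated_emission / sample.absorbance_450)
    return np.asarray(ratios, dtype=float)


def _mean_and_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    if values.size < 2:
        return mean, 0.0
    return mean, float(values.std(ddof=1) / math.sqrt(values.size))


def quantum_yield(
    samples: Sequence[PhotophysicsSample], standard: QYStandard
) -> QYEstimate:
    """Relative quantum yield of a sample series against a standard series.

    The per-sample emission-per-absorbance values ``F/A`` are averaged
    within each series before the ratio to the standard is formed and
    scaled by the standard's known quantum yield.  The uncertainty is
    the first-order (delta-method) propagation of the two series' F/A
    dispersions (standard errors of the means).
    """
    if not samples:
        raise ValueError("sample series is empty")
    sample_fa = _emission_per_absorbance(samples)
    standard_fa = _emission_per_absorbance(standard.samples)
    mean_s, sem_s = _mean_and_sem(sample_fa)
    mean_r, sem_r = _mean_and_sem(standard_fa)
    value = (mean_s / mean_r) * standard.known_qy
    rel = math.sqrt((sem_s / mean_s) ** 2 + (sem_r / mean_r) ** 2)
    return QYEstimate(value=value, sd=value * rel)


def holoprotein_concentration(
    absorbance_450: float,
    epsilon: float = FMN_MOLAR_ABSORPTIVITY,
    path_length_cm: float = 1.0,
) -> float:
    """Beer-Lambert holoprotein concentration ``A / (epsilon * l)`` in molar."""
    if epsilon <= 0 or path_length_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    if absorbance_450 < 0:
        raise ValueError("absorbance cannot be negative")
    return absorbance_450 / (epsilon * path_length_cm)


#: Holoprotein fractions in (1, 1 + this] are treated as measurement
#: round-off and clamped to 1; anything larger is inconsistent.
HOLO_FRACTION_TOLERANCE = 0.05


def holo_fraction(
    c_holo: float, total_protein_conc: float, sd: float = 0.0
) -> HoloFraction:
    """Fraction of FMN-bound holoprotein, ``c_holo / c_total``.

    Values just above 1 (up to 5%) are clamped to 1 with a warning;
    larger excesses indicate inconsistent absorbance/Bradford readings
    and raise :class:`InconsistentMeasurementError`.
    """
    if total_protein_conc <= 0:
        raise ValueError("total protein concentration must be positive")
    f = c_holo / total_protein_conc
    if f > 1.0 + HOLO_FRACTION_TOLERANCE:
        raise InconsistentMeasurementError(
            f"holoprotein fraction {f:.3f} exceeds 1 beyond tolerance; "
            "absorbance and total-protein readings disagree"
        )
    if f > 1.0:
        warnings.warn(
            f"holoprotein fraction {f:.3f} clamped to 1", stacklevel=2
        )
        f = 1.0
    return HoloFraction(c_holo=c_holo, f_holo=f, sd=sd)


def holo_fraction_series(samples: Sequence[PhotophysicsSample]) -> HoloFraction:
    """Mean holoprotein fraction over replicate measurements.

    Each sample must carry a Bradford total-protein concentration; the
    reported ``sd`` is the standard deviation of the per-replicate
    fractions.
    """
    if not samples:
        raise ValueError("no samples provided")
    fractions = []
    c_holos = []
    for sample in samples:
        if sample.total_protein_conc is None:
            raise ValueError("holoprotein fraction requires total protein")
        c = holoprotein_concentration(
            sample.absorbance_450, path_length_cm=sample.path_length_cm
        )
        c_holos.append(c)
        fractions.append(holo_fraction(c, sample.total_protein_conc).f_holo)
    arr = np.asarray(fractions)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return HoloFraction(
        c_holo=float(np.mean(c_holos)), f_holo=float(arr.mean()), sd=sd
    )


def fold_with_error(a: Measurement, b: Measurement) -> Measurement:
    """Ratio ``a/b`` with first-order error propagation (independent errors)."""
    if b.value <= 0:
        raise ValueError("denominator must be positive")
    ratio = a.value / b.value
    rel = math.sqrt((a.sd / a.value) ** 2 + (b.sd / b.value) ** 2) if a.value else 0.0
    return Measurement(value=ratio, sd=abs(ratio) * rel)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting layer only)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
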