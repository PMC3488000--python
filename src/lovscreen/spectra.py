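"""Plate fluorescence-screen processing and hit calling.

The screening readout of a directed-evolution campaign on a flavin-based
fluorescent protein is an emission scan per well (470-600 nm at 1 nm,
excitation 450 nm).  Processing follows the standard plate workflow:

1. subtract the per-plate background (uninduced cells),
2. smooth with a 3rd-order, 5-point Savitzky-Golay filter,
3. take peak wavelength and peak intensity,
4. compare each clone against the wild-type reference wells, and
5. classify: *beneficial* when the peak intensity is at least twofold
   the reference and/or the peak is shifted by 10 nm or more,
   *deleterious* when emission has collapsed (default: at most half the
   reference), *neutral* otherwise.

A candidate counts as a confirmed hit only when it meets the beneficial
criteria in every screening tier it was carried through (96-well plate,
shake flask, purified protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "BENEFICIAL",
    "NEUTRAL",
    "DELETERIOUS",
    "CLASSES",
    "TIERS",
    "EmissionSpectrum",
    "PeakMetrics",
    "ScreenThresholds",
    "TierCall",
    "ScreenRecord",
    "LibrarySummary",
    "SpectrumAlignmentError",
    "subtract_background",
    "savitzky_golay",
    "peak_metrics",
    "classify_clone",
    "confirm_across_tiers",
    "summarize_library",
    "aggregate_class_counts",
    "mean_spectrum",
    "read_plate_scans",
    "spectra_from_frame",
    "run_screen",
    "records_to_frame",
    "SATURATION_SCREEN_COUNTS",
    "PROXIMAL_SIX_TARGETS",
    "SENSITIVE_THREE_TARGETS",
]

BENEFICIAL = "beneficial"
NEUTRAL = "neutral"
DELETERIOUS = "deleterious"
CLASSES = (BENEFICIAL, DELETERIOUS, NEUTRAL)

#: Screening tiers in confirmation order.
TIERS = ("plate", "flask", "purified")

#: Published class counts of the nine single-site NNK saturation
#: libraries of the P. putida FbFP screen (beneficial / deleterious /
#: neutral clones per target position).
SATURATION_SCREEN_COUNTS: Mapping[str, Mapping[str, int]] = {
    "F37X": {BENEFICIAL: 2, DELETERIOUS: 71, NEUTRAL: 103},
    "D52X": {BENEFICIAL: 0, DELETERIOUS: 42, NEUTRAL: 138},
    "A53X": {BENEFICIAL: 0, DELETERIOUS: 60, NEUTRAL: 57},
    "R54X": {BENEFICIAL: 0, DELETERIOUS: 28, NEUTRAL: 152},
    "Q57X": {BENEFICIAL: 0, DELETERIOUS: 30, NEUTRAL: 150},
    "R70X": {BENEFICIAL: 0, DELETERIOUS: 18, NEUTRAL: 120},
    "N85X": {BENEFICIAL: 0, DELETERIOUS: 141, NEUTRAL: 20},
    "W94X": {BENEFICIAL: 0, DELETERIOUS: 15, NEUTRAL: 58},
    "Y112X": {BENEFICIAL: 0, DELETERIOUS: 31, NEUTRAL: 149},
}

#: The six FMN-proximal targets whose libraries were dominated by
#: wild-type-like (neutral) clones.
PROXIMAL_SIX_TARGETS = ("D52X", "R54X", "Q57X", "R70X", "W94X", "Y112X")

#: The three targets whose libraries were dominated by clones with
#: strongly diminished emission.
SENSITIVE_THREE_TARGETS = ("F37X", "A53X", "N85X")


class SpectrumAlignmentError(ValueError):
    """Two spectra do not share a wavelength grid."""


@dataclass
class EmissionSpectrum:
    """A fluorescence emission scan on a strictly increasing grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_nm: float = 450.0
    well: str | None = None
    clone: str | None = None
    role: str = "sample"
    tier: str = "plate"
    plate: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class PeakMetrics:
    peak_wavelength_nm: float
    peak_intensity: float


@dataclass(frozen=True)
class ScreenThresholds:
    """Hit-calling thresholds and smoothing settings.

    ``beneficial_fold`` (default 2.0) and ``beneficial_shift_nm``
    (default 10) encode the at-least-twofold-brighter and/or
    shifted-by-10-nm improvement criteria; ``deleterious_fold``
    (default 0.5) marks collapsed emission and is deliberately the
    log-symmetric mirror of the twofold criterion.
    """

    beneficial_fold: float = 2.0
    beneficial_shift_nm: float = 10.0
    deleterious_fold: float = 0.5
    sg_order: int = 3
    sg_window: int = 5

    def __post_init__(self) -> None:
        if not self.deleterious_fold < 1.0 < self.beneficial_fold:
            raise ValueError("need deleterious_fold < 1 < beneficial_fold")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("smoothing window must be odd and exceed the order")


@dataclass(frozen=True)
class TierCall:
    """Classification of one clone in one screening tier."""

    tier: str
    classification: str
    fold_change: float
    peak_shift_nm: float


@dataclass
class ScreenRecord:
    """A clone's per-tier metrics and its confirmed final class."""

    clone: str
    tier_calls: dict[str, TierCall] = field(default_factory=dict)
    final_class: str | None = None

    @property
    def fold_change(self) -> float | None:
        call = self.tier_calls.get("plate")
        return call.fold_change if call else None

    @property
    def peak_shift_nm(self) -> float | None:
        call = self.tier_calls.get("plate")
        return call.peak_shift_nm if call else None


def _require_same_grid(a: EmissionSpectrum, b: EmissionSpectrum) -> None:
    if a.wavelengths.shape != b.wavelengths.shape or not np.array_equal(
        a.wavelengths, b.wavelengths
    ):
        raise SpectrumAlignmentError("spectra are on different wavelength grids")


def subtract_background(
    sample: EmissionSpectrum, background: EmissionSpectrum
) -> EmissionSpectrum:
    """Pointwise background subtraction; negative residuals are kept."""
    _require_same_grid(sample, background)
    return replace(sample, intensities=sample.intensities - background.intensities)


def savitzky_golay(
    spectrum: EmissionSpectrum, order: int = 3, window: int = 5
) -> EmissionSpectrum:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Edges are handled by mirror padding; the wavelength grid is
    unchanged.  The default order-3 window-5 filter reproduces any
    cubic exactly on interior points.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than the order")
    if spectrum.intensities.size < window:
        raise ValueError("spectrum shorter than the smoothing window")
    smoothed = savgol_filter(spectrum.intensities, window, order, mode="mirror")
    return replace(spectrum, intensities=smoothed)


def peak_metrics(
    spectrum: EmissionSpectrum,
    search_range: tuple[float, float] | None = None,
) -> PeakMetrics:
    """Peak wavelength and intensity over a search range.

    Ties break toward the shorter wavelength (the first index of the
    maximum on the increasing grid).
    """
    wl, inten = spectrum.wavelengths, spectrum.intensities
    if search_range is not None:
        lo, hi = search_range
        if lo < wl[0] or hi > wl[-1] or lo > hi:
            raise ValueError("search range must lie within the scan")
        mask = (wl >= lo) & (wl <= hi)
        if not mask.any():
            raise ValueError("search range contains no grid points")
        wl, inten = wl[mask], inten[mask]
    idx = int(np.argmax(inten))
    return PeakMetrics(float(wl[idx]), float(inten[idx]))


def classify_clone(
    sample_metrics: PeakMetrics,
    reference_metrics: PeakMetrics,
    thresholds: ScreenThresholds = ScreenThresholds(),
    *,
    tier: str = "plate",
) -> TierCall:
    """Classify one clone against the wild-type reference in one tier.

    Beneficial when fold >= ``beneficial_fold`` or the absolute peak
    shift reaches ``beneficial_shift_nm``; deleterious when fold <=
    ``deleterious_fold``; neutral otherwise.  A spectral shift only
    counts for a clone that actually emits: when the fold is at or
    below the deleterious threshold the peak position carries no
    information (it is the argmax of noise), so such clones are called
    deleterious regardless of apparent shift.
    """
    if reference_metrics.peak_intensity <= 0:
        raise ValueError("reference peak intensity must be positive")
    fold = max(sample_metrics.peak_intensity, 0.0) / reference_metrics.peak_intensity
    shift = sample_metrics.peak_wavelength_nm - reference_metrics.peak_wavelength_nm
    shifted = (
        abs(shift) >= thresholds.beneficial_shift_nm
        and fold > thresholds.deleterious_fold
    )
    if fold >= thresholds.beneficial_fold or shifted:
        cls = BENEFICIAL
    elif fold <= thresholds.deleterious_fold:
        cls = DELETERIOUS
    else:
        cls = NEUTRAL
    return TierCall(tier=tier, classification=cls, fold_change=fold, peak_shift_nm=shift)


def confirm_across_tiers(tier_classes: Mapping[str, str]) -> str:
    """Combine per-tier classes into a confirmed final class.

    A clone is beneficial only when it is beneficial in *every* tier it
    was assayed in (plate, shake flask, purified protein); it is
    deleterious when the plate screen called it deleterious; anything
    else is neutral.
    """
    if not tier_classes:
        raise ValueError("no tier classifications provided")
    if "plate" not in tier_classes:
        raise ValueError("the plate tier is required")
    if all(cls == BENEFICIAL for cls in tier_classes.values()):
        return BENEFICIAL
    if tier_classes["plate"] == DELETERIOUS:
        return DELETERIOUS
    return NEUTRAL


@dataclass(frozen=True)
class LibrarySummary:
    """Class counts and percentage fractions for one or more libraries."""

    counts: Mapping[str, int]
    n_records: int

    @property
    def fractions(self) -> dict[str, float]:
        return {cls: self.counts[cls] / self.n_records for cls in CLASSES}

    @property
    def percentages(self) -> dict[str, float]:
        return {cls: 100.0 * frac for cls, frac in self.fractions.items()}


def summarize_library(records: Sequence[ScreenRecord]) -> LibrarySummary:
    """Per-class counts over a set of confirmed screen records."""
    if not records:
        raise ValueError("no records to summarise")
    counts = {cls: 0 for cls in CLASSES}
    for record in records:
        if record.final_class is None:
            raise ValueError(f"record {record.clone!r} has no final class")
        counts[record.final_class] += 1
    return LibrarySummary(counts=counts, n_records=len(records))


def aggregate_class_counts(
    counts_by_library: Mapping[str, Mapping[str, int]],
    libraries: Iterable[str] | None = None,
) -> LibrarySummary:
    """Aggregate per-library class counts into one summary row.

    ``counts_by_library`` maps library name to a mapping with
    beneficial/deleterious/neutral counts (as in
    :data:`SATURATION_SCREEN_COUNTS`).
    """
    names = list(libraries) if libraries is not None else list(counts_by_library)
    totals = {cls: 0 for cls in CLASSES}
    for name in names:
        row = counts_by_library[name]
        for cls in CLASSES:
            totals[cls] += int(row.get(cls, 0))
    n = sum(totals.values())
    if n == 0:
        raise ValueError("aggregated counts are empty")
    return LibrarySummary(counts=totals, n_records=n)


def mean_spectrum(spectra: Sequence[EmissionSpectrum]) -> EmissionSpectrum:
    """Pointwise mean of spectra sharing one grid (metadata from the first)."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for other in spectra[1:]:
        _require_same_grid(first, other)
    stacked = np.stack([s.intensities for s in spectra])
    return replace(first, intensities=stacked.mean(axis=0))


# ---------------------------------------------------------------------------
# Long-format plate I/O and the end-to-end screen

SCAN_COLUMNS = (
    "plate",
    "well",
    "role",
    "tier",
    "clone",
    "excitation_nm",
    "wavelength_nm",
    "intensity",
)


def read_plate_scans(path: str | Path) -> pd.DataFrame:
    """Read long-format plate scans (one row per wavelength per well)."""
    frame = pd.read_csv(path)
    missing = set(SCAN_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"plate scan file is missing columns: {sorted(missing)}")
    return frame


def spectra_from_frame(frame: pd.DataFrame) -> list[EmissionSpectrum]:
    """Convert a long-format scan table into :class:`EmissionSpectrum` objects."""
    spectra: list[EmissionSpectrum] = []
    keys = ["plate", "tier", "well"]
    for (plate, tier, well), group in frame.groupby(keys, sort=True):
        group = group.sort_values("wavelength_nm")
        clone = group["clone"].iloc[0]
        spectra.append(
            EmissionSpectrum(
                wavelengths=group["wavelength_nm"].to_numpy(),
                intensities=group["intensity"].to_numpy(),
                excitation_nm=float(group["excitation_nm"].iloc[0]),
                well=str(well),
                clone=None if pd.isna(clone) else str(clone),
                role=str(group["role"].iloc[0]),
                tier=str(tier),
                plate=str(plate),
            )
        )
    return spectra


def _process_plate(
    spectra: Sequence[EmissionSpectrum], thresholds: ScreenThresholds
) -> dict[str, TierCall]:
    """Background-correct, smooth, and classify every sample well of one plate."""
    backgrounds = [s for s in spectra if s.role == "background"]
    references = [s for s in spectra if s.role == "wt_reference"]
    samples = [s for s in spectra if s.role == "sample"]
    if not backgrounds:
        raise ValueError("plate has no background wells")
    if not references:
        raise ValueError("plate has no wild-type reference wells")

    background = mean_spectrum(backgrounds)

    def prep(spectrum: EmissionSpectrum) -> EmissionSpectrum:
        corrected = subtract_background(spectrum, background)
        return savitzky_golay(corrected, thresholds.sg_order, thresholds.sg_window)

    # Averaging the reference wells before peak extraction keeps the
    # reference essentially noise-free, so the fold denominator does not
    # inherit the positive bias of a peak maximum taken on a noisy scan.
    reference = peak_metrics(mean_spectrum([prep(r) for r in references]))

    calls: dict[str, TierCall] = {}
    for sample in samples:
        if sample.clone is None:
            raise ValueError(f"sample well {sample.well!r} has no clone id")
        metrics = peak_metrics(prep(sample))
        calls[sample.clone] = classify_clone(
            metrics, reference, thresholds, tier=sample.tier
        )
    return calls


def run_screen(
    scans: pd.DataFrame, thresholds: ScreenThresholds = ScreenThresholds()
) -> list[ScreenRecord]:
    """Run the full hit-calling pipeline on a long-format scan table.

    Every (plate, tier) group is processed independently: its background
    wells define the subtraction, its wild-type reference wells the fold
    denominator.  Per-clone tier calls are then combined across tiers
    into the confirmed final class.
    """
    spectra = spectra_from_frame(scans)
    by_plate_tier: dict[tuple[str, str], list[EmissionSpectrum]] = {}
    for spectrum in spectra:
        by_plate_tier.setdefault((spectrum.plate or "", spectrum.tier), []).append(
            spectrum
        )

    records: dict[str, ScreenRecord] = {}
    for (_, tier), plate_spectra in sorted(by_plate_tier.items()):
        for clone, call in _process_plate(plate_spectra, thresholds).items():
            record = records.setdefault(clone, ScreenRecord(clone=clone))
            record.tier_calls[tier] = call
    for record in records.values():
        record.final_class = confirm_across_tiers(
            {tier: call.classification for tier, call in record.tier_calls.items()}
        )
    return [records[clone] for clone in sorted(records)]


def records_to_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    """Tabulate screen records (one row per clone) for TSV export."""
    rows = []
    for record in records:
        row: dict[str, object] = {
            "clone": record.clone,
            "final_class": record.final_class,
            "fold_change": record.fold_change,
            "peak_shift_nm": record.peak_shift_nm,
        }
        for tier in TIERS:
            call = record.tier_calls.get(tier)
            row[f"{tier}_class"] = call.classification if call else None
        rows.append(row)
    return pd.DataFrame(rows)
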