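"""Size-exclusion chromatography mass calibration and oligomeric state.

Over the fractionation range of a gel-filtration column, log10 of the
molecular mass of a globular protein is linear in its elution volume,
with a negative slope (larger proteins elute earlier).  Fitting that
line to standards of known mass calibrates the column; a sample's
elution volume then yields its native (net) mass, and dividing by the
monomer mass gives the oligomeric state (1.81 on a 16.3 kDa monomer
reads as a dimer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FBFP_MONOMER_KDA",
    "SEC_STANDARD_MASSES_KDA",
    "SECStandard",
    "SECCalibration",
    "OligomerEstimate",
    "CalibrationError",
    "fit_calibration",
    "mass_from_elution",
    "oligomeric_state",
    "read_sec_table",
]

#: Sequence-calculated monomer mass of the P. putida FbFP, in kDa.
FBFP_MONOMER_KDA = 16.3

#: Masses (kDa) of the classic globular calibration standards:
#: bovine thyroglobulin, bovine gamma-globulin, chicken ovalbumin,
#: horse myoglobin.
SEC_STANDARD_MASSES_KDA = {
    "thyroglobulin": 670.0,
    "gamma_globulin": 158.0,
    "ovalbumin": 44.0,
    "myoglobin": 17.0,
}

_OLIGOMER_NAMES = {
    1: "monomer",
    2: "dimer",
    3: "trimer",
    4: "tetramer",
    5: "pentamer",
    6: "hexamer",
}


class CalibrationError(ValueError):
    """The standards cannot support a log-linear calibration."""


@dataclass(frozen=True)
class SECStandard:
    name: str
    molecular_mass_kda: float
    elution_volume_ml: float

    def __post_init__(self) -> None:
        if self.molecular_mass_kda <= 0 or self.elution_volume_ml <= 0:
            raise ValueError("mass and elution volume must be positive")


@dataclass(frozen=True)
class SECCalibration:
    """Least-squares fit of log10(mass/kDa) against elution volume (mL)."""

    slope: float
    intercept: float
    r_squared: float
    standards: tuple[SECStandard, ...]

    @property
    def volume_range_ml(self) -> tuple[float, float]:
        volumes = [s.elution_volume_ml for s in self.standards]
        return min(volumes), max(volumes)

    def volume_for_mass(self, mass_kda: float) -> float:
        """Invert the calibration: elution volume at which ``mass_kda`` elutes."""
        if mass_kda <= 0:
            raise ValueError("mass must be positive")
        return (np.log10(mass_kda) - self.intercept) / self.slope


@dataclass(frozen=True)
class OligomerEstimate:
    net_mass_kda: float
    monomer_mass_kda: float
    state_value: float
    state_label: str


def fit_calibration(standards: Sequence[SECStandard]) -> SECCalibration:
    """Ordinary least squares of log10(mass) on elution volume.

    Requires at least three standards with distinct volumes; the fitted
    slope must be negative (larger proteins elute earlier) or the run
    violates SEC physics and a :class:`CalibrationError` is raised.
    """
    if len(standards) < 3:
        raise CalibrationError("at least 3 standards are required")
    volumes = np.asarray([s.elution_volume_ml for s in standards])
    if np.unique(volumes).size != volumes.size:
        raise CalibrationError("standards must have distinct elution volumes")
    log_masses = np.log10([s.molecular_mass_kda for s in standards])
    fit = stats.linregress(volumes, log_masses)
    if fit.slope >= 0:
        raise CalibrationError(
            f"fitted slope {fit.slope:.4f} is non-negative; larger proteins "
            "must elute earlier"
        )
    return SECCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        standards=tuple(standards),
    )


def mass_from_elution(
    calibration: SECCalibration, elution_volume_ml: float
) -> float:
    """Net molecular mass (kDa) predicted for an elution volume.

    Volumes outside the calibrated standard range are extrapolations
    and trigger a warning.
    """
    lo, hi = calibration.volume_range_ml
    if not lo <= elution_volume_ml <= hi:
        warnings.warn(
            f"elution volume {elution_volume_ml} mL outside the calibrated "
            f"range [{lo}, {hi}] mL; extrapolating",
            stacklevel=2,
        )
    return float(10 ** (calibration.intercept + calibration.slope * elution_volume_ml))


def oligomeric_state(
    net_mass_kda: float, monomer_mass_kda: float = FBFP_MONOMER_KDA
) -> OligomerEstimate:
    """Oligomeric state: net mass over monomer mass, labelled by nearest integer.

    A state value of 1.81 labels as "dimer" (1.5 <= v < 2.5); values
    below 1.5 label as "monomer".
    """
    if net_mass_kda <= 0 or monomer_mass_kda <= 0:
        raise ValueError("masses must be positive")
    value = net_mass_kda / monomer_mass_kda
    nearest = max(1, int(np.floor(value + 0.5)))
    label = _OLIGOMER_NAMES.get(nearest, f"{nearest}-mer")
    return OligomerEstimate(
        net_mass_kda=net_mass_kda,
        monomer_mass_kda=monomer_mass_kda,
        state_value=value,
        state_label=label,
    )


def read_sec_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV of SEC runs (name, mass_kda for standards, elution_volume_ml)."""
    frame = pd.read_csv(path)
    if "elution_volume_ml" not in frame.columns or "name" not in frame.columns:
        raise ValueError("SEC table needs 'name' and 'elution_volume_ml' columns")
    return frame
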