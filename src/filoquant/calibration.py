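"""Gel-densitometry calibration of mean Myo10 molecules per transfected cell.

A known number of transfected cells is lysed and run on an SDS-PAGE gel next
to a dilution series of a fluorescent HaloTag standard protein (61 kDa
HaloTag-GST fusion). The TMR fluorescence of the standard lanes defines a
through-origin standard curve (signal per ng). The lysate lane's signal is
converted to nanograms, then to label molecules via the standard's molecular
weight, corrected for the TMR-HaloLigand labeling efficiency, and divided by
the number of transfected cells loaded (total cells × transfection fraction)
to give the mean number of Myo10 molecules per transfected cell, ⟨m⟩.

The slope of the standard curve is treated as the sole error source; its 95%
confidence interval is propagated multiplicatively to every downstream
molecule estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.constants import N_A as AVOGADRO

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UnstableCalibrationError,
)

#: Molecular weight of the HaloTag-GST standard protein, g/mol.
HALOTAG_STANDARD_MW = 61_000.0
#: Fraction of Myo10 molecules carrying a TMR label.
DEFAULT_LABELING_EFFICIENCY = 0.90
#: Masses of the HaloTag standard dilution series loaded on the gel, ng.
STANDARD_MASSES_NG = (1.25, 2.5, 5.0, 10.0, 15.0)


@dataclass(frozen=True)
class GelLane:
    """One gel lane: either a standard of known mass or a cell lysate.

    Parameters
    ----------
    role:
        ``"standard"`` or ``"lysate"``.
    signal:
        Integrated densitometry signal of the band (plus any aggregated
        material retained in the well, summed by the caller).
    mass_ng:
        Loaded protein mass in ng; required for standards.
    cells_loaded:
        Number of cells loaded; required for lysates.
    """

    role: str
    signal: float
    mass_ng: float | None = None
    cells_loaded: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("standard", "lysate"):
            raise InvalidParameterError(f"unknown lane role {self.role!r}")
        if self.signal < 0:
            raise InvalidParameterError("lane signal must be >= 0")
        if self.role == "standard":
            if self.mass_ng is None or self.mass_ng <= 0:
                raise InvalidParameterError("standard lanes need mass_ng > 0")
        else:
            if self.cells_loaded is None or self.cells_loaded <= 0:
                raise InvalidParameterError("lysate lanes need cells_loaded > 0")


@dataclass(frozen=True)
class StandardCurve:
    """Through-origin linear fit of standard-lane signal vs mass."""

    slope: float  # signal per ng
    slope_se: float  # signal per ng
    r_squared: float
    df: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidParameterError("standard-curve slope must be > 0")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise InvalidParameterError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class CalibrationResult:
    """Mean molecules per transfected cell with a slope-propagated 95% CI."""

    mean_molecules_per_cell: float
    ci95: tuple[float, float]
    transfection_fraction: float
    labeling_efficiency: float = DEFAULT_LABELING_EFFICIENCY
    standard_mw: float = HALOTAG_STANDARD_MW

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        m = self.mean_molecules_per_cell
        if not (lo <= m * (1 + 1e-12) + 1e-12 and m <= hi * (1 + 1e-12) + 1e-12):
            raise InvalidParameterError("CI does not bracket the point estimate")
        if not (0 < self.labeling_efficiency <= 1):
            raise InvalidParameterError("labeling_efficiency must be in (0, 1]")


def fit_standard_curve(standards: Sequence[GelLane]) -> StandardCurve:
    """Fit ``signal = slope * mass_ng`` through the origin by least squares.

    slope = Σ(x·y)/Σ(x²); the slope standard error and R² are those of the
    zero-intercept model with df = n − 1 (the uncentered R² convention, since
    the model has no intercept).
    """
    standards = [ln for ln in standards if ln.role == "standard"]
    if len(standards) < 2:
        raise InsufficientDataError("need >= 2 standard lanes")
    x = np.array([ln.mass_ng for ln in standards], dtype=float)
    y = np.array([ln.signal for ln in standards], dtype=float)
    if np.unique(x).size < 2:
        raise InsufficientDataError("standard lanes must span >= 2 distinct masses")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise InsufficientDataError("all standard masses are zero")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    n = x.size
    ss_res = float(np.sum(resid**2))
    slope_se = math.sqrt(ss_res / (n - 1) / sxx)
    ss_tot = float(np.sum(y**2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StandardCurve(slope=slope, slope_se=slope_se, r_squared=min(r_squared, 1.0), df=n - 1)


def signal_to_molecules(
    signal: float,
    curve: StandardCurve,
    labeling_efficiency: float = DEFAULT_LABELING_EFFICIENCY,
    standard_mw: float = HALOTAG_STANDARD_MW,
) -> float:
    """Convert an integrated lane signal to Myo10 molecules.

    ng = signal / slope; label molecules = ng·10⁻⁹ / MW × N_A; Myo10
    molecules = label molecules / labeling_efficiency.
    """
    if not (0 < labeling_efficiency <= 1):
        raise InvalidParameterError("labeling_efficiency must be in (0, 1]")
    if standard_mw <= 0:
        raise InvalidParameterError("standard_mw must be > 0")
    ng = signal / curve.slope
    label_molecules = ng * 1e-9 / standard_mw * AVOGADRO
    return label_molecules / labeling_efficiency


def lane_to_molecules_per_cell(
    lysate: GelLane,
    curve: StandardCurve,
    transfection_fraction: float,
    labeling_efficiency: float = DEFAULT_LABELING_EFFICIENCY,
    standard_mw: float = HALOTAG_STANDARD_MW,
) -> CalibrationResult:
    """Convert a lysate lane to mean molecules per transfected cell, ⟨m⟩.

    The denominator is the number of *transfected* cells loaded: total cells
    loaded times the fraction transfected.
    """
    if lysate.role != "lysate":
        raise InvalidParameterError("lane_to_molecules_per_cell needs a lysate lane")
    if not (0 < transfection_fraction <= 1):
        raise InvalidParameterError("transfection_fraction must be in (0, 1]")
    molecules = signal_to_molecules(lysate.signal, curve, labeling_efficiency, standard_mw)
    mean_m = molecules / (lysate.cells_loaded * transfection_fraction)
    ci = propagate_slope_ci(curve, mean_m)
    return CalibrationResult(
        mean_molecules_per_cell=mean_m,
        ci95=ci,
        transfection_fraction=transfection_fraction,
        labeling_efficiency=labeling_efficiency,
        standard_mw=standard_mw,
    )


def propagate_slope_ci(curve: StandardCurve, estimate: float) -> tuple[float, float]:
    """95% CI of a molecule estimate from the standard-curve slope alone.

    A molecule estimate scales as 1/slope, so the interval is multiplicative:
    estimate × slope / (slope ± t₀.₉₇₅(df) · slope_se), ordered lo ≤ hi.
    """
    if curve.df < 1:
        raise InsufficientDataError("slope CI needs df >= 1")
    if curve.slope_se == 0:
        return (estimate, estimate)
    margin = stats.t.ppf(0.975, curve.df) * curve.slope_se
    if curve.slope - margin <= 0:
        raise UnstableCalibrationError(
            "slope 95% margin crosses zero; calibration too noisy for a CI"
        )
    lo = estimate * curve.slope / (curve.slope + margin)
    hi = estimate * curve.slope / (curve.slope - margin)
    return (min(lo, hi), max(lo, hi))


# ---------------------------------------------------------------------------
# CSV interchange


def lanes_to_frame(lanes: Iterable[GelLane]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "role": ln.role,
                "mass_ng": ln.mass_ng,
                "signal": ln.signal,
                "cells_loaded": ln.cells_loaded,
            }
            for ln in lanes
        ]
    )


def frame_to_lanes(frame: pd.DataFrame) -> list[GelLane]:
    lanes = []
    for _, row in frame.iterrows():
        mass = row.get("mass_ng")
        cells = row.get("cells_loaded")
        lanes.append(
            GelLane(
                role=str(row["role"]),
                signal=float(row["signal"]),
                mass_ng=None if pd.isna(mass) else float(mass),
                cells_loaded=None if pd.isna(cells) else float(cells),
            )
        )
    return lanes


def read_lanes(path) -> list[GelLane]:
    """Read gel lanes from CSV (columns: role, mass_ng, signal, cells_loaded)."""
    return frame_to_lanes(pd.read_csv(path))


def write_lanes(lanes: Iterable[GelLane], path) -> None:
    lanes_to_frame(lanes).to_csv(path, index=False)
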