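"""Geometric models of the filopodial tip.

A filopodium is modeled as a cylinder of radius 0.1 µm around a fascin-actin
bundle of 30 filaments, 16 of which lie on the exposed surface of the bundle.
Steric packing leaves only 4 of the 13 actin monomers per helical turn on a
surface filament accessible to Myo10. These numbers give a fixed accessible
F-actin monomer concentration (~96 µM) against which local Myo10
concentrations at the tip can be compared. A separate membrane budget counts
how many Myo10 molecules fit on the tip membrane (hemispherical cap plus the
cylindrical wall along the punctum) given a per-molecule footprint.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.constants import N_A as AVOGADRO

from .errors import InvalidParameterError

#: litres per cubic micrometre
_L_PER_UM3 = 1e-15


@dataclass(frozen=True)
class FilopodiumGeometry:
    """Geometry of a 'typical' filopodium and its actin bundle.

    radius_um:
        Filopodium radius (cylinder model), µm.
    n_filaments:
        Actin filaments in the fascin bundle.
    n_surface_filaments:
        Filaments on the exposed surface of the bundle.
    accessible_fraction:
        Fraction of monomers per helical turn sterically accessible to Myo10
        on a surface filament (4 of 13).
    monomer_rise_nm:
        Axial rise per actin monomer along a filament, nm.
    """

    radius_um: float = 0.1
    n_filaments: int = 30
    n_surface_filaments: int = 16
    accessible_fraction: float = 4.0 / 13.0
    monomer_rise_nm: float = 2.7

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise InvalidParameterError("radius must be > 0")
        if self.n_surface_filaments > self.n_filaments:
            raise InvalidParameterError("surface filaments cannot exceed total filaments")
        if not (0 <= self.accessible_fraction <= 1):
            raise InvalidParameterError("accessible_fraction must be in [0, 1]")
        if self.monomer_rise_nm <= 0:
            raise InvalidParameterError("monomer rise must be > 0")


@dataclass(frozen=True)
class MembraneBudget:
    """Membrane area available at the tip and the Myo10 count it can hold."""

    hemisphere_area_nm2: float
    wall_area_nm2: float
    footprint_per_myo10_nm2: float
    capacity: int

    @property
    def total_area_nm2(self) -> float:
        return self.hemisphere_area_nm2 + self.wall_area_nm2


class SaturationClass(enum.Enum):
    """Where a tip punctum sits relative to the actin and membrane budgets."""

    BELOW_ACTIN = "below_actin"
    ACTIN_EXCEEDED = "actin_exceeded"
    MEMBRANE_EXCEEDED = "membrane_exceeded"


def cylinder_concentration(
    molecules: float, length_um: float, radius_um: float = 0.1
) -> float:
    """Local concentration (µM) of `molecules` in a cylinder of given size.

    C = molecules / (N_A × π r² L), with the volume in litres.
    """
    if length_um <= 0:
        raise InvalidParameterError("cylinder length must be > 0")
    if radius_um <= 0:
        raise InvalidParameterError("cylinder radius must be > 0")
    if molecules < 0:
        raise InvalidParameterError("molecule count must be >= 0")
    volume_l = math.pi * radius_um**2 * length_um * _L_PER_UM3
    return molecules / (AVOGADRO * volume_l) * 1e6


def accessible_actin_concentration(
    geom: FilopodiumGeometry = FilopodiumGeometry(),
) -> float:
    """Concentration (µM) of actin monomers accessible to Myo10.

    Per unit length of filopodium there are
    n_surface_filaments × accessible_fraction / monomer_rise accessible
    monomers; dividing by the cylinder cross-section volume per unit length
    makes this independent of filopodium length. Defaults give ~96 µM.
    """
    per_um = (
        geom.n_surface_filaments * geom.accessible_fraction * (1000.0 / geom.monomer_rise_nm)
    )
    # any length cancels; use 1 µm explicitly
    return cylinder_concentration(per_um, 1.0, geom.radius_um)


def membrane_capacity(
    punctum_length_um: float,
    radius_um: float = 0.1,
    footprint_nm2: float = 100.0,
) -> MembraneBudget:
    """Myo10 capacity of the tip membrane for a punctum of given length.

    Available area = hemispherical cap (2πr²) + cylindrical wall along the
    punctum (2πrL); capacity = floor(area / footprint).
    """
    if footprint_nm2 <= 0:
        raise InvalidParameterError("footprint must be > 0")
    if punctum_length_um < 0:
        raise InvalidParameterError("punctum length must be >= 0")
    r_nm = radius_um * 1000.0
    l_nm = punctum_length_um * 1000.0
    hemisphere = 2.0 * math.pi * r_nm**2
    wall = 2.0 * math.pi * r_nm * l_nm
    return MembraneBudget(
        hemisphere_area_nm2=hemisphere,
        wall_area_nm2=wall,
        footprint_per_myo10_nm2=footprint_nm2,
        capacity=int(math.floor((hemisphere + wall) / footprint_nm2)),
    )


def actin_saturation_boundary(
    length_um: float, geom: FilopodiumGeometry = FilopodiumGeometry()
) -> float:
    """Molecules at which a punctum of given length reaches the actin limit.

    Solves cylinder_concentration(m, L, r) = accessible_actin_concentration:
    the phase-boundary line in the molecules-vs-length plane.
    """
    c_actin = accessible_actin_concentration(geom)  # µM
    volume_l = math.pi * geom.radius_um**2 * length_um * _L_PER_UM3
    return c_actin * 1e-6 * AVOGADRO * volume_l


def classify_saturation(
    molecules: float,
    punctum_length_um: float,
    geom: FilopodiumGeometry = FilopodiumGeometry(),
    footprint_nm2: float = 100.0,
) -> SaturationClass:
    """Classify a tip punctum against the actin and membrane budgets.

    Membrane excess takes precedence over actin excess.
    """
    budget = membrane_capacity(punctum_length_um, geom.radius_um, footprint_nm2)
    if molecules > budget.capacity:
        return SaturationClass.MEMBRANE_EXCEEDED
    conc = cylinder_concentration(molecules, punctum_length_um, geom.radius_um)
    if conc > accessible_actin_concentration(geom):
        return SaturationClass.ACTIN_EXCEEDED
    return SaturationClass.BELOW_ACTIN


def molecules_per_filament(molecules: float, n_filaments: int = 30) -> float:
    """Average Myo10 molecules per actin filament in the bundle."""
    if n_filaments <= 0:
        raise InvalidParameterError("n_filaments must be > 0")
    return molecules / n_filaments
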