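"""Angular (rose) profiles of filopodial Myo10 around the cell.

Each cell is divided into ``n_sections`` (default 20) angular sections about
its center of mass. Per section we accumulate the filopodial molecules of the
puncta whose centroid falls in the section, count puncta (a punctum whose
pixel set straddles a section border is counted once in every section it
touches), and form molecules per punctum. Profiles are aligned so that the
section with the most (or fewest) molecules sits at 0°, averaged across
cells, and given bootstrap standard errors by resampling cells with
replacement.

Angles are measured counterclockwise from the image +x axis (columns), with
+y pointing up in the displayed image; sections are half-open arcs
[k·360/n, (k+1)·360/n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError
from .quantify import PunctumRecord

DEFAULT_N_SECTIONS = 20


@dataclass(frozen=True)
class RoseProfile:
    """Per-section molecule totals, punctum counts, and molecules/punctum."""

    molecules_per_section: np.ndarray
    puncta_per_section: np.ndarray
    molecules_per_punctum_per_section: np.ndarray  # NaN where no puncta
    n_sections: int = DEFAULT_N_SECTIONS
    alignment_mode: str | None = None  # None | "max" | "min"
    sem_molecules: np.ndarray | None = None
    sem_puncta: np.ndarray | None = None
    sem_molecules_per_punctum: np.ndarray | None = None

    def __post_init__(self) -> None:
        for vec in (
            self.molecules_per_section,
            self.puncta_per_section,
            self.molecules_per_punctum_per_section,
        ):
            if vec.shape != (self.n_sections,):
                raise InvalidParameterError("profile vectors must have length n_sections")


def _angle(point: tuple[float, float], center: tuple[float, float]) -> float:
    """CCW angle in [0, 2π) of a (row, col) point about a (row, col) center."""
    dy = center[0] - point[0]  # +y up means decreasing row
    dx = point[1] - center[1]
    return math.atan2(dy, dx) % (2 * math.pi)


def angular_sections(
    puncta: Sequence[PunctumRecord],
    center_of_mass: tuple[float, float],
    n_sections: int = DEFAULT_N_SECTIONS,
) -> RoseProfile:
    """Bin puncta into angular sections about the cell's center of mass.

    Molecules are assigned by centroid angle; punctum counts include every
    section the punctum's pixel set touches. Puncta must carry ``molecules``
    (falls back to integrated intensity when not converted). An empty
    punctum list yields zero vectors.
    """
    if n_sections < 2:
        raise InvalidParameterError("n_sections must be >= 2")
    width = 2 * math.pi / n_sections
    molecules = np.zeros(n_sections)
    counts = np.zeros(n_sections)
    for p in puncta:
        value = p.molecules if p.molecules is not None else p.integrated_intensity
        sec = int(_angle(p.centroid, center_of_mass) / width) % n_sections
        molecules[sec] += value
        touched = {
            int(_angle((float(r), float(c)), center_of_mass) / width) % n_sections
            for r, c in p.pixels
        }
        for sec_t in touched:
            counts[sec_t] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        per_punctum = np.where(counts > 0, molecules / counts, np.nan)
    return RoseProfile(
        molecules_per_section=molecules,
        puncta_per_section=counts,
        molecules_per_punctum_per_section=per_punctum,
        n_sections=n_sections,
    )


def align_profile(
    profile: RoseProfile, mode: str = "max", rng_seed: int | None = None
) -> RoseProfile:
    """Rotate a profile so the reference section sits at index 0 (degree 0).

    ``mode="max"``: the section with the most molecules (ties broken by
    lowest index). ``mode="min"``: the section with the fewest molecules; if
    more than one section is empty, a seeded random empty section is chosen.
    """
    mol = profile.molecules_per_section
    if mode == "max":
        shift = int(np.argmax(mol))
    elif mode == "min":
        empty = np.flatnonzero(mol == 0)
        if empty.size > 1:
            rng = np.random.default_rng(rng_seed)
            shift = int(rng.choice(empty))
        else:
            shift = int(np.argmin(mol))
    else:
        raise InvalidParameterError(f"unknown alignment mode {mode!r}")
    return replace(
        profile,
        molecules_per_section=np.roll(mol, -shift),
        puncta_per_section=np.roll(profile.puncta_per_section, -shift),
        molecules_per_punctum_per_section=np.roll(
            profile.molecules_per_punctum_per_section, -shift
        ),
        alignment_mode=mode,
    )


def average_profiles(profiles: Sequence[RoseProfile]) -> RoseProfile:
    """Element-wise mean across cells (NaN-aware for molecules per punctum)."""
    if len(profiles) == 0:
        raise InsufficientDataError("no profiles to average")
    n = profiles[0].n_sections
    if any(p.n_sections != n for p in profiles):
        raise InvalidParameterError("profiles must share n_sections")
    mol = np.mean([p.molecules_per_section for p in profiles], axis=0)
    cnt = np.mean([p.puncta_per_section for p in profiles], axis=0)
    with warnings.catch_warnings():
        # sections empty in every cell legitimately average to NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mpp = np.nanmean(
            [p.molecules_per_punctum_per_section for p in profiles], axis=0
        )
    return RoseProfile(
        molecules_per_section=mol,
        puncta_per_section=cnt,
        molecules_per_punctum_per_section=mpp,
        n_sections=n,
        alignment_mode=profiles[0].alignment_mode,
    )


def bootstrap_sem(
    profiles: Sequence[RoseProfile],
    n_boot: int = 500,
    rng_seed: int = 0,
) -> RoseProfile:
    """Mean profile with bootstrap SEM per section.

    Cells are resampled with replacement ``n_boot`` times; the SEM is the
    standard deviation of the bootstrap means in each section.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("bootstrap needs >= 2 profiles")
    mean_profile = average_profiles(profiles)
    rng = np.random.default_rng(rng_seed)
    mol = np.stack([p.molecules_per_section for p in profiles])
    cnt = np.stack([p.puncta_per_section for p in profiles])
    mpp = np.stack([p.molecules_per_punctum_per_section for p in profiles])
    n_cells = mol.shape[0]
    boot_mol = np.empty((n_boot, mol.shape[1]))
    boot_cnt = np.empty_like(boot_mol)
    boot_mpp = np.empty_like(boot_mol)
    with warnings.catch_warnings():
        # sections empty in every resampled cell legitimately give NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_boot):
            idx = rng.integers(0, n_cells, n_cells)
            boot_mol[b] = mol[idx].mean(axis=0)
            boot_cnt[b] = cnt[idx].mean(axis=0)
            boot_mpp[b] = np.nanmean(mpp[idx], axis=0)
        sem_mpp = np.nanstd(boot_mpp, axis=0)
    return replace(
        mean_profile,
        sem_molecules=boot_mol.std(axis=0),
        sem_puncta=boot_cnt.std(axis=0),
        sem_molecules_per_punctum=sem_mpp,
    )


def profile_frame(profile: RoseProfile):
    """Tidy DataFrame of a (possibly averaged) rose profile."""
    import pandas as pd

    degrees = np.arange(profile.n_sections) * 360.0 / profile.n_sections
    data = {
        "section": np.arange(profile.n_sections),
        "degrees": degrees,
        "molecules": profile.molecules_per_section,
        "puncta": profile.puncta_per_section,
        "molecules_per_punctum": profile.molecules_per_punctum_per_section,
    }
    if profile.sem_molecules is not None:
        data["sem_molecules"] = profile.sem_molecules
        data["sem_puncta"] = profile.sem_puncta
        data["sem_molecules_per_punctum"] = profile.sem_molecules_per_punctum
    return pd.DataFrame(data)


def plot_rose(profile: RoseProfile, ax=None, quantity: str = "molecules"):
    """Polar bar plot of a rose profile (matplotlib Axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    values = {
        "molecules": profile.molecules_per_section,
        "puncta": profile.puncta_per_section,
        "molecules_per_punctum": profile.molecules_per_punctum_per_section,
    }[quantity]
    width = 2 * math.pi / profile.n_sections
    theta = np.arange(profile.n_sections) * width
    ax.bar(theta, np.nan_to_num(values), width=width, align="edge")
    ax.set_title(quantity.replace("_", " "))
    return ax
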