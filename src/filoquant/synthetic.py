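"""Synthetic gel, image, and trajectory data with known ground truth.

Every downstream stage of the package is exercised on data from this module,
so each generator records the exact truth it rendered:

* :func:`make_gel_dataset` inverts the gel calibration: the lysate lane's
  expected signal encodes a chosen mean molecules per cell exactly when the
  noise CV is zero.
* :func:`make_cell_scene` renders a cell as a bright elliptical body with a
  smooth interior molecule field and thin filopodia radiating from the body
  perimeter. Each filopodium has a dim one-pixel actin shaft and a compact
  tip punctum whose molecule count is drawn from a log-normal distribution
  (median 730 by default). The camera applies gain, a flat background (plus
  optional gradient), and Gaussian read noise.
* :func:`make_trajectory_set` produces per-frame punctum detections in which
  molecules accrete linearly in time and the punctum advances at a speed set
  by a decreasing speed-vs-molecules law, emulating filopodial initiation,
  second-phase elongation, and retraction events.

Camera noise is Gaussian rather than Poisson for simplicity; photobleaching,
PSF optics, and actin dynamics are deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .calibration import (
    DEFAULT_LABELING_EFFICIENCY,
    HALOTAG_STANDARD_MW,
    STANDARD_MASSES_NG,
)
from .errors import InvalidParameterError
from scipy.constants import N_A as AVOGADRO

#: default pixel size, µm (60x-class objective)
DEFAULT_PIXEL_SIZE_UM = 0.108
#: default fraction of a cell's molecules that sit in filopodia (median 5.35%)
DEFAULT_FILOPODIAL_FRACTION = 0.0535
#: default log-normal parameters of tip punctum molecule counts (median 730)
DEFAULT_MU_LOG = math.log(730.0)
DEFAULT_SIGMA_LOG = 1.3


# ---------------------------------------------------------------------------
# camera


@dataclass(frozen=True)
class CameraModel:
    """Idealized camera: intensity = gain × molecules + background + noise."""

    gain: float = 2.0  # intensity units per molecule
    read_noise_sd: float = 2.0  # intensity units
    background_level: float = 100.0  # intensity units
    background_gradient: float = 0.0  # intensity units per pixel (along columns)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidParameterError("camera gain must be > 0")
        if self.read_noise_sd < 0:
            raise InvalidParameterError("read noise must be >= 0")
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel size must be > 0")


# ---------------------------------------------------------------------------
# gel lanes


def make_gel_dataset(
    true_mean_molecules: float,
    cells_loaded: float = 50_000,
    transfection_fraction: float = 0.5,
    labeling_efficiency: float = DEFAULT_LABELING_EFFICIENCY,
    slope: float = 24.32,
    noise_cv: float = 0.0,
    rng_seed: int = 0,
    standard_mw: float = HALOTAG_STANDARD_MW,
) -> pd.DataFrame:
    """Simulate a gel: HaloTag standard dilution lanes plus one lysate lane.

    The lysate lane's expected signal is the exact inverse of the
    calibration chain, so with ``noise_cv = 0`` the gel_calibration module
    recovers ``true_mean_molecules`` to float precision.

    Returns a DataFrame with columns role, mass_ng, signal, cells_loaded.
    """
    if slope <= 0:
        raise InvalidParameterError("slope must be > 0")
    if true_mean_molecules <= 0 or cells_loaded <= 0:
        raise InvalidParameterError("molecule and cell counts must be > 0")
    for name, value in (
        ("transfection_fraction", transfection_fraction),
        ("labeling_efficiency", labeling_efficiency),
    ):
        if not (0 < value <= 1):
            raise InvalidParameterError(f"{name} must be in (0, 1]")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")

    rng = np.random.default_rng(rng_seed)
    rows = []
    for mass in STANDARD_MASSES_NG:
        expected = slope * mass
        signal = expected * max(0.0, 1.0 + noise_cv * rng.standard_normal())
        rows.append(
            {"role": "standard", "mass_ng": mass, "signal": signal, "cells_loaded": np.nan}
        )
    label_molecules = (
        true_mean_molecules * cells_loaded * transfection_fraction * labeling_efficiency
    )
    lysate_ng = label_molecules * standard_mw / AVOGADRO * 1e9
    expected = slope * lysate_ng
    signal = expected * max(0.0, 1.0 + noise_cv * rng.standard_normal())
    rows.append(
        {"role": "lysate", "mass_ng": np.nan, "signal": signal, "cells_loaded": cells_loaded}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixed-cell scenes


@dataclass(frozen=True)
class FilopodiumTruth:
    """Ground truth for one rendered filopodium."""

    polyline: np.ndarray  # (N, 2) pixel coords, (row, col), base -> tip
    tip_molecules: int
    tip_length_um: float
    shaft_molecules: float
    tip_centroid: tuple[float, float]  # (row, col)

    @property
    def total_molecules(self) -> float:
        return self.tip_molecules + self.shaft_molecules


@dataclass
class SceneTruth:
    """Everything the renderer knows about a synthetic cell."""

    cell_body_mask: np.ndarray  # bool
    filopodia: list[FilopodiumTruth]
    per_pixel_molecules: np.ndarray  # float, >= 0
    total_molecules: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    @property
    def filopodial_molecules(self) -> float:
        return float(sum(f.total_molecules for f in self.filopodia))

    @property
    def body_molecules(self) -> float:
        return float(self.per_pixel_molecules[self.cell_body_mask].sum())

    @property
    def support(self) -> np.ndarray:
        """Pixels carrying any molecules."""
        return self.per_pixel_molecules > 0

    @property
    def filopodia_support(self) -> np.ndarray:
        return self.support & ~self.cell_body_mask


def draw_tip_counts(
    n: int, mu_log: float, sigma_log: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw integer tip punctum molecule counts, i.i.d. log-normal.

    The degenerate case sigma_log = 0 returns exp(mu_log) for every punctum.
    """
    if sigma_log < 0:
        raise InvalidParameterError("sigma_log must be >= 0")
    if sigma_log == 0:
        counts = np.full(n, math.exp(mu_log))
    else:
        counts = rng.lognormal(mean=mu_log, sigma=sigma_log, size=n)
    return np.maximum(1, np.round(counts)).astype(int)


def _stamp_segment(
    shape: tuple[int, int],
    start: np.ndarray,
    end: np.ndarray,
    half_width: float,
) -> np.ndarray:
    """Pixel coordinates within ``half_width`` of the segment start->end."""
    lo = np.maximum(np.floor(np.minimum(start, end) - half_width - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.maximum(start, end) + half_width + 1).astype(int),
        np.array(shape) - 1,
    )
    rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    seg = end - start
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - start, axis=1)
    else:
        t = np.clip((pts - start) @ seg / seg_len2, 0.0, 1.0)
        proj = start + t[:, None] * seg
        dist = np.linalg.norm(pts - proj, axis=1)
    keep = dist <= half_width
    return np.stack([rr.ravel()[keep], cc.ravel()[keep]], axis=1)


def make_cell_scene(
    n_filopodia: int = 30,
    mu_log: float = DEFAULT_MU_LOG,
    sigma_log: float = DEFAULT_SIGMA_LOG,
    camera: CameraModel | None = None,
    angular_bias: tuple[float, float] | None = None,
    rng_seed: int = 0,
    shape: tuple[int, int] = (384, 384),
    filopodial_fraction: float = DEFAULT_FILOPODIAL_FRACTION,
    shaft_molecules_per_um: float = 80.0,
    body_radii: tuple[float, float] = (60.0, 72.0),
    filopodium_length_px: tuple[float, float] = (20.0, 55.0),
    tip_length_um: tuple[float, float] = (0.25, 1.0),
    phalloidin_levels: tuple[float, float] = (300.0, 280.0),
) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render one cell: (myo10 image, phalloidin image, SceneTruth).

    The body is a filled ellipse with a smooth, center-weighted interior
    molecule field, scaled so that ``filopodial_fraction`` of the cell's
    molecules sit in filopodia. Filopodia radiate from the perimeter at
    jittered equally spaced angles (or angles biased toward two opposite
    lobes when ``angular_bias = (strength, theta0)`` is given). Myo10 shafts
    are one-pixel Bresenham chains; tip puncta are ~2 px wide stamps whose
    length is drawn uniformly from ``tip_length_um``. The phalloidin channel
    shows the actin body and shafts but not the Myo10 tip puncta.
    """
    if n_filopodia < 0:
        raise InvalidParameterError("n_filopodia must be >= 0")
    if sigma_log < 0:
        raise InvalidParameterError("sigma_log must be >= 0")
    if not (0 < filopodial_fraction < 1):
        raise InvalidParameterError("filopodial_fraction must be in (0, 1)")
    camera = camera or CameraModel()

    rng = np.random.default_rng(rng_seed)
    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    a, b = body_radii

    body = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center[0], center[1], a, b, shape=shape)
    body[rr, cc] = True

    # smooth interior field, brighter toward the center, nonzero at the edge
    rows, cols = np.nonzero(body)
    d2 = ((rows - center[0]) / a) ** 2 + ((cols - center[1]) / b) ** 2
    body_weights = 1.0 + 1.5 * (1.0 - np.clip(d2, 0, 1))

    per_pixel = np.zeros(shape, dtype=float)

    # filopodium base angles
    if n_filopodia > 0:
        if angular_bias is None:
            spacing = 2 * math.pi / n_filopodia
            angles = (
                np.arange(n_filopodia) * spacing
                + rng.uniform(-0.25 * spacing, 0.25 * spacing, n_filopodia)
                + rng.uniform(0, 2 * math.pi)
            )
        else:
            strength, theta0 = angular_bias
            angles = np.empty(n_filopodia)
            k = 0
            while k < n_filopodia:  # rejection sampling of p ∝ 1 + s·cos(2(θ−θ0))
                theta = rng.uniform(0, 2 * math.pi)
                if rng.uniform(0, 1 + abs(strength)) <= 1 + strength * math.cos(
                    2 * (theta - theta0)
                ):
                    angles[k] = theta
                    k += 1
        tip_counts = draw_tip_counts(n_filopodia, mu_log, sigma_log, rng)
        lengths = rng.uniform(*filopodium_length_px, n_filopodia)
        tip_lengths = rng.uniform(*tip_length_um, n_filopodia)
    else:
        angles = np.empty(0)
        tip_counts = np.empty(0, dtype=int)
        lengths = np.empty(0)
        tip_lengths = np.empty(0)

    filopodia: list[FilopodiumTruth] = []
    shaft_pixels: list[tuple[np.ndarray, np.ndarray, float]] = []
    for theta, length, tip_count, tip_len_um in zip(angles, lengths, tip_counts, tip_lengths):
        direction = np.array([-math.sin(theta), math.cos(theta)])
        # base on the ellipse perimeter along this direction
        denom = math.sqrt((direction[0] / a) ** 2 + (direction[1] / b) ** 2)
        base = center + direction / denom
        tip_end = base + direction * length
        tip_len_px = tip_len_um / camera.pixel_size_um
        tip_start = tip_end - direction * tip_len_px

        r0, c0 = np.round(base).astype(int)
        r1, c1 = np.round(tip_start).astype(int)
        rr_s, cc_s = draw_line(r0, c0, r1, c1)
        inside = (
            (rr_s >= 0) & (rr_s < shape[0]) & (cc_s >= 0) & (cc_s < shape[1])
        )
        rr_s, cc_s = rr_s[inside], cc_s[inside]
        keep = ~body[rr_s, cc_s]
        rr_s, cc_s = rr_s[keep], cc_s[keep]
        shaft_len_um = (length - tip_len_px) * camera.pixel_size_um
        shaft_mol = max(0.0, shaft_molecules_per_um * shaft_len_um)
        if rr_s.size:
            per_pixel[rr_s, cc_s] += shaft_mol / rr_s.size
            shaft_pixels.append((rr_s, cc_s, shaft_mol))
        else:
            shaft_mol = 0.0

        tip_px = _stamp_segment(shape, tip_start, tip_end, half_width=1.0)
        tip_px = tip_px[~body[tip_px[:, 0], tip_px[:, 1]]]
        if tip_px.shape[0] == 0:  # fully clipped; skip this filopodium
            continue
        per_pixel[tip_px[:, 0], tip_px[:, 1]] += tip_count / tip_px.shape[0]
        centroid = tip_px.mean(axis=0)
        filopodia.append(
            FilopodiumTruth(
                polyline=np.array([base, tip_end]),
                tip_molecules=int(tip_count),
                tip_length_um=float(tip_len_um),
                shaft_molecules=float(shaft_mol),
                tip_centroid=(float(centroid[0]), float(centroid[1])),
            )
        )

    filo_total = float(sum(f.total_molecules for f in filopodia))
    if filopodia:
        body_total = filo_total * (1.0 - filopodial_fraction) / filopodial_fraction
    else:
        # body-only scene: scale from the expected per-filopodium load
        body_total = (
            math.exp(mu_log + 0.5 * sigma_log**2)
            * 30
            * (1.0 - filopodial_fraction)
            / filopodial_fraction
        )
    per_pixel[rows, cols] += body_total * body_weights / body_weights.sum()

    truth = SceneTruth(
        cell_body_mask=body,
        filopodia=filopodia,
        per_pixel_molecules=per_pixel,
        total_molecules=int(round(per_pixel.sum())),
        pixel_size_um=camera.pixel_size_um,
    )

    col_grid = np.arange(shape[1], dtype=float)[None, :]
    background = camera.background_level + camera.background_gradient * col_grid
    myo10 = per_pixel * camera.gain + background
    if camera.read_noise_sd > 0:
        myo10 = myo10 + rng.normal(0.0, camera.read_noise_sd, shape)

    phalloidin = np.full(shape, camera.background_level, dtype=float)
    body_level, shaft_level = phalloidin_levels
    phalloidin[body] = camera.background_level + body_level
    for rr_s, cc_s, _ in shaft_pixels:
        phalloidin[rr_s, cc_s] = camera.background_level + shaft_level
    if camera.read_noise_sd > 0:
        phalloidin = phalloidin + rng.normal(0.0, camera.read_noise_sd, shape)

    return myo10, phalloidin, truth


# ---------------------------------------------------------------------------
# live-cell trajectories


@dataclass(frozen=True)
class SpeedLaw:
    """Decreasing speed-vs-molecules law v(m) = v_max / (1 + m / m_half).

    Defaults put v(160) = 160 nm/s, the observed median speed of elongating
    puncta at the median initiation cluster size of 160 molecules.
    """

    v_max_nm_s: float = 320.0
    m_half: float = 160.0

    def __call__(self, molecules: float) -> float:
        return self.v_max_nm_s / (1.0 + molecules / self.m_half)


@dataclass(frozen=True)
class TrajectoryTruth:
    """Generating process for one class of filopodial lifecycle event."""

    phase: str = "initiation"  # initiation | second_phase | retraction
    start_molecules: float = 160.0
    accretion_rate: float = 1.5  # molecules per second
    speed_law: Callable[[float], float] = SpeedLaw()
    frame_interval_s: float = 1.0
    start_sigma_log: float = 0.6  # log-normal spread of start sizes across events

    def __post_init__(self) -> None:
        if self.phase not in ("initiation", "second_phase", "retraction"):
            raise InvalidParameterError(f"unknown phase {self.phase!r}")
        if self.phase != "retraction" and self.accretion_rate < 0:
            raise InvalidParameterError("accretion_rate must be >= 0 for growth phases")
        if self.frame_interval_s <= 0:
            raise InvalidParameterError("frame interval must be > 0")

    @classmethod
    def for_phase(cls, phase: str, **overrides) -> "TrajectoryTruth":
        """Defaults matching the observed phase medians (160/290/240)."""
        presets = {
            "initiation": dict(start_molecules=160.0, accretion_rate=1.5),
            "second_phase": dict(start_molecules=290.0, accretion_rate=1.5),
            "retraction": dict(start_molecules=240.0, accretion_rate=0.0),
        }
        if phase not in presets:
            raise InvalidParameterError(f"unknown phase {phase!r}")
        kwargs = dict(phase=phase, **presets[phase])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class MeasurementNoise:
    """Detection noise on live-cell punctum tables."""

    molecule_cv: float = 0.05
    position_sd_um: float = 0.02

    def __post_init__(self) -> None:
        if self.molecule_cv < 0 or self.position_sd_um < 0:
            raise InvalidParameterError("noise parameters must be >= 0")


def make_trajectory_set(
    truth: TrajectoryTruth,
    n_traj: int = 237,
    n_frames: int = 60,
    noise: MeasurementNoise | float = MeasurementNoise(),
    rng_seed: int = 0,
    grid_spacing_um: float = 8.0,
) -> pd.DataFrame:
    """Simulate per-frame punctum detections for ``n_traj`` events.

    Each trajectory starts on a well-separated grid, moves in a fixed random
    direction at ``truth.speed_law(current molecules)``, and accretes
    ``truth.accretion_rate`` molecules per second. Start sizes are drawn
    log-normal with median ``truth.start_molecules`` (set
    ``start_sigma_log=0`` for every trajectory to start at exactly that
    value). ``noise`` adds multiplicative measurement noise to molecules and
    Gaussian localization error to positions; a plain number is shorthand
    for using it as both the CV and the positional SD in µm. Returns a
    detection table with columns frame, t_s, x_um, y_um, molecules,
    truth_id.
    """
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if n_traj <= 0:
        raise InvalidParameterError("n_traj must be > 0")
    if isinstance(noise, (int, float)):
        noise = MeasurementNoise(molecule_cv=float(noise), position_sd_um=float(noise))

    rng = np.random.default_rng(rng_seed)
    dt = truth.frame_interval_s
    side = int(math.ceil(math.sqrt(n_traj)))

    if truth.start_sigma_log > 0:
        starts = rng.lognormal(math.log(truth.start_molecules), truth.start_sigma_log, n_traj)
    else:
        starts = np.full(n_traj, truth.start_molecules)
    thetas = rng.uniform(0, 2 * math.pi, n_traj)

    records = []
    for i in range(n_traj):
        pos = np.array([(i % side) * grid_spacing_um, (i // side) * grid_spacing_um], float)
        direction = np.array([math.cos(thetas[i]), math.sin(thetas[i])])
        m = float(starts[i])
        for f in range(n_frames):
            measured_m = m * max(0.0, 1.0 + noise.molecule_cv * rng.standard_normal())
            measured_pos = pos + noise.position_sd_um * rng.standard_normal(2)
            records.append(
                {
                    "frame": f,
                    "t_s": f * dt,
                    "x_um": measured_pos[0],
                    "y_um": measured_pos[1],
                    "molecules": measured_m,
                    "truth_id": i,
                }
            )
            speed_um_s = truth.speed_law(m) / 1000.0
            pos = pos + direction * speed_um_s * dt
            m = m + truth.accretion_rate * dt
    return pd.DataFrame.from_records(records)
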