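"""Segmentation of filopodial Myo10 puncta and intensity-to-molecule conversion.

The fixed-cell pipeline mirrors the imaging workflow: background-subtract the
Myo10 channel (mean of a 56×56 px square near the cell, or a 50 px
rolling-ball estimate for live snapshots), threshold to a total-cell mask,
derive a cell-body mask from the phalloidin channel by erosion and opening,
subtract body from total to get a filopodia mask, and run connected-component
analysis (8-connectivity: pixels joined through at most two orthogonal hops)
to obtain per-punctum records. Integrated punctum intensities are converted
to absolute molecule counts through a fluorescence scale established on a
calibration set of n cells holding n·⟨m⟩ molecules in total:

    r = n · ⟨m⟩ · I_ROI / I_n
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image, dilation, disk, erosion, opening
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .calibration import StandardCurve, propagate_slope_ci
from .errors import InvalidParameterError, UndefinedStatisticError
from .synthetic import DEFAULT_PIXEL_SIZE_UM


@dataclass(frozen=True)
class FluorescenceScale:
    """Per-replicate intensity→molecule conversion context.

    n_cells:
        Number of calibration cells imaged.
    mean_molecules:
        ⟨m⟩, mean molecules per transfected cell from the gel calibration.
    total_signal:
        I_n, background-corrected signal summed over all n cells' total-cell
        masks.
    """

    n_cells: int
    mean_molecules: float
    total_signal: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if self.total_signal <= 0:
            raise InvalidParameterError("total_signal must be > 0")


@dataclass(frozen=True)
class MaskSet:
    """Total-cell, cell-body and filopodia masks with their set algebra."""

    total_cell_mask: np.ndarray
    cell_body_mask: np.ndarray
    filopodia_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.total_cell_mask.shape
            == self.cell_body_mask.shape
            == self.filopodia_mask.shape
        ):
            raise InvalidParameterError("masks must share one shape")
        expected = self.total_cell_mask & ~self.cell_body_mask
        if not np.array_equal(self.filopodia_mask, expected):
            raise InvalidParameterError(
                "filopodia_mask must equal total_cell_mask AND NOT cell_body_mask"
            )


@dataclass
class PunctumRecord:
    """One segmented Myo10 spot."""

    label: int
    pixels: np.ndarray  # (N, 2) array of (row, col)
    integrated_intensity: float
    centroid: tuple[float, float]  # (row, col)
    molecules: float | None = None
    molecules_ci: tuple[float, float] | None = None
    length_um: float | None = None
    tip_flag: bool = False
    filopodium_id: int | None = None

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background_square(
    image: np.ndarray,
    square_corner: tuple[int, int],
    size: int = 56,
    return_stats: bool = False,
):
    """Subtract the mean of a size×size square region from every pixel.

    The square must lie fully inside the image and should cover a
    signal-free region near the cell. Negative pixels are clipped to zero so
    that sums over masks are not biased downward. With ``return_stats`` the
    square's (mean, sd) is also returned, the sd being a read-noise estimate.
    """
    r, c = square_corner
    if size < 1:
        raise InvalidParameterError("square size must be >= 1")
    if r < 0 or c < 0 or r + size > image.shape[0] or c + size > image.shape[1]:
        raise InvalidParameterError("background square does not fit inside the image")
    patch = image[r : r + size, c : c + size]
    mean = float(patch.mean())
    corrected = np.clip(image - mean, 0.0, None)
    if return_stats:
        return corrected, (mean, float(patch.std()))
    return corrected


def subtract_background_rolling_ball(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction (morphological background estimate).

    Removes smooth background structure larger than the ball while preserving
    puncta smaller than the ball radius; negatives are clipped to zero.
    """
    if radius < 1:
        raise InvalidParameterError("rolling-ball radius must be >= 1")
    background = rolling_ball(image, radius=radius)
    return np.clip(image - background, 0.0, None)


# ---------------------------------------------------------------------------
# masks


def _threshold(image: np.ndarray, method: str, noise_sd: float | None, k: float) -> float:
    if method == "otsu":
        if image.max() == image.min():
            return float(image.max())  # blank image: nothing passes a > threshold
        return float(threshold_otsu(image))
    if method == "sigma":
        if noise_sd is None:
            # fall back to the spread of the sub-Otsu (background) pixels
            below = image[image < _threshold(image, "otsu", None, k)]
            noise_sd = float(below.std()) if below.size else 0.0
        return k * noise_sd
    raise InvalidParameterError(f"unknown threshold method {method!r}")


def make_total_cell_mask(
    image: np.ndarray,
    min_object_area: int = 500,
    method: str = "otsu",
    noise_sd: float | None = None,
    sigma_k: float = 3.0,
    watershed_min_distance: int = 40,
    watershed_rel_threshold: float = 0.3,
) -> list[np.ndarray]:
    """Segment whole cells from a background-subtracted Myo10 image.

    Thresholds the image (Otsu by default, or ``k × noise sd`` with
    ``method="sigma"`` for flat-background images), removes objects smaller
    than ``min_object_area``, and splits touching cells by watershed seeded
    at distance-transform maxima. Returns one boolean mask per retained
    cell, largest first; a blank image yields an empty list.
    """
    thr = _threshold(image, method, noise_sd, sigma_k)
    fg = image > thr
    # drop components below min_object_area (8-connectivity, like the CCA)
    labeled = cc_label(fg, connectivity=2)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    fg = sizes[labeled] >= min_object_area
    if not fg.any():
        return []

    masks: list[np.ndarray] = []
    labeled = cc_label(fg, connectivity=2)
    for region_label in range(1, labeled.max() + 1):
        comp = labeled == region_label
        dist = ndi.distance_transform_edt(comp)
        peaks = peak_local_max(
            dist,
            min_distance=watershed_min_distance,
            threshold_abs=watershed_rel_threshold * float(dist.max()),
            labels=comp,
        )
        if peaks.shape[0] <= 1:
            masks.append(comp)
            continue
        markers = np.zeros_like(labeled)
        markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
        split = watershed(-dist, markers=markers, mask=comp)
        for sub in range(1, peaks.shape[0] + 1):
            piece = split == sub
            if piece.sum() >= min_object_area:
                masks.append(piece)
    masks.sort(key=lambda m: int(m.sum()), reverse=True)
    return masks


def make_cell_body_mask(
    phalloidin_image: np.ndarray,
    erosion_radius: int = 1,
    opening_radius: int = 2,
    threshold: float | None = None,
) -> np.ndarray:
    """Cell-body mask from the phalloidin channel: threshold, erode, open.

    The erosion pulls the boundary inward and the opening removes thin
    protrusions (filopodia shafts), leaving the body proper. Radii of zero
    skip the corresponding step, so (0, 0) returns the bare threshold mask.
    """
    if threshold is None:
        threshold = _threshold(phalloidin_image, "otsu", None, 3.0)
    mask = phalloidin_image > threshold
    if erosion_radius > 0:
        mask = erosion(mask, disk(erosion_radius))
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    return mask


def make_filopodia_mask(total: np.ndarray, body: np.ndarray) -> np.ndarray:
    """Set difference: pixels in the total-cell mask but not the body mask."""
    if total.shape != body.shape:
        raise InvalidParameterError("total and body masks must share one shape")
    return total & ~body


# ---------------------------------------------------------------------------
# puncta


def label_puncta(
    filopodia_mask: np.ndarray, intensity_image: np.ndarray | None = None
) -> list[PunctumRecord]:
    """Connected-component analysis of the filopodia mask.

    Pixels are neighbors when connected through at most two orthogonal hops,
    i.e. 8-connectivity including diagonals. Returns one record per
    component with its pixel set, centroid, and (if an intensity image is
    given) integrated background-corrected intensity.
    """
    labeled = cc_label(filopodia_mask, connectivity=2)
    records = []
    for prop in regionprops(labeled, intensity_image=intensity_image):
        intensity = (
            float(prop.image_intensity[prop.image].sum())
            if intensity_image is not None
            else float("nan")
        )
        records.append(
            PunctumRecord(
                label=int(prop.label),
                pixels=np.asarray(prop.coords),
                integrated_intensity=intensity,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    return records


def group_puncta_into_filopodia(
    puncta: Sequence[PunctumRecord],
    max_gap_um: float,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[PunctumRecord]:
    """Assign filopodium ids by single-linkage grouping of punctum pixel sets.

    Two puncta join the same filopodium when their pixel sets approach
    within ``max_gap_um`` (closest-point distance); grouping is transitive.
    ``max_gap_um = 0`` leaves every punctum its own filopodium. Ids are
    assigned in order of first appearance. Returns new records.
    """
    if max_gap_um < 0:
        raise InvalidParameterError("max_gap must be >= 0")
    n = len(puncta)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    max_gap_px = max_gap_um / pixel_size_um
    if max_gap_px > 0:
        trees = [cKDTree(p.pixels.astype(float)) for p in puncta]
        for i in range(n):
            for j in range(i + 1, n):
                # cheap bounding check before the exact closest-pair query
                ci, cj = np.array(puncta[i].centroid), np.array(puncta[j].centroid)
                reach = (
                    np.linalg.norm(ci - cj)
                    - math.hypot(*(np.ptp(puncta[i].pixels, axis=0) + 1))
                    - math.hypot(*(np.ptp(puncta[j].pixels, axis=0) + 1))
                )
                if reach > max_gap_px:
                    continue
                dists, _ = trees[j].query(puncta[i].pixels.astype(float), k=1)
                if float(np.min(dists)) <= max_gap_px:
                    parent[find(i)] = find(j)
    ids: dict[int, int] = {}
    out = []
    for i, punctum in enumerate(puncta):
        root = find(i)
        if root not in ids:
            ids[root] = len(ids)
        out.append(replace(punctum, filopodium_id=ids[root]))
    return out


def assign_tip_flags(
    puncta: Sequence[PunctumRecord], body_mask: np.ndarray
) -> list[PunctumRecord]:
    """Flag, per filopodium group, the punctum most distal from the body.

    Distality is the Euclidean distance from the punctum centroid to the
    nearest body-mask pixel. Requires ``filopodium_id`` to be assigned.
    """
    dist_map = ndi.distance_transform_edt(~body_mask)
    out = [replace(p, tip_flag=False) for p in puncta]
    groups: dict[int, list[int]] = {}
    for idx, p in enumerate(out):
        if p.filopodium_id is None:
            raise InvalidParameterError("assign filopodium ids before tip flags")
        groups.setdefault(p.filopodium_id, []).append(idx)
    for indices in groups.values():
        def distality(i: int) -> float:
            r, c = out[i].centroid
            return float(dist_map[int(round(r)), int(round(c))])

        tip = max(indices, key=distality)
        out[tip] = replace(out[tip], tip_flag=True)
    return out


def convex_hull_mask(
    puncta: Sequence[PunctumRecord], shape: tuple[int, int]
) -> tuple[np.ndarray, bool]:
    """Filled convex hull of all punctum pixels (live-cell total-cell region).

    Degenerate geometry (fewer than 3 non-collinear pixels) falls back to the
    bounding box; the second return value flags the fallback.
    """
    pts = np.concatenate([p.pixels for p in puncta], axis=0)
    if pts.shape[0] == 0:
        raise InvalidParameterError("no punctum pixels for a hull")
    scatter = np.zeros(shape, dtype=bool)
    scatter[pts[:, 0], pts[:, 1]] = True
    unique = np.unique(pts, axis=0)
    degenerate = unique.shape[0] < 3 or (
        np.linalg.matrix_rank(unique - unique.mean(axis=0)) < 2
    )
    if degenerate:
        box = np.zeros(shape, dtype=bool)
        r0, c0 = pts.min(axis=0)
        r1, c1 = pts.max(axis=0)
        box[r0 : r1 + 1, c0 : c1 + 1] = True
        return box, True
    return convex_hull_image(scatter), False


# ---------------------------------------------------------------------------
# molecule conversion and descriptors


def intensity_to_molecules(i_roi: float, scale: FluorescenceScale) -> float:
    """r = n · ⟨m⟩ · I_ROI / I_n."""
    if i_roi < 0:
        raise InvalidParameterError("I_ROI must be >= 0")
    return scale.n_cells * scale.mean_molecules * i_roi / scale.total_signal


def percent_filopodial(filopodial_molecules: float, total_molecules: float) -> float:
    """Percent of a cell's Myo10 localized in filopodia."""
    if total_molecules <= 0:
        raise UndefinedStatisticError("percent filopodial undefined for zero total")
    if filopodial_molecules < 0 or filopodial_molecules > total_molecules * (1 + 1e-9):
        raise InvalidParameterError("filopodial molecules must lie in [0, total]")
    return 100.0 * filopodial_molecules / total_molecules


def punctum_length(
    punctum: PunctumRecord, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> float:
    """Apparent punctum length: maximum Feret-style diameter × pixel size.

    Computed as the maximum pairwise pixel-center distance plus one pixel
    (accounting for pixel extent), with a floor of one pixel for a single-
    pixel punctum.
    """
    if punctum.pixels.shape[0] == 0:
        raise InvalidParameterError("punctum has no pixels")
    if punctum.pixels.shape[0] == 1:
        return pixel_size_um
    max_d = float(pdist(punctum.pixels.astype(float)).max())
    return (max_d + 1.0) * pixel_size_um


# ---------------------------------------------------------------------------
# pipeline convenience


@dataclass
class SceneQuantification:
    """Result bundle of :func:`quantify_scene`."""

    masks: MaskSet
    puncta: list[PunctumRecord]
    cell_total_intensity: float
    cell_total_molecules: float | None
    filopodial_molecules: float | None
    percent_filopodial: float | None
    noise_sd: float
    filopodium_totals: dict[int, float] = field(default_factory=dict)
    filopodium_tip_centroids: dict[int, tuple[float, float]] = field(default_factory=dict)


def quantify_scene(
    myo10_image: np.ndarray,
    phalloidin_image: np.ndarray,
    scale: FluorescenceScale | None = None,
    curve: StandardCurve | None = None,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    bg_square_corner: tuple[int, int] = (0, 0),
    bg_square_size: int = 56,
    threshold_method: str = "sigma",
    min_object_area: int = 500,
    body_erosion_radius: int = 1,
    body_opening_radius: int = 2,
    body_margin_px: int = 3,
    max_gap_um: float = 0.5,
) -> SceneQuantification:
    """Run the fixed-cell pipeline on one two-channel image.

    Steps: square background subtraction on both channels, total-cell mask
    from the Myo10 channel (largest cell retained), body mask from
    phalloidin, filopodia mask by subtraction after dilating the body mask
    by ``body_margin_px`` (so eroded-boundary body pixels cannot masquerade
    as filopodial puncta), connected-component labeling, single-linkage
    grouping into filopodia, tip flagging, and — when a fluorescence scale
    is supplied — molecule conversion with slope-propagated CIs.
    """
    myo10_corr, (_, noise_sd) = subtract_background_square(
        myo10_image, bg_square_corner, bg_square_size, return_stats=True
    )
    phalloidin_corr = subtract_background_square(
        phalloidin_image, bg_square_corner, bg_square_size
    )

    cells = make_total_cell_mask(
        myo10_corr,
        min_object_area=min_object_area,
        method=threshold_method,
        noise_sd=noise_sd,
    )
    if not cells:
        raise InvalidParameterError("no cell found in the image")
    total = cells[0]

    body = make_cell_body_mask(
        phalloidin_corr,
        erosion_radius=body_erosion_radius,
        opening_radius=body_opening_radius,
    )
    body_for_subtraction = (
        dilation(body, disk(body_margin_px)) if body_margin_px > 0 else body
    )
    filopodia = make_filopodia_mask(total, body_for_subtraction)
    masks = MaskSet(
        total_cell_mask=total,
        cell_body_mask=body_for_subtraction,
        filopodia_mask=filopodia,
    )

    puncta = label_puncta(filopodia, intensity_image=myo10_corr)
    puncta = group_puncta_into_filopodia(puncta, max_gap_um, pixel_size_um)
    puncta = assign_tip_flags(puncta, body_for_subtraction)
    for i, p in enumerate(puncta):
        puncta[i] = replace(p, length_um=punctum_length(p, pixel_size_um))

    cell_total_intensity = float(myo10_corr[total].sum())
    filopodial_intensity = float(myo10_corr[filopodia].sum())

    cell_total_molecules = filopodial_molecules = pct = None
    if scale is not None:
        cell_total_molecules = intensity_to_molecules(cell_total_intensity, scale)
        filopodial_molecules = intensity_to_molecules(filopodial_intensity, scale)
        pct = (
            percent_filopodial(filopodial_molecules, cell_total_molecules)
            if cell_total_molecules > 0
            else None
        )
        for i, p in enumerate(puncta):
            mol = intensity_to_molecules(p.integrated_intensity, scale)
            ci = propagate_slope_ci(curve, mol) if curve is not None else None
            puncta[i] = replace(p, molecules=mol, molecules_ci=ci)

    filopodium_totals: dict[int, float] = {}
    tip_centroids: dict[int, tuple[float, float]] = {}
    for p in puncta:
        if p.filopodium_id is None:
            continue
        value = p.molecules if p.molecules is not None else p.integrated_intensity
        filopodium_totals[p.filopodium_id] = filopodium_totals.get(p.filopodium_id, 0.0) + value
        if p.tip_flag:
            tip_centroids[p.filopodium_id] = p.centroid

    return SceneQuantification(
        masks=masks,
        puncta=puncta,
        cell_total_intensity=cell_total_intensity,
        cell_total_molecules=cell_total_molecules,
        filopodial_molecules=filopodial_molecules,
        percent_filopodial=pct,
        noise_sd=noise_sd,
        filopodium_totals=filopodium_totals,
        filopodium_tip_centroids=tip_centroids,
    )
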