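"""Pipeline configuration, YAML round-trip, and the stage orchestrator."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    DEFAULT_LABELING_EFFICIENCY,
    HALOTAG_STANDARD_MW,
    fit_standard_curve,
    lane_to_molecules_per_cell,
    read_lanes,
)
from .errors import InvalidParameterError
from .tipmodels import (
    FilopodiumGeometry,
    accessible_actin_concentration,
    classify_saturation,
    cylinder_concentration,
)
from .synthetic import DEFAULT_PIXEL_SIZE_UM

logger = logging.getLogger("filoquant")

#: fields that must be explicitly present in a config file
REQUIRED_KEYS = ("pixel_size_um", "frame_interval_s")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serializable to YAML.

    The physical scale of the data (pixel size and frame interval) must be
    stated explicitly when loading from a file; everything else has
    defaults.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = 1.0
    labeling_efficiency: float = DEFAULT_LABELING_EFFICIENCY
    transfection_fraction: float = 0.5
    standard_mw: float = HALOTAG_STANDARD_MW
    geometry: FilopodiumGeometry = field(default_factory=FilopodiumGeometry)
    myo10_footprint_nm2: float = 100.0
    # segmentation
    bg_square_size: int = 56
    rolling_ball_radius: int = 50
    min_object_area: int = 500
    body_erosion_radius: int = 1
    body_opening_radius: int = 2
    body_margin_px: int = 3
    threshold_method: str = "sigma"
    max_gap_um: float = 0.5
    # linking
    max_link_um: float = 0.5
    max_gap_frames: int = 2
    gap_close_dist_um: float = 1.0
    # rose
    n_sections: int = 20
    n_boot: int = 500
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "labeling_efficiency",
            "transfection_fraction",
            "standard_mw",
            "myo10_footprint_nm2",
            "max_link_um",
            "gap_close_dist_um",
        ):
            value = getattr(self, name)
            if value is None or value <= 0:
                raise InvalidParameterError(f"config field {name!r} must be positive")
        if not (0 < self.labeling_efficiency <= 1):
            raise InvalidParameterError("config field 'labeling_efficiency' must be in (0, 1]")
        if not (0 < self.transfection_fraction <= 1):
            raise InvalidParameterError(
                "config field 'transfection_fraction' must be in (0, 1]"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        for key in REQUIRED_KEYS:
            if key not in data:
                raise InvalidParameterError(f"config is missing required field {key!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config fields: {sorted(unknown)}")
        data = dict(data)
        if "geometry" in data and isinstance(data["geometry"], dict):
            data["geometry"] = FilopodiumGeometry(**data["geometry"])
        config = cls(**data)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash identifying this exact parameterization."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    inputs: dict,
    out_dir: str | Path,
    stages: tuple[str, ...] = ("calibrate",),
) -> dict:
    """Execute the requested stages and write tables plus a run log.

    ``inputs`` maps stage inputs to paths or in-memory objects:
    ``lanes`` (CSV path) for calibrate; ``myo10_image``/``phalloidin_image``
    (arrays or TIFF paths) for quantify; ``detections`` (CSV path or
    DataFrame) for track; ``puncta_values``/``punctum_lengths`` for tips.
    Every written table carries the config hash in a header comment. Returns
    a result dictionary with one entry per stage.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    chash = config.config_hash()

    def write_table(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        with open(path, "w") as handle:
            handle.write(f"# filoquant {__version__} config_hash={chash}\n")
            frame.to_csv(handle, index=False)

    curve = None
    if "calibrate" in stages:
        if "lanes" not in inputs:
            raise InvalidParameterError("stage 'calibrate' needs input 'lanes'")
        lanes = (
            read_lanes(inputs["lanes"])
            if isinstance(inputs["lanes"], (str, Path))
            else inputs["lanes"]
        )
        standards = [ln for ln in lanes if ln.role == "standard"]
        lysates = [ln for ln in lanes if ln.role == "lysate"]
        curve = fit_standard_curve(standards)
        if not lysates:
            raise InvalidParameterError("stage 'calibrate' found no lysate lane")
        calib = lane_to_molecules_per_cell(
            lysates[0],
            curve,
            config.transfection_fraction,
            config.labeling_efficiency,
            config.standard_mw,
        )
        results["calibrate"] = {"curve": curve, "result": calib}
        write_table(
            pd.DataFrame(
                [
                    {
                        "slope": curve.slope,
                        "slope_se": curve.slope_se,
                        "r_squared": curve.r_squared,
                        "df": curve.df,
                        "mean_molecules_per_cell": calib.mean_molecules_per_cell,
                        "ci95_lo": calib.ci95[0],
                        "ci95_hi": calib.ci95[1],
                    }
                ]
            ),
            "calibration.csv",
        )

    if "quantify" in stages:
        from .quantify import quantify_scene

        for key in ("myo10_image", "phalloidin_image"):
            if key not in inputs:
                raise InvalidParameterError(f"stage 'quantify' needs input {key!r}")

        def load(obj):
            if isinstance(obj, (str, Path)):
                import tifffile

                return tifffile.imread(obj).astype(float)
            return np.asarray(obj, float)

        scale = inputs.get("scale")
        quant = quantify_scene(
            load(inputs["myo10_image"]),
            load(inputs["phalloidin_image"]),
            scale=scale,
            curve=curve,
            pixel_size_um=config.pixel_size_um,
            bg_square_size=config.bg_square_size,
            threshold_method=config.threshold_method,
            min_object_area=config.min_object_area,
            body_erosion_radius=config.body_erosion_radius,
            body_opening_radius=config.body_opening_radius,
            body_margin_px=config.body_margin_px,
            max_gap_um=config.max_gap_um,
            bg_square_corner=inputs.get("bg_square_corner", (0, 0)),
        )
        results["quantify"] = quant
        rows = [
            {
                "label": p.label,
                "filopodium_id": p.filopodium_id,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "area_px": p.area,
                "intensity": p.integrated_intensity,
                "molecules": p.molecules,
                "molecules_ci_lo": p.molecules_ci[0] if p.molecules_ci else None,
                "molecules_ci_hi": p.molecules_ci[1] if p.molecules_ci else None,
                "length_um": p.length_um,
                "tip_flag": p.tip_flag,
            }
            for p in quant.puncta
        ]
        write_table(pd.DataFrame(rows), "puncta.csv")

    if "rose" in stages:
        from .rose import align_profile, angular_sections, bootstrap_sem, profile_frame

        if "cells" not in inputs:
            raise InvalidParameterError(
                "stage 'rose' needs input 'cells' (list of (puncta, center) pairs)"
            )
        profiles = [
            align_profile(
                angular_sections(puncta, center, config.n_sections),
                mode=inputs.get("rose_mode", "max"),
                rng_seed=config.rng_seed,
            )
            for puncta, center in inputs["cells"]
        ]
        mean_profile = bootstrap_sem(profiles, config.n_boot, config.rng_seed)
        results["rose"] = mean_profile
        write_table(profile_frame(mean_profile), "rose.csv")

    if "tips" in stages:
        if "tip_table" not in inputs:
            raise InvalidParameterError(
                "stage 'tips' needs input 'tip_table' (molecules, length_um columns)"
            )
        table = inputs["tip_table"]
        if isinstance(table, (str, Path)):
            table = pd.read_csv(table)
        geom = config.geometry
        rows = []
        for _, row in table.iterrows():
            conc = cylinder_concentration(
                row["molecules"], row["length_um"], geom.radius_um
            )
            cls = classify_saturation(
                row["molecules"], row["length_um"], geom, config.myo10_footprint_nm2
            )
            rows.append(
                {
                    "molecules": row["molecules"],
                    "length_um": row["length_um"],
                    "concentration_uM": conc,
                    "saturation": cls.value,
                }
            )
        frame = pd.DataFrame(rows)
        results["tips"] = {
            "table": frame,
            "accessible_actin_uM": accessible_actin_concentration(geom),
        }
        write_table(frame, "tips.csv")

    if "track" in stages:
        from .tracks import link_puncta, phase_statistics, trajectories_to_frame

        if "detections" not in inputs:
            raise InvalidParameterError("stage 'track' needs input 'detections'")
        det = inputs["detections"]
        if isinstance(det, (str, Path)):
            det = pd.read_csv(det)
        trajectories = link_puncta(
            det,
            max_link_um=config.max_link_um,
            max_gap_frames=config.max_gap_frames,
            gap_close_dist_um=config.gap_close_dist_um,
            frame_interval_s=config.frame_interval_s,
        )
        results["track"] = {
            "trajectories": trajectories,
            "statistics": phase_statistics(trajectories),
        }
        write_table(trajectories_to_frame(trajectories), "trajectories.csv")
        (out_dir / "track_statistics.json").write_text(
            json.dumps(results["track"]["statistics"], indent=2)
        )

    log = {
        "filoquant_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config_hash": chash,
        "config": config.to_dict(),
        "stages": list(stages),
        "rng_seed": config.rng_seed,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline finished: stages=%s out=%s", stages, out_dir)
    return results
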