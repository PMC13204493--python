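"""Single-JSON configuration carrying every numeric default of the tool."""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Any

from .imageio import DEFAULT_PIXEL_SIZE_UM, ImagingGeometry
from .prefilter import PrefilterConfig
from .synth import CalSimConfig, SceneConfig

__all__ = ["default_config", "load_config", "save_config", "prefilter_from_config"]

DEFAULT_SEED = 20240101


def default_config() -> dict[str, Any]:
    """All tunable defaults, grouped by module."""
    geometry = ImagingGeometry()
    scene = SceneConfig()
    cal = CalSimConfig()
    return {
        "imaging": {
            "camera_pixel_um": geometry.camera_pixel_um,
            "magnification": geometry.magnification,
            "pixel_size_um": DEFAULT_PIXEL_SIZE_UM,
            "view_px": list(geometry.view_px),
            "images_per_set": geometry.images_per_set,
        },
        "prefilter": dataclasses.asdict(PrefilterConfig()),
        "classifier": {
            "n_trees": 100,
            "max_features": "sqrt",
            "bootstrap": True,
            "n_per_class": 150,
            "split": [100, 50],
            "seed": DEFAULT_SEED,
        },
        "calibration": {
            "concentrations": list(cal.concentrations),
            "replicates": cal.replicates,
            "capture_efficiency": cal.capture_efficiency,
            "effective_volume_ul": cal.effective_volume_ul,
            "background_mean": cal.background_mean,
            "background_sd": cal.background_sd,
            "confidence": 0.95,
            "z_detection": 1.645,
            "quantification_sd_multiple": 10.0,
        },
        "synth": {
            "tile_px": list(scene.tile_px),
            "background_level": scene.background_level,
            "read_noise_sd": scene.read_noise_sd,
            "densities": dict(scene.densities),
            "cell_diameter_um_range": list(scene.cell_diameter_um_range),
            "platelet_diameter_um_range": list(scene.platelet_diameter_um_range),
            "rbc_diameter_um_range": list(scene.rbc_diameter_um_range),
            "cell_contrast": scene.cell_contrast,
            "crowding": scene.crowding,
            "fluor_positive_fraction": 0.88,
        },
        "mixture": {"min_sd": 1e-4, "max_iter": 500},
    }


def save_config(config: dict[str, Any], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path: str | os.PathLike | None = None) -> dict[str, Any]:
    """Defaults, overlaid (one level deep) with the user's JSON file."""
    config = default_config()
    if path is None:
        return config
    with open(path) as fh:
        user = json.load(fh)
    for section, values in user.items():
        if section in config and isinstance(values, dict):
            config[section].update(values)
        else:
            config[section] = values
    return config


def prefilter_from_config(config: dict[str, Any]) -> PrefilterConfig:
    fields = {f.name for f in dataclasses.fields(PrefilterConfig)}
    values = {k: v for k, v in config.get("prefilter", {}).items() if k in fields}
    return PrefilterConfig(**values)


def scene_from_config(config: dict[str, Any], seed: int | None = None) -> SceneConfig:
    synth = config.get("synth", {})
    kwargs: dict[str, Any] = {}
    for key in (
        "background_level",
        "read_noise_sd",
        "densities",
        "cell_contrast",
        "crowding",
    ):
        if key in synth:
            kwargs[key] = synth[key]
    for key in ("tile_px", "cell_diameter_um_range", "platelet_diameter_um_range",
                "rbc_diameter_um_range"):
        if key in synth:
            kwargs[key] = tuple(synth[key])
    if seed is not None:
        kwargs["seed"] = seed
    return SceneConfig(**kwargs)
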