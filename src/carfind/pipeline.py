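"""End-to-end sample pipeline: detect -> classify -> count -> report.

A run takes a directory of brightfield tiles, a trained model and a
stored calibration fit; it reports per-class counts, the CART total,
and the concentration obtained by inverting the calibration curve,
flagged against the fit's LOD/LOQ:

* ``not detected`` — count below the detection threshold;
* ``detected, below quantification`` — between LOD and LOQ thresholds;
* ``quantified`` — at or above the quantification threshold.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Optional

from . import __version__
from .imageio import Image, read_image
from .objects import TrainedModel, load_model
from .prefilter import PrefilterConfig
from .quantify import CalibrationFit, Z_95, count_sample

__all__ = ["RunManifest", "run_pipeline", "load_fit", "save_fit"]


@dataclass
class RunManifest:
    tool_version: str
    config: dict[str, Any]
    input_hashes: dict[str, str]
    seeds: dict[str, int]
    timestamp: str
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_fit(fit: CalibrationFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")


def load_fit(path) -> CalibrationFit:
    with open(path) as fh:
        blob = json.load(fh)
    return CalibrationFit(
        form=blob["form"],
        a=blob["a"],
        b=blob["b"],
        r_squared=blob["r_squared"],
        residual_sd=blob["residual_sd"],
        blank_mean=blob.get("blank_mean", 0.0),
        blank_sd=blob.get("blank_sd", 0.0),
        lod=blob.get("lod"),
        loq=blob.get("loq"),
        confidence=blob.get("confidence", 0.95),
    )


def _classify_count(count: float, fit: CalibrationFit) -> tuple[Optional[float], str]:
    """Invert the fit at the observed count and flag against LOD/LOQ."""
    sd = fit.blank_sd if fit.blank_sd > 0 else fit.residual_sd
    y_d = fit.blank_mean + 2.0 * Z_95 * sd
    y_q = fit.blank_mean + 10.0 * sd
    if count <= fit.blank_mean:
        return 0.0, "not detected"
    try:
        concentration = fit.invert(count)
    except ValueError:
        return 0.0, "not detected"
    if count < y_d:
        return concentration, "not detected"
    if count < y_q:
        return concentration, "detected, below quantification"
    return concentration, "quantified"


def run_pipeline(
    tiles: list[Image] | str,
    model: TrainedModel | str,
    fit: CalibrationFit | str,
    config: dict[str, Any] | None = None,
    prefilter_config: PrefilterConfig | None = None,
    sample_id: str = "sample",
    out_dir: Optional[str] = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Run detect->classify->count->invert on a tile set and report.

    ``tiles`` may be a directory of TIFFs or in-memory images; ``model``
    and ``fit`` may be paths or objects. Writes ``report.json``,
    ``report.txt`` and ``manifest.json`` when ``out_dir`` is given, and
    returns the report dict.
    """
    from .config import default_config, prefilter_from_config

    config = config or default_config()
    if prefilter_config is None:
        prefilter_config = prefilter_from_config(config)

    input_hashes: dict[str, str] = {}
    if isinstance(tiles, str):
        paths = sorted(glob.glob(os.path.join(tiles, "*.tif")) +
                       glob.glob(os.path.join(tiles, "*.tiff")))
        if not paths:
            raise FileNotFoundError(f"no TIFF tiles in {tiles!r}")
        pixel_size = config["imaging"]["pixel_size_um"]
        tile_images = [read_image(p, pixel_size_um=pixel_size) for p in paths]
        for p in paths:
            input_hashes[os.path.basename(p)] = _sha256(p)
    else:
        tile_images = list(tiles)
    if isinstance(model, str):
        input_hashes["model"] = _sha256(model)
        model = load_model(model)
    if isinstance(fit, str):
        input_hashes["fit"] = _sha256(fit)
        fit = load_fit(fit)

    result = count_sample(tile_images, model, prefilter_config, sample_id=sample_id)
    concentration, flag = _classify_count(result.cart_count, fit)

    report = {
        "schema_version": 1,
        "sample_id": sample_id,
        "tiles": result.tiles,
        "per_class_counts": result.per_class_counts,
        "cart_count": result.cart_count,
        "estimated_concentration_cells_per_ul": concentration,
        "flag": flag,
        "calibration": fit.to_dict(),
    }
    manifest = RunManifest(
        tool_version=__version__,
        config=config,
        input_hashes=input_hashes,
        seeds={"pipeline": seed},
        timestamp=datetime.now(timezone.utc).isoformat(),
        stage_counts={
            "tiles": result.tiles,
            "candidates": int(sum(sum(c.values()) for c in result.per_tile_counts)),
            "cart": result.cart_count,
        },
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, default=str)
            fh.write("\n")
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            fh.write(_human_report(report))
    report["manifest"] = manifest.to_dict()
    return report


def _human_report(report: dict[str, Any]) -> str:
    lines = [
        f"Sample:        {report['sample_id']}",
        f"Tiles:         {report['tiles']}",
        f"CAR T count:   {report['cart_count']}",
        "Per-class:     "
        + ", ".join(f"{k}={v}" for k, v in report["per_class_counts"].items()),
        f"Concentration: {report['estimated_concentration_cells_per_ul']:.3g} cells/uL"
        if report["estimated_concentration_cells_per_ul"] is not None
        else "Concentration: n/a",
        f"Status:        {report['flag']}",
    ]
    return "\n".join(lines) + "\n"
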