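"""Ground-truthed synthetic brightfield/fluorescence data.

Emulates the acquisition this pipeline targets: 16-bit monochrome tiles
(2048x2048 at full scale, 512x512 by default to keep tests fast) with a
0.1625 µm sample-plane pixel, containing

* ``CART`` — lymphocyte-scale (7-15 µm) cells with defocus ring
  contrast (bright center, dark rim, optionally inverted);
* ``PLATELET`` — small (2-4 µm) low-contrast blobs;
* ``RBC`` — residual red cells: dark discs with a brighter central
  dimple (biconcave profile);
* ``OTHER`` — irregular multi-lobed debris.

Counts per tile are Poisson at configured densities; pixels carry
additive Gaussian read noise. Every generator is deterministic under
its seed, and every rendered object is recorded in a ground-truth
table. A separate calibration simulator produces (concentration,
count) tables with a capture-efficiency and blood-background model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imageio import Image, ImagingGeometry
from .objects import CLASSES, extract_features
from .prefilter import (
    Candidate,
    PrefilterConfig,
    disc_template,
    local_std_filter,
    radial_segment,
)

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "TruthRecord",
    "CalSimConfig",
    "PlacementError",
    "render_tile",
    "render_fluor",
    "make_object_library",
    "simulate_calibration",
]


class PlacementError(RuntimeError):
    """Raised when the requested density cannot be packed at the
    configured minimum spacing."""


@dataclass
class SceneConfig:
    """Generator knobs; defaults are the study's imaging conditions."""

    geometry: ImagingGeometry = field(default_factory=ImagingGeometry)
    tile_px: tuple[int, int] = (512, 512)
    background_level: float = 30000.0
    read_noise_sd: float = 300.0
    densities: dict[str, float] = field(
        default_factory=lambda: {"CART": 10.0, "PLATELET": 10.0, "RBC": 5.0, "OTHER": 5.0}
    )
    cell_diameter_um_range: tuple[float, float] = (7.0, 15.0)
    platelet_diameter_um_range: tuple[float, float] = (2.0, 4.0)
    rbc_diameter_um_range: tuple[float, float] = (6.0, 8.5)
    cell_contrast: float = 0.15  # ring amplitude relative to background
    crowding: float = 40.0  # minimum center spacing in px; 0 allows touching
    invert_contrast: bool = False
    exact_counts: bool = False  # use densities as exact per-tile counts
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be >= 0")
        for lo, hi in (
            self.cell_diameter_um_range,
            self.platelet_diameter_um_range,
            self.rbc_diameter_um_range,
        ):
            if not 0 < lo <= hi:
                raise ValueError("diameter ranges must be positive and ordered")
        amp = self.cell_contrast * self.background_level
        if not 0 <= self.background_level + amp <= 65535:
            raise ValueError("background plus contrast amplitude exceeds the 16-bit range")

    @property
    def pixel_size_um(self) -> float:
        return self.geometry.pixel_size_um


@dataclass
class TruthRecord:
    center: tuple[float, float]  # (row, col)
    radius_px: float
    object_class: str
    amplitude: float  # rendered contrast in intensity units


@dataclass
class GroundTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def totals(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for rec in self.records:
            out[rec.object_class] += 1
        return out

    def centers(self, object_class: Optional[str] = None) -> np.ndarray:
        pts = [
            r.center
            for r in self.records
            if object_class is None or r.object_class == object_class
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": [r.center[0] for r in self.records],
                "col": [r.center[1] for r in self.records],
                "radius_px": [r.radius_px for r in self.records],
                "class": [r.object_class for r in self.records],
                "amplitude": [r.amplitude for r in self.records],
            }
        )


def _sample_radius_px(rng, diameter_um_range, pixel_size_um) -> float:
    d = rng.uniform(*diameter_um_range)
    return d / 2.0 / pixel_size_um


def _granularity(shape, envelope, amplitude, rng, sigma_px=1.5) -> np.ndarray:
    """Intracellular granular contrast: smoothed noise under an envelope.

    Real brightfield lymphocytes are internally textured (organelles,
    membrane ruffling); this is what makes the local-SD stage light the
    whole cell up, not just its rim.
    """
    field_ = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma_px)
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return amplitude * field_ * envelope


def _profile_patch(shape, center, radius, kind, amplitude, rng) -> np.ndarray:
    """Additive intensity patch of one object on a local grid."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    R = radius
    if kind == "CART":
        # bright center, dark defocus rim at the edge, granular interior
        patch = np.exp(-((r / (0.55 * R)) ** 2)) - 0.8 * np.exp(
            -(((r - R) / (0.25 * R)) ** 2)
        )
        envelope = np.exp(-((r / (0.85 * R)) ** 4))
        return amplitude * patch + _granularity(shape, envelope, 0.35 * amplitude, rng)
    if kind == "PLATELET":
        sigma = R / 1.5
        return 0.4 * amplitude * np.exp(-(r**2) / (2 * sigma**2))
    if kind == "RBC":
        edge = 0.08 * R + 1.0
        body = 1.0 / (1.0 + np.exp((r - R) / edge))
        dimple = 0.5 * np.exp(-((r / (0.35 * R)) ** 2))
        envelope = np.exp(-((r / (0.85 * R)) ** 4))
        return amplitude * (-body + dimple) + _granularity(
            shape, envelope, 0.12 * amplitude, rng
        )
    if kind == "OTHER":
        # irregular: a central lobe plus 1-3 offset lobes of random sign
        patch = np.zeros(shape, dtype=float)
        n_lobes = int(rng.integers(2, 5))
        for i in range(n_lobes):
            if i == 0:
                cy, cx = center
            else:
                cy = center[0] + rng.uniform(-0.8, 0.8) * R
                cx = center[1] + rng.uniform(-0.8, 0.8) * R
            sigma = rng.uniform(0.3, 0.7) * R
            sign = 1.0 if (i == 0 or rng.random() < 0.5) else -1.0
            amp = rng.uniform(0.5, 1.1) * amplitude * sign
            rl = np.hypot(yy - cy, xx - cx)
            patch += amp * np.exp(-(rl**2) / (2 * sigma**2))
        return patch
    raise ValueError(f"unknown object kind {kind!r}")


def _place_centers(rng, shape, n, radius_max, existing, crowding) -> list[tuple[float, float]]:
    """Dart-throwing with restarts, then a shuffled-grid fallback.

    Near the packing limit plain rejection sampling stalls; a jittered
    square grid at the crowding pitch is always feasible while it has at
    least ``n`` free nodes.
    """
    h, w = shape
    margin = radius_max + 5
    if 2 * margin >= min(h, w):
        raise PlacementError("tile too small for the object size")

    def far_enough(cy, cx, pts):
        return all((cy - oy) ** 2 + (cx - ox) ** 2 >= crowding**2 for oy, ox in pts)

    for _ in range(10):  # dart throwing, restarted
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n and attempts < 200 * max(n, 1):
            attempts += 1
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if crowding > 0 and not far_enough(cy, cx, placed + existing):
                continue
            placed.append((cy, cx))
        if len(placed) == n:
            return placed

    if crowding > 0:
        pitch = crowding * 1.01
        ys = np.arange(margin, h - margin, pitch)
        xs = np.arange(margin, w - margin, pitch)
        nodes = [(float(y), float(x)) for y in ys for x in xs]
        rng.shuffle(nodes)
        placed = []
        for cy, cx in nodes:
            if far_enough(cy, cx, placed + existing):
                placed.append((cy, cx))
            if len(placed) == n:
                return placed
    raise PlacementError(
        f"could not place {n} objects at spacing {crowding} px in a {h}x{w} tile"
    )


def _render_object(canvas, rec: TruthRecord, rng, config: SceneConfig) -> None:
    R = rec.radius_px
    extent = int(math.ceil(2.2 * R)) + 3
    r0 = max(0, int(rec.center[0]) - extent)
    c0 = max(0, int(rec.center[1]) - extent)
    r1 = min(canvas.shape[0], int(rec.center[0]) + extent + 1)
    c1 = min(canvas.shape[1], int(rec.center[1]) + extent + 1)
    patch = _profile_patch(
        (r1 - r0, c1 - c0),
        (rec.center[0] - r0, rec.center[1] - c0),
        R,
        rec.object_class,
        rec.amplitude,
        rng,
    )
    if config.invert_contrast:
        patch = -patch
    canvas[r0:r1, c0:c1] += patch


def render_tile(config: SceneConfig, seed: Optional[int] = None) -> tuple[Image, GroundTruth]:
    """One brightfield tile plus its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.tile_px
    canvas = np.full((h, w), config.background_level, dtype=float)
    amp = config.cell_contrast * config.background_level
    px_um = config.pixel_size_um

    diameter_ranges = {
        "CART": config.cell_diameter_um_range,
        "PLATELET": config.platelet_diameter_um_range,
        "RBC": config.rbc_diameter_um_range,
        "OTHER": (5.0, 12.0),
    }
    truth = GroundTruth()
    existing: list[tuple[float, float]] = []
    for cls in CLASSES:
        density = config.densities.get(cls, 0.0)
        if density <= 0:
            continue
        n = int(round(density)) if config.exact_counts else int(rng.poisson(density))
        if n == 0:
            continue
        radius_max = diameter_ranges[cls][1] / 2.0 / px_um
        centers = _place_centers(rng, (h, w), n, radius_max, existing, config.crowding)
        existing.extend(centers)
        for cy, cx in centers:
            rec = TruthRecord(
                center=(cy, cx),
                radius_px=_sample_radius_px(rng, diameter_ranges[cls], px_um),
                object_class=cls,
                amplitude=amp,
            )
            _render_object(canvas, rec, rng, config)
            truth.records.append(rec)

    canvas += rng.normal(0.0, config.read_noise_sd, size=canvas.shape)
    np.clip(canvas, 0, 65535, out=canvas)
    image = Image(
        pixels=canvas, pixel_size_um=px_um, name=f"synthetic_seed{seed if seed is not None else config.seed}"
    )
    return image, truth


DEFAULT_DOT_MODEL = {
    "background_level": 500.0,
    "read_noise_sd": 30.0,
    "autofluor_amplitude": 120.0,
    "dot_amplitude": 4000.0,
    "dot_sigma_px": 2.5,
    "n_dots_range": (3, 8),
}


def render_fluor(
    truth: GroundTruth,
    positive_fraction: float,
    tile_px: tuple[int, int],
    dot_model: Optional[dict] = None,
    seed: int = 0,
) -> tuple[Image, np.ndarray]:
    """Paired fluorescence tile on the brightfield coordinates.

    Each CART object is CAR-positive with probability
    ``positive_fraction``; positives receive 3-8 bright punctate dots
    inside their footprint, negatives only uniform dim autofluorescence.
    Returns the image and a boolean positivity flag per truth record
    (False for non-CART objects).
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    model = dict(DEFAULT_DOT_MODEL)
    if dot_model:
        model.update(dot_model)
    rng = np.random.default_rng(seed)
    h, w = tile_px
    canvas = np.full((h, w), model["background_level"], dtype=float)
    positives = np.zeros(len(truth.records), dtype=bool)

    def local_grid(cy, cx, extent):
        r0, c0 = max(0, int(cy - extent)), max(0, int(cx - extent))
        r1, c1 = min(h, int(cy + extent) + 1), min(w, int(cx + extent) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        return (slice(r0, r1), slice(c0, c1)), yy, xx

    for i, rec in enumerate(truth.records):
        if rec.object_class != "CART":
            continue
        cy, cx = rec.center
        R = rec.radius_px
        sl, yy, xx = local_grid(cy, cx, R + 2)
        canvas[sl][np.hypot(yy - cy, xx - cx) <= R] += model["autofluor_amplitude"]
        if rng.random() < positive_fraction:
            positives[i] = True
            lo, hi = model["n_dots_range"]
            n_dots = int(rng.integers(lo, hi + 1))
            sigma = model["dot_sigma_px"]
            for _ in range(n_dots):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, 0.7 * R)
                dy, dx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                sl, yy, xx = local_grid(dy, dx, 5 * sigma)
                d2 = (yy - dy) ** 2 + (xx - dx) ** 2
                canvas[sl] += model["dot_amplitude"] * np.exp(-d2 / (2 * sigma**2))
    canvas += rng.normal(0.0, model["read_noise_sd"], size=canvas.shape)
    np.clip(canvas, 0, 65535, out=canvas)
    return Image(pixels=canvas, name=f"fluor_seed{seed}"), positives


def _zncc_at(arr: np.ndarray, center: tuple[int, int], template: np.ndarray) -> float:
    """Zero-mean normalized correlation of one window with the template."""
    r = template.shape[0] // 2
    cy, cx = center
    window = arr[cy - r : cy + r + 1, cx - r : cx + r + 1]
    t0 = template - template.mean()
    w0 = window - window.mean()
    den = math.sqrt(float((w0 * w0).sum()) * float((t0 * t0).sum()))
    if den == 0:
        return 0.0
    return float((w0 * t0).sum() / den)


def _render_crop(cls: str, config: SceneConfig, rng) -> tuple[np.ndarray, TruthRecord]:
    diameter_ranges = {
        "CART": config.cell_diameter_um_range,
        "PLATELET": config.platelet_diameter_um_range,
        "RBC": config.rbc_diameter_um_range,
        "OTHER": (5.0, 12.0),
    }
    px_um = config.pixel_size_um
    radius = _sample_radius_px(rng, diameter_ranges[cls], px_um)
    side = 2 * 80 + 33  # room for the largest cell ring plus the background ring
    center = (side // 2, side // 2)
    canvas = np.full((side, side), config.background_level, dtype=float)
    rec = TruthRecord(
        center=(float(center[0]), float(center[1])),
        radius_px=radius,
        object_class=cls,
        amplitude=config.cell_contrast * config.background_level,
    )
    _render_object(canvas, rec, rng, config)
    canvas += rng.normal(0.0, config.read_noise_sd, size=canvas.shape)
    np.clip(canvas, 0, 65535, out=canvas)
    return canvas, rec


def make_object_library(
    n_per_class: int = 150,
    split: tuple[int, int] = (100, 50),
    config: Optional[SceneConfig] = None,
    seed: int = 0,
    prefilter_config: Optional[PrefilterConfig] = None,
) -> tuple[list[tuple[Candidate, str]], list[tuple[Candidate, str]]]:
    """Labeled crop library: 4 classes x ``n_per_class`` with a disjoint
    train/test split (default 150 each, split 100/50 → 400 train + 200
    test objects).

    Masks and features come from the same radial-segmentation and
    feature operators used at detection time, so classifier training
    matches the deployment distribution.
    """
    if sum(split) != n_per_class:
        raise ValueError(f"split {split} must sum to n_per_class={n_per_class}")
    if config is None:
        config = SceneConfig()
    if prefilter_config is None:
        prefilter_config = PrefilterConfig()
    rng = np.random.default_rng(seed)
    template = disc_template(prefilter_config.template_radius_px)

    items: list[tuple[Candidate, str]] = []
    for cls in CLASSES:
        made = 0
        guard = 0
        while made < n_per_class:
            guard += 1
            if guard > 50 * n_per_class:
                raise RuntimeError(f"could not segment enough {cls} crops")
            crop, rec = _render_crop(cls, config, rng)
            sd = local_std_filter(crop, prefilter_config.std_window_px)
            cy, cx = int(rec.center[0]), int(rec.center[1])
            score = _zncc_at(sd, (cy, cx), template)
            if score <= 0:
                continue
            cands = radial_segment(crop, [(cy, cx, score)], prefilter_config)
            if not cands:
                continue
            cand = cands[0]
            r0, c0 = cand.crop_origin
            h, w = cand.crop.shape
            cand.features = extract_features(cand, sd[r0 : r0 + h, c0 : c0 + w])
            items.append((cand, cls))
            made += 1

    n_train, n_test = split
    train: list[tuple[Candidate, str]] = []
    test: list[tuple[Candidate, str]] = []
    for k, cls in enumerate(CLASSES):
        block = items[k * n_per_class : (k + 1) * n_per_class]
        order = rng.permutation(n_per_class)
        train.extend(block[i] for i in order[:n_train])
        test.extend(block[i] for i in order[n_train : n_train + n_test])
    return train, test


@dataclass
class CalSimConfig:
    """Calibration-experiment simulator: spiked concentrations, capture
    efficiency, and a blood-blank background model.

    ``response="linear"`` models dilute buffer capture
    (expected = efficiency x volume x concentration). ``response="log"``
    models the saturating whole-blood response — competitive adsorption
    on limited capture sites gives counts ~ amplitude x ln(1 + x/x0) —
    on top of a high white-cell background.
    """

    concentrations: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    replicates: int = 3
    capture_efficiency: float = 0.85
    effective_volume_ul: float = 7.1
    background_mean: float = 0.0
    background_sd: float = 0.0
    count_noise: str = "poisson"  # or "poisson+gaussian"
    response: str = "linear"  # or "log"
    log_amplitude: float = 300.0
    log_x0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.count_noise not in ("poisson", "poisson+gaussian"):
            raise ValueError(f"unknown count_noise {self.count_noise!r}")
        if self.response not in ("linear", "log"):
            raise ValueError(f"unknown response {self.response!r}")

    @classmethod
    def whole_blood(cls, **kwargs) -> "CalSimConfig":
        """Whole-blood defaults: saturating response plus >100-count
        white-cell background."""
        defaults = dict(response="log", background_mean=120.0)
        defaults.update(kwargs)
        return cls(**defaults)

    def expected_captured(self, concentration: float) -> float:
        if self.response == "linear":
            return concentration * self.effective_volume_ul * self.capture_efficiency
        return self.log_amplitude * math.log1p(concentration / self.log_x0)


def simulate_calibration(
    config: CalSimConfig, seed: Optional[int] = None, include_blanks: bool = True
) -> pd.DataFrame:
    """Poisson-sampled count table over the spiked concentrations.

    Expected observed count = expected captured + background mean;
    blanks (concentration 0) carry background only.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    concentrations = list(config.concentrations)
    if include_blanks:
        concentrations = [0.0] + concentrations
    for conc in concentrations:
        true_count = config.expected_captured(conc) if conc > 0 else 0.0
        expected = true_count + config.background_mean
        for rep in range(config.replicates):
            observed = float(rng.poisson(expected)) if expected > 0 else 0.0
            if config.count_noise == "poisson+gaussian" and config.background_sd > 0:
                observed += rng.normal(0.0, config.background_sd)
            rows.append(
                {
                    "concentration": conc,
                    "replicate": rep,
                    "true_count": true_count,
                    "observed_count": max(observed, 0.0),
                }
            )
    return pd.DataFrame(rows)
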