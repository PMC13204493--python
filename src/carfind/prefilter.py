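"""Five-stage candidate prefilter for brightfield tiles.

The chain converts a raw tile into isolated candidate objects:

1. **local standard-deviation filter** — texture response that rectifies
   contrast polarity (bright-center and dark-center cells both light up);
2. **match filter** — zero-mean normalized cross-correlation of the SD
   response with a rotationally symmetric disc/annulus template, so flat
   background scores 0 and cell-sized texture blobs score near 1;
3. **negative-value thresholding** — responses below max(0, threshold)
   are zeroed;
4. **local-maxima identification** — greedy non-maximum suppression with
   a minimum peak separation;
5. **radial segmentation** — ray-casting on the original tile delineates
   each candidate's footprint and rejects sub-/super-sized objects.

All stages use reflective border padding and the (row, col) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.draw import polygon as draw_polygon

from .imageio import Image

__all__ = [
    "PrefilterConfig",
    "Candidate",
    "disc_template",
    "annulus_template",
    "local_std_filter",
    "match_filter",
    "negative_threshold",
    "find_local_maxima",
    "radial_segment",
    "detect_candidates",
]


@dataclass
class PrefilterConfig:
    """Tunable constants of the five-stage prefilter.

    Defaults assume the 0.1625 µm/px sample-plane scale: a 10 µm
    lymphocyte spans ~62 px, hence the 31 px template radius.
    """

    std_window_px: int = 9
    template_radius_px: int = 35
    template_kind: str = "disc"  # or "annulus"
    annulus_inner_fraction: float = 0.6
    threshold: float = 0.45
    min_peak_distance_px: int = 35
    segment_radius_px: int = 60
    n_rays: int = 32
    boundary_fraction: float = 0.2
    min_area_px: int = 80
    max_area_px: int = 15000

    def __post_init__(self) -> None:
        if self.std_window_px < 3 or self.std_window_px % 2 == 0:
            raise ValueError("std_window_px must be odd and >= 3")
        if self.template_radius_px < 1:
            raise ValueError("template_radius_px must be >= 1")
        if self.template_kind not in ("disc", "annulus"):
            raise ValueError(f"unknown template kind {self.template_kind!r}")
        if self.min_peak_distance_px < 1:
            raise ValueError("min_peak_distance_px must be >= 1")
        if not 0 < self.min_area_px < self.max_area_px:
            raise ValueError("need 0 < min_area_px < max_area_px")


@dataclass
class Candidate:
    """A detected object: center, footprint, crop and (later) features."""

    center: tuple[float, float]  # (row, col)
    radius_px: float
    crop: np.ndarray
    mask: np.ndarray
    peak_score: float
    crop_origin: tuple[int, int] = (0, 0)  # (row, col) of crop[0, 0] in the tile
    features: Optional[np.ndarray] = None
    label: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.mask.shape != self.crop.shape:
            raise ValueError("mask and crop shapes differ")
        if not self.mask.any():
            raise ValueError("candidate mask is empty")
        if self.peak_score <= 0:
            raise ValueError("peak_score must be positive")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def disc_template(radius_px: int) -> np.ndarray:
    """Binary disc of the given radius on a (2r+1)^2 support."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= r**2).astype(float)


def annulus_template(radius_px: int, inner_fraction: float = 0.6) -> np.ndarray:
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    inner = inner_fraction * r
    return ((d2 <= r**2) & (d2 > inner**2)).astype(float)


def _as_array(image) -> np.ndarray:
    if isinstance(image, Image):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def local_std_filter(image, window_px: int) -> np.ndarray:
    """Population SD of the window centered at each pixel (reflect borders).

    Intensities are shifted by their global mean before the moment sums;
    the SD is shift-invariant and this keeps E[x^2] - E[x]^2 well
    conditioned at 16-bit scales.
    """
    arr = _as_array(image)
    if window_px % 2 == 0:
        raise ValueError("window must be odd")
    if window_px > min(arr.shape):
        raise ValueError("window exceeds image size")
    arr = arr - arr.mean()
    mean = ndimage.uniform_filter(arr, size=window_px, mode="reflect")
    mean_sq = ndimage.uniform_filter(arr * arr, size=window_px, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def _template_for(config: PrefilterConfig) -> np.ndarray:
    if config.template_kind == "disc":
        return disc_template(config.template_radius_px)
    return annulus_template(config.template_radius_px, config.annulus_inner_fraction)


def match_filter(response, config: PrefilterConfig) -> np.ndarray:
    """Zero-mean normalized cross-correlation with a symmetric template.

    Both the template and each sliding window are mean-subtracted over
    the full square support, so a flat window scores exactly 0 and the
    output lies in [-1, 1]. Borders use reflective padding; windows with
    zero variance score 0.
    """
    arr = _as_array(response)
    template = _template_for(config)
    th, tw = template.shape
    if th > arr.shape[0] or tw > arr.shape[1]:
        raise ValueError("template larger than image")

    t0 = template - template.mean()
    t_norm = math.sqrt(float((t0 * t0).sum()))
    n = template.size
    r = th // 2
    arr = arr - arr.mean()  # ZNCC is shift-invariant; keeps sums conditioned
    # edge-including reflection, same convention as the SD stage
    padded = np.pad(arr, r, mode="symmetric")

    # sum_w x*t0 equals sum_w (x - mean_w)(t - mean_t) because t0 sums to 0
    kernel = t0[::-1, ::-1]
    num = fftconvolve(padded, kernel, mode="valid")
    win_sum = fftconvolve(padded, np.ones_like(template), mode="valid")
    win_sumsq = fftconvolve(padded * padded, np.ones_like(template), mode="valid")
    win_var = np.maximum(win_sumsq - win_sum * win_sum / n, 0.0)
    den = np.sqrt(win_var) * t_norm

    # zero-variance windows (den == 0 up to FFT round-off) score 0
    out = np.zeros_like(num)
    good = win_var > 1e-12 * np.maximum(win_sumsq, np.finfo(float).tiny)
    out[good] = num[good] / den[good]
    return np.clip(out, -1.0, 1.0)


def negative_threshold(correlation, threshold: float = 0.0) -> np.ndarray:
    """Zero every value below max(0, threshold); keep the rest unchanged."""
    arr = _as_array(correlation)
    cut = max(0.0, float(threshold))
    out = arr.copy()
    out[out < cut] = 0.0
    return out


def find_local_maxima(thresholded, min_distance_px: int) -> list[tuple[int, int, float]]:
    """Strictly positive local maxima with greedy minimum-distance suppression.

    A pixel qualifies if it attains the maximum of its
    (2*min_distance+1)-square neighborhood (within the grid). Qualifying
    pixels are visited in descending score, ties broken by (row, col),
    and any pixel within Euclidean ``min_distance_px`` of an already
    accepted peak is suppressed.
    """
    arr = _as_array(thresholded)
    d = int(min_distance_px)
    if d < 1:
        raise ValueError("min_distance_px must be >= 1")
    size = 2 * d + 1
    neigh_max = ndimage.maximum_filter(arr, size=size, mode="constant", cval=-np.inf)
    cand_mask = (arr > 0) & (arr >= neigh_max)
    rows, cols = np.nonzero(cand_mask)
    if rows.size == 0:
        return []
    scores = arr[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    accepted: list[tuple[int, int, float]] = []
    acc_rc: list[tuple[int, int]] = []
    min_d2 = d * d
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if any((r - ar) ** 2 + (c - ac) ** 2 < min_d2 for ar, ac in acc_rc):
            continue
        accepted.append((r, c, float(scores[idx])))
        acc_rc.append((r, c))
    return accepted


def _ray_boundaries(
    arr: np.ndarray,
    peak: tuple[int, int],
    config: PrefilterConfig,
) -> Optional[np.ndarray]:
    """Per-ray boundary radii, or None when the center has no contrast.

    The local background is the median intensity on the circle of radius
    ``segment_radius_px`` around the peak (clipped to the grid); on each
    of ``n_rays`` rays the boundary is the first radius where
    |I - background| drops below ``boundary_fraction`` of its value at
    the center.
    """
    h, w = arr.shape
    pr, pc = peak
    rad = config.segment_radius_px
    angles = np.linspace(0.0, 2.0 * math.pi, config.n_rays, endpoint=False)

    ring_r = np.clip(np.rint(pr + rad * np.sin(angles)).astype(int), 0, h - 1)
    ring_c = np.clip(np.rint(pc + rad * np.cos(angles)).astype(int), 0, w - 1)
    background = float(np.median(arr[ring_r, ring_c]))

    center_dev = abs(float(arr[pr, pc]) - background)
    if center_dev <= 0.0:
        return None
    cutoff = config.boundary_fraction * center_dev

    radii = np.arange(1, rad + 1)
    rr = np.clip(np.rint(pr + np.outer(np.sin(angles), radii)).astype(int), 0, h - 1)
    cc = np.clip(np.rint(pc + np.outer(np.cos(angles), radii)).astype(int), 0, w - 1)
    dev = np.abs(arr[rr, cc] - background)  # (n_rays, rad)
    below = dev < cutoff
    # stop at the first sub-cutoff radius; the boundary is the last
    # radius still at/above the cutoff
    boundary = np.where(below.any(axis=1), below.argmax(axis=1).astype(float), float(rad))
    # circular 3-tap median across rays: a single ray stopped early by a
    # noise dip (or punched through a gap) must not dent the polygon
    stacked = np.stack([np.roll(boundary, 1), boundary, np.roll(boundary, -1)])
    return np.median(stacked, axis=0)


def radial_segment(
    original,
    peaks: list[tuple[int, int, float]],
    config: PrefilterConfig,
    source: str = "",
) -> list[Candidate]:
    """Ray-cast a footprint around each peak on the original tile.

    Each peak yields its own candidate; overlapping footprints are kept
    separate (separating crowded neighbors is the point of this stage).
    Candidates with footprint area outside [min_area_px, max_area_px]
    are discarded.
    """
    arr = _as_array(original)
    h, w = arr.shape
    candidates: list[Candidate] = []
    angles = np.linspace(0.0, 2.0 * math.pi, config.n_rays, endpoint=False)

    for pr, pc, score in peaks:
        pr_i, pc_i = int(round(pr)), int(round(pc))
        if not (0 <= pr_i < h and 0 <= pc_i < w):
            raise ValueError(f"peak ({pr}, {pc}) outside image of shape {arr.shape}")
        # ray-cast, then re-seed from the footprint centroid: the match
        # peak can sit off-center when object and template sizes disagree,
        # and a centered seed gives a more symmetric boundary polygon
        fill_r = fill_c = None
        for _ in range(3):
            boundary = _ray_boundaries(arr, (pr_i, pc_i), config)
            if boundary is None:
                break
            poly_r = pr_i + boundary * np.sin(angles)
            poly_c = pc_i + boundary * np.cos(angles)
            fr, fc = draw_polygon(poly_r, poly_c, shape=arr.shape)
            if fr.size == 0:
                break
            fill_r, fill_c = fr, fc
            nr, nc = int(round(fr.mean())), int(round(fc.mean()))
            if (nr, nc) == (pr_i, pc_i):
                break
            pr_i, pc_i = nr, nc
        if fill_r is None or fill_r.size == 0:
            continue
        full_mask = np.zeros(arr.shape, dtype=bool)
        full_mask[fill_r, fill_c] = True
        area = int(full_mask.sum())
        if area < config.min_area_px or area > config.max_area_px:
            continue
        r0, r1 = fill_r.min(), fill_r.max()
        c0, c1 = fill_c.min(), fill_c.max()
        # bounding square padded by 2 px, clipped to the tile
        side = max(r1 - r0, c1 - c0) + 1 + 4
        cr0 = max(0, (r0 + r1) // 2 - side // 2)
        cc0 = max(0, (c0 + c1) // 2 - side // 2)
        cr1 = min(h, cr0 + side)
        cc1 = min(w, cc0 + side)
        cr0 = max(0, cr1 - side)
        cc0 = max(0, cc1 - side)
        crop = arr[cr0:cr1, cc0:cc1].copy()
        mask = full_mask[cr0:cr1, cc0:cc1].copy()
        # report the footprint centroid: better localized than the match
        # peak when the object and template sizes disagree
        com_r = float(fill_r.mean())
        com_c = float(fill_c.mean())
        candidates.append(
            Candidate(
                center=(com_r, com_c),
                radius_px=math.sqrt(area / math.pi),
                crop=crop,
                mask=mask,
                peak_score=float(score),
                crop_origin=(int(cr0), int(cc0)),
                source=source,
            )
        )
    return candidates


def detect_candidates(image, config: PrefilterConfig | None = None) -> list[Candidate]:
    """Run the full five-stage chain on one brightfield tile.

    Deterministic for fixed input and config.
    """
    if config is None:
        config = PrefilterConfig()
    arr = _as_array(image)
    name = image.name if isinstance(image, Image) else ""
    sd = local_std_filter(arr, config.std_window_px)
    corr = match_filter(sd, config)
    thr = negative_threshold(corr, config.threshold)
    peaks = find_local_maxima(thr, config.min_peak_distance_px)
    return radial_segment(arr, peaks, config, source=name)


def stage_outputs(image, config: PrefilterConfig | None = None) -> dict[str, np.ndarray]:
    """All intermediate grids, for inspection / --save-stages."""
    if config is None:
        config = PrefilterConfig()
    arr = _as_array(image)
    sd = local_std_filter(arr, config.std_window_px)
    corr = match_filter(sd, config)
    thr = negative_threshold(corr, config.threshold)
    return {"local_std": sd, "match_filter": corr, "thresholded": thr}
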