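"""Fluorescence validation: per-cell SD/median statistic and gating.

CAR expression shows up as clustered punctate fluorescence inside a
cell's footprint. The per-cell statistic is the population standard
deviation of the fluorescence intensities in the cell's ROI divided by
their median — the division normalizes away lamp/gain differences
between experiments, so the statistic is invariant under multiplicative
gain. Across many cells the statistic is bimodal: a low mode of
non-expressing cells and a high mode of expressing cells. A
two-component Gaussian mixture is fitted by EM and the intersection
point of the two weighted component densities, between the two means,
is the positivity threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imageio import Image, RoiSet

__all__ = [
    "FluorRecord",
    "MixtureFit",
    "fluor_statistic",
    "pair_rois",
    "fit_two_gaussians",
    "positivity_fraction",
]


@dataclass
class FluorRecord:
    cell_id: str
    bf_center: tuple[float, float]  # (row, col)
    raw_sd: float
    raw_median: float
    stat: float


def fluor_statistic(pixels) -> tuple[float, float, float]:
    """(population SD, median, SD/median) over a cell ROI's pixels."""
    vals = np.asarray(pixels, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 pixels")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("zero/negative median: background-dominated ROI")
    sd = float(vals.std())  # population SD
    return sd, med, sd / med


def pair_rois(bf_detections: RoiSet, fluor_image: Image) -> list[FluorRecord]:
    """Compute the statistic over each brightfield ROI disc on the paired
    fluorescence image (shared stage coordinates).

    Out-of-bounds ROIs are skipped with a warning, never silently.
    """
    arr = np.asarray(fluor_image.pixels, dtype=float)
    h, w = arr.shape
    records: list[FluorRecord] = []
    for i, roi in enumerate(bf_detections.rois):
        r, c, rad = roi.y_px, roi.x_px, roi.radius_px
        if not (0 <= r - rad and r + rad < h and 0 <= c - rad and c + rad < w):
            warnings.warn(
                f"ROI {i} at ({c:.1f}, {r:.1f}) r={rad:.1f} exceeds fluorescence "
                f"image bounds {arr.shape}; skipped",
                stacklevel=2,
            )
            continue
        r0, r1 = int(math.floor(r - rad)), int(math.ceil(r + rad)) + 1
        c0, c1 = int(math.floor(c - rad)), int(math.ceil(c + rad)) + 1
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disc = (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
        sd, med, stat = fluor_statistic(arr[r0:r1, c0:c1][disc])
        records.append(
            FluorRecord(
                cell_id=roi.label or f"cell_{i}",
                bf_center=(float(r), float(c)),
                raw_sd=sd,
                raw_median=med,
                stat=stat,
            )
        )
    return records


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture on the per-cell statistic."""

    weights: tuple[float, float]
    means: tuple[float, float]  # ascending
    sds: tuple[float, float]
    threshold: float
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def _intersection(w1, m1, s1, w2, m2, s2) -> float:
    """Root of w1 N(x|m1,s1) = w2 N(x|m2,s2) strictly between the means.

    Equating log densities gives a quadratic in x (linear when the SDs
    coincide).
    """
    if not m1 < m2:
        raise ValueError("means must be distinct and ordered")
    # A x^2 + B x + C = 0 from log(w1) - log(s1) - (x-m1)^2/(2 s1^2) = ...
    A = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    B = m1 / s1**2 - m2 / s2**2
    C = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + math.log(w1 / w2) + math.log(s2 / s1))
    if abs(A) < 1e-300:
        if B == 0:
            raise ValueError("identical components: intersection undefined")
        roots = [-C / B]
    else:
        disc = B**2 - 4 * A * C
        if disc < 0:
            raise ValueError("weighted densities do not intersect between the means")
        sq = math.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    between = [r for r in roots if m1 < r < m2]
    if not between:
        raise ValueError("no density intersection strictly between the component means")
    return float(between[0])


def _kmeans_init(x, rng, min_sd):
    """1-D 2-means (Lloyd's from quantile seeds) -> (w, mu, sd)."""
    centers = np.percentile(x, [25, 75]).astype(float)
    if centers[0] == centers[1]:
        centers = centers + np.array([-1e-6, 1e-6])
    for _ in range(50):
        assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == k].mean() if np.any(assign == k) else centers[k] + rng.normal(0, 1e-6)
            for k in range(2)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
    w = np.array([max((assign == k).mean(), 1e-3) for k in range(2)])
    w /= w.sum()
    sd = np.array([
        max(x[assign == k].std(), min_sd) if np.any(assign == k) else x.std() + min_sd
        for k in range(2)
    ])
    return w, centers.copy(), sd


def _run_em(x, w, mu, sd, max_iter, tol, min_sd):
    """EM to convergence from one start; returns (w, mu, sd, trace)."""
    w, mu, sd = w.copy(), mu.copy(), sd.copy()
    trace: list[float] = []
    prev = -np.inf
    for it in range(max_iter):
        dens = np.stack([w[k] * _gauss(x, mu[k], sd[k]) for k in range(2)])  # (2, n)
        total = np.maximum(dens.sum(axis=0), np.finfo(float).tiny)
        ll = float(np.log(total).sum())
        trace.append(ll)
        resp = dens / total  # responsibilities
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            raise ValueError(
                "EM degeneracy: a component lost all responsibility; "
                "raise min_sd or inspect the data"
            )
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.sqrt(var)
        if np.any(sd < min_sd):
            raise ValueError(
                f"EM degeneracy: component SD fell below the floor {min_sd}; "
                "raise min_sd or add jitter to the data"
            )
        w = nk / x.size
        if ll - prev < tol and it > 0:
            break
        prev = ll
    return w, mu, sd, trace


def fit_two_gaussians(
    stats: Sequence[float],
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
    min_sd: float = 1e-4,
    n_restarts: int = 3,
) -> MixtureFit:
    """Fit a 2-component Gaussian mixture by EM, k-means initialized.

    EM is a local optimizer, and when one population is much narrower
    than the other the variance-minimizing 2-means split can seed it
    inside the broad mode; a few additional quantile/random restarts are
    therefore run and the highest-likelihood solution kept. Deterministic
    for a given seed. If either component SD collapses to the configured
    floor the fit aborts with an error advising a larger ``min_sd``; the
    log-likelihood is non-decreasing over iterations and components are
    reported with means ascending.
    """
    x = np.asarray(stats, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 values to fit a mixture")
    rng = np.random.default_rng(seed)
    global_sd = max(float(x.std()), min_sd)

    starts = [_kmeans_init(x, rng, min_sd)]
    for q_lo, q_hi in ((5.0, 95.0), (10.0, 50.0)):
        lo, hi = np.percentile(x, [q_lo, q_hi])
        if lo < hi:
            starts.append(
                (np.array([0.5, 0.5]), np.array([lo, hi]),
                 np.array([global_sd / 4, global_sd / 4]))
            )
    for _ in range(n_restarts):
        mu0 = np.sort(rng.choice(x, size=2, replace=False))
        starts.append(
            (np.array([0.5, 0.5]), mu0.astype(float),
             np.array([global_sd / 4, global_sd / 4]))
        )

    best = None
    failure: Exception | None = None
    for w0, mu0, sd0 in starts:
        try:
            w, mu, sd, trace = _run_em(x, w0, mu0, sd0, max_iter, tol, min_sd)
        except ValueError as exc:
            failure = exc
            continue
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, sd, trace)
    if best is None:
        raise failure if failure is not None else ValueError("EM failed from all starts")
    w, mu, sd, trace = best

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    if not mu[0] < mu[1]:
        raise ValueError("identical component means: threshold undefined")
    threshold = _intersection(w[0], mu[0], sd[0], w[1], mu[1], sd[1])
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        threshold=threshold,
        loglik=trace[-1],
        loglik_trace=trace,
        n_iter=len(trace),
    )


def positivity_fraction(stats: Sequence[float], threshold: float) -> float:
    """Fraction of cells whose statistic lies strictly above the threshold.

    The complement is the low-expresser fraction.
    """
    x = np.asarray(stats, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("stats must be nonempty")
    return float((x > threshold).mean())
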