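"""Sample counting, calibration fits and detection/quantification limits.

Counts of classifier-identified CAR T-cells across the 30-tile channel
scan are related to spiked concentration by one of two monotone forms:

* buffer: power law ``y = a * x**b`` fitted by least squares on the
  log-log scale;
* whole blood: ``y = a * ln(x) + b`` fitted by ordinary least squares of
  counts on ln(concentration) — whole-blood blanks carry a high
  background (>100 counts) that enters through the blank statistics,
  not by subtraction from the curve.

The 95%-certainty limits use the blank-based decision thresholds
``y_D = blank_mean + 2*1.645*blank_sd`` (detection, alpha = beta = 0.05)
and ``y_Q = blank_mean + 10*blank_sd`` (quantification), inverted
through the fitted curve in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .imageio import Image
from .objects import TrainedModel, classify, extract_features
from .prefilter import PrefilterConfig, detect_candidates, local_std_filter

__all__ = [
    "Z_95",
    "CountResult",
    "CalibrationFit",
    "RatioStat",
    "count_sample",
    "fit_power",
    "fit_log",
    "lod_loq",
    "ratio_stat",
]

#: One-sided 95% normal quantile used by the detection threshold.
Z_95 = 1.645


@dataclass
class CountResult:
    sample_id: str
    tiles: int
    per_class_counts: dict[str, int]
    cart_count: int
    per_tile_counts: list[dict[str, int]] = field(default_factory=list)
    spiked_concentration: Optional[float] = None


def count_sample(
    tiles: Sequence[Image],
    model: TrainedModel,
    config: PrefilterConfig | None = None,
    sample_id: str = "",
) -> CountResult:
    """Detect, classify and sum CART objects over a tile set.

    Tiles are treated as disjoint fields of view; no cross-tile
    deduplication is applied.
    """
    if not tiles:
        raise ValueError("need at least one tile")
    if config is None:
        config = PrefilterConfig()
    totals: dict[str, int] = {c: 0 for c in model.classes}
    per_tile: list[dict[str, int]] = []
    for tile in tiles:
        candidates = detect_candidates(tile, config)
        sd = local_std_filter(tile.pixels, config.std_window_px)
        for cand in candidates:
            r0, c0 = cand.crop_origin
            h, w = cand.crop.shape
            cand.features = extract_features(cand, sd[r0 : r0 + h, c0 : c0 + w])
        _, counts = classify(model, candidates)
        per_tile.append(counts)
        for cls, n in counts.items():
            totals[cls] += n
    return CountResult(
        sample_id=sample_id,
        tiles=len(tiles),
        per_class_counts=totals,
        cart_count=totals.get("CART", 0),
        per_tile_counts=per_tile,
    )


@dataclass
class CalibrationFit:
    """A fitted concentration-count relation with blank statistics.

    ``form`` is ``"power"`` (y = a x^b) or ``"log"`` (y = a ln x + b);
    ``r_squared`` and ``residual_sd`` are computed on the fitting scale
    (log-log for power, semilog for log).
    """

    form: str
    a: float
    b: float
    r_squared: float
    residual_sd: float
    blank_mean: float = 0.0
    blank_sd: float = 0.0
    lod: Optional[float] = None
    loq: Optional[float] = None
    confidence: float = 0.95

    def predict(self, concentration) -> np.ndarray:
        x = np.asarray(concentration, dtype=float)
        if np.any(x <= 0):
            raise ValueError("concentration must be positive")
        if self.form == "power":
            return self.a * x**self.b
        return self.a * np.log(x) + self.b

    def invert(self, count: float) -> float:
        """Concentration at which the fitted curve equals ``count``."""
        if self.form == "power":
            if count <= 0:
                raise ValueError("power form is positive; count threshold <= 0 has no solution")
            return (count / self.a) ** (1.0 / self.b)
        if self.a == 0:
            raise ValueError("flat logarithmic fit cannot be inverted")
        return math.exp((count - self.b) / self.a)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "a": self.a,
            "b": self.b,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "fit_scale": "log-log" if self.form == "power" else "semilog-x",
            "blank_mean": self.blank_mean,
            "blank_sd": self.blank_sd,
            "lod": self.lod,
            "loq": self.loq,
            "confidence": self.confidence,
        }


def _validate_xy(concentrations, counts, positive_counts: bool) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and counts must be equal-length 1-D")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive (handle blanks separately)")
    if positive_counts and np.any(y <= 0):
        raise ValueError("counts must be positive for the power form")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    return x, y


def _linfit(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float]:
    """Least squares v = slope*u + intercept; returns slope, intercept, R^2, residual SD."""
    res = stats.linregress(u, v)
    pred = res.slope * u + res.intercept
    ss_res = float(((v - pred) ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = max(len(u) - 2, 1)
    return float(res.slope), float(res.intercept), r2, math.sqrt(ss_res / dof)


def fit_power(concentrations, counts) -> CalibrationFit:
    """Fit y = a x^b by linear regression of ln y on ln x."""
    x, y = _validate_xy(concentrations, counts, positive_counts=True)
    slope, intercept, r2, resid_sd = _linfit(np.log(x), np.log(y))
    return CalibrationFit(
        form="power", a=math.exp(intercept), b=slope, r_squared=r2, residual_sd=resid_sd
    )


def fit_log(concentrations, counts) -> CalibrationFit:
    """Fit y = a ln(x) + b by OLS of counts on ln(concentration)."""
    x, y = _validate_xy(concentrations, counts, positive_counts=False)
    slope, intercept, r2, resid_sd = _linfit(np.log(x), y)
    return CalibrationFit(
        form="log", a=slope, b=intercept, r_squared=r2, residual_sd=resid_sd
    )


def lod_loq(
    fit: CalibrationFit, blank_mean: float, blank_sd: float
) -> tuple[float, float]:
    """95%-certainty detection and quantification limits (cells/µL).

    If the blank SD is zero the residual SD of the fit substitutes; if
    both vanish, LOD = LOQ = the concentration where the curve equals
    the blank mean.
    """
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    sd = blank_sd if blank_sd > 0 else fit.residual_sd
    y_d = blank_mean + 2.0 * Z_95 * sd
    y_q = blank_mean + 10.0 * sd
    lod = fit.invert(y_d)
    loq = fit.invert(y_q)
    fit.blank_mean = blank_mean
    fit.blank_sd = blank_sd
    fit.lod = lod
    fit.loq = loq
    return lod, loq


@dataclass
class RatioStat:
    """Mean and spread of paired after/before count ratios.

    Covers both reported ratios: filtration efficiency
    (WBC_after / WBC_before) and attachment retention (cells bound
    after / before flushing).
    """

    ratios: list[float]
    ratio: float
    sd: float
    se: float
    numerator_count: float
    denominator_count: float


def ratio_stat(before: Sequence[float], after: Sequence[float]) -> RatioStat:
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1 or before.size == 0:
        raise ValueError("before/after must be paired non-empty lists")
    if np.any(before <= 0):
        raise ValueError("before-counts must be positive")
    ratios = after / before
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return RatioStat(
        ratios=[float(r) for r in ratios],
        ratio=float(ratios.mean()),
        sd=sd,
        se=sd / math.sqrt(ratios.size) if ratios.size > 1 else 0.0,
        numerator_count=float(after.sum()),
        denominator_count=float(before.sum()),
    )
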