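"""Cuticle brightness from RGB regions of interest, and its age calibration.

Cuticle brightness b_RGB = (R + G + B) / (3 · 255) — the unweighted
greyscale mean of the channel means over a region of interest on the
mandible blade — is the study's proxy for worker age post eclosion: cuticle
darkens as it sclerotizes.  Known-age reference groups anchor a monotone
brightness → age map; outside the observed brightness range the map only
returns censored bounds ("younger than the youngest group" / "older than the
oldest"), because sclerotization saturates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps

__all__ = [
    "ROISample",
    "AgeGroup",
    "AgeCalibration",
    "compute_brightness",
    "extract_roi",
    "stripe_gains",
    "apply_gains",
    "calibrate_age",
]


@dataclass(frozen=True)
class ROISample:
    """Per-channel means over a region of interest (0–255 scale)."""

    mean_R: float
    mean_G: float
    mean_B: float
    roi_shape: str = "circle"
    n_pixels: int = 1

    def __post_init__(self):
        for ch in (self.mean_R, self.mean_G, self.mean_B):
            if not (0 <= ch <= 255):
                raise ValueError(f"channel mean {ch} outside [0, 255]")
        if self.n_pixels < 1:
            raise ValueError("ROI must contain at least one pixel")


@dataclass(frozen=True)
class AgeGroup:
    """Brightness values of ants with known age post eclosion."""

    age_days: float
    brightness_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "brightness_values",
                           np.atleast_1d(np.asarray(self.brightness_values, dtype=float)))
        if self.age_days <= 0:
            raise ValueError("age must be positive")
        if self.brightness_values.size < 1:
            raise ValueError("each age group needs at least one brightness value")


def compute_brightness(roi: ROISample) -> float:
    """b_RGB = (R + G + B) / (3 · 255), dimensionless in [0, 1]."""
    return (roi.mean_R + roi.mean_G + roi.mean_B) / (3.0 * 255.0)


def _circle_mask(shape, center, radius):
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def extract_roi(image: np.ndarray, shape: str, **geometry) -> ROISample:
    """Channel means over an ROI mask of an RGB image.

    ``shape="rectangle"`` takes ``corner=(row, col), size=(height, width)``;
    ``shape="circle"`` takes ``center=(row, col)`` and ``radius`` or
    ``diameter`` (pixels included when centre distance ≤ radius).  The ROI
    must lie fully inside the image.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("image must be an RGB array (H, W, 3)")
    h, w = img.shape[:2]
    if shape == "rectangle":
        r0, c0 = geometry["corner"]
        hh, ww = geometry["size"]
        if r0 < 0 or c0 < 0 or r0 + hh > h or c0 + ww > w or hh < 1 or ww < 1:
            raise ValueError("rectangle ROI outside image bounds")
        mask = np.zeros((h, w), dtype=bool)
        mask[r0 : r0 + hh, c0 : c0 + ww] = True
    elif shape == "circle":
        center = geometry["center"]
        radius = geometry.get("radius", geometry.get("diameter", 0) / 2.0)
        if radius <= 0:
            raise ValueError("circle ROI needs a positive radius or diameter")
        if (center[0] - radius < -0.5 or center[1] - radius < -0.5
                or center[0] + radius > h - 0.5 or center[1] + radius > w - 0.5):
            raise ValueError("circle ROI outside image bounds")
        mask = _circle_mask((h, w), center, radius)
    else:
        raise ValueError(f"unknown ROI shape {shape!r}")
    n = int(mask.sum())
    means = [float(img[..., ch][mask].mean()) for ch in range(3)]
    return ROISample(*means, roi_shape=shape, n_pixels=n)


def stripe_gains(stripe_samples: dict, reference_rgb: dict) -> np.ndarray:
    """Per-channel linear gains mapping measured colour-stripe ROIs onto
    reference RGB values (optional normalization across photographs; the
    printed stripe is a baseline, so correction is off unless requested)."""
    gains = np.ones(3)
    chan = {"stripe_red": 0, "stripe_green": 1, "stripe_blue": 2}
    for role, idx in chan.items():
        if role in stripe_samples and role in reference_rgb:
            measured = (stripe_samples[role].mean_R,
                        stripe_samples[role].mean_G,
                        stripe_samples[role].mean_B)[idx]
            if measured <= 0:
                raise ValueError(f"{role} channel mean is zero; cannot form a gain")
            gains[idx] = reference_rgb[role] / measured
    return gains


def apply_gains(roi: ROISample, gains) -> ROISample:
    g = np.asarray(gains, dtype=float)
    vals = np.clip(np.array([roi.mean_R, roi.mean_G, roi.mean_B]) * g, 0, 255)
    return ROISample(*vals, roi_shape=roi.roi_shape, n_pixels=roi.n_pixels)


@dataclass
class AgeCalibration:
    """Monotone brightness → age map anchored at known-age group means."""

    ages_d: np.ndarray          # ascending
    mean_brightness: np.ndarray  # descending with age
    sd_brightness: np.ndarray
    F_statistic: float
    F_df: tuple
    p_value: float
    degenerate: bool = False
    _knots: np.ndarray | None = None  # strictly decreasing interpolation anchors

    def estimate_age(self, brightness: float):
        """Piecewise-linear interpolation of age against log(brightness).

        Returns ``(age_days, flag)`` with flag ``"ok"`` inside the calibrated
        brightness range, else ``"younger_than_min_age"`` or
        ``"older_than_max_age"`` (censored; age is clamped to the boundary).
        """
        if self.degenerate:
            raise ValueError("degenerate calibration: brightness → age map undefined")
        knots = self.mean_brightness if self._knots is None else self._knots
        b = float(brightness)
        b_young, b_old = knots[0], knots[-1]
        eps = 1e-9
        if b > b_young + eps:
            return float(self.ages_d[0]), "younger_than_min_age"
        if b < b_old - eps:
            return float(self.ages_d[-1]), "older_than_max_age"
        b = min(max(b, b_old), b_young)
        # log-brightness ascending for np.interp
        age = np.interp(np.log(b), np.log(knots[::-1]), self.ages_d[::-1])
        return float(age), "ok"


def calibrate_age(groups) -> AgeCalibration:
    """Fit the brightness–age calibration from known-age groups.

    ``groups`` is a sequence of :class:`AgeGroup` or ``(age, values)`` pairs
    with at least two distinct ages.  The F statistic treats age as a single
    continuous regressor (regression F with 1 and n − 2 degrees of freedom)
    for the per-ant brightness values.
    """
    parsed = []
    for g in groups:
        if not isinstance(g, AgeGroup):
            g = AgeGroup(age_days=g[0], brightness_values=np.asarray(g[1]))
        parsed.append(g)
    parsed.sort(key=lambda g: g.age_days)
    ages = np.array([g.age_days for g in parsed])
    if np.unique(ages).size < 2:
        raise ValueError("need at least two groups with distinct ages")
    means = np.array([g.brightness_values.mean() for g in parsed])
    sds = np.array([g.brightness_values.std(ddof=1) if g.brightness_values.size > 1 else 0.0
                    for g in parsed])

    x = np.concatenate([np.full(g.brightness_values.size, g.age_days) for g in parsed])
    y = np.concatenate([g.brightness_values for g in parsed])
    n = y.size
    degenerate = bool(np.ptp(y) == 0)
    if degenerate:
        warnings.warn("all brightness values identical: degenerate fit, map undefined")
        F, p = 0.0, 1.0
    else:
        slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
        intercept = y.mean() - slope * x.mean()
        pred = intercept + slope * x
        ssr = float(np.sum((pred - y.mean()) ** 2))
        sse = float(np.sum((y - pred) ** 2))
        if sse == 0:
            F, p = np.inf, 0.0
        else:
            F = ssr / (sse / (n - 2))
            p = float(sps.f.sf(F, 1, n - 2))
    knots = None
    if not degenerate and np.any(np.diff(means) >= 0):
        warnings.warn("group-mean brightness is not strictly decreasing with age; "
                      "the interpolated map uses an isotonic adjustment")
        knots = np.minimum.accumulate(means) - 1e-9 * np.arange(means.size)
    return AgeCalibration(
        ages_d=ages, mean_brightness=means, sd_brightness=sds,
        F_statistic=float(F), F_df=(1, n - 2), p_value=float(p),
        degenerate=degenerate, _knots=knots,
    )
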