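"""Backscatter-SEM density quantification and gray-to-density calibration.

Density of a skeletal region is obtained from backscatter gray levels by
linear interpolation between a zero-density background and an enamel
reference slab of known density (2.8 g/cm^3):

    rho = (T_or_R - B) / (E - B) * rho_enamel

where T/R, B and E are the gray-value *modes* of the TD-or-RAD, background
and enamel regions.  SEM-derived densities are then paired with gray modes
from X-ray absorption volumes to fit an ordinary-least-squares line that
maps absorption gray values to density everywhere in the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantom import ENAMEL_DENSITY

__all__ = [
    "ROISample",
    "CalibrationModel",
    "roi_mode",
    "eq1_density",
    "fit_gray_to_density",
    "apply_calibration",
]


@dataclass(frozen=True)
class ROISample:
    """Gray-value mode of one region of interest."""

    region_label: str  # TD, RAD, enamel or background
    gray_mode: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Affine gray -> density map with OLS diagnostics."""

    slope: float  # g/cm^3 per gray unit
    intercept: float  # g/cm^3
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def predict(self, gray):
        return self.slope * np.asarray(gray, dtype=float) + self.intercept


def roi_mode(image, mask, bin_width: float = 1.0) -> float:
    """Gray-value mode of a masked region.

    Histograms the masked pixels with bins of ``bin_width`` anchored so the
    minimum value sits at a bin centre, and returns the centre of the most
    populated bin; ties break toward the lower bin.  Works for 2D images and
    3D volumes alike.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(image, dtype=float)[mask]
    lo = values.min()
    n_bins = int(np.floor((values.max() - lo) / bin_width)) + 1
    edges = lo - bin_width / 2.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return float(lo + bin_width * int(np.argmax(counts)))  # argmax -> lowest tie


def eq1_density(
    gray_target: float,
    gray_background: float,
    gray_enamel: float,
    enamel_density: float = ENAMEL_DENSITY,
) -> float:
    """Region density from backscatter gray modes.

    rho = (target - background) / (enamel - background) * enamel_density.
    Affine in the target gray value: background maps to 0 and the enamel
    level maps to the enamel density exactly.
    """
    if gray_enamel == gray_background:
        raise ValueError("degenerate calibration: enamel and background gray equal")
    return (
        (gray_target - gray_background)
        / (gray_enamel - gray_background)
        * enamel_density
    )


def fit_gray_to_density(pairs) -> CalibrationModel:
    """OLS line through (gray_mode, density) pairs.

    ``pairs`` is an iterable of 2-tuples; TD and RAD samples are normally
    pooled into one line per growth condition, but nothing prevents fitting
    per-phase lines from separate pair lists.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    gray = np.array([p[0] for p in pairs], dtype=float)
    dens = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(gray) == 0.0:
        raise ValueError("all gray values identical: calibration line undefined")
    res = stats.linregress(gray, dens)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pairs),
    )


def apply_calibration(gray_volume, model: CalibrationModel) -> np.ndarray:
    """Voxelwise affine gray -> density map; preserves shape."""
    return model.predict(np.asarray(gray_volume, dtype=float))
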