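"""3D morphometry of labelled skeletal volumes.

Per-septum, height-normalized profiles (cross-sectional area, best-fitting
ellipse width/length, density, second moment of area), phase volumes, RAD
onset height, and the AUC-based group comparison used to contrast growth
conditions.  Heights are expressed as percent of the coral height, defined
as the z-extent of all mineral voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "LabelVolume",
    "SliceMetrics",
    "SeptumProfile",
    "InertiaProfile",
    "TestResult",
    "segment_phases",
    "slice_metrics",
    "septum_profile",
    "rad_onset_height",
    "phase_volume",
    "principal_moments_of_area",
    "max_moment_of_inertia",
    "inertia_profile",
    "auc",
    "compare_auc",
    "profile_to_dataframe",
]

BACKGROUND, TD, RAD = 0, 1, 2


@dataclass(frozen=True)
class LabelVolume:
    """Label volume with codes {0 background, 1 TD, 2 RAD}."""

    labels: np.ndarray
    voxel_size: float  # um

    def __post_init__(self) -> None:
        codes = np.unique(self.labels)
        if not set(codes.tolist()) <= {BACKGROUND, TD, RAD}:
            raise ValueError(f"unexpected label codes: {codes}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


@dataclass(frozen=True)
class SliceMetrics:
    """Cross-sectional measurements of one phase in one tomographic slice.

    Width and length are the full minor/major axes of the ellipse whose
    second central moments equal those of the binary cross-section.
    """

    z_index: int
    area: float  # um^2
    width: float  # um, minor full axis
    length: float  # um, major full axis
    centroid: tuple[float, float]  # (x, y) um


@dataclass
class SeptumProfile:
    """Height-binned metric curves per septum with mean +/- SEM across septa."""

    height_pct: np.ndarray  # bin centres, % of coral height
    per_septum: np.ndarray  # (n_septa, n_bins)
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.height_pct) > 0):
            raise ValueError("heights must be strictly increasing")
        self.mean = np.nanmean(self.per_septum, axis=0)
        n = np.sum(~np.isnan(self.per_septum), axis=0)
        sd = np.nanstd(self.per_septum, axis=0, ddof=1)
        self.sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)


@dataclass(frozen=True)
class InertiaProfile:
    """Maximum second moment of area vs percent coral height."""

    height_pct: np.ndarray
    i_max: np.ndarray  # um^4


@dataclass(frozen=True)
class TestResult:
    """Outcome of the gated two-group AUC comparison."""

    test_name: str  # "t-test" or "Mann-Whitney"
    statistic: float
    p_value: float
    normality_pass: bool
    variance_pass: bool
    auc_a: tuple
    auc_b: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def segment_phases(
    density_volume,
    thresholds: tuple[float, float],
    voxel_size: float,
) -> LabelVolume:
    """Threshold a density volume into background / TD / RAD.

    ``thresholds = (background_td, td_rad)`` must be ordered ascending:
    densities above the first are mineral, above the second are RAD
    candidates.  RAD connected components (26-connectivity) are retained
    only when adjacent to TD material — isolated bright speckles are
    reassigned to TD.  In this phantom's density ordering RADs are *less*
    dense than TDs; pass thresholds accordingly (the second threshold
    separates the brighter phase, whichever it is labelled).
    """
    t_bg, t_phase = thresholds
    if not t_bg < t_phase:
        raise ValueError("thresholds must be strictly increasing")
    rho = np.asarray(density_volume, dtype=float)
    labels = np.zeros(rho.shape, dtype=np.uint8)
    mineral = rho > t_bg
    labels[mineral] = TD
    labels[mineral & (rho <= t_phase)] = RAD

    if np.any(labels == RAD):
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        comp, n_comp = ndimage.label(labels == RAD, structure=structure)
        td_neighbourhood = ndimage.binary_dilation(labels == TD, structure=structure)
        embedded = np.unique(comp[(comp > 0) & td_neighbourhood])
        drop = np.setdiff1d(np.arange(1, n_comp + 1), embedded)
        if drop.size:
            labels[np.isin(comp, drop)] = TD
    return LabelVolume(labels=labels, voxel_size=voxel_size)


def _ellipse_axes(coords: np.ndarray) -> tuple[float, float]:
    """Full (minor, major) axes in pixels of the equal-moments ellipse."""
    if coords.shape[0] < 2:
        return (0.0, 0.0) if coords.shape[0] == 0 else (1.0, 1.0)
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / coords.shape[0]
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    minor, major = 4.0 * np.sqrt(eig[0]), 4.0 * np.sqrt(eig[1])
    return float(minor), float(major)


def slice_metrics(
    volume: LabelVolume, phase: int, z: int, mask: np.ndarray | None = None
) -> SliceMetrics:
    """Area, ellipse axes and centroid of one phase in slice ``z``.

    ``mask`` restricts the slice (e.g. to one septum).  An empty slice
    yields zero area and axes.
    """
    if not 0 <= z < volume.labels.shape[2]:
        raise IndexError(f"slice {z} outside volume")
    vs = volume.voxel_size
    sl = volume.labels[:, :, z] == phase
    if mask is not None:
        sl = sl & mask
    coords = np.argwhere(sl).astype(float)
    if coords.shape[0] == 0:
        return SliceMetrics(z_index=z, area=0.0, width=0.0, length=0.0, centroid=(0.0, 0.0))
    minor, major = _ellipse_axes(coords)
    cx, cy = coords.mean(axis=0)
    return SliceMetrics(
        z_index=z,
        area=float(coords.shape[0]) * vs**2,
        width=minor * vs,
        length=major * vs,
        centroid=(cx * vs, cy * vs),
    )


def _coral_z_extent(labels: np.ndarray) -> tuple[int, int]:
    zs = np.flatnonzero((labels > 0).any(axis=(0, 1)))
    if zs.size == 0:
        raise ValueError("zero-height object: no mineral voxels")
    return int(zs[0]), int(zs[-1])


def septum_profile(
    volume: LabelVolume,
    phase: int,
    septum_labels: np.ndarray,
    n_bins: int = 100,
    metric: str = "area",
    value_volume: np.ndarray | None = None,
) -> SeptumProfile:
    """Height-normalized per-septum metric profile with mean +/- SEM.

    ``septum_labels`` assigns septum ids 1..n to voxels (phantom truth, or
    tracked connected components).  ``metric`` is one of ``area`` (um^2),
    ``width``/``length`` (um), ``imax`` (um^4), or ``density`` (mean of
    ``value_volume`` over the phase voxels).  Metrics are computed per slice
    and averaged within each height bin.
    """
    if metric == "density" and value_volume is None:
        raise ValueError("metric 'density' requires value_volume")
    z0, z1 = _coral_z_extent(volume.labels)
    height = z1 - z0 + 1
    n_septa = int(septum_labels.max())
    if n_septa == 0:
        raise ValueError("no septa in septum_labels")
    vs = volume.voxel_size

    sums = np.zeros((n_septa, n_bins))
    counts = np.zeros((n_septa, n_bins))
    for iz in range(z0, z1 + 1):
        h = (iz - z0 + 0.5) / height
        b = min(int(h * n_bins), n_bins - 1)
        phase_sl = volume.labels[:, :, iz] == phase
        sep_sl = septum_labels[:, :, iz]
        for s in range(1, n_septa + 1):
            sel = phase_sl & (sep_sl == s)
            if metric == "area":
                val = sel.sum() * vs**2
            elif metric in ("width", "length"):
                minor, major = _ellipse_axes(np.argwhere(sel).astype(float))
                val = (minor if metric == "width" else major) * vs
            elif metric == "imax":
                val = max_moment_of_inertia(sel, vs)
            elif metric == "density":
                val = float(value_volume[:, :, iz][sel].mean()) if sel.any() else 0.0
            else:
                raise ValueError(f"unknown metric '{metric}'")
            sums[s - 1, b] += val
            counts[s - 1, b] += 1

    with np.errstate(invalid="ignore"):
        per_septum = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) / n_bins * 100.0
    return SeptumProfile(height_pct=centers, per_septum=per_septum)


def rad_onset_height(
    profile: SeptumProfile, area_threshold: float = 0.0
) -> float | None:
    """First height (percent) where the mean RAD area exceeds the threshold.

    Returns ``None`` when the profile never exceeds the threshold (RADs
    absent).
    """
    above = np.flatnonzero(np.nan_to_num(profile.mean) > area_threshold)
    if above.size == 0:
        return None
    return float(profile.height_pct[above[0]])


def phase_volume(volume: LabelVolume, phase: int) -> float:
    """Total phase volume in um^3 (voxel count x voxel volume)."""
    return float(np.count_nonzero(volume.labels == phase)) * volume.voxel_size**3


def principal_moments_of_area(mask_slice, voxel_size: float) -> tuple[float, float]:
    """(I_max, I_min) of a binary cross-section about its centroid, um^4.

    Discrete second moments of area with the per-pixel self-term
    (voxel_size^4 / 12) so small rasterized shapes match closed forms.
    """
    mask = np.asarray(mask_slice, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    n = coords.shape[0]
    if n == 0:
        return 0.0, 0.0
    c = coords - coords.mean(axis=0)
    ixx = np.sum(c[:, 1] ** 2) + n / 12.0  # about the x-axis: integrate y^2
    iyy = np.sum(c[:, 0] ** 2) + n / 12.0
    ixy = -np.sum(c[:, 0] * c[:, 1])
    tensor = np.array([[ixx, ixy], [ixy, iyy]])
    eig = np.linalg.eigvalsh(tensor)
    scale = voxel_size**4
    return float(eig[1] * scale), float(max(eig[0], 0.0) * scale)


def max_moment_of_inertia(mask_slice, voxel_size: float) -> float:
    """Largest principal second moment of area of a cross-section, um^4."""
    return principal_moments_of_area(mask_slice, voxel_size)[0]


def inertia_profile(
    volume: LabelVolume, phase: int, n_bins: int = 100
) -> InertiaProfile:
    """Maximum second moment of area of a phase vs percent coral height.

    The cross-section in each slice pools all septa (material distribution
    about the common centroid is what resists bending); values are averaged
    within height bins.
    """
    z0, z1 = _coral_z_extent(volume.labels)
    height = z1 - z0 + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for iz in range(z0, z1 + 1):
        h = (iz - z0 + 0.5) / height
        b = min(int(h * n_bins), n_bins - 1)
        sums[b] += max_moment_of_inertia(
            volume.labels[:, :, iz] == phase, volume.voxel_size
        )
        counts[b] += 1
    vals = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = (np.arange(n_bins) + 0.5) / n_bins * 100.0
    return InertiaProfile(height_pct=centers, i_max=vals)


def auc(values, heights) -> float:
    """Trapezoidal area under a metric profile over normalized height."""
    values = np.asarray(values, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if values.size < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(values, heights))


def compare_auc(group_a, group_b, alpha: float = 0.05) -> TestResult:
    """Two-group comparison of per-septum AUC values with assumption gating.

    Shapiro-Wilk normality on each group and Levene homogeneity of variance
    gate the choice: unpaired t-test when both pass, Mann-Whitney otherwise.
    No multiple-testing correction is applied.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 AUC values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constant groups: no evidence of difference
        return TestResult(
            test_name="t-test",
            statistic=0.0,
            p_value=1.0,
            normality_pass=True,
            variance_pass=True,
            auc_a=tuple(a),
            auc_b=tuple(b),
        )
    normal = (
        stats.shapiro(a).pvalue > alpha and stats.shapiro(b).pvalue > alpha
        if (np.ptp(a) > 0 and np.ptp(b) > 0)
        else False
    )
    equal_var = stats.levene(a, b).pvalue > alpha
    if normal and equal_var:
        res = stats.ttest_ind(a, b)
        name = "t-test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney"
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_pass=bool(normal),
        variance_pass=bool(equal_var),
        auc_a=tuple(a),
        auc_b=tuple(b),
    )


def profile_to_dataframe(
    profile: SeptumProfile, condition: str, phase: str, metric: str
) -> pd.DataFrame:
    """Tidy long-format export: condition, phase, septum, height_pct, metric, value."""
    rows = []
    for s in range(profile.per_septum.shape[0]):
        for h, v in zip(profile.height_pct, profile.per_septum[s]):
            rows.append(
                {
                    "condition": condition,
                    "phase": phase,
                    "septum": s + 1,
                    "height_pct": h,
                    "metric": metric,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)
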