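"""Synthetic inputs with recorded ground truth.

Three generators emulate the measurement chain of an early-polyp
skeletogenesis study so that every downstream stage is testable without any
scan data:

* :func:`generate_polyp_phantom` — a labelled 3D grayscale volume of a
  six-septa primary-polyp skeleton.  Septa are radially arranged
  elongated-ellipse pillars attached to a cup wall; each carries a medial
  rapid-accretion-deposit (RAD) rod embedded in thickening-deposit (TD)
  material, starting at a configurable fraction of the coral height.
* :func:`generate_sem_field` — a backscatter-SEM-like 2D field with enamel
  reference, background, TD, and RAD patches whose gray levels follow the
  linear backscatter-vs-density model, so density recovery is exactly
  invertible in the noise-free limit.
* :func:`generate_xrd_profile` — an aragonite (200) reflection with planted
  crystallite-size (Lorentzian) and instrument (Gaussian) broadening.

Gray values are linear in density between the background and enamel anchor
levels, and noise is additive and independent per voxel — the simplest model
that supports mode-based region statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .diffraction import (
    DiffractionProfile,
    bragg_center,
    scherrer_fwhm_deg,
    voigt_curve,
    wavelength_angstrom,
)

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "SEMFieldSpec",
    "SEMField",
    "XRDPeakSpec",
    "generate_polyp_phantom",
    "generate_sem_field",
    "generate_xrd_profile",
    "density_to_gray",
]

Profile = Union[float, Callable[[float], float]]

ENAMEL_DENSITY = 2.8  # g/cm^3, bovine-enamel reference slab

LABEL_BACKGROUND = 0
LABEL_TD = 1
LABEL_RAD = 2


def density_to_gray(
    density: float | np.ndarray,
    gray_background: float,
    gray_enamel: float,
    enamel_density: float = ENAMEL_DENSITY,
):
    """Gray level of a material, linear in density between the anchors.

    gray = B + (rho / rho_enamel) * (E - B); the exact inverse of the
    backscatter density equation, so calibration round trips are exact
    without noise.
    """
    return gray_background + (np.asarray(density) / enamel_density) * (
        gray_enamel - gray_background
    )


def _eval_profile(p: Profile, h: float) -> float:
    return float(p(h)) if callable(p) else float(p)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, densities and imaging parameters of the synthetic polyp.

    Lengths in micrometres; densities in g/cm^3; ``rad_onset_fraction`` is
    the fraction of the coral height below which no RAD material exists.
    Width/length profiles may be constants or callables of normalized height.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 120)  # (nx, ny, nz)
    voxel_size: float = 2.2  # um
    n_septa: int = 6
    wall_radius: float = 80.0  # um, cup radius septa attach to
    septum_width_profile: Profile = 14.0  # um, tangential full width
    septum_length_profile: Profile = 52.0  # um, radial full length
    rad_onset_fraction: float = 0.05
    rad_radius: float = 4.5  # um, medial rod radius
    density_td: float = 2.18
    density_rad: float = 2.10
    noise_sd: float = 1.0  # gray-value units
    gray_background: float = 20.0
    gray_enamel: float = 188.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rad_onset_fraction <= 1.0:
            raise ValueError("rad_onset_fraction must lie in [0, 1]")
        if self.voxel_size <= 0 or self.wall_radius <= 0:
            raise ValueError("geometric lengths must be positive")
        if self.rad_radius < 0 or self.noise_sd < 0:
            raise ValueError("rad_radius and noise_sd must be >= 0")
        if self.n_septa < 1:
            raise ValueError("need at least one septum")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid too small")


@dataclass
class PhantomVolume:
    """Generated volume plus planted truth.

    ``labels`` uses 0 = background, 1 = TD, 2 = RAD.  ``septum_labels``
    assigns 1..n_septa to mineral voxels.  ``truth`` records the spec and
    per-slice planted areas (um^2): keys ``td_area_per_slice``,
    ``rad_area_per_slice`` (nz,), and ``septum_td_area``/``septum_rad_area``
    of shape (n_septa, nz).
    """

    gray: np.ndarray
    labels: np.ndarray
    septum_labels: np.ndarray
    voxel_size: float
    truth: dict


def generate_polyp_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate the labelled synthetic polyp volume.

    Deterministic for a fixed seed.  TD septa span the full height of the
    grid; RAD rods start at ``rad_onset_fraction`` of the coral height.
    Raises ``ValueError`` when the septum geometry does not fit in the grid.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    max_len = max(_eval_profile(spec.septum_length_profile, h) for h in (0.0, 0.5, 1.0))
    max_wid = max(_eval_profile(spec.septum_width_profile, h) for h in (0.0, 0.5, 1.0))
    if max_wid <= 0 or max_len <= 0:
        raise ValueError("septum width/length must be positive")
    if spec.wall_radius - max_len / 2.0 <= 0:
        raise ValueError("septum length exceeds the cup radius")
    reach = spec.wall_radius + max_wid / 2.0
    if reach > min(cx, cy) * vs:
        raise ValueError(
            f"geometry exceeds grid: septa reach {reach:.1f} um, "
            f"grid half-width {min(cx, cy) * vs:.1f} um"
        )
    if spec.rad_radius > 0 and 2.0 * spec.rad_radius >= max_wid:
        raise ValueError("RAD rod diameter must be smaller than the septum width")

    xs = (np.arange(nx) - cx) * vs
    ys = (np.arange(ny) - cy) * vs
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    septum_labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    angles = 2.0 * np.pi * np.arange(spec.n_septa) / spec.n_septa

    septum_td_area = np.zeros((spec.n_septa, nz))
    septum_rad_area = np.zeros((spec.n_septa, nz))

    for iz in range(nz):
        h = (iz + 0.5) / nz  # normalized height of the slice
        wid = _eval_profile(spec.septum_width_profile, h)
        length = _eval_profile(spec.septum_length_profile, h)
        a, b = length / 2.0, wid / 2.0  # radial, tangential semi-axes
        rad_here = spec.rad_radius > 0 and h >= spec.rad_onset_fraction
        for k, ang in enumerate(angles):
            ux, uy = np.cos(ang), np.sin(ang)
            ox, oy = (spec.wall_radius - a) * ux, (spec.wall_radius - a) * uy
            # radial / tangential coordinates about the septum centre
            Xr = (X - ox) * ux + (Y - oy) * uy
            Xt = -(X - ox) * uy + (Y - oy) * ux
            inside = (Xr / a) ** 2 + (Xt / b) ** 2 <= 1.0
            labels[inside, iz] = LABEL_TD
            septum_labels[inside, iz] = k + 1
            septum_td_area[k, iz] = inside.sum() * vs**2
            if rad_here:
                rad = Xr**2 + Xt**2 <= spec.rad_radius**2
                labels[rad, iz] = LABEL_RAD
                septum_rad_area[k, iz] = rad.sum() * vs**2
                septum_td_area[k, iz] -= septum_rad_area[k, iz]

    density = np.zeros((nx, ny, nz))
    density[labels == LABEL_TD] = spec.density_td
    density[labels == LABEL_RAD] = spec.density_rad
    gray = np.asarray(
        density_to_gray(density, spec.gray_background, spec.gray_enamel), dtype=float
    )
    gray[labels == LABEL_BACKGROUND] = spec.gray_background
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sd, gray.shape)

    truth = {
        "spec": spec,
        "td_area_per_slice": septum_td_area.sum(axis=0),
        "rad_area_per_slice": septum_rad_area.sum(axis=0),
        "septum_td_area": septum_td_area,
        "septum_rad_area": septum_rad_area,
    }
    return PhantomVolume(
        gray=gray,
        labels=labels,
        septum_labels=septum_labels,
        voxel_size=vs,
        truth=truth,
    )


@dataclass(frozen=True)
class SEMFieldSpec:
    """Synthetic backscatter-SEM field: patch densities and gray anchors."""

    density_td: float = 2.18
    density_rad: float = 2.10
    enamel_density: float = ENAMEL_DENSITY
    gray_background: float = 20.0
    gray_enamel: float = 188.0
    noise_sd: float = 0.0
    shape: tuple[int, int] = (160, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gray_enamel <= self.gray_background:
            raise ValueError("gray_enamel must exceed gray_background")
        if self.enamel_density <= 0:
            raise ValueError("enamel_density must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SEMField:
    """Generated SEM-like image with disjoint named region masks."""

    image: np.ndarray
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        total = np.zeros(self.image.shape, dtype=int)
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"mask '{name}' is empty")
            total += m.astype(int)
        if total.max() > 1:
            raise ValueError("masks overlap")


def generate_sem_field(spec: SEMFieldSpec) -> SEMField:
    """Generate the four-patch SEM field (enamel / background / TD / RAD).

    Patch gray levels satisfy gray = B + (rho/rho_enamel)(E - B) before
    noise.  A density above the enamel reference triggers a warning: the
    patch would then be brighter than the calibration anchor.
    """
    for name, rho in (("TD", spec.density_td), ("RAD", spec.density_rad)):
        if rho > spec.enamel_density:
            warnings.warn(
                f"{name} density {rho} exceeds enamel reference "
                f"{spec.enamel_density}; gray level exceeds the enamel anchor",
                stacklevel=2,
            )

    h, w = spec.shape
    image = np.full((h, w), float(spec.gray_background))
    masks = {
        "enamel": np.zeros((h, w), dtype=bool),
        "background": np.zeros((h, w), dtype=bool),
        "TD": np.zeros((h, w), dtype=bool),
        "RAD": np.zeros((h, w), dtype=bool),
    }
    q_h, q_w = h // 2, w // 2
    pad_h, pad_w = max(h // 10, 2), max(w // 10, 2)

    masks["enamel"][pad_h : q_h - pad_h, pad_w : q_w - pad_w] = True
    masks["TD"][pad_h : q_h - pad_h, q_w + pad_w : w - pad_w] = True
    masks["RAD"][q_h + pad_h : h - pad_h, pad_w : q_w - pad_w] = True
    masks["background"][q_h + pad_h : h - pad_h, q_w + pad_w : w - pad_w] = True

    levels = {
        "enamel": float(spec.gray_enamel),
        "background": float(spec.gray_background),
        "TD": float(
            density_to_gray(
                spec.density_td,
                spec.gray_background,
                spec.gray_enamel,
                spec.enamel_density,
            )
        ),
        "RAD": float(
            density_to_gray(
                spec.density_rad,
                spec.gray_background,
                spec.gray_enamel,
                spec.enamel_density,
            )
        ),
    }
    for name, level in levels.items():
        image[masks[name]] = level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    return SEMField(image=image, masks=masks)


@dataclass(frozen=True)
class XRDPeakSpec:
    """Planted aragonite (200) reflection with size and instrument broadening."""

    crystal_size: float = 128.0  # nm
    lattice_a: float = 4.9598  # Angstrom
    photon_energy: float = 18.0  # keV
    instrument_fwhm: float = 0.02  # degrees 2-theta (Gaussian)
    amplitude: float = 1000.0  # peak counts above background
    background: float = 50.0  # counts
    grid: tuple[float, float, float] = (14.0, 18.0, 0.002)  # 2-theta lo, hi, step
    noise_sd: float = 0.0  # counts
    scherrer_k: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crystal_size <= 0:
            raise ValueError("crystal_size must be positive")
        if self.grid[1] <= self.grid[0] or self.grid[2] <= 0:
            raise ValueError("invalid 2-theta grid")


def generate_xrd_profile(spec: XRDPeakSpec) -> DiffractionProfile:
    """Background + Voigt (200) peak at the Bragg angle of ``lattice_a``.

    The Lorentzian FWHM follows the Scherrer relation at the planted crystal
    size; the Gaussian FWHM is the instrument width.  Raises ``ValueError``
    when the grid does not bracket the Bragg angle.
    """
    center = bragg_center(spec.lattice_a, spec.photon_energy)
    lo, hi, step = spec.grid
    if not (lo < center < hi):
        raise ValueError(
            f"2-theta grid [{lo}, {hi}] does not cover the (200) Bragg angle "
            f"{center:.2f} deg"
        )
    lam = wavelength_angstrom(spec.photon_energy)
    l_fwhm = scherrer_fwhm_deg(spec.crystal_size, center, lam, spec.scherrer_k)
    two_theta = np.arange(lo, hi + step / 2.0, step)
    intensity = voigt_curve(
        two_theta,
        center=center,
        amplitude=spec.amplitude,
        gaussian_fwhm=spec.instrument_fwhm,
        lorentzian_fwhm=l_fwhm,
        background=spec.background,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = np.clip(
            intensity + rng.normal(0.0, spec.noise_sd, intensity.shape), 0.0, None
        )
    return DiffractionProfile(two_theta=two_theta, intensity=intensity)
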