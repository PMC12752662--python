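"""Monte-Carlo simulation of keV electron trajectories in calcium-carbonate targets.

The engine implements the classical single-scattering model for electron
transport in solids: screened-Rutherford elastic scattering between
collisions, with energy depleted continuously along each free path using the
Bethe stopping power with the Joy–Luo low-energy modification.  Trajectories
are traced until the electron re-exits the entrance surface (backscattered),
leaves through the bottom of the substrate (transmitted), or slows below a
tracking cutoff (absorbed).

The quantity of interest for backscatter-SEM interpretation is the maximum
depth reached by electrons that eventually re-emerge from the entrance
surface: the deeper those electrons travel before turning around, the more
material attenuates the backscatter signal.  Substrates may be homogeneous
or periodic aragonite/ACC lamellar composites oriented parallel
("horizontal") or perpendicular ("vertical") to the entrance surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementSpec",
    "Material",
    "LayeredSubstrate",
    "BeamConfig",
    "MCSummary",
    "ARAGONITE",
    "ACC",
    "caco3_material",
    "screening_parameter",
    "elastic_cross_section",
    "mean_free_path",
    "stopping_power",
    "sample_polar_angle",
    "material_at",
    "trace_electron",
    "run_simulation",
    "kanaya_okayama_range",
]

AVOGADRO = 6.02214076e23  # mol^-1


@dataclass(frozen=True)
class ElementSpec:
    """One element of a compound target."""

    Z: int
    A: float  # g/mol
    weight_fraction: float

    def __post_init__(self) -> None:
        if self.Z <= 0 or self.A <= 0:
            raise ValueError("Z and A must be positive")
        if not 0.0 <= self.weight_fraction <= 1.0:
            raise ValueError("weight_fraction must lie in [0, 1]")


# CaCO3 weight fractions from atomic masses (Ca 40.078, C 12.011, O 15.999).
_CACO3_ELEMENTS = (
    ElementSpec(Z=20, A=40.078, weight_fraction=0.4004),
    ElementSpec(Z=6, A=12.011, weight_fraction=0.1200),
    ElementSpec(Z=8, A=15.999, weight_fraction=0.4796),
)


@dataclass(frozen=True)
class Material:
    """Elemental composition plus bulk density of a target material."""

    name: str
    elements: tuple[ElementSpec, ...]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        total = sum(e.weight_fraction for e in self.elements)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weight fractions sum to {total}, expected 1")

    @property
    def mean_Z(self) -> float:
        return sum(e.weight_fraction * e.Z for e in self.elements)


def caco3_material(density: float, name: str = "caco3") -> Material:
    """CaCO3 of arbitrary bulk density (used for homogeneous substrates)."""
    return Material(name=name, elements=_CACO3_ELEMENTS, density=density)


#: Crystalline aragonite, the dominant coral skeletal polymorph.
ARAGONITE = caco3_material(2.93, "aragonite")
#: Lumped non-crystalline phase (ACC and hydrated intermediates).
ACC = caco3_material(1.62, "acc")


@dataclass(frozen=True)
class LayeredSubstrate:
    """Periodic lamellar aragonite/ACC composite of finite total thickness.

    ``horizontal`` lamellae are slabs stacked along the beam axis (z);
    ``vertical`` lamellae are slabs periodic along x, parallel to the beam.
    The aragonite layer sits first at the entrance surface (horizontal) or at
    the beam axis origin (vertical).  Setting one layer thickness to zero
    yields a homogeneous substrate of the other material.
    """

    aragonite_layer_nm: float
    acc_layer_nm: float
    orientation: str = "horizontal"
    total_thickness_nm: float = 5000.0
    materials: tuple[Material, Material] = (ARAGONITE, ACC)

    def __post_init__(self) -> None:
        if self.aragonite_layer_nm < 0 or self.acc_layer_nm < 0:
            raise ValueError("layer thicknesses must be >= 0")
        if self.aragonite_layer_nm == 0 and self.acc_layer_nm == 0:
            raise ValueError("at least one layer thickness must be positive")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be 'horizontal' or 'vertical'")
        if self.total_thickness_nm <= 0:
            raise ValueError("total_thickness_nm must be positive")

    @classmethod
    def homogeneous(
        cls, material: Material, total_thickness_nm: float = 5000.0
    ) -> "LayeredSubstrate":
        return cls(
            aragonite_layer_nm=1.0,
            acc_layer_nm=0.0,
            orientation="horizontal",
            total_thickness_nm=total_thickness_nm,
            materials=(material, material),
        )

    @property
    def period_nm(self) -> float:
        return self.aragonite_layer_nm + self.acc_layer_nm

    def material_index(self, x_nm, z_nm):
        """Vectorized lamella lookup: 0 = first material, 1 = second."""
        coord = z_nm if self.orientation == "horizontal" else x_nm
        if self.acc_layer_nm == 0:
            return np.zeros(np.shape(coord), dtype=np.int8)
        if self.aragonite_layer_nm == 0:
            return np.ones(np.shape(coord), dtype=np.int8)
        phase = np.mod(coord, self.period_nm)
        return (phase >= self.aragonite_layer_nm).astype(np.int8)


def material_at(substrate: LayeredSubstrate, x_nm: float, z_nm: float) -> Material:
    """Material at a position inside the substrate.

    Raises ``ValueError`` with an 'exited' message when the depth coordinate
    lies outside [0, total_thickness].
    """
    if z_nm < 0 or z_nm > substrate.total_thickness_nm:
        raise ValueError("position outside substrate: electron exited")
    idx = int(substrate.material_index(np.asarray(x_nm), np.asarray(z_nm)))
    return substrate.materials[idx]


@dataclass(frozen=True)
class BeamConfig:
    """Electron-beam settings: 20 keV, 25 nm spot, 50k trajectories by default."""

    e0: float = 20.0  # keV
    radius: float = 25.0  # nm
    n_electrons: int = 50_000
    cutoff: float = 0.5  # keV, tracking cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.e0 > self.cutoff > 0:
            raise ValueError("require e0 > cutoff > 0")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass(frozen=True)
class MCSummary:
    """Aggregate backscatter statistics of one simulation run.

    Depth statistics are computed over backscattered electrons only: electrons
    absorbed or transmitted never contribute to the backscatter signal.
    """

    eta: float  # backscatter coefficient
    depth_mean: float  # nm, mean max depth of backscattered electrons
    depth_sd: float  # nm
    depth_sem: float  # nm
    n_backscattered: int
    n_electrons: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "eta": self.eta,
            "depth_mean_nm": self.depth_mean,
            "depth_sd_nm": self.depth_sd,
            "depth_sem_nm": self.depth_sem,
            "n_backscattered": self.n_backscattered,
            "n_electrons": self.n_electrons,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Single-scattering physics
# ---------------------------------------------------------------------------

def screening_parameter(Z, E_keV):
    """Nuclear screening parameter of the screened-Rutherford cross section.

    alpha = 3.4e-3 * Z^0.67 / E  (E in keV, dimensionless result).
    """
    Z = np.asarray(Z, dtype=float)
    E = np.asarray(E_keV, dtype=float)
    return 3.4e-3 * Z**0.67 / E


def elastic_cross_section(Z, E_keV):
    """Total screened-Rutherford elastic cross section per atom, in cm^2.

    Includes the standard relativistic correction factor
    ((E + 511)/(E + 1024))^2 with E in keV.
    """
    Z = np.asarray(Z, dtype=float)
    E = np.asarray(E_keV, dtype=float)
    alpha = screening_parameter(Z, E)
    rel = ((E + 511.0) / (E + 1024.0)) ** 2
    return 5.21e-21 * (Z**2 / E**2) * (4.0 * np.pi / (alpha * (1.0 + alpha))) * rel


def _number_densities(material: Material) -> np.ndarray:
    """Atoms per cm^3 for each element of the material."""
    return np.array(
        [
            AVOGADRO * material.density * e.weight_fraction / e.A
            for e in material.elements
        ]
    )


def mean_free_path(material: Material, E_keV):
    """Elastic mean free path in nm: 1 / sum_i n_i * sigma_i."""
    E = np.asarray(E_keV, dtype=float)
    n_i = _number_densities(material)
    inv = np.zeros_like(E)
    for n, e in zip(n_i, material.elements):
        inv = inv + n * elastic_cross_section(e.Z, E)
    return 1.0 / inv * 1.0e7  # cm -> nm


def _mean_ionization_keV(Z: float) -> float:
    """Joy–Luo-compatible mean ionization potential, keV (Berger–Seltzer fit)."""
    return (9.76 * Z + 58.5 * Z ** (-0.19)) * 1e-3


def stopping_power(material: Material, E_keV):
    """Continuous energy loss -dE/ds in keV/nm (Bethe with Joy–Luo term).

    The Joy–Luo modified logarithm ln(1.166 (E + 0.85 J)/J) keeps the loss
    positive down to energies well below the mean ionization potential, so
    tracking to a 0.5 keV cutoff is stable.
    """
    E = np.asarray(E_keV, dtype=float)
    total = np.zeros_like(E)
    for e in material.elements:
        J = _mean_ionization_keV(e.Z)
        total = total + (e.weight_fraction * e.Z / e.A) * np.log(
            1.166 * (E + 0.85 * J) / J
        )
    per_cm = 78500.0 * (material.density / E) * total  # keV/cm
    return per_cm * 1.0e-7  # keV/nm


def sample_polar_angle(alpha, u):
    """Polar scattering angle from the screened-Rutherford angular law.

    cos(theta) = 1 - 2*alpha*u / (1 + alpha - u) for u ~ Uniform[0, 1).
    Returns theta in radians; the azimuth is sampled separately, uniform
    on [0, 2*pi).
    """
    alpha = np.asarray(alpha, dtype=float)
    u = np.asarray(u, dtype=float)
    cos_t = 1.0 - 2.0 * alpha * u / (1.0 + alpha - u)
    return np.arccos(np.clip(cos_t, -1.0, 1.0))


def kanaya_okayama_range(material: Material, E_keV: float) -> float:
    """Kanaya–Okayama total electron range in nm (sanity bound, not used in
    transport)."""
    inv = 0.0
    for e in material.elements:
        r_i = 27.6 * e.A * E_keV**1.67 / (e.Z**0.89 * material.density)  # nm
        inv += e.weight_fraction / r_i
    return 1.0 / inv


# ---------------------------------------------------------------------------
# Trajectory tracing
# ---------------------------------------------------------------------------

def _element_tables(material: Material):
    """Per-element (Z, number density) arrays used in collision sampling."""
    Zs = np.array([e.Z for e in material.elements], dtype=float)
    ns = _number_densities(material)
    return Zs, ns


def _scatter_directions(dx, dy, dz, theta, psi):
    """Rotate unit direction vectors by polar angle theta, azimuth psi."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    # Guard the pole where the direction is (0, 0, +-1).
    denom = np.sqrt(np.maximum(1.0 - dz**2, 1e-24))
    polar = denom < 1e-9
    ndx = st * (dx * dz * cp - dy * sp) / denom + dx * ct
    ndy = st * (dy * dz * cp + dx * sp) / denom + dy * ct
    ndz = -denom * st * cp + dz * ct
    sign = np.where(dz >= 0, 1.0, -1.0)
    ndx = np.where(polar, st * cp, ndx)
    ndy = np.where(polar, st * sp, ndy)
    ndz = np.where(polar, sign * ct, ndz)
    norm = np.sqrt(ndx**2 + ndy**2 + ndz**2)
    return ndx / norm, ndy / norm, ndz / norm


def trace_electron(
    substrate: LayeredSubstrate,
    beam: BeamConfig,
    rng: np.random.Generator,
    record_path: bool = False,
):
    """Trace a single electron; reference scalar implementation.

    Returns ``(backscattered, max_depth_nm, exit_energy_keV)`` or, with
    ``record_path=True``, a 4-tuple whose last element is the list of
    ``(s, dE)`` step lengths and energy losses (for bookkeeping checks).
    The vectorized ensemble in :func:`run_simulation` implements identical
    physics; this routine exists for clarity and path-level testing.
    """
    r = beam.radius * math.sqrt(rng.random())
    phi = 2.0 * math.pi * rng.random()
    x, y, z = r * math.cos(phi), r * math.sin(phi), 0.0
    dx, dy, dz = 0.0, 0.0, 1.0
    E = beam.e0
    max_depth = 0.0
    path = []

    mats = substrate.materials
    tables = [_element_tables(m) for m in mats]

    while True:
        mi = int(substrate.material_index(np.asarray(x), np.asarray(z)))
        mat = mats[mi]
        lam = float(mean_free_path(mat, E))
        sp = float(stopping_power(mat, E))
        s = -lam * math.log(1.0 - rng.random())

        nz = z + dz * s
        if nz < 0.0:  # crosses the entrance surface: backscattered
            s_exit = z / -dz
            E_exit = max(E - sp * s_exit, 0.0)
            if record_path:
                path.append((s_exit, E - E_exit))
                return True, max_depth, E_exit, path
            return True, max_depth, E_exit
        if nz > substrate.total_thickness_nm:  # transmitted
            s_exit = (substrate.total_thickness_nm - z) / dz
            E_exit = max(E - sp * s_exit, 0.0)
            max_depth = substrate.total_thickness_nm
            if record_path:
                path.append((s_exit, E - E_exit))
                return False, max_depth, E_exit, path
            return False, max_depth, E_exit

        x, y, z = x + dx * s, y + dy * s, nz
        max_depth = max(max_depth, z)
        dE = sp * s
        if record_path:
            path.append((s, min(dE, E)))
        E -= dE
        if E <= beam.cutoff:  # absorbed
            if record_path:
                return False, max_depth, 0.0, path
            return False, max_depth, 0.0

        # collision partner sampled proportionally to n_i * sigma_i
        Zs, ns = tables[mi]
        weights = ns * elastic_cross_section(Zs, E)
        weights = weights / weights.sum()
        j = int(rng.choice(len(Zs), p=weights))
        alpha = float(screening_parameter(Zs[j], E))
        theta = float(sample_polar_angle(alpha, rng.random()))
        psi = 2.0 * math.pi * rng.random()
        ndx, ndy, ndz = _scatter_directions(
            np.asarray(dx), np.asarray(dy), np.asarray(dz),
            np.asarray(theta), np.asarray(psi),
        )
        dx, dy, dz = float(ndx), float(ndy), float(ndz)


def run_simulation(
    substrate: LayeredSubstrate,
    beam: BeamConfig,
    max_steps: int = 200_000,
) -> MCSummary:
    """Trace the whole electron ensemble and aggregate backscatter statistics.

    All electrons are advanced together with NumPy array operations; an
    electron drops out of the active set when it backscatters, transmits, or
    falls below the tracking cutoff.  Depth statistics (mean, SD, SEM of the
    maximum depth reached) are computed over backscattered electrons only.
    """
    if beam.n_electrons < 1:
        raise ValueError("n_electrons must be >= 1")
    rng = np.random.default_rng(beam.seed)
    n = beam.n_electrons

    r = beam.radius * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    z = np.zeros(n)
    dx = np.zeros(n)
    dy = np.zeros(n)
    dz = np.ones(n)
    E = np.full(n, beam.e0)
    max_depth = np.zeros(n)
    state = np.zeros(n, dtype=np.int8)  # 0 active, 1 backscattered, 2 gone
    exit_energy = np.zeros(n)

    mats = substrate.materials
    tables = [_element_tables(m) for m in mats]
    thickness = substrate.total_thickness_nm

    active = np.arange(n)
    for _ in range(max_steps):
        if active.size == 0:
            break
        xa, za, Ea = x[active], z[active], E[active]
        mi = substrate.material_index(xa, za)

        lam = np.empty_like(Ea)
        sp = np.empty_like(Ea)
        for m in (0, 1):
            sel = mi == m
            if np.any(sel):
                lam[sel] = mean_free_path(mats[m], Ea[sel])
                sp[sel] = stopping_power(mats[m], Ea[sel])

        s = -lam * np.log1p(-rng.random(active.size))
        dza = dz[active]
        nz = za + dza * s

        out_top = nz < 0.0
        out_bot = nz > thickness
        stays = ~(out_top | out_bot)

        if np.any(out_top):
            idx = active[out_top]
            s_exit = za[out_top] / -dza[out_top]
            exit_energy[idx] = np.maximum(Ea[out_top] - sp[out_top] * s_exit, 0.0)
            state[idx] = 1
        if np.any(out_bot):
            idx = active[out_bot]
            s_exit = (thickness - za[out_bot]) / dza[out_bot]
            exit_energy[idx] = np.maximum(Ea[out_bot] - sp[out_bot] * s_exit, 0.0)
            max_depth[idx] = thickness
            state[idx] = 2

        idx = active[stays]
        ss = s[stays]
        x[idx] += dx[idx] * ss
        y[idx] += dy[idx] * ss
        z[idx] = nz[stays]
        np.maximum.at(max_depth, idx, z[idx])
        E[idx] -= sp[stays] * ss

        absorbed = E[idx] <= beam.cutoff
        state[idx[absorbed]] = 2
        idx = idx[~absorbed]

        if idx.size:
            # collision partner ~ n_i * sigma_i within the local material
            Ei = E[idx]
            mi_s = substrate.material_index(x[idx], z[idx])
            Zpick = np.empty_like(Ei)
            for m in (0, 1):
                sel = mi_s == m
                if not np.any(sel):
                    continue
                Zs, ns = tables[m]
                w = np.stack(
                    [ni * elastic_cross_section(Zi, Ei[sel]) for Zi, ni in zip(Zs, ns)]
                )
                w /= w.sum(axis=0)
                u = rng.random(sel.sum())
                choice = (u[None, :] >= np.cumsum(w, axis=0)).sum(axis=0)
                Zpick[sel] = Zs[np.minimum(choice, len(Zs) - 1)]

            alpha = screening_parameter(Zpick, Ei)
            theta = sample_polar_angle(alpha, rng.random(idx.size))
            psi = 2.0 * np.pi * rng.random(idx.size)
            ndx, ndy, ndz = _scatter_directions(dx[idx], dy[idx], dz[idx], theta, psi)
            dx[idx], dy[idx], dz[idx] = ndx, ndy, ndz

        active = idx
    else:
        raise RuntimeError("electron tracing did not terminate within max_steps")

    back = state == 1
    n_back = int(back.sum())
    if n_back == 0:
        raise RuntimeError(
            "no backscattered electrons: substrate/beam configuration yields "
            f"eta = 0 over {n} trajectories"
        )
    depths = max_depth[back]
    depth_mean = float(depths.mean())
    depth_sd = float(depths.std(ddof=1)) if n_back > 1 else 0.0
    return MCSummary(
        eta=n_back / n,
        depth_mean=depth_mean,
        depth_sd=depth_sd,
        depth_sem=depth_sd / math.sqrt(n_back) if n_back > 1 else 0.0,
        n_backscattered=n_back,
        n_electrons=n,
        seed=beam.seed,
    )
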