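# Methods

`coralskel` chains five measurement stages — synthetic-input generation,
backscatter density calibration, 3D morphometry, electron Monte-Carlo
simulation, and XRD line-profile sizing — into one reproducible pipeline
for quantifying early coral skeletogenesis.  This note records the models,
parameter choices and numerical decisions behind each stage, and what the
synthetic phantom does and does not establish about real scan data.

## Synthetic polyp phantom

The phantom stands in for segmented tomographic volumes of primary-polyp
skeletons.  It is a geometric idealization, not a reconstruction of real
polyp anatomy: six septa are modelled as radially arranged elongated-ellipse
pillars attached to a cup wall of radius `wall_radius` (default 80 µm at a
2.2 µm voxel size), each carrying a medial RAD rod (default radius 4.5 µm)
embedded in TD material.  RAD rods start at `rad_onset_fraction` of the
coral height (default 0.05, the normal-pH onset; 0.10 emulates the delayed
onset under acidified conditions).  Septum width and length may be constants
or callables of normalized height, which is how tapered test geometries are
planted.

Densities default to 2.18 g/cm³ for TDs and 2.10 g/cm³ for RADs (RADs a few
percent less dense than TDs at normal pH).  Gray values are linear in
density between a background anchor (20) and the level an enamel reference
of 2.8 g/cm³ would produce (188), which makes the density-recovery equation
exactly invertible; additive, per-voxel Gaussian noise (default SD 1 gray
unit, ≈0.6 % of the dynamic range, in the range of averaged synchrotron
reconstructions) is the simplest model supporting mode-based region
statistics.  Because the gray model is exactly the inverse of the
calibration equation and the noise is idealized, passing round trips
demonstrate correctness of the arithmetic and bookkeeping, not robustness
to detector nonlinearity, beam hardening or phase-contrast fringes — all of
which are absent from the phantom.

One geometric note: a RAD rod thicker than two voxels necessarily has
interior voxels touching only other RAD voxels, so "RADs embedded in TDs"
is enforced and tested at the connected-component level (every RAD
component is 26-adjacent to TD), not per voxel.

## Backscatter density calibration

Region density is computed from gray-value modes as
`rho = (T_or_R − B)/(E − B) × 2.8`, with B and E the background and enamel
modes.  The mode uses a histogram with 1-gray-unit bins anchored so the
region minimum sits at a bin centre, ties breaking toward the lower bin;
the bin width is configurable since 8- vs 16-bit data differ.  The
gray→density transfer into absorption volumes is an ordinary least-squares
line (scipy), pooling TD and RAD pairs into one line per condition; the
line is not forced through the origin because a detector offset cannot be
excluded.  With noise at ≤2 % of the dynamic range the phantom round trip
recovers planted densities to better than 1 %; noise-free it is exact to
arithmetic precision.

## Morphometry

Heights are normalized to the z-extent of all mineral voxels and binned in
1 % steps by default.  Cross-sections are summarized by the ellipse with
the same second central moments as the binary mask; width and length are
the full minor and major axes (validated against
`skimage.regionprops` axis lengths and against rasterized discs and
ellipses to 1 px).  The second moment of area adds a per-pixel self-term
(voxel⁴/12) so small shapes match the closed forms πr⁴/4 and a⁴/12 within
2 %; `I_max` is the larger eigenvalue of the area-moment tensor about the
centroid.  Phase segmentation for volumes without planted labels is by two
ordered density thresholds with a connectivity cleanup that keeps RAD
components only when 26-adjacent to TD.  Septum identity comes from the
phantom truth when available.

Group comparisons integrate each per-septum profile over normalized height
(trapezoid rule — "area between the curve and the height axis"; the
alternative reading, integrating height over the metric, is not used) and
compare the resulting AUC lists with an unpaired t-test, falling back to
Mann–Whitney when Shapiro–Wilk normality (either group) or Levene variance
homogeneity fails at α = 0.05.  No multiple-testing correction is applied.

## Electron Monte-Carlo simulation

The engine is the classical single-scattering model: elastic collisions
follow the screened-Rutherford cross section
σ = 5.21×10⁻²¹ (Z²/E²)·4π/(α(1+α))·((E+511)/(E+1024))² cm² with screening
α = 3.4×10⁻³ Z^0.67/E, free paths are sampled exponentially from the
elastic mean free path, and energy is depleted continuously along each step
with the Bethe stopping power using the Joy–Luo low-energy form
(J = (9.76 Z + 58.5 Z^−0.19)×10⁻³ keV), which stays positive down to the
0.5 keV tracking cutoff.  Collision partners are drawn proportionally to
nᵢσᵢ; the polar deflection follows cos θ = 1 − 2αu/(1+α−u) with uniform
azimuth.  CaCO₃ is Ca 0.4004, C 0.1200, O 0.4796 by weight; aragonite is
2.93 g/cm³ and the lumped non-crystalline phase ("ACC", which may include
hydrated intermediates) 1.62 g/cm³.

Beam defaults are 20 keV, a uniform 25 nm disc at normal incidence, 50 000
trajectories, in a 5000 nm substrate.  Lamellar composites alternate
aragonite and ACC layers either stacked along the beam (horizontal) or
periodic in x parallel to the beam (vertical); the aragonite layer sits
first at the entrance surface or axis origin, and the beam is centred on a
lamella boundary.  The material of the segment start point applies to the
whole step (layer crossings within one free path, ~20–30 nm at 20 keV, are
not subdivided).  All top-surface exits count as backscattered regardless
of exit angle, and the reported penetration depth is the **mean over
backscattered electrons of the maximum depth reached** (mode or percentiles
of that distribution are plausible alternatives; the mean is implemented).
Statistics exclude absorbed and transmitted electrons.

The ensemble is advanced with vectorized NumPy array operations (a 50 000
trajectory run takes a few seconds on one CPU), and a scalar
reference tracer exists for path-level bookkeeping tests.  Fixed seeds make
runs bit-reproducible; common random numbers make the mass-depth product
ρ·depth exactly invariant across densities at fixed composition.

Validation: backscatter coefficients at 20 keV match experimental values
across Z (C ≈ 0.056 vs ≈0.06, Al ≈ 0.16 vs ≈0.15, Cu ≈ 0.32 vs ≈0.30,
Au ≈ 0.55 vs ≈0.49), and depths sit inside the 0.08–0.35 band of the
Kanaya–Okayama range.  Known limitation: screened-Rutherford cross sections
underestimate total elastic scattering at these energies relative to Mott
partial-wave tables, so absolute penetration depths run ≈10–15 % deeper
than Mott-based simulators report for the same configurations.  Relative
quantities — density ordering, mass-depth scaling, and the depth-matching
inference below, where target and model share the engine — are insensitive
to this common-mode bias.  Mott tables, secondary electrons and X-ray
generation are out of scope.

## Phase-fraction inference

`PhaseFractionModel` bisects the aragonite layer-thickness fraction f of
the lamellar composite until its simulated depth matches a target depth,
exploiting that depth decreases monotonically in f.  The aragonite layer
thickness is pinned to the XRD crystal size (128 nm normal pH, 168 nm
acidified); the ACC layer is `crystal·(1−f)/f`.  The fraction is a
layer-thickness (volume) fraction along the lamella normal.  By default
both orientations are simulated and their mean depth is matched, with each
orientation keeping one fixed seed across every f evaluated (common random
numbers), so Monte-Carlo noise cannot break the bisection.  Iteration stops
when the mismatch falls below max(tol_nm, 3×MC-SEM); evaluations therefore
run at the full 50 000 trajectories by default so this stop rule resolves
the crossing instead of quantizing the estimate at coarse bisection
midpoints.  Targets outside the [depth(f=1), depth(f=0)] envelope raise an
error naming the envelope.

The implied linear-mixing density f·2.93 + (1−f)·1.62 is reported for
transparency only: a measured density of 2.18 g/cm³ is not consistent with
linear mixing at the depth-matched fraction, and the method deliberately
matches depths, not densities.  Only two phases are modelled; hydrated
polymorphs are lumped into the non-crystalline phase.

## XRD line-profile sizing

Synthetic (200) reflections are Voigt lines at the Bragg angle of the
a-lattice parameter (4.9598 Å at 18 keV → 2θ ≈ 15.97°; λ[Å] = 12.3984/E),
with the Gaussian FWHM set to the instrument width (corundum-calibrated in
a real experiment) and the Lorentzian FWHM from the Scherrer relation at
the planted size.  Fitting uses lmfit's Voigt model with an independent
Lorentzian width plus a constant background; size broadening is assigned
entirely to the Lorentzian component and inverted with K = 0.9
(config-exposed; the single-line method's standard partition, since the
true instrument-correction scheme of any given beamline varies).  Strain
broadening is assumed zero.  Round trips are exact to ≪1 % for sizes of
50–500 nm and insensitive to background level and amplitude.  Size maps
are grids of independent per-point 1D fits; 2D detector geometry and
azimuthal integration are upstream concerns outside this package.

## Pipeline and problem sizes

The CLI (`coralskel`) wires the stages with a master seed; every artifact
is checksummed into a run manifest, and reruns with the same configuration
and seed are bit-identical.  Default problem sizes — a 96×96×120 voxel
phantom, 50 000-trajectory simulations, 2000-point diffraction grids —
keep any stage within minutes on a single CPU while leaving Monte-Carlo
SEMs at a few nm.  Tests use smaller phantoms (64×64×60) and reduced
trajectory counts except where a property is resolution-limited, in which
case the full 50 000 trajectories are used.
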