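# coralskel

Quantitative tools for studying the earliest mineral a stony-coral polyp
deposits.  Young *Stylophora pistillata* recruits build their first skeleton
out of two co-joined growth zones — rapid accretion deposits (RADs) and
thickening deposits (TDs) — whose density, geometry and crystalline content
shift when the surrounding seawater acidifies.  `coralskel` implements the
measurement chain needed to quantify those shifts, exercised end-to-end on a
synthetic polyp phantom so no microscope or beamline data is required:

1. **Backscatter-SEM density calibration.**  Region density from gray-value
   modes against a bovine-enamel reference slab:
   `rho = (T_or_R − B) / (E − B) × 2.8 g cm⁻³`, then an OLS gray→density
   line transfers the SEM densities into X-ray absorption volumes.
2. **3D septum morphometry.**  Per-septum, height-normalized profiles of
   cross-sectional area, best-fitting-ellipse width/length and density;
   phase volumes; RAD onset height; the maximum second moment of area
   `I_max` (bending resistance); and AUC-based group comparisons gated by
   Shapiro–Wilk and Levene tests (unpaired t-test or Mann–Whitney).
3. **Electron Monte-Carlo backscatter simulation.**  A single-scattering
   trajectory engine (screened-Rutherford elastic cross sections, Bethe
   stopping power with the Joy–Luo low-energy term) that reports the
   backscatter coefficient η and the mean maximum depth reached by
   backscattered electrons in homogeneous or lamellar aragonite/ACC
   substrates.
4. **Phase-fraction inference.**  A statsmodels-style model
   (`PhaseFractionModel.fit()` → `PhaseFractionResult`) that bisects the
   aragonite layer-thickness fraction of the lamellar composite until its
   simulated backscatter depth matches a target depth — typically the depth
   simulated for a homogeneous substrate at the SEM-measured density.
5. **XRD crystal sizing.**  Voigt line-profile fits of the aragonite (200)
   reflection with the Scherrer relation `L = Kλ/(β cos θ)` applied to the
   Lorentzian breadth, plus a-lattice parameters and size-histogram modes.

A synthetic-data module generates all inputs with recorded ground truth:
labelled six-septa polyp volumes, four-patch SEM fields consistent with the
density equation, and (200) reflections with planted size broadening.

## Worked example

Infer the crystalline fraction of thickening deposits grown at normal pH,
whose SEM-measured density is 2.18 g cm⁻³ and whose XRD crystal size is
128 nm:

```python
from coralskel.inference import InferenceConfig, PhaseFractionModel
from coralskel.montecarlo import BeamConfig

cfg = InferenceConfig(crystal_size_nm=128.0,
                      beam=BeamConfig(n_electrons=8000, seed=11))
res = PhaseFractionModel(measured_density=2.18, config=cfg).fit()
print(res.summary())
```

```
Phase-fraction inference (backscatter depth matching)
========================================================
target depth                 798.9 nm  (from rho = 2.18 g/cm3)
matched depth                796.4 nm  (MC SEM 8.4 nm)
aragonite fraction            37.5 %
ACC fraction                  62.5 %
implied mixture density      2.111 g/cm3
crystal size                 128.0 nm
iterations                       3
  horizontal depth    790.3 nm (SEM 12.0 nm)
  vertical   depth    802.4 nm (SEM 11.8 nm)
```

The target depth is what a homogeneous CaCO₃ substrate at the measured
density produces under a 20 keV, 25 nm beam; the fit says a lamellar
composite of 128 nm aragonite crystals needs to be roughly one-third
aragonite (and the rest amorphous calcium carbonate at 1.62 g cm⁻³) to
return electrons from the same depth — i.e. most of this early mineral is
not crystalline aragonite.  The implied linear-mixing density is reported
for transparency; the inference matches depths, not densities.

The same chain is available from the shell:

```sh
coralskel repro-table1 --seed 1 --outdir run/
coralskel xrd-size --seed 1 --outdir run/
```

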