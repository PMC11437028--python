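# tristream

Retrieval of surface biogeochemical constituents — chlorophyll-a, coloured
dissolved organic matter (CDOM) and non-algal particles (NAP) — from
multispectral remote-sensing reflectance, by inverting an analytic
three-stream irradiance model of the water column.

The package is aimed at ocean-colour and biogeochemical modellers who want
an inversion operator that is *coherent* with the forward optics used in
spectral biogeochemical models: the same radiative-transfer approximation,
the same bio-optical coefficients and the same photoacclimation law are
used to simulate reflectance and to invert it, so retrieved constituents
can feed model validation or data assimilation without a change of
formalism.

## The model

**Forward optics.** Per wavelength λ, three irradiance streams are tracked
in a homogeneous, infinitely deep column (depth z, positive downward): the
direct solar beam E_dir, the downward diffuse field E_dif and the upward
diffuse field E_u,

    dE_dir/dz = −(a+b)/cosθ_d · E_dir
    dE_dif/dz = −(a + r_dif·b_b)/v̄_dif · E_dif + r_u·b_b/v̄_u · E_u + (b − r_dir·b_b)/cosθ_d · E_dir
    −dE_u/dz  = −(a + r_u·b_b)/v̄_u · E_u + r_dif·b_b/v̄_dif · E_dif + r_dir·b_b/cosθ_d · E_dir

with E_dir, E_dif given just below the surface and E_u → 0 at depth.
Because the coefficients are constant the system solves in closed form
(exponential direct beam, a decaying diffuse eigenmode exp(−k⁺z) and a
particular solution ∝ E_dir); the implementation derives the coefficients
from the 2×2 linear system and certifies them against a numerical
boundary-value solver. Remote-sensing reflectance follows as

    Rrs(λ) = E_u(0⁻,λ) / ( Q · [E_dir(0⁻,λ) + E_dif(0⁻,λ)] )

carried through the air–sea interface with the semi-analytic transfer
T·r/(1−Γ·r) (T = 0.52, Γ = 1.7).

**Bio-optics.** Bulk IOPs are linear in the constituents:
a = a_w + a*_PH·Chl + a*_CDOM·CDOM + a*_NAP·NAP, and likewise for
scattering and backscattering, with phytoplankton carbon C = Chl/θ_CHL(PAR)
where θ_CHL is a decreasing sigmoid of surface PAR (photoacclimation).
CDOM and NAP absorption decay exponentially in λ; NAP scattering follows a
(550/λ)^f power law; CDOM does not scatter.

**Inversion.** The constituent vector x = (Chl-a, CDOM, NAP) minimises the
spectral cost

    J(x) = Σ_λ ( Rrs_model(λ,x) − Rrs_obs(λ) )²     [sr⁻²]

under box bounds, using multi-start L-BFGS-B on log-transformed
concentrations.

Around this core the package provides the observational quality-control
chain (3-σ clipping, Savitzky–Golay smoothing, buoy record filters),
log-space skill statistics with target-diagram coordinates, full-factorial
sensitivity ensembles over the optical (EXP-1) and photoacclimation
(EXP-2) parameters, and a synthetic scenario generator that emulates a
northwestern-Mediterranean seasonal cycle so everything is testable
offline.

## Worked example

Forward spectrum and retrieval for a moderately productive surface state
(Chl-a = 0.5 mg m⁻³, CDOM = 1 mg C m⁻³, NAP = 2 mg C m⁻³, PAR = 500
µmol quanta m⁻² s⁻¹, sun at 30°):

```python
import numpy as np, tristream as ts

cfg = ts.BioOpticalConfig.ref()          # packaged REF coefficients
bc = ts.SurfaceBoundary(cfg.grid, 0.7 * np.ones(5), 0.3 * np.ones(5),
                        par=500.0, sun_zenith=30.0)
x = ts.ConstituentVector(chl=0.5, cdom=1.0, nap=2.0)

rrs = ts.forward_rrs(x, bc, cfg)         # sr^-1 at 412.5 ... 555 nm
res = ts.invert_spectrum(rrs, bc, cfg)   # retrieve x back from the spectrum
```

The forward chain prints (wavelength, Rrs, Kd over the 4–9 m layer, bbp):

```
  412.5  0.004030  0.0716  0.001677
  442.5  0.004058  0.0624  0.001616
  490.0  0.003836  0.0535  0.001620
  510.0  0.003318  0.0582  0.001611
  555.0  0.001840  0.0863  0.001506
```

Rrs peaks in the blue-green and drops sharply by 555 nm (water
absorption); Kd has its clear-water minimum near 490 nm. Inverting the
same spectrum returns `chl=0.500, cdom=1.000, nap=2.000` with final cost
J ≈ 1.3e-21 sr⁻² — a machine-precision round trip.

The same operations are available from the shell:

```bash
tristream synth --days 365 --seed 3 --noise-sd 0.05 --out-dir scene/
tristream invert --rrs scene/rrs.csv --boundary scene/boundary.csv --out retrieved.csv
tristream skill --model model_chl.csv --obs obs_chl.csv --out stats.csv
tristream ensemble --experiment EXP-1 --levels 3 --rrs scene/rrs.csv \
    --boundary scene/boundary.csv --obs-chl obs_chl.csv --out skill_table.csv
```

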