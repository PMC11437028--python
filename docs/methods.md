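# Methods

This note documents the model equations, the parameter defaults and their
units, the synthetic scenario used for verification, and the numerical and
design choices made where the design was genuinely open.

## 1. Forward model

### Three-stream radiative transfer

The water column is homogeneous and effectively infinitely deep; depth z is
in metres, positive downward, with 0⁻ just below the air–sea interface.
Three irradiance streams are resolved per wavelength: the collimated direct
beam E_dir, the downward diffuse field E_dif and the upward diffuse field
E_u (units W m⁻² nm⁻¹). Writing a, b, b_b for the bulk absorption,
scattering and backscattering coefficients (m⁻¹):

    dE_dir/dz = −c_dir E_dir,                     c_dir = (a+b)/cosθ_d
    dE_dif/dz = −C_s E_dif + B_u E_u + F_d E_dir
    −dE_u/dz  = −C_u E_u + B_s E_dif + B_d E_dir

    C_s = (a + r_dif b_b)/v̄_dif     B_u = r_u b_b/v̄_u
    C_u = (a + r_u b_b)/v̄_u         B_s = r_dif b_b/v̄_dif
    F_d = (b − r_dir b_b)/cosθ_d    B_d = r_dir b_b/cosθ_d

Boundary conditions: E_dir(0⁻) and E_dif(0⁻) prescribed (typically from an
atmospheric irradiance model; here often from the synthetic stand-in),
E_u(∞) = 0. The average cosine of the downward diffuse field is treated as
one constant v̄_dif wherever it appears.

With constant coefficients the (E_dif, E_u) pair is linear: its homogeneous
part has eigen-decay rates given by (C_s − k)(C_u + k) = B_u B_s. The
positive root

    k⁺ = [ (C_s − C_u) + sqrt( (C_s + C_u)² − 4 B_u B_s ) ] / 2

is the decaying diffuse eigenvalue (the companion root is negative, i.e. a
mode growing with depth, excluded by E_u(∞) = 0), with eigenvector ratio
r⁺ = B_s/(C_u + k⁺) = E_u/E_dif of the decaying mode. A particular solution
proportional to exp(−c_dir z) has coefficients (x, y) solving

    (C_s − c_dir) x − B_u y = F_d
    −B_s x + (C_u + c_dir) y = B_d

so the full profile is

    E_dif(z) = (E_dif(0) − x E_dir(0)) e^(−k⁺z) + x E_dir(z)
    E_u(z)   = (E_dif(0) − x E_dir(0)) r⁺ e^(−k⁺z) + y E_dir(z)

Sign note: in scattering-dominated water x is negative — the diffuse field
first grows with depth as the direct beam decays into it — and the profile
remains non-negative because the eigenmode amplitude then exceeds |x|E_dir.

Two independent certifications back the closed form instead of a printed
coefficient table: (i) substituting the profile into the governing
equations leaves relative residuals ≤ 1e-8 at random depths over random
physical parameter draws, and (ii) a collocation boundary-value solver
(`scipy.integrate.solve_bvp`) on a truncated domain with E_u(z_max) = 0
agrees with the analytic profile to ≤ 1e-6 of the surface irradiance
scale. For the truncation screen the bound k⁺ ≥ a/v̄_dif is used (from
C_s − k⁺ = B_u B_s/(C_u + k⁺) ≤ r_dif b_b/v̄_dif).

**Resonance.** When c_dir coincides with k⁺ the particular-solution system
is singular. Detected at relative determinant < 1e-9, resolved by nudging
c_dir by one part in 1e-6 and flagging the wavelength in the solution
diagnostics. The nudge is far below every tolerance used downstream.

### Surface transfer and diagnostics

The subsurface reflectance ratio is r(λ) = E_u(0⁻)/(Q·[E_dir(0⁻)+E_dif(0⁻)])
with Q the irradiance-to-radiance bidirectionality factor (default a
constant 4 sr; replaceable per record or by a function of sun zenith). The
water-to-air transition uses the semi-analytic relation
Rrs(0⁺) = T·r/(1 − Γ·r), T = 0.52, Γ = 1.7; an `identity` mode returns the
bare subsurface ratio for testing. A Raman correction hook is provided as a
multiplicative spectral factor, default off (identity).

Diagnostics: Kd(λ) = ln[E_d(z₁)/E_d(z₂)]/(z₂−z₁) with E_d = E_dir+E_dif and
default depths 4 and 9 m (mirroring a moored radiometer pair);
b_bp(λ) = b_b(λ) − b_bw(λ).

### Geometry defaults

The stream geometry is configurable; defaults are v̄_dif = 0.83, v̄_u = 0.4,
r_dir = 1.0, r_dif = 1.5, r_u = 3.0, consistent with the three-stream
literature. cosθ_d is the in-water cosine of the sun beam refracted through
a flat interface (Snell, n = 1.34).

## 2. Bio-optical parameterisations

Bulk IOPs are linear in the constituent concentrations (Chl-a in mg m⁻³,
CDOM and NAP in mg C m⁻³):

    a   = a_w  + a*_PH·Chl + a*_CDOM·CDOM + a*_NAP·NAP
    b   = b_w  + b*_PH·C   + b*_NAP·NAP
    b_b = b_bw + b*_bPH·C  + b*_bNAP·NAP,     C = Chl/θ_CHL(PAR)

The packaged REF table (`tristream/data/bio_optics_ref.csv`) carries the
water and phytoplankton spectra on the retrieval grid (412.5, 442.5, 490,
510, 555 nm); the water backscattering-to-scattering ratio is 0.5.

Spectral laws (REF values in parentheses):

* CDOM: a*_CDOM(λ) = a*(450)·exp(−S_CDOM(λ−450)), a*(450) = 0.015 m² (mg C)⁻¹,
  S_CDOM = 0.017 nm⁻¹. CDOM does not scatter.
* NAP absorption: a*_NAP(λ) = a*(440)·exp(−S_NAP(λ−440)),
  a*(440) = 0.0013 m² (mg C)⁻¹, S_NAP = 0.013 nm⁻¹.
* NAP scattering: b*_NAP(λ) = b*(550)·(550/λ)^f, b*(550) = 0.02875
  m² (mg C)⁻¹, f = 0.5; backscattering ratio 0.005 (small organic
  detritus). All NAP coefficients are per mg C.
* Photoacclimation: θ_CHL(PAR) = θ⁰·sigmoid(−(PAR−β)/σ) + θ^min with
  θ⁰ = 0.03 and θ^min = 0.005 mg Chl (mg C)⁻¹, σ = 20 and β = 500
  µmol quanta m⁻² s⁻¹. Strictly decreasing, bounded in
  (θ^min, θ^min+θ⁰), equal to θ⁰/2+θ^min at PAR = β. Evaluated through
  `scipy.special.expit` so extreme PAR cannot overflow.

### Ensemble perturbations of the phytoplankton optics

`perturb_phyto_optics` exposes the three knobs explored by the optical
ensemble (EXP-1):

* **a*_PH factor** ∈ [0.05, 1.95], default a uniform scale of the whole
  spectrum (giving a*_PH(412.5) ∈ [0.0017, 0.0663] m² (mg Chl)⁻¹). An
  alternative `tilt` mode applies the factor fully at 412.5 nm and tapers
  it to 1 at 555 nm, for studies of spectral-shape rather than amplitude
  uncertainty; uniform is the default because the perturbation is defined
  as an amplification of the reference curve.
* **b*_PH slope ratio** ∈ [0.5, 22], the b*_PH(412.5)/b*_PH(555) ratio.
  The REF curve is multiplied by the power-law tilt (555/λ)^(η−η_ref),
  η = ln(ratio)/ln(555/412.5). This choice (rather than replacing the
  spectrum by a pure power law) preserves the 555 nm value exactly,
  attains the requested blue/green ratio exactly, and reduces to the
  identity at the REF ratio — a pure power law cannot reproduce the REF
  curve, whose fine structure is non-monotonic (3% discrepancy at 490 nm).
* **b*_bPH/b*_PH ratio** ∈ [1.3e-4, 5e-3], applied wavelength-flat (the
  REF table's own ratio is flat to ~2%).

Out of scope by design: photoprotective-pigment absorption and
phytoplankton-type-resolved optics.

## 3. Inversion

J(x) = Σ_λ (Rrs_model − Rrs_obs)², equal weights, summed over the
available wavelengths only (minimum 3 of 5 bands per record; records with
negative reflectance are rejected). Minimisation uses L-BFGS-B with
gradients by finite differences on **log10-transformed** concentrations —
the constituents span decades, and the log parameterisation makes the
bound box and the curvature scale-free. Bounds (linear units):
Chl ∈ [1e-3, 50] mg m⁻³, CDOM and NAP ∈ [1e-2, 1e3] mg C m⁻³, spanning the
oligo-to-mesotrophic range with wide margin.

Because the cost landscape can hold local minima, each retrieval tries
several starts: the log-mid-bounds point plus seeded log-uniform jitters
(4 starts by default), keeping the best minimiser; identical inputs and
settings (including the seed) give identical outputs. A start is accepted
early when J falls below 1e-20 sr⁻² (machine-zero fit). Series inversion
warm-starts each day from the previous day's solution, which on smooth
series makes the remaining starts rarely necessary. Retrievals that end on
a bound raise a degeneracy warning (e.g. an all-zero spectrum pins the
lower bounds). Optimiser tolerances default to ftol = 1e-16,
gtol = 1e-12, 500 iterations; these are engineering choices, as are the
multi-start counts.

## 4. Quality control

* **3-σ clip**: single pass; mean and *sample* standard deviation
  (ddof = 1) over the whole series; points with |v−mean| > kσ removed.
* **Savitzky–Golay smoothing**: 3rd-order polynomial, 11-sample centred
  window realising a 10-day span on daily data (symmetric SG windows must
  be odd; both order and window are configurable). Applied per contiguous
  daily segment with no interpolation across gaps; segments shorter than
  the window pass through unsmoothed and are flagged. The filter
  reproduces cubic signals exactly. Note that least-squares smoothing of a
  hard step exhibits ringing (total variation can increase slightly);
  what the filter guarantees is high-frequency noise suppression, which is
  what the tests assert.
* **Kd record filters** (each active when its metadata column is present):
  acquisition time within [10:00, 14:00] GMT — closed interval, 10:00 and
  14:00 kept; |tilt| ≤ 10° (10.0° kept); sensor depth offset ≤ 2 m (2.0 m
  kept); upstream irradiance E_d ≥ 0.005 µW cm⁻² nm⁻¹; then σ-clip,
  rejection of non-positive Kd, and SG smoothing.
* **Rrs filters**: cloud-flag screen, σ-clip on the per-wavelength quality
  indicator (whatever indicator column the product supplies), SG
  smoothing. Missing flag columns are treated as all-pass and logged.
* A `manual_flag` column implements visual/plausibility rejection as an
  explicit user input rather than an automatic heuristic.

Every stage is non-expansive and reports its removal count;
n_in − Σ removals = n_out is asserted. Record-level filters are
idempotent.

## 5. Skill metrics

Model and observations are matched by calendar day (inner join); pairs
with non-positive values are dropped (log domain) and counted. On
m = log10(model), o = log10(obs): bias = mean(m−o),
rmse = sqrt(mean((m−o)²)), corr = Pearson(m, o) (undefined — returned as
missing — when either log series has zero variance). Target-diagram
coordinates use population moments so that bias² + uRMSD² = rmse² holds to
machine precision: y = bias/σ_o, x = sign(σ_m−σ_o)·uRMSD/σ_o with
uRMSD² = mean(((m−m̄)−(o−ō))²), normalised by the observed log-space
standard deviation. All statistics are invariant under a common positive
rescaling of both series.

## 6. Sensitivity ensembles

Full-factorial grids, 11 levels per parameter by default:

* EXP-1 (optics): a*_PH factor linear 0.05→1.95; b*_PH slope ratio
  log-spaced 22→0.5; b*_bPH/b*_PH log-spaced 1.3e-4→5e-3 → 11³ = 1331
  members. Log spacing for the two ratio-type parameters places the
  physically interesting neighbourhoods (slope ratio ≈ 1.56, backscatter
  ratio ≈ 1e-4) on grid levels; the linear a*_PH grid contains the
  reference factor 1.0.
* EXP-2 (photoacclimation): σ linear 10→30, β linear 250→750, θ⁰ linear
  0.015→0.045, θ^min linear 0.0005→0.01 → 11⁴ = 14641 members; σ = 20,
  β = 500, θ⁰ = 0.03 sit on the default grids.

Each member re-runs the series inversion under its perturbed configuration
and is scored per target variable (Chl-a; Kd at 412.5 nm over the 4–9 m
layer; b_bp at 442.5 nm) against an observation bundle. Execution order is
deterministic; failed members yield flagged rows; an evenly strided
`subset` supports desk-scale runs. Ranking is ascending RMSE (the Chl-a
RMSE is the default selection metric) with |bias| and member id as
deterministic tie-breakers — a pure permutation of the rows. A full EXP-2
sweep over a multi-year daily series is cluster-scale; the package runs
any grid/series subset and scales linearly in members × days.

## 7. Synthetic scenario

The generator emulates a northwestern-Mediterranean mooring site
(43.37° N) so the whole chain runs without downloads:

* **Chl-a**: log10-space sinusoid between 0.1 (summer) and 2.0 mg m⁻³
  (bloom peak near mid-March, day-of-year 75), plus seeded AR(1) noise
  (sd 0.05 log10 units, ρ = 0.8), clipped to the configured range; spans
  over an order of magnitude by construction.
* **CDOM / NAP**: affine in (lagged) Chl — CDOM = 0.5 + 0.8·Chl lagged
  30 days (peaking after the bloom), NAP = 1.0 + 3.0·Chl unlagged
  (synchronised with the bloom) — each with independent AR(1) noise and
  floored at the offsets. These couplings put the implied constituent
  absorptions in the range observed at oligo/mesotrophic sites
  (a_CDOM(442.5) ≈ 0.01–0.05 m⁻¹); much higher CDOM/NAP loads would bury
  the chlorophyll signal in the spectrum and change the identifiability of
  the retrieval qualitatively. A `decorrelated` mode removes the coupling
  for identifiability stress tests.
* **Boundary**: local-noon solar zenith from standard declination
  geometry (zenith ≈ 19.9° at the summer solstice at 43.37° N); a fixed
  five-band clear-sky spectral shape (~1.05–1.2 W m⁻² nm⁻¹) scaled by
  cos(zenith); direct/diffuse split 0.7/0.3; PAR as the visible-band
  energy integral converted to quanta (4.6 µmol J⁻¹) times a sinusoidal
  daylight factor, yielding a ~140–590 µmol quanta m⁻² s⁻¹ seasonal range
  that straddles the photoacclimation inflection β = 500. Sun below the
  horizon gives zero irradiance and a `dark` flag.
* **Observations**: Rrs(λ,t) = forward(x(t))·exp(ε), ε ~ N(0, sd²) i.i.d.
  per band and day, default sd = 5%; sd = 0 reproduces the forward values
  exactly. All randomness flows from the scenario seed.

**What the stand-in does not emulate**: aerosols, clouds, sub-daily solar
geometry, spectrally realistic sky radiance, band-correlated or
heteroscedastic observation error, and instrument drift. Passing
round-trip tests therefore demonstrates the correctness and conditioning
of the forward/inverse pair under the stated noise model — not retrieval
skill on real satellite products.

## 8. Verification problem sizes

The shipped verification suite uses: 100 random parameter draws for the
residual and oracle checks; 365-day and 3000-day noise-free round trips
(worst-case per-constituent error < 0.5%, log10-Chl RMSE < 0.01); a
100-replicate Monte-Carlo at 5% observation noise about the scenario's
central state (median Chl-a error < 25% — at the site's CDOM/NAP levels;
see §7); and a 27-member reduced EXP-1 grid whose data-generating member
must rank first by Chl-a RMSE. The acceptance script
(`scripts/acceptance.py`) re-evaluates the REF parameter laws at their
anchor points and a 120-day seeded round trip.

## 9. Known limitations

* One homogeneous layer: vertically resolved retrievals are out of scope
  (with independent layers the data constrain only the layer adjacent to
  the surface).
* Equal spectral weighting in J; no per-band uncertainty model.
* Q factor constant by default; bidirectional effects beyond 1/Q are not
  modelled. Raman scattering is off unless a user factor is supplied.
* The Chl retrieval degrades gracefully but markedly in CDOM-dominated
  water (see §7) — a property of the physics, not of the optimiser.
* Sea-surface roughness, whitecaps and polarisation are not represented.
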