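# Reference (REF) configuration: every scalar bio-optical, physiological,
# geometric and numerical parameter of the inversion system, overridable by
# user config files.  Spectral water/phytoplankton coefficients live in
# bio_optics_ref.csv alongside this file.
wavelengths: [412.5, 442.5, 490.0, 510.0, 555.0]
cdom:
  a_star_ref: 0.015      # m^2 (mg C)^-1 at lambda_ref
  lambda_ref: 450.0      # nm
  s_cdom: 0.017          # nm^-1 spectral slope
nap:
  a_star_ref: 0.0013     # m^2 (mg C)^-1 at 440 nm
  s_nap: 0.013           # nm^-1
  b_star_ref: 0.02875    # m^2 (mg C)^-1 at 550 nm
  f_nap: 0.5             # power-law exponent
  bb_ratio: 0.005        # backscattering-to-scattering ratio
photoacclimation:
  theta0: 0.03           # mg Chl (mg C)^-1
  theta_min: 0.005       # mg Chl (mg C)^-1
  sigma: 20.0            # umol quanta m^-2 s^-1
  beta: 500.0            # umol quanta m^-2 s^-1
geometry:
  v_dif: 0.83            # average cosine, downward diffuse stream
  v_u: 0.4               # average cosine, upward stream
  r_dir: 1.0             # effective scattering coefficients
  r_dif: 1.5
  r_u: 3.0
  q_factor: 4.0          # sr, irradiance-to-radiance bidirectionality
  refractive_index: 1.34 # seawater, for Snell refraction of the sun beam
surface:
  mode: interface        # interface | identity
  t_transfer: 0.52       # water-to-air transmission factor
  gamma_transfer: 1.7    # internal-reflection feedback factor
inversion:
  chl_bounds: [1.0e-3, 50.0]     # mg m^-3
  cdom_bounds: [1.0e-2, 1.0e+3]  # mg C m^-3
  nap_bounds: [1.0e-2, 1.0e+3]   # mg C m^-3
  n_starts: 4
  seed: 0
  maxiter: 500
  ftol: 1.0e-16
  min_wavelengths: 3
qc:
  sigma_k: 3.0
  sg_window: 11          # samples (10-day span on daily data)
  sg_polyorder: 3
  time_window: ["10:00", "14:00"]  # GMT, closed interval
  max_tilt_deg: 10.0
  max_depth_offset_m: 2.0
  min_ed: 0.005          # uW cm^-2 nm^-1
logging:
  level: INFO
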