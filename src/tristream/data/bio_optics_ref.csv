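wavelength_nm,a_w,b_w,b_bw,a_star_ph,b_star_ph,b_star_bph
412.5,0.0048,0.00535,0.002674,0.034,0.02102,5.38e-05
442.5,0.00742,0.00437,0.002184,0.040,0.02022,5.18e-05
490,0.01758,0.00284,0.001421,0.028,0.02054,5.26e-05
510,0.02918,0.00247,0.001234,0.018,0.02050,5.25e-05
555,0.06098,0.00167,0.000836,0.009,0.01907,4.88e-05
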