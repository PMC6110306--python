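# material: pmma
# density_g_cm3: 1.19
# mass attenuation coefficients (cm2/g); total anchored at standard reference values,
# incoherent = Klein-Nishina * Z/A, photoelectric = total - incoherent (coherent folded in)
energy_keV,mu_pe,mu_incoh,mu_coh
20.000,0.370257,0.200743,0
30.000,0.108913,0.194087,0
40.000,0.0470059,0.187994,0
50.000,0.0256032,0.182397,0
60.000,0.0147639,0.177236,0
80.000,0.0069679,0.168032,0
100.000,0.00393833,0.160062,0
150.000,0.00190166,0.144098,0
200.000,1e-08,0.13204,0
300.000,0.000187174,0.114813,0
400.000,1e-08,0.102868,0
500.000,1e-08,0.0939312,0
600.000,1e-08,0.0868924,0
700.000,1e-08,0.0811442,0
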