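# material: air
# density_g_cm3: 0.001205
# mass attenuation coefficients (cm2/g); total anchored at standard reference values,
# incoherent = Klein-Nishina * Z/A, photoelectric = total - incoherent (coherent folded in)
energy_keV,mu_pe,mu_incoh,mu_coh
20.000,0.592217,0.185783,0
30.000,0.174378,0.179622,0
40.000,0.0760166,0.173983,0
50.000,0.0391968,0.168803,0
60.000,0.0239728,0.164027,0
80.000,0.0114909,0.155509,0
100.000,0.00586728,0.148133,0
150.000,0.00264091,0.133359,0
200.000,0.000801018,0.122199,0
300.000,0.000743858,0.106256,0
400.000,0.000198041,0.095202,0
500.000,6.92236e-05,0.0869308,0
600.000,8.34941e-05,0.0804165,0
700.000,0.000303299,0.0750967,0
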