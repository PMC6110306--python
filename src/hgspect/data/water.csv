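# material: water
# density_g_cm3: 1.0
# mass attenuation coefficients (cm2/g); total anchored at standard reference values,
# incoherent = Klein-Nishina * Z/A, photoelectric = total - incoherent (coherent folded in)
energy_keV,mu_pe,mu_incoh,mu_coh
20.000,0.603414,0.206586,0
30.000,0.176264,0.199736,0
40.000,0.0745341,0.193466,0
50.000,0.0392943,0.187706,0
60.000,0.0236052,0.182395,0
70.000,0.0165181,0.177482,0
80.000,0.0110771,0.172923,0
100.000,0.0062795,0.16472,0
150.000,0.00270747,0.148293,0
200.000,0.00111728,0.135883,0
250.000,0.000892374,0.126108,0
300.000,0.000845384,0.118155,0
400.000,0.000137405,0.105863,0
500.000,0.000234788,0.0966652,0
600.000,0.000178521,0.0894215,0
700.000,0.000494033,0.083506,0
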