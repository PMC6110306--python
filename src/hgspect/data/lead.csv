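# material: lead
# density_g_cm3: 11.35
# mass attenuation coefficients (cm2/g); total anchored at standard reference values,
# incoherent = Klein-Nishina * Z/A, photoelectric = total - incoherent (coherent folded in)
# K_edge_keV: 88.005
# K_yield: 0.75
# K_lines_keV: 74.97:0.462,72.80:0.277,84.94:0.107,87.32:0.039
energy_keV,mu_pe,mu_incoh,mu_coh
20.000,86.2127,0.147283,0
30.000,30.1776,0.142399,0
40.000,14.2221,0.137929,0
50.000,7.90718,0.133822,0
60.000,4.89096,0.130036,0
70.000,3.26347,0.126533,0
80.000,2.29572,0.123283,0
88.004,1.86016,0.120845,0
88.006,7.56216,0.120844,0
100.000,5.43157,0.117435,0
150.000,1.90828,0.105723,0
200.000,0.902125,0.0968755,0
250.000,0.516094,0.0899065,0
300.000,0.318863,0.0842365,0
400.000,0.156827,0.0754731,0
500.000,0.092484,0.068916,0
600.000,0.0610483,0.0637517,0
700.000,0.0448657,0.0595343,0
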