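# material: nai
# density_g_cm3: 3.667
# mass attenuation coefficients (cm2/g); total anchored at standard reference values,
# incoherent = Klein-Nishina * Z/A, photoelectric = total - incoherent (coherent folded in)
# K_edge_keV: 33.17 (iodine; fluorescence escape not modeled)
energy_keV,mu_pe,mu_incoh,mu_coh
20.000,29.2857,0.158901,0
25.000,14.9943,0.156207,0
30.000,8.67725,0.153632,0
33.168,6.42078,0.152059,0
33.172,35.9434,0.152057,0
40.000,20.5,0.148809,0
50.000,10.496,0.144379,0
60.000,6.07407,0.140294,0
70.000,3.82507,0.136515,0
80.000,2.5625,0.133008,0
100.000,1.312,0.126699,0
134.000,0.54528,0.117701,0
150.000,0.388741,0.114063,0
200.000,0.164,0.104518,0
250.000,0.083968,0.0969991,0
300.000,0.0485926,0.0908818,0
400.000,0.0205,0.081427,0
500.000,0.010496,0.0743526,0
600.000,0.00607407,0.0687809,0
700.000,0.00382507,0.0642308,0
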