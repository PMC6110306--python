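# material: aluminum
# density_g_cm3: 2.699
# mass attenuation coefficients (cm2/g); total anchored at standard reference values,
# incoherent = Klein-Nishina * Z/A, photoelectric = total - incoherent (coherent folded in)
energy_keV,mu_pe,mu_incoh,mu_coh
20.000,3.26169,0.179307,0
30.000,0.954639,0.173361,0
40.000,0.400581,0.167919,0
50.000,0.205181,0.162919,0
60.000,0.11949,0.15831,0
70.000,0.0759543,0.154046,0
80.000,0.0517113,0.150089,0
100.000,0.0274306,0.142969,0
150.000,0.00908925,0.128711,0
200.000,0.00436036,0.11794,0
300.000,0.0016475,0.102553,0
400.000,0.000816378,0.0918836,0
500.000,0.000499263,0.0839007,0
600.000,0.000286473,0.0776135,0
700.000,0.000220852,0.0724791,0
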