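energy_kev,water_mu_rho_cm2_g,iodine_mu_rho_cm2_g
40,0.2683,22.10
50,0.2269,12.32
60,0.2059,7.579
80,0.1837,3.510
100,0.1707,1.942
150,0.1505,0.6978
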