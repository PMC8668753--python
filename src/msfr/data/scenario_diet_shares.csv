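species,mass_pct_2011,mass_pct_2020,energy_kj_per_g
cod,5.9,3.8,4.2
herring,4.1,1.8,6.2
sandeel,26.6,9.8,5.8
sprat,3.8,9.5,7.6
whiting,9.5,15.3,4.3
other,50.1,59.8,4.4
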