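species,energy_kj_per_g
cod,4.2
herring,6.2
sandeel,5.8
sprat,7.6
whiting,4.3
other,4.4
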