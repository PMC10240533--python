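energy_eV	rotatory_1e-40cgs
4.10	-25.0
5.30	15.0
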