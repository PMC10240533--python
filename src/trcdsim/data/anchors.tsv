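phi1_deg	phi2_deg	rotatory_1e-40cgs
165	-60	175
-165	60	-175
165	165	175
-165	-165	-175
60	-165	25
-60	165	-25
60	60	0
-60	-60	0
60	-60	0
-60	60	0
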