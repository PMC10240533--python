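label	weight
t+Zg-	0.28
t+Zt+	0.07
t+Zg+	0.00
t+Zt-	0.00
t-Zg-	0.02
t-Zt+	0.01
t-Zg+	0.00
t-Zt-	0.00
g+Zt-	0.115
g+Zg+	0.09
g+Zg-	0.035
g+Zt+	0.0225
g-Zg-	0.14
g-Zg+	0.065
g-Zt+	0.0225
g-Zt-	0.13
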