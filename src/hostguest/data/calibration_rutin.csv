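concentration_mM,absorbance
0.02,0.489
0.03,0.622
0.04,0.926
0.05,1.232
0.06,1.250
0.07,1.507
0.08,1.758
0.09,1.926
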