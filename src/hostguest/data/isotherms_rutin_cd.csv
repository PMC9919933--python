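system,host_conc_mM,absorbance
beta-CD,0,0.145
beta-CD,2,0.253
beta-CD,4,0.298
beta-CD,6,0.343
beta-CD,8,0.401
beta-CD,10,0.447
HP-beta-CD,0,0.145
HP-beta-CD,2,0.270
HP-beta-CD,4,0.443
HP-beta-CD,6,0.509
HP-beta-CD,8,0.584
HP-beta-CD,10,0.648
DM-beta-CD,0,0.145
DM-beta-CD,2,0.264
DM-beta-CD,4,0.403
DM-beta-CD,6,0.554
DM-beta-CD,8,0.678
DM-beta-CD,10,0.843
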