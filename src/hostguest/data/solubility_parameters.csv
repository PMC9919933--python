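material,delta_cal_cm3_half
rutin,12.650
beta-CD,9.658
HP-beta-CD,10.677
DM-beta-CD,12.422
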