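pollutant,c_max_mg_l,c_nat_mg_l
TN,1.5,0.4
TP,0.035,0.01
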