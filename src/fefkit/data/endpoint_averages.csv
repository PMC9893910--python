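scenario,group,value
base,ecosystem,1.41e-6
base,human_health,2.58e-7
BMP1,ecosystem,1.34e-6
BMP1,human_health,2.40e-7
BMP2,ecosystem,1.28e-6
BMP2,human_health,2.22e-7
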