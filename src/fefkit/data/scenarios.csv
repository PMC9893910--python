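scenario_id,fertilizer_reduction,irrigation_reduction,filter_strip,description
base,0,0,none,Without BMP
BMP1,0.25,0.25,slim,"25% reduction of fertilizers and water for irrigation, with slim vegetated filter strip"
BMP2,0.5,0.5,moderate,"50% reduction of fertilizers and water for irrigation with moderate vegetated filter strip"
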