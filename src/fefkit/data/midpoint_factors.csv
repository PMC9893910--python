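species,emission_compartment,category,factor
nitrate,freshwater,marine_eutrophication,0.07
nitrite,freshwater,marine_eutrophication,0.09
phosphorus,freshwater,freshwater_eutrophication,1
phosphate,freshwater,freshwater_eutrophication,33
nitrate,marine,marine_eutrophication,0.23
nitrite,marine,marine_eutrophication,0.3
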