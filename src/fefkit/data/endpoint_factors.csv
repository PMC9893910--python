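endpoint_row,group,midpoint_category,factor,unit,normalization
health_water,human_health,water_consumption,2.22e-06,DALY/m3,1.96e-04
terrestrial_water,ecosystem,water_consumption,1.35e-08,species.yr/m3,3.48e-06
freshwater_eutro,ecosystem,freshwater_eutrophication,6.71e-07,species.yr/kg P-eq,4.90e-07
freshwater_water,ecosystem,water_consumption,6.04e-13,species.yr/m3,6.16e-10
marine_eutro,ecosystem,marine_eutrophication,1.70e-09,species.yr/kg N-eq,6.12e-09
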