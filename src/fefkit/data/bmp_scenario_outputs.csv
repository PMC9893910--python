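lu_name,irrigated,caloric_value_cal_kg,scenario,yield_ton_ha,wf_m3_ton,nutrition_mcal_yr
alfalfa,True,230,base,4.5,2699.7,91
apple,True,520,base,11.2,1065.8,431
rf_barley,False,3540,base,0.9,3521.0,464
barley,True,3540,base,2.1,2095.1,200
rf_pea,False,420,base,0.5,8497.6,61
rf_grape,False,670,base,4.0,939.5,536
tobacco,True,0,base,1.9,4149.6,0
tomato,True,180,base,11.1,974.3,27
rf_wheat,False,3640,base,1.1,2926.1,4004
wheat,True,3640,base,2.8,2206.7,1303
alfalfa,True,230,BMP1,3.93,2673.5,79
apple,True,520,BMP1,9.28,1114.1,357
rf_barley,False,3540,BMP1,0.90,3499.3,464
barley,True,3540,BMP1,2.10,2048.8,200
rf_pea,False,420,BMP1,0.50,8479.7,61
rf_grape,False,670,BMP1,4.00,936.1,536
tobacco,True,0,BMP1,1.67,4221.0,0
tomato,True,180,BMP1,9.10,1028.1,22
rf_wheat,False,3640,BMP1,1.10,2909.0,4004
wheat,True,3640,BMP1,2.74,2196.1,1275
alfalfa,True,230,BMP2,3.4,2529.3,68
apple,True,520,BMP2,7.4,1144.9,284
rf_barley,False,3540,BMP2,0.9,3451.3,464
barley,True,3540,BMP2,2.1,1953.1,200
rf_pea,False,420,BMP2,0.5,8477.3,61
rf_grape,False,670,BMP2,4.0,927.7,536
tobacco,True,0,BMP2,1.5,4075.8,0
tomato,True,180,BMP2,3.7,2077.4,9
rf_wheat,False,3640,BMP2,1.1,2872.6,4004
wheat,True,3640,BMP2,2.6,2173.0,1224
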