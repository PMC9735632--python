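service,2000,2010,2020
food_production,237.08,298.60,323.01
raw_materials,221.02,280.20,304.54
water_supply,111.14,150.38,168.24
atmospheric_regulation,641.59,816.23,888.39
climate_regulation,1509.19,1928.08,2104.55
waste_treatment,497.60,640.70,701.75
water_regulation,1275.62,1734.90,1941.11
soil_formation,818.54,1040.22,1131.54
nutrient_cycling,68.99,87.48,95.04
biodiversity,620.04,792.01,864.49
recreation,277.25,354.58,387.44
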