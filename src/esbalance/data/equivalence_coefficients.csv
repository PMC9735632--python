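service,agricultural,woodland,grassland,wetland,water,construction,unutilized
food_production,0.79,0.29,0.35,0.47,0.74,0.00,0.01
raw_materials,0.37,0.66,0.52,0.47,0.21,0.00,0.03
water_supply,0.02,0.34,0.29,2.41,7.71,0.00,0.02
atmospheric_regulation,0.62,2.19,1.83,1.77,0.72,0.02,0.10
climate_regulation,0.33,6.54,4.85,3.35,2.13,0.00,0.09
waste_treatment,0.09,1.85,1.60,3.35,5.16,0.09,0.29
water_regulation,0.25,3.26,3.55,22.53,95.08,0.03,0.20
soil_formation,0.96,2.66,2.23,2.15,0.86,0.02,0.12
nutrient_cycling,0.11,0.20,0.17,0.17,0.07,0.00,0.01
biodiversity,0.12,2.42,2.03,7.32,2.37,0.02,0.11
recreation,0.06,1.06,0.89,4.40,1.76,0.01,0.05
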