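factor,2000,2010,2020
elevation,0.575534,0.544357,0.549024
slope,0.316982,0.292234,0.314731
temperature,0.365293,0.352226,0.383257
precipitation,0.316975,0.238479,0.157708
construction_share,0.736342,0.728005,0.733867
woodland_share,0.169143,0.169610,0.182215
agricultural_share,0.536538,0.517546,0.413186
population_density,0.750288,0.753995,0.776130
gdp_per_land,0.690186,0.607622,0.621392
city_development_stage,0.143244,0.134165,0.131011
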