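land_class,weight
agricultural,0.545
woodland,0.114
grassland,0.215
wetland,0.120
water,0.120
construction,0.936
unutilized,0.063
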