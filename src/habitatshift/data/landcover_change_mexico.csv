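class,start_area_km2,end_area_km2,loss_km2,gain_km2
Bare,2759,2650,141,32
Shrub/Herbaceous,393630,382501,20507,9378
Tree cover,126023,124592,3404,1973
Wetland herb,4970,4381,1178,589
Wetland tree,599,626,66,93
Water,3538,4053,630,1146
Cropland,49496,51423,8914,10840
Built-up,18869,29659,0,10790
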