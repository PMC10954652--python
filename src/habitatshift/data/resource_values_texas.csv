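class,fall_nectar_mean,fall_nectar_sd,spring_nectar_mean,spring_nectar_sd,milkweed_mean,milkweed_sd
Dev. Open,0.460,0.254,0.461,0.293,28.5,58.0
Dev. Low,0.477,0.242,0.533,0.185,9.6,23.0
Dev. Med,0.393,0.240,0.402,0.235,6.2,17.9
Dev. High,0.263,0.178,0.317,0.210,3.3,8.5
Bare,0.22,0.124,0.25,0.133,0,0
Deciduous,0.399,0.328,0.714,0.281,37.4,185.1
Evergreen,0.366,0.254,0.438,0.299,6.2,18.0
Mixed,0.378,0.324,0.594,0.325,50.8,142.7
Shrubland,0.456,0.325,0.685,0.234,8.9,46.2
Grass,0.491,0.383,0.574,0.334,66.8,195.5
Pasture,0.366,0.223,0.298,0.252,21.6,118.3
Cropland,0.329,0.286,0.308,0.286,0,0
Wetland woody,0.434,0.299,0.587,0.193,0,0
Wetland herb,0.458,0.340,0.463,0.201,0,0
Water,0,0,0,0,0,0
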