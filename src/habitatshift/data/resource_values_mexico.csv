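class,fall_nectar_mean,fall_nectar_sd,spring_nectar_mean,spring_nectar_sd,milkweed_mean,milkweed_sd
Shrub/Herbaceous,0.414,0.235,0.447,0.272,0.233,0.170
Cropland,0.439,0.254,0.418,0.293,0.263,0.212
Wetland herb,0.201,0.119,0.237,0.134,0.146,0.120
Wetland tree,0.380,0.222,0.411,0.251,0.267,0.204
Bare,0.332,0.215,0.402,0.205,0.237,0.180
Built-up,0.410,0.253,0.418,0.274,0.251,0.199
Tree cover,0.404,0.249,0.474,0.272,0.287,0.226
Water,0,0,0,0,0,0
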