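class,start_area_km2,end_area_km2,loss_km2,gain_km2
Bare,2251,1922,690,361
Cropland,43589,47101,1290,4802
Dev. High,2306,3396,0.4,1090
Dev. Low,9285,10421,495,1631
Dev. Med,5378,8127,35,2784
Dev. Open,13553,13652,1255,1355
Deciduous,18983,18105,2059,1181
Evergreen,37933,38246,4847,5160
Mixed,14837,14401,1733,1297
Grass,72387,69922,8196,5731
Pasture,72955,67612,5875,532
Shrubland,193272,192920,8012,7659
Water,16003,16969,394,1359
Wetland herb,7066,6995,1288,1217
Wetland woody,18875,18883,921,930
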