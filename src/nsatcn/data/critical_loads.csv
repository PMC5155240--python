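index,vegetation_type,usa,china,europe,other
1,Tropical evergreen forest,0.9,5.6,,3.25
2,Tropical deciduous forest,0.9,5.6,,3.25
3,Temperate evergreen broadleaf forest,0.9,2.25,1.5,1.55
4,Temperate evergreen conifer forest,0.9,2.25,1.5,1.55
5,Temperate deciduous forest,0.9,2.25,1.5,1.55
6,Boreal evergreen forest,0.57,1.25,1.25,1.02
7,Boreal deciduous forest,0.57,1.25,1.25,1.02
8,Mixed forest,0.8,2.9,1.4,1.7
9,Savanna,,5,,5
10,Grassland,,1.25,1.45,1.35
11,Dense shrubland,0.47,0.92,,0.69
12,Open shrubland,0.47,0.92,,0.69
13,Tundra,0.2,0.75,0.4,0.45
14,Desert,0,1,0,1
15,Polar desert/rock/ice,0,1,0,1
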