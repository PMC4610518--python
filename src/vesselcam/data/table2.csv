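image,level_mm,diameter_mm,calc_vol_ml,level_px,area_px2,derived_vol_ml,outlier
1,60,64,193,146,8215,193,False
2,60,64,193,11,37173,,True
3,60,64,193,147,8019,195,False
4,50,67,169,133,12106,176,False
5,50,67,169,132,9932,172,False
6,50,67,169,133,11596,176,False
7,40,69,139,109,13895,140,False
8,40,69,139,110,16630,144,False
9,40,69,139,111,18662,146,False
10,30,71,108,74,28001,103,False
11,30,71,108,75,30119,104,False
12,30,71,108,76,28314,105,False
13,20,72,73,43,41572,76,False
14,20,72,73,44,40306,76,False
15,20,72,73,44,44878,77,False
16,10,73,37,64,21279,,True
17,10,73,37,80,20109,,True
18,10,73,37,,,,True
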