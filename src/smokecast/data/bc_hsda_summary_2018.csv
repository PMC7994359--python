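hsda_id,name,population_2018,pm25_2018,pm25_2016,dispensations_2018,pct_increase_vs_2016
11,East Kootenay,84594,45.5,4.4,2245,31
12,Kootenay Boundary,82620,47.1,4.3,2170,38
13,Okanagan,387135,33.4,4.8,8988,49
14,Thompson Cariboo,234874,34.5,4.9,7475,39
21,Fraser East,319023,19.9,4.7,8087,30
22,Fraser North,685094,18.5,4.6,10895,20
23,Fraser South,856681,18.8,4.6,15256,29
31,Richmond,216300,18.7,4.7,2255,27
32,Vancouver,692228,18.5,5.3,9324,20
33,North Shore/Garibaldi,302363,18.0,4.6,5116,24
41,South Vancouver Island,413406,18.0,2.8,7190,29
42,Central Vancouver Island,291209,17.4,3.0,7855,29
43,North Vancouver Island,131256,15.5,2.4,3294,27
51,Northwest,75104,10.5,3.8,1558,7
52,Northern Interior,148845,44.8,5.2,4962,50
53,Northeast,70955,20.4,4.7,1743,22
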