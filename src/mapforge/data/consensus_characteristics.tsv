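chromosome	markers	bins	length_cM
1A	1496	534	127.38
1B	2282	470	119.27
1D	774	170	94.50
2A	1885	549	152.96
2B	2872	822	288.30
2D	728	194	100.64
3A	1437	476	177.17
3B	2261	702	149.72
3D	410	118	102.44
4A	1547	468	165.54
4B	865	342	90.15
4D	118	75	67.71
5A	1371	537	179.22
5B	2741	763	198.74
5D	391	157	118.67
6A	1953	455	144.96
6B	2022	623	120.72
6D	388	136	94.52
7A	2010	686	194.48
7B	1835	556	110.32
7D	306	127	109.45
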