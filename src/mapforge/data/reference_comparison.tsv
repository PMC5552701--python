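chromosome	n_consistent	n_new	n_inconsistent
1A	1197	223	76
1B	1856	294	132
1D	679	61	34
2A	1350	328	207
2B	2098	553	221
2D	552	103	73
3A	1104	240	93
3B	1612	509	140
3D	250	100	60
4A	1258	197	92
4B	688	138	39
4D	87	22	9
5A	1047	289	35
5B	2259	364	118
5D	231	128	32
6A	1491	338	124
6B	1568	336	118
6D	260	74	54
7A	1505	346	159
7B	1502	247	86
7D	142	92	72
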