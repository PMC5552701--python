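chromosome	n_ests	n_snps	corresponding_bins	all_bins
1A	38	50	3	6
2A	55	76	4	4
3A	44	54	4	6
4A	50	80	8	9
5A	43	63	7	9
6A	56	96	6	6
7A	49	68	8	10
1B	74	106	11	11
2B	65	100	7	8
3B	59	86	8	8
4B	31	41	6	7
5B	48	83	9	11
6B	52	85	5	6
7B	57	93	5	6
1D	19	28	2	7
2D	27	39	3	6
3D	12	19	4	6
4D	4	4	2	8
5D	12	17	3	8
6D	13	22	5	10
7D	11	11	4	7
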