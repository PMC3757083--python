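polarity	region	n_genes	n_overlap	n_in_table	printed_pct_in_table	printed_pct_filtered
gain	7	942	268	617	65	57
gain	8	487	128	347	71	63
gain	12	271	62	150	55	59
gain	15	441	138	303	69	54
gain	17	505	54	368	73	85
gain	Focals	196	74	144	73	49
gain	Total	2840	724	1929	68	62
loss	1	1064	332	768	72	57
loss	3	254	64	178	70	64
loss	4	495	63	326	66	81
loss	8	238	74	137	58	46
loss	9	214	36	127	59	72
loss	10	785	164	551	70	70
loss	11	1344	229	789	59	71
loss	13	205	22	158	77	86
loss	16 region 1	103	3	70	68	96
loss	16 region 2	177	7	118	67	94
loss	17	475	165	312	66	47
loss	18	292	105	196	67	46
loss	22	463	108	316	68	66
loss	X	376	38	172	46	78
loss	Focals	60	4	40	67	90
loss	Total	6545	1414	4258	65	67
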