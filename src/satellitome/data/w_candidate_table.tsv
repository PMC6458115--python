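superfamily	family	rul	at_content_pct	n_variants	abundance_female_pct	abundance_male_pct	divergence_female_pct	divergence_male_pct	fm_ratio
15	MmaSat155-71	71	50.7	1	0.000152	NA	15.94	NA	NA
13	MmaSat158-39	39	41.0	1	0.000093	NA	26.05	NA	NA
NA	MmaSat162-48	48	47.9	1	0.000003	NA	35.77	NA	NA
NA	MmaSat036-74	74	62.2	1	0.068342	0.000202	6.42	26.04	338.5455746
NA	MmaSat097-39	39	53.8	3	0.024361	0.000274	10.39	14.26	88.86575875
NA	MmaSat122-54	54	57.4	6	0.013087	0.000266	9.96	16.68	49.1743487
13	MmaSat063-47	47	42.6	7	0.041342	0.000943	12.26	20.11	43.81854155
4	MmaSat139-47	47	70.2	1	0.005029	0.000126	20.27	20.93	39.95338983
NA	MmaSat128-38	38	57.9	4	0.011009	0.000373	9.47	15.14	29.52932761
NA	MmaSat127-42	42	64.3	6	0.011488	0.000682	10.8	25.76	16.8478686
4	MmaSat113-52	52	61.5	5	0.016611	0.001260	12.05	18.25	13.18306878
NA	MmaSat092-46	46	54.3	11	0.028944	0.003685	14.74	33.82	7.853690304
15	MmaSat058-71	71	49.3	3	0.044410	0.006081	9.57	9.95	7.303293426
7	MmaSat153-40	40	65.0	1	0.000377	0.000073	26.6	15.54	5.141818182
8	MmaSat061-33	33	45.5	1	0.042897	0.008779	10.86	12.19	4.886482382
8	MmaSat151-33	33	48.5	1	0.000646	0.000158	26.07	32.66	4.086003373
NA	MmaSat111-33	33	57.6	3	0.017022	0.004862	16.72	30.69	3.501042124
12	MmaSat145-67	67	55.2	1	0.001107	0.000370	10.57	10.84	2.994227994
NA	MmaSat017-72	72	57.9	6	0.128001	0.056303	9.01	9.7	2.273440312
8	MmaSat150-31	31	58.1	1	0.000685	0.000319	15.86	21.31	2.147157191
NA	MmaSat152-31	31	61.3	1	0.000413	0.000211	29.91	31.53	1.957016435
1	MmaSat009-53	53	58.5	5	0.251590	0.137215	9.15	10.23	1.833544197
NA	MmaSat099-31	31	61.3	7	0.023434	0.013165	10.89	11.75	1.779963135
NA	MmaSat154-30	30	43.3	1	0.000305	0.000181	25.44	32.57	1.685840708
NA	MmaSat029-32	32	46.9	8	0.084698	0.050374	14.12	15.34	1.68137639
NA	MmaSat107-44	44	54.6	1	0.017750	0.010899	5.84	7.03	1.628611974
NA	MmaSat098-37	37	45.9	7	0.024099	0.014946	13.69	15.41	1.61236797
NA	MmaSat048-1298	1298	49.2	1	0.058376	0.036578	6.3	7.51	1.595953778
5	MmaSat118-66	66	68.2	2	0.015043	0.009519	9.16	10.05	1.580305365
2	MmaSat108-295	295	60.3	1	0.017656	0.011712	6.92	9.63	1.507559543
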