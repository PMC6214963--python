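family	members	reads_BR	reads_BS	total	ratio	conserved
miR156/157	14	40	40	80	1.00	1
miR159	12	2305	1840	4145	0.80	1
miR160	4	29	17	46	0.59	1
miR162	4	424	358	782	0.84	1
miR164	7	88	66	154	0.75	1
miR165/166	14	2818	2359	5177	0.84	1
miR167	8	321	309	630	0.96	1
miR168	3	31	19	50	0.61	1
miR169	8	553	256	809	0.46	1
miR171	8	46	33	79	0.72	1
miR172	8	55	33	88	0.60	1
miR173	1	0	1	1	—	1
miR319	10	1883	1364	3247	0.72	1
miR390	5	104	83	187	0.80	1
miR393	2	0	2	2	—	1
miR394	3	3	1	4	0.33	1
miR395	8	17	16	33	0.94	1
miR396	11	8218	9997	18215	1.22	1
miR397	1	2	2	4	1.00	1
miR398	3	105	76	181	0.72	1
miR399	6	1984	883	2867	0.45	1
miR408	2	4	0	4	0.00	1
miR482	4	4	2	6	0.50	1
miR535	1	1	0	1	0.00	1
miR403	1	0	1	1	—	0
miR414	1	2	0	2	0.00	0
miR477	6	92	50	142	0.54	0
miR529	1	0	2	2	—	0
miR827	1	138	84	222	0.61	0
miR845	5	69	67	136	0.97	0
miR854	1	1	0	1	0.00	0
miR858	1	156	18	174	0.12	0
miR894	1	226	184	410	0.81	0
miR1511	2	80	61	141	0.76	0
miR1863	2	39	36	75	0.92	0
miR2111	6	59	71	130	1.20	0
miR2118	1	1	0	1	0.00	0
miR3630	1	1	1	2	1.00	0
miR502	1	3	5	8	1.67	0
miR5293	1	1	0	1	0.00	0
miR5298	1	0	1	1	—	0
miR5654	1	1	0	1	0.00	0
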