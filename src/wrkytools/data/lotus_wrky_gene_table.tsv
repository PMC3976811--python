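annotation_id	gene_name	group	chromosome	location	pseudogene
CM0012.480.r2.a	LjWRKY1	I	1	58226335	0
CM0032.140.r2.d	LjWRKY2	IIc	1	17061228	0
CM0032.170.r2.d	LjWRKY3	IIc	1	17093440	0
CM0105.740.r2.a	LjWRKY4	III	1	65847050	0
CM0122.1300.r2.m	LjWRKY5	IIb	1	62472860	0
CM0122.2160.r2.d	LjWRKY6	IIe	1	63001936	0
CM0123.240.r2.m	LjWRKY7	IIb	1	6329403	0
CM0133.780.r2.m	LjWRKY8	IIc	1	23799861	0
CM0147.250.r2.m	LjWRKY9	IIc	1	42532993	0
CM0315.160.r2.m	LjWRKY10	IIb	1	35572836	0
CM0320.110.r2.d	LjWRKY11	III	1	15934171	0
CM0433.90.r2.d	LjWRKY12	IIa	1	24711963	0
CM1413.480.r2.d	LjWRKY13	I	1	34039015	1
CM1413.70.r2.d	LjWRKY14	IIe	1	33660455	0
CM0058.50.r2.m	LjWRKY15	I	2	34643392	0
CM0060.250.r2.a	LjWRKY16	III	2	31851611	0
CM0120.570.r2.d	LjWRKY17	IIc	2	20356545	0
CM0191.300.r2.a	LjWRKY18	I	2	43680266	0
CM0608.50.r2.m	LjWRKY19	IIx	2	20505843	0
CM0608.70.r2.m	LjWRKY20	IIc	2	20514487	0
CM1895.20.r2.m	LjWRKY21	III	2	34148852	0
LjB06N21.120.r2.a	LjWRKY22	IIb	2	42171450	0
CM0243.470.r2.m	LjWRKY23	IIb	3	39562863	0
CM0936.60.r2.d	LjWRKY24	I	3	18082486	0
LjT41F16.60.r2.d	LjWRKY25	III	3	33152607	0
LjT45M09.130.r2.d	LjWRKY26	IIa	3	474491	0
CM0004.1290.r2.m	LjWRKY27	III	4	40133355	0
CM0004.880.r2.d	LjWRKY28	IIe	4	39837881	0
CM0007.1120.r2.a	LjWRKY29	IIc	4	3358814	0
CM0046.1360.r2.d	LjWRKY30	IIe	4	36250655	0
CM0179.130.r2.m	LjWRKY31	I	4	28951362	0
CM0227.580.r2.m	LjWRKY32	I	4	10519027	0
CM0244.860.r2.m	LjWRKY33	IId	4	30871468	0
CM0333.340.r2.d	LjWRKY34	IIc	4	32856509	0
CM0333.510.r2.a	LjWRKY35	IIc	4	32985615	0
CM0337.220.r2.d	LjWRKY36	IIb	4	3852684	0
CM0432.2010.r2.d	LjWRKY37	IIx	4	7529554	1
CM0536.110.r2.d	LjWRKY38	IId	4	13585366	0
CM1622.200.r2.a	LjWRKY39	IIc	4	37600439	0
CM0040.550.r2.d	LjWRKY40	IIa	5	5190496	1
CM0040.670.r2.d	LjWRKY41	IIa	5	5268779	1
CM0239.70.r2.d	LjWRKY42	IIc	5	25979555	0
CM0852.250.r2.d	LjWRKY43	IId	5	2801268	0
CM1574.880.r2.m	LjWRKY44	IId	5	18726557	0
CM0037.660.r2.m	LjWRKY45	I	6	14396956	0
CM1034.270.r2.d	LjWRKY46	IIe	6	19990091	0
LjT11E14.30.r2.m	LjWRKY47	I	6	9459959	0
LjT46F23.30.r2.d	LjWRKY48	IId	6	17672968	0
LjSGA_012799.2	LjWRKY49	IIc	nd	nd	1
LjSGA_014003.1	LjWRKY50	I	nd	nd	1
LjSGA_015261.1	LjWRKY51	I	nd	nd	1
LjSGA_020468.1	LjWRKY52	I	nd	nd	0
LjSGA_021425.1	LjWRKY53	III	nd	nd	0
LjSGA_025444.2	LjWRKY54	IIe	nd	nd	0
LjSGA_038153.1	LjWRKY55	nd	nd	nd	0
LjSGA_038411.1	LjWRKY56	nd	nd	nd	0
LjSGA_046833.1	LjWRKY57	IIa	nd	nd	0
LjSGA_050544.1	LjWRKY58	nd	nd	nd	0
LjSGA_055568.1	LjWRKY59	IIe	nd	nd	0
LjSGA_058050.1	LjWRKY60	IIe	nd	nd	1
LjSGA_058052.1	LjWRKY61	nd	nd	nd	0
LjSGA_066036.1	LjWRKY62	nd	nd	nd	0
LjSGA_069579.1	LjWRKY63	IIc	nd	nd	1
LjSGA_074792.1	LjWRKY64	IIe	nd	nd	0
LjSGA_084767.1	LjWRKY65	nd	nd	nd	0
LjSGA_086809.1	LjWRKY66	nd	nd	nd	0
LjSGA_091481.1	LjWRKY67	nd	nd	nd	0
LjSGA_107504.1	LjWRKY68	nd	nd	nd	0
LjSGA_116672.1	LjWRKY69	nd	nd	nd	0
LjT10P12.70.r2.d	LjWRKY70	IIb	nd	nd	0
LjT45D24.80.r2.d	LjWRKY71	IIb	nd	nd	0
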